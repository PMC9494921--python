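"""Per-array firing metrics from voltage traces or spike-event tables.

The processing chain mirrors standard multi-electrode-array practice:

1. raw voltage (12 kHz) is band-pass filtered (Butterworth 200-2500 Hz,
   3rd order, forward-backward for zero phase);
2. spikes are detected where |v(t)| exceeds a "crossing threshold" of
   5.5 x the RMS of the filtered trace over a trailing 10 ms window,
   with rising-edge detection and a 1 ms refractory hold-off;
3. spurious events from high-noise electrodes are removed by a plate-level
   rule: events whose crossing threshold exceeds mean + 3 SD of all
   crossing thresholds are excluded;
4. the array's mean firing rate is MFR = n/s over the pooled electrodes,
   reported on the log scale as log10[(n + 1)/s] so that silent arrays
   (n = 0) remain defined.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .exceptions import DegenerateInputError, InvalidInputError


@dataclass(frozen=True)
class RecordingMeta:
    """Acquisition parameters for raw-trace spike detection."""

    duration_s: float
    sampling_hz: float = 12000.0
    band_low_hz: float = 200.0
    band_high_hz: float = 2500.0
    detect_sd: float = 5.5
    rms_window_ms: float = 10.0
    refractory_ms: float = 1.0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise InvalidInputError("duration_s must be positive")
        if not 0 < self.band_low_hz < self.band_high_hz < self.sampling_hz / 2:
            raise InvalidInputError(
                "need 0 < band_low < band_high < Nyquist frequency")


@dataclass(frozen=True)
class SpikeEvent:
    """A detected firing event on one electrode."""

    electrode: int
    t_s: float
    threshold_uv: float


@dataclass(frozen=True)
class ArrayMetrics:
    """Firing metrics for one array at one recording timepoint."""

    array_id: str
    n_spikes: int
    duration_s: float
    mfr_hz: float
    log10hz: float


def bandpass_filter(trace: np.ndarray, meta: RecordingMeta) -> np.ndarray:
    """Zero-phase 3rd-order Butterworth band-pass of the raw voltage."""
    sos = signal.butter(3, [meta.band_low_hz, meta.band_high_hz],
                        btype="bandpass", fs=meta.sampling_hz, output="sos")
    return signal.sosfiltfilt(sos, trace)


def _trailing_rms(x: np.ndarray, window: int) -> np.ndarray:
    """Causal RMS over a trailing window; grown from the start for t < window."""
    sq = np.concatenate([[0.0], np.cumsum(x * x)])
    n = x.size
    idx = np.arange(1, n + 1)
    lo = np.maximum(idx - window, 0)
    return np.sqrt((sq[idx] - sq[lo]) / (idx - lo))


def detect_spikes(trace: np.ndarray, meta: RecordingMeta,
                  electrode: int = 0) -> list[SpikeEvent]:
    """Threshold-crossing spike detection on one electrode's voltage trace.

    An event fires at each sample where the absolute filtered voltage first
    exceeds 5.5 x the trailing-window RMS (rising edge), and re-triggering
    is suppressed for ``refractory_ms`` after each event. The crossing
    threshold in microvolts is stored with each event; it is the quantity
    pooled plate-wide by :func:`exclude_noise_events`.
    """
    trace = np.asarray(trace, dtype=float)
    window = int(round(meta.rms_window_ms / 1000.0 * meta.sampling_hz))
    if trace.size < window:
        raise DegenerateInputError(
            f"trace ({trace.size} samples) shorter than the RMS window ({window})")
    if not np.all(np.isfinite(trace)):
        raise InvalidInputError("trace contains non-finite samples")

    filtered = bandpass_filter(trace, meta)
    sigma = _trailing_rms(filtered, window)
    thr = meta.detect_sd * sigma
    above = np.abs(filtered) > thr
    rising = above & ~np.concatenate([[False], above[:-1]])
    candidates = np.nonzero(rising)[0]

    hold = int(round(meta.refractory_ms / 1000.0 * meta.sampling_hz))
    events: list[SpikeEvent] = []
    last = -1 - hold
    for i in candidates:
        if i - last <= hold:
            continue
        last = i
        events.append(SpikeEvent(electrode=electrode,
                                 t_s=i / meta.sampling_hz,
                                 threshold_uv=float(thr[i])))
    return events


def events_to_table(events: list[SpikeEvent], well: str) -> pd.DataFrame:
    """SpikeEvent list -> interchange table (well, electrode, t_s, threshold_uV)."""
    return pd.DataFrame({
        "well": well,
        "electrode": [e.electrode for e in events],
        "t_s": [e.t_s for e in events],
        "threshold_uV": [e.threshold_uv for e in events],
    })


def noise_upper_limit(thresholds: np.ndarray) -> float:
    """Plate-level exclusion limit: mean + 3 x sample SD of all crossing
    thresholds pooled over every spike event in the recording."""
    thresholds = np.asarray(thresholds, dtype=float)
    sd = thresholds.std(ddof=1) if thresholds.size > 1 else 0.0
    return float(thresholds.mean() + 3.0 * sd)


def exclude_noise_events(events: pd.DataFrame
                         ) -> tuple[pd.DataFrame, float]:
    """Drop events whose crossing threshold exceeds the plate-level limit.

    The limit is computed once from the full pooled event table and applied
    in a single pass (no recomputation on the reduced set). Row order is
    preserved. An empty table returns (empty, nan) with a warning.
    """
    if len(events) == 0:
        warnings.warn("no spike events; noise exclusion limit undefined",
                      stacklevel=2)
        return events.copy(), float("nan")
    limit = noise_upper_limit(events["threshold_uV"].to_numpy())
    kept = events.loc[events["threshold_uV"] <= limit].copy()
    return kept, limit


def array_metrics(n_spikes: int, duration_s: float,
                  array_id: str = "") -> ArrayMetrics:
    """MFR = n/s and log10[(n + 1)/s] for one array (electrodes pooled)."""
    if duration_s <= 0:
        raise InvalidInputError("duration_s must be positive")
    if n_spikes < 0:
        raise InvalidInputError("n_spikes must be non-negative")
    return ArrayMetrics(array_id=array_id, n_spikes=int(n_spikes),
                        duration_s=float(duration_s),
                        mfr_hz=n_spikes / duration_s,
                        log10hz=float(np.log10((n_spikes + 1) / duration_s)))


def table_to_metrics(events: pd.DataFrame, duration_s: float,
                     wells: list[str] | None = None) -> pd.DataFrame:
    """Per-array metrics from a (noise-excluded) event table.

    ``wells`` lists every array in the recording so that silent arrays are
    retained with n = 0 (the log transform exists precisely for them).
    Returns a frame with columns array, n_spikes, duration_s, mfr_hz,
    log10hz.
    """
    counts = events.groupby("well").size() if len(events) else pd.Series(dtype=int)
    if wells is None:
        wells = list(counts.index)
    rows = []
    for w in wells:
        m = array_metrics(int(counts.get(w, 0)), duration_s, array_id=w)
        rows.append({"array": m.array_id, "n_spikes": m.n_spikes,
                     "duration_s": m.duration_s, "mfr_hz": m.mfr_hz,
                     "log10hz": m.log10hz})
    return pd.DataFrame(rows)
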