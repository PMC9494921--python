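"""Plain-text interchange formats tying the pipeline stages together.

Everything is CSV/TSV with a header row; missing LFQ entries are empty
cells. Column layouts are documented in docs/FORMATS.md. The vendor's
proprietary binary recording format is out of scope — recordings enter as
the extracted spike-event CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import InvalidInputError
from .proteome_prep import LfqMatrix

SPIKE_COLUMNS = ["well", "electrode", "t_s", "threshold_uV"]
METRIC_COLUMNS = ["array", "n_spikes", "duration_s", "mfr_hz", "log10hz"]
PHENOTYPE_COLUMNS = ["individual", "category", "assay", "ni_percent",
                     "dlog10hz"]
SAMPLE_COLUMNS = ["individual", "run", "category"]


def read_spikes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, SPIKE_COLUMNS, path)
    return df


def write_spikes(df: pd.DataFrame, path: str | Path) -> None:
    df[SPIKE_COLUMNS].to_csv(path, index=False)


def read_array_metrics(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require(df, METRIC_COLUMNS, path)
    return df


def write_array_metrics(df: pd.DataFrame, path: str | Path) -> None:
    df[METRIC_COLUMNS].to_csv(path, sep="\t", index=False)


def read_lfq(lfq_path: str | Path, samples_path: str | Path) -> LfqMatrix:
    """LFQ matrix (rows proteins, columns individuals, empty = missing)
    plus the sample sheet carrying run and category labels."""
    values = pd.read_csv(lfq_path, sep="\t", index_col=0)
    samples = pd.read_csv(samples_path, sep="\t")
    _require(samples, SAMPLE_COLUMNS, samples_path)
    samples = samples.set_index("individual")
    missing = set(values.columns) - set(samples.index)
    if missing:
        raise InvalidInputError(
            f"individuals in {lfq_path} without sample metadata: "
            f"{sorted(missing)[:5]}")
    return LfqMatrix(values=values, runs=samples["run"],
                     categories=samples["category"], stage="raw")


def write_lfq(matrix: LfqMatrix, lfq_path: str | Path,
              samples_path: str | Path | None = None) -> None:
    matrix.values.to_csv(lfq_path, sep="\t", index_label="protein")
    if samples_path is not None:
        samples = pd.DataFrame({
            "individual": matrix.values.columns,
            "run": matrix.runs.reindex(matrix.values.columns).to_numpy(),
            "category": (matrix.categories.reindex(matrix.values.columns)
                         if matrix.categories is not None else ""),
        })
        samples.to_csv(samples_path, sep="\t", index=False)


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require(df, PHENOTYPE_COLUMNS, path)
    return df


def write_phenotypes(df: pd.DataFrame, path: str | Path) -> None:
    df[PHENOTYPE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_measures(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.name != "individual":
        raise InvalidInputError(
            f"{path}: first column must be 'individual'")
    return df


def write_measures(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="individual")


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_manifest(manifest: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True,
                                     default=str) + "\n")


def _require(df: pd.DataFrame, columns: list[str], path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise InvalidInputError(f"{path}: missing columns {missing}")


# ---------------------------------------------------------------------------
# validation report
# ---------------------------------------------------------------------------

def validate_tables(spikes: str | Path | None = None,
                    lfq: str | Path | None = None,
                    samples: str | Path | None = None,
                    phenotypes: str | Path | None = None,
                    measures: str | Path | None = None) -> list[str]:
    """Schema, cross-reference and unit-sanity checks over the interchange
    tables. Returns a list of failure descriptions (empty = all clean)."""
    failures: list[str] = []

    pheno_df = None
    lfq_matrix = None

    if spikes is not None:
        try:
            sp = read_spikes(spikes)
            if (sp["t_s"] < 0).any():
                failures.append("spikes: negative timestamps")
            if (sp["threshold_uV"] <= 0).any():
                failures.append("spikes: non-positive crossing thresholds")
            if sp["electrode"].min() < 0:
                failures.append("spikes: negative electrode index")
        except Exception as exc:  # schema failure is itself a finding
            failures.append(f"spikes: {exc}")

    if lfq is not None and samples is not None:
        try:
            lfq_matrix = read_lfq(lfq, samples)
            vals = lfq_matrix.values.to_numpy(dtype=float)
            if np.nanmin(vals) < 0:
                failures.append("lfq: negative abundances")
            if lfq_matrix.values.columns.has_duplicates:
                failures.append("lfq: duplicate individual ids")
            if lfq_matrix.values.index.has_duplicates:
                failures.append("lfq: duplicate protein ids")
        except Exception as exc:
            failures.append(f"lfq: {exc}")

    if phenotypes is not None:
        try:
            pheno_df = read_phenotypes(phenotypes)
            if pheno_df["individual"].duplicated().any():
                failures.append("phenotypes: duplicate individual ids")
            ni = pheno_df["ni_percent"].dropna()
            if ((ni < 0) | (ni > 110)).any():
                failures.append("phenotypes: ni_percent outside [0, 110]%")
            dl = pheno_df["dlog10hz"].dropna()
            if ((dl < -5) | (dl > 2)).any():
                failures.append("phenotypes: implausible dlog10hz values")
        except Exception as exc:
            failures.append(f"phenotypes: {exc}")

    if pheno_df is not None and lfq_matrix is not None:
        absent = set(pheno_df["individual"]) - set(lfq_matrix.values.columns)
        if absent:
            failures.append(
                "cross-reference: phenotype individuals absent from lfq "
                f"columns: {sorted(absent)[:5]}")

    if measures is not None:
        try:
            ms = read_measures(measures)
            if (ms.select_dtypes("number") < 0).any().any():
                failures.append("measures: negative concentrations")
            if pheno_df is not None:
                absent = set(ms.index) - set(pheno_df["individual"])
                if absent:
                    failures.append(
                        "cross-reference: measure individuals absent from "
                        f"phenotypes: {sorted(absent)[:5]}")
        except Exception as exc:
            failures.append(f"measures: {exc}")

    return failures
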