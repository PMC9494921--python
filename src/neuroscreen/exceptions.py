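"""Exception hierarchy shared across the pipeline stages."""


class NeuroscreenError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(NeuroscreenError, ValueError):
    """A configuration object violates its invariants."""


class InvalidInputError(NeuroscreenError, ValueError):
    """Input data violates a stage's preconditions (non-finite, wrong sign...)."""


class DegenerateInputError(NeuroscreenError, ValueError):
    """Input is structurally too small for the operation (too short, too few rows)."""


class InfeasibleDesignError(NeuroscreenError, ValueError):
    """A requested experimental design cannot be realised from the available pool."""


class ContractError(NeuroscreenError, ValueError):
    """An inter-stage contract was violated (stage order, dimension mismatch...)."""
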