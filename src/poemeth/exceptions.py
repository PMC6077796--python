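"""Exception hierarchy shared across the pipeline stages."""


class PoemethError(Exception):
    """Base class for all package errors."""


class SpecificationError(PoemethError, ValueError):
    """Invalid simulation or analysis specification (bad MAF, positions, ...)."""


class GenerationError(PoemethError, RuntimeError):
    """A simulation request that cannot be satisfied (e.g. infeasible poe_r2)."""


class ConsistencyError(PoemethError, ValueError):
    """Sample/metadata mismatch between pipeline inputs."""


class InputError(PoemethError, ValueError):
    """Malformed input file or out-of-range value."""


class DegenerateDesignError(PoemethError, RuntimeError):
    """Regression design without usable POE contrast (rank deficient or
    a heterozygote ordering absent)."""


class CalibrationError(PoemethError, RuntimeError):
    """A requested operating point (e.g. target AUC) is unattainable."""
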