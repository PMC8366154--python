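"""Exception hierarchy for prospmatch."""


class ProspmatchError(Exception):
    """Base class for all package errors."""


class ConfigError(ProspmatchError, ValueError):
    """A configuration value violates its constraint; message names the field."""


class InputError(ProspmatchError, ValueError):
    """Malformed input data (e.g. mixed patient ids, unsorted schedule)."""


class DegenerateInputError(ProspmatchError, ValueError):
    """Structurally valid input on which the operation is undefined
    (empty arm, zero-variance matching variable, ...)."""


class UndefinedSMDError(DegenerateInputError):
    """Standardized mean difference has a zero denominator with unequal means."""


class SimulationError(ProspmatchError, RuntimeError):
    """A Monte-Carlo run failed beyond the tolerated failure fraction."""
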