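"""Exception hierarchy.

All package errors derive from :class:`PestiscreenError` so callers (and the
CLI) can distinguish domain failures (exit code 1) from usage errors (exit
code 2, handled by click).
"""


class PestiscreenError(Exception):
    """Base class for all pestiscreen errors."""


class ConfigurationError(PestiscreenError):
    """A config file, column mapping, or reference table is unusable."""


class ValidationError(PestiscreenError):
    """Input data violates a documented invariant."""


class RowParseError(ValidationError):
    """A specific CSV row could not be parsed; carries the 0-based row index."""

    def __init__(self, row: int, message: str):
        super().__init__(f"row {row}: {message}")
        self.row = row


class StructureError(PestiscreenError):
    """A SMILES string could not be parsed; carries the offending string."""

    def __init__(self, smiles: str, message: str = ""):
        super().__init__(message or f"unparseable SMILES: {smiles!r}")
        self.smiles = smiles


class DescriptorError(PestiscreenError):
    """A required molecular descriptor is missing or non-finite."""


class ParameterError(PestiscreenError):
    """A model parameter is out of its admissible range."""


class CategoryLookupError(PestiscreenError):
    """A functional-class/MOA category is absent from the bounds table."""


class ComparabilityError(PestiscreenError):
    """Two assessments were produced under different configurations."""


class DegenerateFitError(PestiscreenError):
    """A regression or confidence interval was requested on degenerate data."""
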