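"""Exception hierarchy for asd_swnet.

All package-specific failures derive from :class:`AsdSwnetError` so callers
can catch one base class at pipeline boundaries.
"""


class AsdSwnetError(Exception):
    """Base class for all asd_swnet errors."""


class FormatError(AsdSwnetError, ValueError):
    """A file is structurally malformed (e.g. ragged rows, bad header)."""


class RejectedSubjectError(AsdSwnetError, ValueError):
    """A subject's data contain missing or non-numeric cells.

    Callers iterating over a cohort may catch this and skip the subject;
    the loader logs every exclusion.
    """


class DimensionError(AsdSwnetError, ValueError):
    """Shapes or dimensions of inputs do not match what an operation needs."""


class ConfigError(AsdSwnetError, ValueError):
    """An invalid configuration value."""


class NumericalError(AsdSwnetError, ArithmeticError):
    """A numerical invariant was violated (e.g. negative distance radicand)."""


class LeakageError(AsdSwnetError, RuntimeError):
    """Test subjects leaked into a fitting or augmentation step."""
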