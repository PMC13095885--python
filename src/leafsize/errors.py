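"""Exception hierarchy for leafsize.

All errors raised by the library derive from :class:`LeafSizeError` so callers
can catch the whole family with one clause; validation errors additionally
derive from ``ValueError``.
"""


class LeafSizeError(Exception):
    """Base class for all leafsize errors."""


class ParameterDomainError(LeafSizeError, ValueError):
    """A model parameter violates its domain invariant (e.g. cm <= 0)."""


class TlnRangeError(LeafSizeError, ValueError):
    """Requested total leaf number lies outside the plausible range."""


class PositionDomainError(LeafSizeError, ValueError):
    """Leaf position outside the model domain (positions start at 1)."""


class GroupSizeError(LeafSizeError, ValueError):
    """A TLN group has too few observations to fit."""


class DegenerateDataError(LeafSizeError, ValueError):
    """Regression input is rank-deficient (e.g. a single distinct TLN)."""


class CalibrationError(LeafSizeError, ValueError):
    """Species calibration cannot proceed (insufficient groups etc.)."""


class SchemaError(LeafSizeError, ValueError):
    """A delimited-text input violates the leaf-record schema."""
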