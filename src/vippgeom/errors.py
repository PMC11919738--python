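"""Exception types shared across the toolkit."""


class VippGeomError(Exception):
    """Base class for all toolkit errors."""


class InvalidArgumentError(VippGeomError, ValueError):
    """An argument violates a documented precondition."""


class FormatError(VippGeomError, ValueError):
    """A file could not be parsed; the message names the offending field."""


class InsufficientArcError(VippGeomError, ValueError):
    """A spiral trace spans less than the minimum angular arc (1.5 turns)."""


class TraceError(VippGeomError, ValueError):
    """A trace is not a single-armed monotone spiral after angle unwrapping."""


class PlacementError(VippGeomError, RuntimeError):
    """Objects could not be placed in the synthetic field without overlap."""


class ResourceLimitError(VippGeomError, RuntimeError):
    """A simulation would exceed a hard resource bound (e.g. subunit count)."""
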