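"""Exception hierarchy shared across the package."""


class AllokinError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(AllokinError, ValueError):
    """A numeric argument violates a documented precondition."""


class ParseError(AllokinError, ValueError):
    """A text input could not be parsed; message carries the line number."""


class SelectionError(AllokinError, ValueError):
    """An atom/residue selection is empty or inconsistent."""


class GridMismatchError(AllokinError, ValueError):
    """Two grids expected to share axes do not."""


class NoPathError(AllokinError, RuntimeError):
    """Source and target are not connected on the (masked) grid."""


class InsufficientDataError(AllokinError, ValueError):
    """Too few observations for the requested statistic."""
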