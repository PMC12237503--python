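"""Exception hierarchy shared across dapcy modules."""


class DapcyError(Exception):
    """Base class for all dapcy errors."""


class InputError(DapcyError):
    """Unreadable or empty input file."""


class FormatError(DapcyError):
    """Structurally invalid input (e.g. BED/BIM/FAM dimension mismatch)."""


class ParameterError(DapcyError, ValueError):
    """Parameter outside its documented range."""


class ShapeError(DapcyError, ValueError):
    """Dimension mismatch between arrays/models."""


class StratificationError(DapcyError):
    """A class is too small for the requested stratified split."""


class FoldError(DapcyError):
    """A cross-validation fold is unusable (e.g. a class vanished from training)."""


class SingularScatterError(DapcyError):
    """Within-class scatter is singular and cannot support a discriminant fit."""


class ModelFormatError(DapcyError):
    """Model archive is corrupt or has an incompatible format version."""
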