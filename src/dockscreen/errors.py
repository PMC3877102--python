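"""Exception types shared across the package."""


class DockscreenError(Exception):
    """Base class for all package-specific errors."""


class FormatError(DockscreenError):
    """A structure/pose file could not be parsed; message names the offending record."""


class EmptyStructureError(FormatError):
    """A parsed structure contained no atoms."""


class NeedsEmbeddingError(DockscreenError):
    """A connectivity-only molecule (e.g. from SMILES) was used where 3D coordinates are required."""


class SchemaMismatchError(DockscreenError):
    """A feature vector does not match the schema a fitted model was trained on."""


class DegenerateLabelsError(DockscreenError):
    """A training table has too few examples or too few distinct labels to fit."""


class UndefinedCorrelationError(DockscreenError):
    """Pearson correlation requested on a zero-variance input."""
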