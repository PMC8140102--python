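"""Exception hierarchy shared across the package."""


class EnsembleDiffError(Exception):
    """Base class for all package errors."""


class ValidationError(EnsembleDiffError, ValueError):
    """An input violates a documented precondition or invariant."""


class FormatError(EnsembleDiffError, IOError):
    """A file could not be parsed or is inconsistent with its topology."""


class DegenerateGeometryError(EnsembleDiffError, ValueError):
    """Coordinates are collinear/coincident and a rotation is ill-defined."""


class InfeasibleConstraintError(EnsembleDiffError, ValueError):
    """An EM count window has zero probability for the given batch."""


class CheckpointError(EnsembleDiffError, IOError):
    """A model checkpoint is missing fields or has an unknown version."""
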