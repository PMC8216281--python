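"""Exception types shared across the pipeline."""


class ConascreenError(Exception):
    """Base class for all package errors."""


class PlacementError(ConascreenError):
    """Bead placement could not satisfy the separation constraint."""


class ConfigError(ConascreenError):
    """Invalid configuration, layout, or parameter value."""


class InputError(ConascreenError):
    """Invalid input data (image geometry, dose design, ...)."""


class IndexingError(ConascreenError):
    """Image directory does not form a complete well/field/channel index."""


class QCError(ConascreenError):
    """Plate quality-control statistics could not be computed."""


class ZPrimeUndefinedError(QCError):
    """Z' is undefined because the control means coincide."""
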