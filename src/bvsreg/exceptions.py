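"""Exception types shared across the package."""


class BvsError(Exception):
    """Base class for all package errors."""


class InvalidDataError(BvsError, ValueError):
    """Input data violate a model contract (shape, range, finiteness)."""


class InvalidStateError(BvsError, RuntimeError):
    """A chain state became inconsistent (non-finite draw or residual)."""


class DesignError(BvsError, ValueError):
    """A simulation design is internally inconsistent."""


class ParseError(BvsError, ValueError):
    """An on-disk file violates its format contract.

    Carries human-readable coordinates (row/column identifiers) when known.
    """


class AlignmentError(BvsError, ValueError):
    """Individuals or SNPs cannot be aligned across inputs."""


class UndefinedRocError(BvsError, ValueError):
    """ROC requested on a truth set with no causal or no non-causal SNPs."""


class ConfigError(BvsError, ValueError):
    """A run configuration is invalid."""
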