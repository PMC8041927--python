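"""Exception hierarchy shared across the package."""


class M6acallError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(M6acallError):
    """Invalid or infeasible configuration (simulation or run parameters)."""


class AnnotationError(M6acallError):
    """Malformed annotation input; message names the offending line or id."""


class InputError(M6acallError):
    """Missing or malformed data table."""


class ValidationError(M6acallError):
    """Domain-level precondition violated (e.g. swapped tumor diameters)."""
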