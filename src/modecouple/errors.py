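"""Exception hierarchy.

Configuration problems and physics problems are kept distinct so the CLI can
map them to different exit codes.
"""


class ModeCoupleError(Exception):
    """Base class for all package errors."""


class ConfigError(ModeCoupleError):
    """Invalid configuration, model specification, or input file."""


class ParseError(ConfigError):
    """Malformed input file; carries the offending line number when known."""

    def __init__(self, message, line=None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ComputationError(ModeCoupleError):
    """A calculation could not be carried out on valid input."""


class DegenerateGeometryError(ComputationError):
    """Geometry collapsed (non-positive bond length)."""


class InvalidStateError(ComputationError):
    """Electronic state specification is unphysical (e.g. too many electrons)."""


class DegenerateLevelError(ComputationError):
    """Analytic eigenvalue derivative requested for a (near-)degenerate level.

    Hellmann-Feynman derivatives are only defined for isolated levels; a
    degenerate pair requires a subspace (degenerate perturbation theory)
    treatment instead.
    """


class CapabilityError(ComputationError):
    """Backend does not provide a required capability (e.g. excited states)."""
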