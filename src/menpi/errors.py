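"""Exception hierarchy shared across the simulator stages."""


class MenpiError(Exception):
    """Base class for all package-specific errors."""


class GeometryError(MenpiError):
    """Invalid or out-of-bounds geometry (radii ordering, spot outside tissue, ...)."""


class ConfigurationError(MenpiError):
    """Invalid configuration value (missing conductivity label, bad loop model, ...)."""


class FormatError(MenpiError):
    """File content has the wrong structure (e.g. a 4-D volume where 3-D is required)."""


class ValidationError(MenpiError):
    """Data violates a domain invariant (unknown tissue labels, ...)."""


class SolverError(MenpiError):
    """Iterative solver failed to converge or the problem has no solution."""


class ShapeError(MenpiError):
    """Grids that must be aligned have mismatching shapes."""


class ModeError(MenpiError):
    """Particle-mode mismatch (e.g. demodulating with swapped MN/MEN images)."""


class QuantumRegimeWarning(UserWarning):
    """Inter-particle spacing below 5 nm: quantum-mechanical interactions ignored."""
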