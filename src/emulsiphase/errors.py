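"""Exception hierarchy shared across the pipeline."""


class EmulsiphaseError(Exception):
    """Base class for all package errors."""


class DegenerateCompositionError(EmulsiphaseError, ValueError):
    """Pseudophase volume fractions make the requested quantity undefined."""


class InsufficientDataError(EmulsiphaseError, ValueError):
    """Too few observations for the requested fit or extraction."""


class FitFailureError(EmulsiphaseError, RuntimeError):
    """Optimizer failed to converge; carries diagnostics in ``args``."""


class GeometryError(EmulsiphaseError, ValueError):
    """Inconsistent or degenerate droplet geometry."""


class MissingSpeciesError(EmulsiphaseError, KeyError):
    """A requested species (or reference site) is absent from the frame."""


class EmptyTrajectoryError(EmulsiphaseError, ValueError):
    """An operation requires at least one frame / one sample."""


class TemplateMismatchError(EmulsiphaseError, ValueError):
    """A molecule does not carry the full expected atom-label set."""


class BoundaryEstimationError(EmulsiphaseError, RuntimeError):
    """Region boundaries cannot be located (e.g. no bulk-water plateau)."""


class NoBreakpointError(EmulsiphaseError, RuntimeError):
    """Two-segment fit produced parallel lines; no intersection exists."""


class NormalizationError(EmulsiphaseError, ValueError):
    """Signal normalization impossible (non-positive reference)."""


class SolverError(EmulsiphaseError, RuntimeError):
    """ODE integration failed; message echoes the parameter set."""


class FormatError(EmulsiphaseError, ValueError):
    """File cannot be parsed or frames have inconsistent atom rosters."""


class MappingError(EmulsiphaseError, KeyError):
    """A residue/atom name cannot be resolved to a known species/label."""
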