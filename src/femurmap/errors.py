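"""Exception hierarchy.

All package errors derive from :class:`FemurMapError` so callers can catch
one base class; subclasses mirror the failure categories of the pipeline
(topology, metric, layout, detection, fitting, geometry, statistics,
generation, configuration).
"""


class FemurMapError(Exception):
    """Base class for all femurmap errors."""


class FormatError(FemurMapError):
    """A mesh file could not be parsed in the requested format."""


class TopologyError(FemurMapError):
    """Mesh violates manifoldness/orientability or has the wrong topology."""


class MetricError(FemurMapError):
    """An edge-length assignment violates a triangle inequality."""


class ConvergenceError(FemurMapError):
    """Iterative solver failed to reach tolerance.

    Carries ``residual_history`` (list of max curvature residuals per
    iteration) for diagnostics.
    """

    def __init__(self, msg, residual_history=None):
        super().__init__(msg)
        self.residual_history = list(residual_history or [])


class LayoutError(FemurMapError):
    """Planar layout produced a flipped (negatively oriented) face."""


class DetectionError(FemurMapError):
    """Feature detection found too few (or no) usable peaks."""


class FitError(FemurMapError):
    """A model fit (e.g. Gaussian region fit) was degenerate."""


class GeometryError(FemurMapError):
    """A geometric precondition failed (segment outside domain, flipped
    target faces, non-parallel boundaries, ...)."""


class SolverError(FemurMapError):
    """A linear solve failed (e.g. ill-conditioned RBF kernel matrix)."""


class DesignError(FemurMapError):
    """A statistical design matrix is rank deficient or mismatched."""


class GenerationError(FemurMapError):
    """Synthetic geometry specification produced an invalid surface."""


class ConfigError(FemurMapError):
    """Invalid run configuration."""


class ArgumentError(FemurMapError):
    """Invalid argument value outside the other categories."""
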