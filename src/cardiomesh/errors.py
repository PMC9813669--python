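"""Exception hierarchy shared across the package."""


class CardioMeshError(Exception):
    """Base class for all package errors."""


class MeshParseError(CardioMeshError):
    """A mesh file could not be parsed in the requested format."""


class UnsupportedTopologyError(CardioMeshError):
    """Mesh contains non-triangular faces or other unsupported topology."""


class EmptyInputError(CardioMeshError):
    """An operation received an empty mesh or dataset."""


class TopologyError(CardioMeshError):
    """Surface topology violates an operation's requirements (non-manifold,
    multi-loop boundary, ...)."""


class InvalidAnatomyError(CardioMeshError):
    """Clinically impossible anatomy, e.g. negative wall volume."""


class DataLeakageError(CardioMeshError):
    """Statistics were requested from a non-training split."""


class ConfigurationError(CardioMeshError):
    """Invalid or inconsistent configuration values."""


class DimensionError(CardioMeshError):
    """Array shapes inconsistent with the model or graph."""


class DegenerateFitError(CardioMeshError):
    """A model fit is degenerate, e.g. single-class labels."""
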