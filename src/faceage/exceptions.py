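"""Exception types shared across the pipeline."""


class FaceAgeError(Exception):
    """Base class for all package-specific errors."""


class MeshParseError(FaceAgeError):
    """A mesh file violates the supported OBJ/PLY subset."""


class ValidationError(FaceAgeError):
    """An input object violates a documented invariant."""


class DegenerateGeometryError(FaceAgeError):
    """Geometry is rank-deficient (e.g. collinear landmarks)."""


class PipelineStageError(FaceAgeError):
    """A pipeline stage failed; message carries stage + specimen context."""
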