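"""Exception hierarchy shared across the pipeline stages."""


class StereoVRError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(StereoVRError):
    """A configuration value violates its invariant (e.g. non-positive FoV)."""


class NotRenderableError(StereoVRError):
    """A requested disparity cannot be represented on the headset's pixel grid."""


class GeometryInfeasibleError(StereoVRError):
    """The distance solver found no root in (0, D_total)."""


class InvalidDisparityError(StereoVRError):
    """The disparity difference is outside the solvable range."""


class InsufficientDataError(StereoVRError):
    """Too few valid samples remain for the requested computation."""


class InvalidSampleError(StereoVRError):
    """A sample violates its contract (e.g. zero-length gaze vector)."""


class StratificationError(StereoVRError):
    """A cross-validation fold cannot preserve both classes."""


class SchemaError(StereoVRError):
    """A CSV/JSON artifact does not match the expected schema."""
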