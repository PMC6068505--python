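"""Exception hierarchy for the gaze3d package."""


class Gaze3DError(Exception):
    """Base class for all package-specific errors."""


class NoEyeFoundError(Gaze3DError):
    """Projection profiles are too flat to localise an eye region."""


class InsufficientEdgeSupportError(Gaze3DError):
    """Fewer edge points than the ellipse model requires."""


class FitFailedError(Gaze3DError):
    """A least-squares fit returned a degenerate (non-elliptical) solution."""


class NoCornerError(Gaze3DError):
    """No corner response above threshold in the search region."""


class DegenerateGeometryError(Gaze3DError):
    """Parallel sightlines, collinear circle points, zero disparity, ..."""


class PartialRecordError(Gaze3DError):
    """A binocular record is missing one eye."""


class ScenarioError(Gaze3DError):
    """Invalid synthetic-rig scenario (e.g. target behind the eyes)."""


class CalibrationError(Gaze3DError):
    """Convergence-point search or model fit could not be completed."""


class ConfigurationError(Gaze3DError):
    """Invalid parameter combination."""


class SchemaError(Gaze3DError):
    """Malformed or version/unit-mismatched session file."""
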