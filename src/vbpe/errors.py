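"""Exception hierarchy.

Input errors (bad files, malformed landmarks, implausible geometry) are kept
distinct from quality errors (untrackable video, too few beats) so callers
and the CLI can map them to different exit codes.
"""


class VbpeError(Exception):
    """Base class for all package errors."""


class InputError(VbpeError):
    """Invalid or malformed input (file, landmark set, parameter)."""


class QualityError(VbpeError):
    """Input was readable but too degraded to produce a reliable estimate."""


class VideoQualityError(QualityError):
    """Video fails tracking/resolution/frame-rate quality requirements."""


class SignalQualityError(QualityError):
    """Pulse signal too short or too noisy for event detection/pairing."""


class GeometryError(InputError):
    """Implausible or degenerate body geometry."""


class ModelDomainError(InputError):
    """Hemodynamic model evaluated outside its domain (e.g. PTT <= 0)."""
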