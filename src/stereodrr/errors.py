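"""Exception hierarchy shared by all modules."""


class StereoDrrError(Exception):
    """Base class for all package-specific errors."""


class FrameError(StereoDrrError):
    """A vector was used in (or mixed with) the wrong coordinate frame."""


class GeometryError(StereoDrrError):
    """Invalid or degenerate imaging geometry (angles, axes, triads)."""


class DecompositionError(StereoDrrError):
    """Renderer-matrix decomposition failed (singular / rank-deficient input)."""


class ConfigError(StereoDrrError):
    """Vendor configuration file is missing, malformed or incomplete."""


class DicomError(StereoDrrError):
    """DICOM series / RT Plan could not be interpreted as required."""
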