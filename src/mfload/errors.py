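"""Exception hierarchy."""


class MfloadError(Exception):
    """Base class for all package errors."""


class ConfigError(MfloadError):
    """Invalid configuration or parameter value."""


class ChannelSelectionError(MfloadError):
    """Expected channel labels are missing from a recording."""


class EpochingError(MfloadError):
    """A requested epoch window cannot be extracted."""


class CSPError(MfloadError):
    """Spatial-filter decomposition failed."""


class TrainingError(MfloadError):
    """Classifier training inputs are invalid (missing class, bad labels)."""


class PredictionError(MfloadError):
    """Decoder applied to incompatible epochs."""


class ProtocolError(MfloadError):
    """Session protocol mismatch (e.g. two-class decoder on session 5)."""


class PairingError(MfloadError):
    """Paired statistics requested on unpaired inputs."""


class RangeError(MfloadError):
    """Requested band/window does not intersect the available grid."""


class ParseError(MfloadError):
    """A serialized artifact could not be read."""
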