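"""Exception hierarchy for afield."""


class AFieldError(Exception):
    """Base class for all afield errors."""


class InvalidParameterError(AFieldError, ValueError):
    """A model parameter violates its domain (e.g. non-positive sd)."""


class DegenerateProfileError(AFieldError, ValueError):
    """A profile is numerically zero everywhere and cannot be fit."""


class DesignError(AFieldError, ValueError):
    """A run design is internally inconsistent (e.g. sweeps overflow the task block)."""


class ConfigurationError(AFieldError, ValueError):
    """A configuration value is unusable (e.g. pixel grid too coarse)."""


class CollinearDesignError(AFieldError, ValueError):
    """A GLM design matrix is rank deficient."""


class DataMismatchError(AFieldError, ValueError):
    """Voxel identifiers do not line up across datasets."""
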