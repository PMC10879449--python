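"""Exception hierarchy shared by all pipeline stages."""


class DyadSyncError(Exception):
    """Base class for all package-specific errors."""


class UnusableRecordError(DyadSyncError):
    """A participant record cannot support the requested stage
    (too few beats, no spline support, too few valid seconds, ...)."""


class DegenerateInputError(DyadSyncError):
    """Input is formally valid but statistically degenerate
    (constant series, empty series, too-short contiguous run)."""


class ConfigError(DyadSyncError):
    """A configuration value is missing, malformed, or inconsistent."""


class UndefinedKappaError(DyadSyncError):
    """Cohen's kappa is undefined because chance agreement equals 1."""
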