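"""Exception hierarchy shared across the package."""


class Sca3ProgError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(Sca3ProgError):
    """Invalid simulator or model configuration."""


class CohortLoadError(Sca3ProgError):
    """A cohort file violated the long-format contract."""


class DesignError(Sca3ProgError):
    """A design matrix could not be built (unknown model, missing column)."""


class FitError(Sca3ProgError):
    """Mixed-model estimation could not proceed (e.g. rank-deficient X)."""


class NonNestedError(Sca3ProgError):
    """A likelihood-ratio test was requested for non-nested models."""
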