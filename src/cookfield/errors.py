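"""Exception hierarchy shared across the package."""


class CookfieldError(Exception):
    """Base class for all package-specific errors."""


class FormatError(CookfieldError):
    """A file does not conform to the documented CSV schema."""


class RecordValidationError(CookfieldError):
    """A parsed record violates a field invariant (e.g. negative flux density)."""


class LinkageError(CookfieldError):
    """A grid measurement references a household with no device covariates."""


class SingularityError(CookfieldError):
    """Field requested at the dipole origin (r = 0)."""


class MissingVariableError(CookfieldError):
    """A model term requires a covariate the query does not supply."""


class UnestimableError(CookfieldError):
    """No model's variable requirements can be satisfied by a response."""


class FitError(CookfieldError):
    """Least-squares fitting failed (non-convergence, rank deficiency, too few rows)."""


class DegenerateTestError(CookfieldError):
    """A statistic is undefined for the given input (constant vector, zero variance)."""


class PairingError(CookfieldError):
    """Two samples that must be paired on the same subjects are not."""


class ConfigError(CookfieldError):
    """Simulation config contains unknown or invalid keys."""
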