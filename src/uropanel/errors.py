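"""Exception hierarchy shared across the package."""


class UropanelError(Exception):
    """Base class for all package-specific errors."""


class CohortFormatError(UropanelError):
    """A cohort file is structurally invalid (e.g. a required column is absent)."""


class CohortValidationError(UropanelError):
    """A cohort violates a domain invariant (e.g. a methylation fraction outside [0, 1])."""


class ConfigurationError(UropanelError):
    """A configuration object is inconsistent or references unknown entities."""


class UndefinedMetricError(UropanelError):
    """A performance metric has an empty denominator (no classified cases or controls)."""


class InfeasibleConstraintError(UropanelError):
    """No operating point satisfies the requested constraint."""
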