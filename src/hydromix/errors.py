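"""Exception hierarchy shared across the package."""


class HydromixError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(HydromixError, ValueError):
    """A value violates an operation's precondition or a type invariant."""


class DegenerateFitError(HydromixError, ValueError):
    """A regression problem is rank-deficient or has too few points."""


class CalibrationError(HydromixError, ValueError):
    """Anchor set is infeasible for the chosen model form."""


class ConfigError(HydromixError, ValueError):
    """Configuration file is missing, malformed, or out of range."""
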