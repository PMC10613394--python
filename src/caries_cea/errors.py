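"""Exception hierarchy for the caries-cea package."""


class CariesCEAError(Exception):
    """Base class for all package-specific errors."""


class ConfigParseError(CariesCEAError):
    """A configuration file could not be parsed or contains unknown keys."""


class ConfigValidationError(CariesCEAError):
    """One or more parameter invariants are violated.

    Carries the full list of violations so a hand-edited config can be
    fixed in one pass.
    """

    def __init__(self, violations):
        self.violations = list(violations)
        super().__init__(
            "invalid configuration:\n  - " + "\n  - ".join(self.violations)
        )


class CalibrationError(CariesCEAError):
    """A calibration target lies outside the range reachable under
    probability bounds. The message reports the achievable range."""


class UndefinedICERError(CariesCEAError):
    """ICER requested between strategies with equal effectiveness.

    The cost difference is preserved so callers can still reason about
    weak dominance."""

    def __init__(self, cost_difference):
        self.cost_difference = cost_difference
        super().__init__(
            "ICER undefined: equal effectiveness "
            f"(cost difference {cost_difference:+.2f})"
        )


class SamplingError(CariesCEAError):
    """A PSA distribution could not be built for an arm/parameter."""
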