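"""Exception hierarchy shared across the package."""


class RfasimError(ValueError):
    """Base class for all package-specific errors."""


class PhantomSpecError(RfasimError):
    """Invalid synthetic-phantom specification (geometry out of bounds, empty masks, ...)."""


class RegistrationError(RfasimError):
    """Under-determined or invalid landmark configuration for the rigid fit."""


class NeedleError(RfasimError):
    """Invalid needle geometry (coincident tip/shaft, missing prongs, ...)."""


class StabilityError(RfasimError):
    """Explicit time step exceeds the scheme's stability bound."""


class StateError(RfasimError):
    """Cell-state fields are negative or violate A+V+D=1 beyond tolerance."""


class PowerError(RfasimError):
    """No power can be deposited (all source points outside the ROI)."""


class MetricsError(RfasimError):
    """Overlap/surface metrics undefined for the given masks or surfaces."""


class EnsembleError(RfasimError):
    """Degenerate or invalid ensemble (too few members, duplicate parameters, ...)."""


class ConfigError(RfasimError):
    """Missing or contradictory configuration keys."""
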