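"""Package-wide error types."""


class DesignError(ValueError):
    """A study-design parameter is infeasible or inconsistent."""


class InsufficientDataError(ValueError):
    """Too few observations/features to run the requested analysis."""


class EmptyResultError(ValueError):
    """A filtering step removed every feature."""


class CapacityError(ValueError):
    """Requested annotation density does not fit the simulated genome."""


class PlacementError(ValueError):
    """An interval cannot be placed inside any segment of the target space."""
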