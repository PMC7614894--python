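"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """Invalid geometry, rates, schedule or config file content."""


class SimulationError(RuntimeError):
    """An operation was applied to a state that cannot support it
    (e.g. dividing a vacant site, scoring an extinct clone)."""


class EmptyInputError(ValueError):
    """A summary was requested on an empty table."""


class UnidentifiableFitError(ValueError):
    """The data cannot constrain the requested parameter
    (e.g. zero retention everywhere, or a single observation time for k_d)."""


class EstimationError(RuntimeError):
    """A Monte-Carlo estimate is undefined (e.g. no surviving clones)."""
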