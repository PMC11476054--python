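"""Exception types raised by the simulator."""


class ParameterError(ValueError):
    """A model parameter violates its constraints."""


class DataError(ValueError):
    """An input array (genome, phenotype vector) is malformed."""


class StateError(RuntimeError):
    """An operation was invoked on an invalid population state."""


class ConfigError(ValueError):
    """An experiment configuration file is invalid."""
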