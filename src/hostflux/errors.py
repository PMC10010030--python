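"""Exception types shared across the pipeline."""


class HostfluxError(Exception):
    """Base class for all hostflux errors."""


class ConfigurationError(HostfluxError):
    """A configuration field is invalid; the message names the field."""


class InputError(HostfluxError):
    """An input object or file violates a precondition."""
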