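"""Exception types shared across the package."""


class PPGHemoError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(PPGHemoError, ValueError):
    """A configuration value violates an invariant; the message names the field."""


class BeatDetectionError(PPGHemoError, RuntimeError):
    """No cardiac pulses could be detected in a recording."""
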