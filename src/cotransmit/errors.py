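"""Exception types shared across the pipeline stages."""


class CotransmitError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CotransmitError):
    """A configuration value is inconsistent or invalid; the message names the field."""


class FormatError(CotransmitError):
    """An input file violates its declared format; the message carries file context."""


class PipelineError(CotransmitError):
    """A pipeline stage failed after validation."""
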