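"""Exception hierarchy for caninakit."""


class CaninakitError(Exception):
    """Base class for all caninakit errors."""


class ConfigurationError(CaninakitError):
    """Invalid configuration value; the message names the offending field."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"{field}: {message}")


class ModelError(CaninakitError):
    """A genetic-model precondition was violated (e.g. no bivalent partner)."""


class FormatError(CaninakitError):
    """Malformed record in an input file."""

    def __init__(self, path, line_no, reason):
        self.path, self.line_no, self.reason = path, line_no, reason
        super().__init__(f"{path}:{line_no}: {reason}")


class PipelineError(CaninakitError):
    """A pipeline stage failed; the message names the stage."""
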