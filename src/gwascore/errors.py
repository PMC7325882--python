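"""Exception types shared across the package."""


class GwascoreError(Exception):
    """Base class for all package errors."""


class ValidationError(GwascoreError):
    """An input record or configuration value violates a domain invariant."""


class PipelineError(GwascoreError):
    """A pipeline stage failed; the message is prefixed with the stage name."""
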