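"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """A simulation or pipeline configuration is invalid or incomplete."""


class EpochUnavailableError(RuntimeError):
    """The recording is too short to supply the requested analysis epoch."""


class DegenerateDesignError(ValueError):
    """A factorial design has no residual degrees of freedom."""


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and input."""
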