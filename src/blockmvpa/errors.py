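"""Exception types shared across the pipeline."""


class BlockMVPAError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(BlockMVPAError, ValueError):
    """A parameter set violates one of its documented invariants."""


class DesignError(BlockMVPAError, ValueError):
    """A schedule or design matrix is structurally invalid (e.g. rank deficient)."""


class StageError(BlockMVPAError, RuntimeError):
    """A pipeline stage failed; carries the stage name for provenance."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
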