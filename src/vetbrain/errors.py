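"""Exception and warning hierarchy shared across the pipeline."""


class VetbrainError(Exception):
    """Base class for all pipeline errors."""


class DegenerateInputError(VetbrainError):
    """Input is structurally valid but degenerate (empty foreground, zero variance...)."""


class InconsistencyError(VetbrainError):
    """Input pieces disagree with each other (mixed geometry within a series...)."""


class ConfigurationError(VetbrainError):
    """Missing or invalid configuration."""


class BackendError(VetbrainError):
    """A segmentation backend failed or violated its contract."""


class EmptyMaskError(VetbrainError):
    """A binary mask that must be nonempty is empty."""


class RepositioningWarning(UserWarning):
    """A mask maps mostly outside the target field of view (patient repositioned)."""


class TieBreakWarning(UserWarning):
    """A deterministic tie-break was applied (e.g. equal-size connected components)."""
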