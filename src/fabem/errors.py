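"""Exception types shared across the pipeline."""


class FabemError(Exception):
    """Base class for all errors raised by fabem."""


class FormatError(FabemError):
    """Input image has the wrong shape, channel count or dtype."""


class NoSkullDetected(FabemError):
    """Slice maximum is below the skull floor; the max-relative thresholds
    would degenerate to an (almost) all-ones mask, so the slice is rejected."""


class EmptyMaskError(FabemError):
    """An operation that needs a nonempty mask received an all-zero one."""


class EmptySeedRegion(FabemError):
    """Seed selection was asked to place a seed on an empty mask."""


class PluginNotFound(FabemError):
    """Requested plugin name is not in the registry."""


class PluginContractError(FabemError):
    """A plugin does not satisfy the classifier/segmenter interface."""


class PhantomSpecError(FabemError):
    """A phantom specification violates its geometric/intensity invariants."""
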