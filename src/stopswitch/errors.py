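"""Exception hierarchy shared across the package."""


class StopSwitchError(Exception):
    """Base class for all package errors."""


class AlphabetError(StopSwitchError, ValueError):
    """Sequence contains characters outside the allowed nucleotide alphabet."""


class FrameError(StopSwitchError, ValueError):
    """Coding sequence length is not a multiple of three."""


class ProfileKindError(StopSwitchError, ValueError):
    """An operation received an editor profile of the wrong deaminase class."""


class EditPreconditionError(StopSwitchError, ValueError):
    """The base found at an edit site does not match the expected base."""


class InconsistentInputError(StopSwitchError, ValueError):
    """Two inputs that must agree (e.g. guide and context) do not."""


class SaturationError(StopSwitchError, ValueError):
    """All partitions positive: the Poisson occupancy estimate is unbounded."""
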