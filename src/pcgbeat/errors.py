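"""Exception hierarchy for the pcgbeat pipeline.

Every stage raises a distinct, named error so that a CLI run can map a
failure to the stage that produced it.
"""


class PcgBeatError(Exception):
    """Base class for all pcgbeat errors."""


class RecordingReadError(PcgBeatError):
    """A recording file could not be read or parsed in the named format."""


class MissingSampleRateError(PcgBeatError):
    """A format without an embedded rate was read without an override."""


class ChannelRoleMismatchError(PcgBeatError):
    """The supplied channel roles do not match the channel count."""


class InvalidFilterBandError(PcgBeatError):
    """Filter band edges are mis-ordered or at/above Nyquist."""


class SignalTooShortError(PcgBeatError):
    """The signal is too short for the requested transform or detection."""


class ConstantSignalError(PcgBeatError):
    """An operation that needs signal variance received a constant input."""


class OutOfRangeError(PcgBeatError):
    """Input samples violate a required amplitude range."""


class InsufficientPeaksError(PcgBeatError):
    """Too few peaks to estimate the presumed heart period or median R-R."""


class InsufficientDataError(PcgBeatError):
    """The recording is too short for heart-sound detection."""


class TooFewPairsError(PcgBeatError):
    """Too few jointly defined windows for a paired comparison."""


class InvalidSpecError(PcgBeatError):
    """A simulation specification violates its invariants."""
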