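"""Exception hierarchy for the migrasleep pipeline."""


class MigrasleepError(Exception):
    """Base class for all package errors."""


class FormatError(MigrasleepError):
    """A file does not conform to the expected dialect."""


class ValidationError(MigrasleepError):
    """An in-memory object violates its invariants or preconditions."""


class DetectionError(MigrasleepError):
    """No usable sleep interval could be found in a recording."""


class SplitError(MigrasleepError):
    """A train/validation/test split cannot be constructed; the message
    names the deficit (e.g. too few migraine nights)."""


class FitError(MigrasleepError):
    """A discriminant model cannot be estimated from the given data."""
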