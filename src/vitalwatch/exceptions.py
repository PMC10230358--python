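"""Exception hierarchy for vitalwatch."""


class VitalwatchError(Exception):
    """Base class for all vitalwatch errors."""


class FormatError(VitalwatchError, ValueError):
    """A file does not conform to the expected on-disk layout."""


class ValidationError(VitalwatchError, ValueError):
    """Input data violate a documented precondition or invariant."""


class InsufficientDataError(VitalwatchError, ValueError):
    """Too few observations to carry out a fit or estimate."""
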