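"""Exception hierarchy shared across the package."""


class LungNtcpError(Exception):
    """Base class for all package-specific errors."""


class MalformedInputError(LungNtcpError, ValueError):
    """Input text or arrays violate the structural contract (e.g. non-monotone doses)."""


class RangeError(LungNtcpError, ValueError):
    """A numeric value lies outside its admissible range."""


class EmptyInputError(LungNtcpError, ValueError):
    """An operation received an empty stream, histogram or cohort."""


class ModeError(LungNtcpError, ValueError):
    """A histogram was passed in the wrong mode (cumulative vs differential)."""


class ParameterError(LungNtcpError, ValueError):
    """A model or configuration parameter is invalid."""


class DegenerateDataError(LungNtcpError, ValueError):
    """Data carry no information for the requested operation (all events, single class, zero marginal...)."""


class InsufficientDataError(LungNtcpError, ValueError):
    """Too few observations for the requested statistic."""


class RankError(LungNtcpError, ValueError):
    """A design matrix is rank-deficient / singular."""
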