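"""Exception hierarchy shared across the package."""


class CletoolsError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(CletoolsError, ValueError):
    """A parameter object or argument violates its invariants."""


class FormatError(CletoolsError, ValueError):
    """An input file does not conform to the expected dialect."""


class DataError(CletoolsError, ValueError):
    """A well-formed file contains internally inconsistent data."""


class TooShortError(CletoolsError, ValueError):
    """A trajectory is too short for the requested kinematic quantity."""


class DegenerateDataError(CletoolsError, ValueError):
    """Data carry no information about the model parameters (e.g. flat curve)."""
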