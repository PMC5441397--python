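"""Exception hierarchy shared across the package."""


class CvleakError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(CvleakError, ValueError):
    """Invalid generative, splitting, or classifier parameters."""


class InfeasibleSplitError(CvleakError, ValueError):
    """Requested more folds than available units (records or subjects)."""


class DegenerateTrainingError(CvleakError, RuntimeError):
    """A training set contained a single class; the caller should re-stratify."""


class ConsistencyError(CvleakError, ValueError):
    """Mismatched record counts or feature dimensions between objects."""


class FormatError(CvleakError, ValueError):
    """Malformed input file; the message names the offending line numbers."""
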