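"""Exception hierarchy for stratccd."""


class StratCCDError(Exception):
    """Base class for all stratccd errors."""


class FormatError(StratCCDError):
    """A file does not conform to its declared format (GCT, TSV, GMT, ...)."""


class ValidationError(StratCCDError):
    """Inputs violate a documented invariant (duplicate ids, bad p-values, ...)."""


class EstimationError(StratCCDError):
    """A statistic cannot be estimated (too few samples, too few panel genes)."""


class AnalysisError(StratCCDError):
    """A tissue-level analysis cannot be run as configured."""
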