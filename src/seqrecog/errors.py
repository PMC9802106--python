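"""Exception types shared across the pipeline."""


class SeqrecogError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(SeqrecogError, ValueError):
    """A configuration value violates a precondition."""


class InvalidInputError(SeqrecogError, ValueError):
    """A data argument violates a precondition (shape, range, coverage)."""


class RankError(SeqrecogError, ValueError):
    """A matrix is singular or rank-deficient where an inverse is needed."""


class NoCorrectTrialsError(SeqrecogError, ValueError):
    """A participant has zero correct trials in a condition and must be
    excluded from group statistics."""
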