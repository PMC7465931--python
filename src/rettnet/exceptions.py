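"""Exception hierarchy for rettnet.

All package errors derive from :class:`RettNetError` so callers can catch one
base class; the subclasses mark the distinct failure modes of the pipeline
(bad montage, degenerate numerical input, unrealisable simulation design,
empty data after rejection, unbalanced repeated-measures designs, empty
feature selections).
"""


class RettNetError(Exception):
    """Base class for all rettnet errors."""


class MontageError(RettNetError):
    """Channel labels cannot be resolved against the configured montage."""


class FormatError(RettNetError):
    """A recording or table file could not be parsed."""


class DegenerateInputError(RettNetError):
    """Input is numerically degenerate (zero power, too few segments/rows)."""


class DesignError(RettNetError):
    """A simulation design is invalid or unrealisable (e.g. coherence target
    outside [0, 1) or below the background level)."""


class EmptyDataError(RettNetError):
    """No usable data remain (e.g. every epoch rejected)."""


class UnbalancedDesignError(RettNetError):
    """A repeated-measures design is missing observations; listwise deletion
    is never applied silently."""


class EmptySelectionError(RettNetError):
    """Feature selection returned no features at the requested alpha."""


class UndefinedTestError(RettNetError):
    """A statistical test is undefined for the given data (e.g. all paired
    differences zero)."""
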