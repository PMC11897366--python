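"""Typed exceptions shared across the package."""


class BiofilmStabError(Exception):
    """Base class for all package errors."""


class InvalidDesignError(BiofilmStabError, ValueError):
    """A regime design or world configuration violates its invariants."""


class ValidationError(BiofilmStabError, ValueError):
    """An input table or tree violates a structural contract."""


class InsufficientDataError(BiofilmStabError, ValueError):
    """Not enough observations (dates, plots, taxa) for the requested statistic."""


class UndefinedSampleError(BiofilmStabError, ValueError):
    """The statistic is undefined for this sample (e.g. an all-zero community)."""
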