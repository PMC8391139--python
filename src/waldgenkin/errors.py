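"""Exception hierarchy for the screening pipeline."""


class WaldGenkinError(Exception):
    """Base class for all package errors."""


class ValidationError(WaldGenkinError):
    """A record or configuration value violates its invariants.

    The message names the offending field.
    """


class DomainError(WaldGenkinError):
    """An input lies outside the domain of a formula (e.g. a predicted
    vital lung capacity that comes out non-positive for a very short or
    very young subject)."""


class CoverageError(WaldGenkinError):
    """A measurement falls outside every interval of a norms table."""


class DegenerateCountsError(WaldGenkinError):
    """A deciban coefficient was requested for counts with an empty cell
    and no continuity correction, so a proportion is 0 or 1 and the
    log-ratio is undefined."""


class InversionError(WaldGenkinError):
    """No integer count pair reproduces a printed coefficient pair."""


class EmptyTableError(WaldGenkinError):
    """Every criterion fell below the informativeness cutoff."""
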