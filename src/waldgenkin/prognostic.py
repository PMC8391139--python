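"""Deciban predictive coefficients, Kullback informativeness, and the
prognostic table.

The Wald-Genkin method summarises how well a binary criterion separates
two groups by a likelihood-ratio score in decibans,

    pc_presence = 10 * log10(P1 / P2),        P_k = d_k / s_k,

where ``d_k`` of ``s_k`` subjects in group *k* show the criterion, and
the complementary score for its absence uses ``(1 - P_k)``.  Criteria are
weighted by the (presence-gradation) Kullback informativeness

    i = 0.5 * pc_presence * (100*P1 - 100*P2),

ranked by it, and criteria below a cutoff (30.0 by convention) are
dropped as insignificant.  The retained rows, with coefficients printed
to one decimal, form the published screening instrument.

Because a printed coefficient *pair* (presence, absence) strongly
over-determines the underlying integer counts, this module also provides
an exhaustive-search oracle that inverts a printed pair back to
``(d1, d2)`` — the route by which the packaged reference table's counts
were reconstructed.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from ._round import round_half_up
from .errors import (DegenerateCountsError, EmptyTableError, InversionError,
                     ValidationError)
from .indices import CRITERIA, CriterionProfile, Group, Status

logger = logging.getLogger(__name__)

#: Informativeness below this value is considered insignificant.
DEFAULT_MIN_INFORMATIVENESS = 30.0
#: Continuity correction added to all cells when a count cell is empty.
DEFAULT_SMOOTHING = 0.5


@dataclass(frozen=True)
class GradationCounts:
    """Exceedance counts for one criterion: d1 of s1 athletes and d2 of
    s2 controls show the criterion."""

    d1: int
    s1: int
    d2: int
    s2: int

    def __post_init__(self) -> None:
        if self.s1 < 1 or self.s2 < 1:
            raise ValidationError("group sizes must be >= 1")
        if not (0 <= self.d1 <= self.s1 and 0 <= self.d2 <= self.s2):
            raise ValidationError(
                f"counts out of range: d1={self.d1}/{self.s1}, "
                f"d2={self.d2}/{self.s2}")

    def swapped(self) -> "GradationCounts":
        """The same criterion with group roles exchanged."""
        return GradationCounts(self.d2, self.s2, self.d1, self.s1)


def _proportions(counts: GradationCounts, smoothing: float
                 ) -> tuple[float, float]:
    """Presence proportions (P1, P2), continuity-corrected only when some
    cell of the 2x2 table is empty."""
    cells = (counts.d1, counts.s1 - counts.d1, counts.d2, counts.s2 - counts.d2)
    if 0 in cells:
        if smoothing <= 0:
            raise DegenerateCountsError(
                f"counts {counts} have an empty cell and smoothing is 0; "
                "the log-ratio is undefined")
        c = smoothing
        return ((counts.d1 + c) / (counts.s1 + 2 * c),
                (counts.d2 + c) / (counts.s2 + 2 * c))
    return counts.d1 / counts.s1, counts.d2 / counts.s2


def predictive_coefficient(counts: GradationCounts, gradation: str = "presence",
                           smoothing: float = DEFAULT_SMOOTHING) -> float:
    """Unrounded deciban coefficient for one gradation of a criterion.

    ``gradation="presence"`` scores observing the criterion,
    ``"absence"`` scores not observing it.  Display rounding to one
    decimal is the caller's concern.
    """
    p1, p2 = _proportions(counts, smoothing)
    if gradation == "presence":
        return 10.0 * math.log10(p1 / p2)
    if gradation == "absence":
        return 10.0 * math.log10((1.0 - p1) / (1.0 - p2))
    raise ValidationError(f"unknown gradation {gradation!r}")


def informativeness(counts: GradationCounts,
                    smoothing: float = DEFAULT_SMOOTHING,
                    both_gradations: bool = False) -> float:
    """Kullback informativeness of a criterion.

    By default only the presence-gradation term is returned,
    ``0.5 * pc_presence * (100*P1 - 100*P2)``, computed from the
    *unrounded* coefficient — this is the form the published tables use.
    With ``both_gradations=True`` the absence term
    ``0.5 * pc_absence * (100*(1-P1) - 100*(1-P2))`` is added, giving the
    full symmetrised Kullback divergence (in deciban-percent units).
    Always non-negative; zero iff the group proportions are equal.
    """
    p1, p2 = _proportions(counts, smoothing)
    result = 0.5 * predictive_coefficient(counts, "presence", smoothing) \
        * (100.0 * p1 - 100.0 * p2)
    if both_gradations:
        result += 0.5 * predictive_coefficient(counts, "absence", smoothing) \
            * (100.0 * (1.0 - p1) - 100.0 * (1.0 - p2))
    return result


@dataclass(frozen=True)
class InversionResult:
    """All count pairs consistent with a printed coefficient pair."""

    matches: tuple[GradationCounts, ...]

    @property
    def unique(self) -> bool:
        return len(self.matches) == 1

    @property
    def counts(self) -> GradationCounts:
        if not self.unique:
            raise InversionError(
                f"{len(self.matches)} count pairs match; not unique")
        return self.matches[0]


def invert_pc_pair(pc_presence_printed: float, pc_absence_printed: float,
                   s1: int, s2: int) -> InversionResult:
    """Recover integer counts from a printed coefficient pair.

    Exhaustively searches all ``(d1, d2)`` in ``[0, s1] x [0, s2]`` for
    pairs whose unrounded presence *and* absence coefficients round
    (half-up, one decimal) to the printed values.  Degenerate cells are
    searched without smoothing, i.e. only interior counts can match —
    appropriate for inverting tables whose published coefficients are
    finite.  Raises :class:`InversionError`, listing the nearest
    candidates, when nothing matches.
    """
    if s1 > 100 or s2 > 100:
        raise ValidationError("exhaustive inversion supported for sizes <= 100")
    target = (round_half_up(pc_presence_printed, 1),
              round_half_up(pc_absence_printed, 1))
    matches = []
    near: list[tuple[float, GradationCounts]] = []
    for d1 in range(s1 + 1):
        for d2 in range(s2 + 1):
            counts = GradationCounts(d1, s1, d2, s2)
            try:
                pres = predictive_coefficient(counts, "presence", smoothing=0.0)
                absn = predictive_coefficient(counts, "absence", smoothing=0.0)
            except DegenerateCountsError:
                continue
            if (round_half_up(pres, 1), round_half_up(absn, 1)) == target:
                matches.append(counts)
            else:
                gap = abs(pres - target[0]) + abs(absn - target[1])
                near.append((gap, counts))
    if not matches:
        near.sort(key=lambda item: item[0])
        nearest = ", ".join(f"(d1={c.d1}, d2={c.d2})" for _, c in near[:3])
        raise InversionError(
            f"no counts in [0,{s1}]x[0,{s2}] reproduce the pair "
            f"({target[0]}, {target[1]}); nearest candidates: {nearest}")
    if len(matches) > 1:
        logger.info("inversion of (%s, %s) is non-unique: %d matches",
                    *target, len(matches))
    return InversionResult(tuple(matches))


def count_exceedances(profiles: Iterable[CriterionProfile]
                      ) -> dict[str, GradationCounts]:
    """Tally per-criterion presence counts for the two groups.

    Subjects with a *missing* status are excluded from both the
    numerator and the effective group size of that criterion.  A
    criterion missing in an entire group is dropped with a log entry.
    """
    tallies = {c: {Group.ATHLETE: [0, 0], Group.CONTROL: [0, 0]}
               for c in CRITERIA}
    seen = {Group.ATHLETE: 0, Group.CONTROL: 0}
    for profile in profiles:
        if profile.group is None:
            raise ValidationError(
                f"profile {profile.subject_id} has no group label")
        seen[profile.group] += 1
        for criterion, status in profile.statuses.items():
            if status is Status.MISSING:
                continue
            bucket = tallies[criterion][profile.group]
            bucket[1] += 1
            if status is Status.PRESENT:
                bucket[0] += 1
    if not all(seen.values()):
        raise ValidationError(
            f"both groups must be non-empty (athlete={seen[Group.ATHLETE]}, "
            f"control={seen[Group.CONTROL]})")
    result: dict[str, GradationCounts] = {}
    for criterion, groups in tallies.items():
        (d1, s1), (d2, s2) = groups[Group.ATHLETE], groups[Group.CONTROL]
        if s1 == 0 or s2 == 0:
            logger.warning("criterion %s missing in an entire group; dropped",
                           criterion)
            continue
        result[criterion] = GradationCounts(d1, s1, d2, s2)
    return result


@dataclass(frozen=True)
class PrognosticRow:
    """One criterion's scores, with the counts they came from."""

    criterion_id: str
    pc_presence: float
    pc_absence: float
    informativeness: float
    counts: GradationCounts

    @property
    def pc_presence_display(self) -> float:
        return round_half_up(self.pc_presence, 1)

    @property
    def pc_absence_display(self) -> float:
        return round_half_up(self.pc_absence, 1)

    @property
    def informativeness_display(self) -> float:
        return round_half_up(self.informativeness, 2)


_TABLE_COLUMNS = ("criterion_id", "d1", "s1", "d2", "s2",
                  "pc_presence", "pc_absence", "informativeness",
                  "pc_presence_display", "pc_absence_display",
                  "informativeness_display")


@dataclass(frozen=True)
class PrognosticTable:
    """Criteria ranked by descending informativeness, cutoff applied."""

    rows: tuple[PrognosticRow, ...]
    min_informativeness: float = DEFAULT_MIN_INFORMATIVENESS

    def __post_init__(self) -> None:
        infos = [row.informativeness for row in self.rows]
        if any(b > a + 1e-12 for a, b in zip(infos, infos[1:])):
            raise ValidationError("rows must be sorted by descending "
                                  "informativeness")
        if any(i < self.min_informativeness for i in infos):
            raise ValidationError("a retained row falls below the cutoff")

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)

    def row(self, criterion_id: str) -> PrognosticRow:
        for row in self.rows:
            if row.criterion_id == criterion_id:
                return row
        raise KeyError(criterion_id)

    def to_frame(self) -> pd.DataFrame:
        """Full-precision values plus the display columns, one row per
        retained criterion, in table order."""
        records = [{
            "criterion_id": r.criterion_id,
            "d1": r.counts.d1, "s1": r.counts.s1,
            "d2": r.counts.d2, "s2": r.counts.s2,
            "pc_presence": r.pc_presence,
            "pc_absence": r.pc_absence,
            "informativeness": r.informativeness,
            "pc_presence_display": r.pc_presence_display,
            "pc_absence_display": r.pc_absence_display,
            "informativeness_display": r.informativeness_display,
        } for r in self.rows]
        return pd.DataFrame.from_records(records, columns=_TABLE_COLUMNS)

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path,
                 min_informativeness: float = DEFAULT_MIN_INFORMATIVENESS
                 ) -> "PrognosticTable":
        frame = pd.read_csv(path)
        missing = set(_TABLE_COLUMNS[:8]) - set(frame.columns)
        if missing:
            raise ValidationError(f"table file lacks columns: {sorted(missing)}")
        rows = tuple(
            PrognosticRow(
                criterion_id=str(rec.criterion_id),
                pc_presence=float(rec.pc_presence),
                pc_absence=float(rec.pc_absence),
                informativeness=float(rec.informativeness),
                counts=GradationCounts(int(rec.d1), int(rec.s1),
                                       int(rec.d2), int(rec.s2)))
            for rec in frame.itertuples())
        return cls(rows, min_informativeness)


def build_table(counts_by_criterion: Mapping[str, GradationCounts],
                min_informativeness: float = DEFAULT_MIN_INFORMATIVENESS,
                smoothing: float = DEFAULT_SMOOTHING) -> PrognosticTable:
    """Assemble the prognostic table from per-criterion counts.

    Rows with informativeness strictly below the cutoff are dropped; the
    rest are sorted by descending informativeness.  Ties are broken by
    the fixed canonical criterion order (deterministically, for
    reproducibility).  A warning is emitted when the retained row count
    falls outside the 7-10 range conventionally regarded as sufficient
    for a reliable prediction.
    """
    if not counts_by_criterion:
        raise ValidationError("at least one criterion is required")
    canonical = {criterion: rank for rank, criterion in enumerate(CRITERIA)}
    rows = []
    for position, (criterion, counts) in enumerate(counts_by_criterion.items()):
        info = informativeness(counts, smoothing)
        if info < min_informativeness:
            logger.info("criterion %s excluded: informativeness %.2f < %.1f",
                        criterion, info, min_informativeness)
            continue
        rows.append(PrognosticRow(
            criterion_id=criterion,
            pc_presence=predictive_coefficient(counts, "presence", smoothing),
            pc_absence=predictive_coefficient(counts, "absence", smoothing),
            informativeness=info,
            counts=counts))
    if not rows:
        raise EmptyTableError(
            f"no criterion reaches informativeness {min_informativeness}")
    rows.sort(key=lambda r: (-r.informativeness,
                             canonical.get(r.criterion_id, len(canonical))))
    if not 7 <= len(rows) <= 10:
        warnings.warn(
            f"{len(rows)} criteria retained; 7-10 are conventionally "
            "considered sufficient for a reliable prediction", stacklevel=2)
    return PrognosticTable(tuple(rows), min_informativeness)
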