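"""Morphofunctional indices and criterion binarization.

Candidates for artistic-swimming selection are characterised by a small
battery of anthropometric indices (Erisman index, biceps index, ratio of
actual to proper vital lung capacity, weight-for-height harmony) and
functional tests (Stange and Genchi breath-holds, "Splits", "Crab
position" and "Forward bend" flexibility tests).  Each measurement is
reduced to a binary criterion — present when the subject's value lies on
the "trained athlete" side of a fixed threshold — and the ordered
nine-element profile of these criteria is what the prognostic table
consumes.

All threshold comparisons are strict: a value landing exactly on a
threshold counts as *absent*.  Missing measurements yield a *missing*
status and are never imputed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Optional, Sequence

from .errors import CoverageError, DomainError, ValidationError

logger = logging.getLogger(__name__)

#: Fixed criterion order, top-to-bottom as in the published screening table.
CRITERIA: tuple[str, ...] = (
    "vlc_ratio_gt1",
    "biceps_gt_6_7pct",
    "weight_deficit",
    "forward_bend_gt10s",
    "splits_lt0",
    "stange_gt_norm",
    "genchi_gt_norm",
    "erisman_lt0",
    "crab_lt60",
)

#: Biceps-index criterion threshold as a fraction (the table prints 6.7%).
BICEPS_THRESHOLD = 0.067
#: Forward-bend criterion threshold, seconds.
FORWARD_BEND_THRESHOLD_S = 10.0
#: Crab-position criterion threshold, cm.
CRAB_THRESHOLD_CM = 60.0


class Status(str, Enum):
    """Presence status of one criterion for one subject."""

    PRESENT = "present"
    ABSENT = "absent"
    MISSING = "missing"


class Group(str, Enum):
    """Cohort membership: trained athletes vs untrained controls."""

    ATHLETE = "athlete"
    CONTROL = "control"


def _check_positive(name: str, value: float) -> None:
    if not math.isfinite(value) or value <= 0:
        raise ValidationError(f"{name} must be positive, got {value!r}")


@dataclass(frozen=True)
class SubjectRecord:
    """Raw measurements for one subject.

    Units are fixed: lengths and circumferences in cm, weight in kg,
    lung capacity in litres, times in seconds, age in years.  ``splits``
    may be negative under the bench-elevated protocol used for athletes
    (the foot rests on a gymnastic bench so the groin can descend below
    floor level).  Any field except ``subject_id`` may be ``None`` to
    mark a missing measurement.
    """

    subject_id: str
    group: Optional[Group] = None
    age: Optional[float] = None
    body_length: Optional[float] = None
    body_weight: Optional[float] = None
    chest_circumference: Optional[float] = None
    vlc_actual: Optional[float] = None
    biceps_tense: Optional[float] = None
    biceps_rest: Optional[float] = None
    stange: Optional[float] = None
    genchi: Optional[float] = None
    splits: Optional[float] = None
    crab: Optional[float] = None
    forward_bend: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("body_length", "body_weight", "chest_circumference",
                     "vlc_actual", "biceps_tense", "biceps_rest"):
            value = getattr(self, name)
            if value is not None:
                _check_positive(name, value)
        if self.age is not None and not 5 < self.age < 25:
            raise ValidationError(
                f"age must lie in (5, 25) years, got {self.age!r}")
        for name in ("stange", "genchi", "forward_bend"):
            value = getattr(self, name)
            if value is not None and (not math.isfinite(value) or value < 0):
                raise ValidationError(
                    f"{name} must be non-negative, got {value!r}")
        if (self.biceps_tense is not None and self.biceps_rest is not None
                and self.biceps_tense < self.biceps_rest):
            logger.warning(
                "subject %s: biceps tense (%.1f) below rest (%.1f)",
                self.subject_id, self.biceps_tense, self.biceps_rest)


@dataclass(frozen=True)
class WeightNorm:
    """Weight norm for one height interval [min_height, max_height): the
    regression-scale mean M and its permissible deviation delta_R (kg)."""

    min_height: float
    max_height: float
    M: float
    delta_R: float


@dataclass(frozen=True)
class AgeNorm:
    """A reference value for one age bracket [min_age, max_age)."""

    min_age: float
    max_age: float
    value: float


@dataclass(frozen=True)
class NormTable:
    """Configurable stand-in for external physical-development standards.

    Holds weight-for-height norms (regression scale, M ± delta_R per
    height interval) and age norms for the Stange and Genchi breath-hold
    tests.  Intervals are half-open ``[min, max)``, must be sorted and
    non-overlapping.
    """

    weight_norms: tuple[WeightNorm, ...]
    stange_norm: tuple[AgeNorm, ...]
    genchi_norm: tuple[AgeNorm, ...]

    def __post_init__(self) -> None:
        for norm in self.weight_norms:
            if norm.delta_R <= 0:
                raise ValidationError(
                    f"delta_R must be positive, got {norm.delta_R!r}")
        for name, intervals in (
                ("weight_norms",
                 [(n.min_height, n.max_height) for n in self.weight_norms]),
                ("stange_norm",
                 [(n.min_age, n.max_age) for n in self.stange_norm]),
                ("genchi_norm",
                 [(n.min_age, n.max_age) for n in self.genchi_norm])):
            for (lo, hi) in intervals:
                if lo >= hi:
                    raise ValidationError(
                        f"{name}: empty interval [{lo}, {hi})")
            for (_, hi), (lo2, _) in zip(intervals, intervals[1:]):
                if lo2 < hi:
                    raise ValidationError(
                        f"{name}: intervals overlap or are unsorted at {lo2}")

    def weight_norm_for(self, height: float) -> WeightNorm:
        for norm in self.weight_norms:
            if norm.min_height <= height < norm.max_height:
                return norm
        raise CoverageError(
            f"body length {height} cm outside all weight-norm intervals "
            f"(covered: {self.weight_norms[0].min_height}-"
            f"{self.weight_norms[-1].max_height} cm)"
            if self.weight_norms else "weight-norm table is empty")

    def _age_value(self, norms: tuple[AgeNorm, ...], age: float,
                   label: str) -> float:
        for norm in norms:
            if norm.min_age <= age < norm.max_age:
                return norm.value
        raise CoverageError(f"age {age} outside all {label} brackets")

    def stange_norm_for(self, age: float) -> float:
        return self._age_value(self.stange_norm, age, "stange_norm")

    def genchi_norm_for(self, age: float) -> float:
        return self._age_value(self.genchi_norm, age, "genchi_norm")


def default_norms() -> NormTable:
    """A synthetic norms fixture plausible for 11-13-year-old girls.

    The published physical-development standards behind the original
    screening table are not reproduced here; these values are a
    documented stand-in so the pipeline runs end-to-end.  Real use should
    load locale-appropriate standards via :func:`waldgenkin.io.read_norms`.
    """
    weight = tuple(
        WeightNorm(lo, lo + 5.0, m, d)
        for lo, m, d in (
            (130.0, 28.5, 4.0), (135.0, 31.0, 4.2), (140.0, 33.8, 4.5),
            (145.0, 37.0, 4.8), (150.0, 40.5, 5.1), (155.0, 44.2, 5.4),
            (160.0, 48.0, 5.7), (165.0, 51.8, 6.0),
        ))
    stange = (AgeNorm(10.0, 12.0, 40.0), AgeNorm(12.0, 14.0, 45.0))
    genchi = (AgeNorm(10.0, 12.0, 20.0), AgeNorm(12.0, 14.0, 24.0))
    return NormTable(weight, stange, genchi)


@dataclass(frozen=True)
class CriterionProfile:
    """The ordered nine-criterion presence/absence vector for one subject."""

    subject_id: str
    statuses: Mapping[str, Status]
    group: Optional[Group] = None

    def __post_init__(self) -> None:
        if tuple(self.statuses) != CRITERIA:
            raise ValidationError(
                "statuses must contain exactly the nine criteria in "
                f"canonical order; got {tuple(self.statuses)!r}")

    def __getitem__(self, criterion_id: str) -> Status:
        return self.statuses[criterion_id]


def erisman_index(chest_circumference: float, body_length: float) -> float:
    """Chest circumference minus half of body length (cm).

    Negative values indicate narrow-chested, disharmonious development —
    in this screening context a marker of the gracile athlete morphotype.
    """
    _check_positive("chest_circumference", chest_circumference)
    _check_positive("body_length", body_length)
    return chest_circumference - 0.5 * body_length


def proper_vlc(body_length: float, age: float) -> float:
    """Predicted ("proper") vital lung capacity in litres.

    Linear in height (cm) and age (years):
    ``pvlc = 0.041 * height - 0.018 * age - 3.7``.  The formula is only
    meaningful where it is positive; short or very young subjects fall
    outside its domain and raise :class:`DomainError`.
    """
    _check_positive("body_length", body_length)
    _check_positive("age", age)
    pvlc = body_length * 0.041 - age * 0.018 - 3.7
    if pvlc <= 0:
        raise DomainError(
            f"proper VLC formula out of domain: height {body_length} cm, "
            f"age {age} y gives pvlc = {pvlc:.3f} L <= 0")
    return pvlc


def vlc_ratio(vlc_actual: float, pvlc: float) -> float:
    """Ratio of actual to proper vital lung capacity.

    Values above 1 indicate above-norm respiratory function, the
    direction in which trained athletes exceed untrained peers.
    """
    _check_positive("vlc_actual", vlc_actual)
    if pvlc <= 0:
        raise DomainError(f"proper VLC must be positive, got {pvlc!r}")
    return vlc_actual / pvlc


def biceps_index(biceps_tense: float, biceps_rest: float) -> float:
    """Relative biceps circumference gain under tension, (tense-rest)/rest.

    The criterion compares the unrounded fraction against 0.067 (printed
    as 6.7%), so a subject at 6.67% is below threshold.
    """
    _check_positive("biceps_rest", biceps_rest)
    _check_positive("biceps_tense", biceps_tense)
    if biceps_tense < biceps_rest:
        logger.warning("biceps tense (%s) below rest (%s)",
                       biceps_tense, biceps_rest)
    return (biceps_tense - biceps_rest) / biceps_rest


def weight_deficit(record: SubjectRecord, norms: NormTable) -> Status:
    """Body-weight deficit relative to the height-interval norm.

    Present iff weight is strictly below ``M - delta_R`` for the interval
    containing the subject's height (regression-scale harmony rule).
    """
    if record.body_weight is None or record.body_length is None:
        return Status.MISSING
    norm = norms.weight_norm_for(record.body_length)
    below = record.body_weight < norm.M - norm.delta_R
    return Status.PRESENT if below else Status.ABSENT


def binarize(record: SubjectRecord, norms: NormTable) -> CriterionProfile:
    """Reduce one subject's measurements to the nine-criterion profile.

    Each criterion is a strict inequality in the printed direction; a
    value exactly on its threshold is *absent*.  Any criterion whose
    input measurements are missing gets status *missing*.
    """
    statuses: dict[str, Status] = {}

    def put(criterion: str, condition: Optional[bool]) -> None:
        if condition is None:
            statuses[criterion] = Status.MISSING
        else:
            statuses[criterion] = Status.PRESENT if condition else Status.ABSENT

    if (record.vlc_actual is None or record.body_length is None
            or record.age is None):
        put("vlc_ratio_gt1", None)
    else:
        ratio = vlc_ratio(record.vlc_actual,
                          proper_vlc(record.body_length, record.age))
        put("vlc_ratio_gt1", ratio > 1.0)

    if record.biceps_tense is None or record.biceps_rest is None:
        put("biceps_gt_6_7pct", None)
    else:
        put("biceps_gt_6_7pct",
            biceps_index(record.biceps_tense, record.biceps_rest)
            > BICEPS_THRESHOLD)

    statuses["weight_deficit"] = weight_deficit(record, norms)

    put("forward_bend_gt10s",
        None if record.forward_bend is None
        else record.forward_bend > FORWARD_BEND_THRESHOLD_S)
    put("splits_lt0",
        None if record.splits is None else record.splits < 0.0)

    if record.stange is None or record.age is None:
        put("stange_gt_norm", None)
    else:
        put("stange_gt_norm", record.stange > norms.stange_norm_for(record.age))
    if record.genchi is None or record.age is None:
        put("genchi_gt_norm", None)
    else:
        put("genchi_gt_norm", record.genchi > norms.genchi_norm_for(record.age))

    if record.chest_circumference is None or record.body_length is None:
        put("erisman_lt0", None)
    else:
        put("erisman_lt0",
            erisman_index(record.chest_circumference, record.body_length) < 0.0)

    put("crab_lt60",
        None if record.crab is None else record.crab < CRAB_THRESHOLD_CM)

    return CriterionProfile(record.subject_id, statuses, record.group)
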