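"""Synthetic two-cohort data with the structure the analysis assumes.

The reference study's raw data were never published, so validation rests
on synthetic cohorts generated at two tiers:

* **binary** — nine-criterion profiles for the two groups, with
  per-criterion presence either fixed to exact counts (so the estimation
  pipeline must recover them identically) or drawn as independent
  Bernoulli variables with per-group probabilities;
* **measurements** — full measurement records back-solved so that
  :func:`waldgenkin.indices.binarize` provably reproduces a target
  binary profile, exercising the index formulas end-to-end.

Criteria are generated independently (no correlation structure is
asserted by the method), and the measurement distributions are fixture
choices plausible for 11-13-year-old girls, not empirical claims.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .classify import DecisionConfig, Outcome, classify
from .errors import ValidationError
from .indices import (CRITERIA, CriterionProfile, Group, NormTable, Status,
                      SubjectRecord, binarize)
from .prognostic import PrognosticTable

_MAX_BACKSOLVE_ATTEMPTS = 25


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for one synthetic two-group cohort.

    Exactly one of ``fixed_counts`` (criterion -> (d1, d2), exact
    presence counts per group) or ``probabilities`` (criterion ->
    (p1, p2), Bernoulli presence probabilities) must be given, covering
    all nine criteria.  Defaults mirror the reference two-group design
    of 15 athletes vs 15 controls.
    """

    n1: int = 15
    n2: int = 15
    fixed_counts: Optional[Mapping[str, tuple[int, int]]] = None
    probabilities: Optional[Mapping[str, tuple[float, float]]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n1 < 1 or self.n2 < 1:
            raise ValidationError("group sizes must be >= 1")
        if (self.fixed_counts is None) == (self.probabilities is None):
            raise ValidationError(
                "give exactly one of fixed_counts or probabilities")
        if self.fixed_counts is not None:
            if set(self.fixed_counts) != set(CRITERIA):
                raise ValidationError("fixed_counts must cover all criteria")
            for criterion, (d1, d2) in self.fixed_counts.items():
                if not (0 <= d1 <= self.n1 and 0 <= d2 <= self.n2):
                    raise ValidationError(
                        f"{criterion}: counts ({d1}, {d2}) exceed group sizes")
        if self.probabilities is not None:
            if set(self.probabilities) != set(CRITERIA):
                raise ValidationError("probabilities must cover all criteria")
            for criterion, (p1, p2) in self.probabilities.items():
                if not (0.0 <= p1 <= 1.0 and 0.0 <= p2 <= 1.0):
                    raise ValidationError(
                        f"{criterion}: probabilities must lie in [0, 1]")


def _presence_matrix(spec: CohortSpec, rng: np.random.Generator
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Boolean (n, 9) presence matrices for group 1 and group 2."""
    mats = []
    for group_index, n in ((0, spec.n1), (1, spec.n2)):
        mat = np.zeros((n, len(CRITERIA)), dtype=bool)
        for j, criterion in enumerate(CRITERIA):
            if spec.fixed_counts is not None:
                d = spec.fixed_counts[criterion][group_index]
                chosen = rng.choice(n, size=d, replace=False)
                mat[chosen, j] = True
            else:
                p = spec.probabilities[criterion][group_index]
                mat[:, j] = rng.random(n) < p
        mats.append(mat)
    return mats[0], mats[1]


def _profiles_from_matrix(mat: np.ndarray, group: Group, prefix: str
                          ) -> list[CriterionProfile]:
    profiles = []
    for i, row in enumerate(mat):
        statuses = {c: (Status.PRESENT if row[j] else Status.ABSENT)
                    for j, c in enumerate(CRITERIA)}
        profiles.append(CriterionProfile(f"{prefix}{i + 1:03d}", statuses,
                                         group))
    return profiles


def generate_binary(spec: CohortSpec) -> list[CriterionProfile]:
    """Generate labelled binary criterion profiles for both groups.

    With fixed counts, exactly ``d`` presences are assigned to a seeded
    random subset of each group; with probabilities, independent
    Bernoulli draws.  Reproducible under an identical spec and seed.
    """
    rng = np.random.default_rng(spec.seed)
    mat1, mat2 = _presence_matrix(spec, rng)
    return (_profiles_from_matrix(mat1, Group.ATHLETE, "A")
            + _profiles_from_matrix(mat2, Group.CONTROL, "C"))


def _backsolve_record(subject_id: str, group: Group,
                      target: Mapping[str, Status], norms: NormTable,
                      rng: np.random.Generator) -> SubjectRecord:
    """Draw plausible measurements, then nudge each field across or away
    from its criterion threshold so binarize() reproduces *target*."""
    present = {c: target[c] is Status.PRESENT for c in CRITERIA}

    age = float(np.clip(rng.normal(12.0, 0.4), 10.5, 13.5))
    height_lo = norms.weight_norms[0].min_height
    height_hi = norms.weight_norms[-1].max_height
    body_length = float(np.clip(rng.normal(152.0, 6.0),
                                height_lo + 1.0, height_hi - 1.0))

    pvlc = body_length * 0.041 - age * 0.018 - 3.7
    if present["vlc_ratio_gt1"]:
        ratio = 1.0 + rng.uniform(0.02, 0.25)
    else:
        ratio = 1.0 - rng.uniform(0.02, 0.25)
    vlc_actual = pvlc * ratio

    biceps_rest = float(np.clip(rng.normal(21.0, 1.5), 17.0, 26.0))
    frac = (rng.uniform(0.072, 0.13) if present["biceps_gt_6_7pct"]
            else rng.uniform(0.0, 0.062))
    biceps_tense = biceps_rest * (1.0 + frac)

    norm = norms.weight_norm_for(body_length)
    if present["weight_deficit"]:
        body_weight = norm.M - norm.delta_R - rng.uniform(0.5, 4.0)
    else:
        body_weight = norm.M - norm.delta_R + rng.uniform(0.5, 2 * norm.delta_R)

    forward_bend = (rng.uniform(10.5, 25.0) if present["forward_bend_gt10s"]
                    else rng.uniform(2.0, 9.5))
    splits = (-rng.uniform(0.5, 8.0) if present["splits_lt0"]
              else rng.uniform(0.5, 12.0))

    stange_ref = norms.stange_norm_for(age)
    stange = (stange_ref + rng.uniform(2.0, 15.0) if present["stange_gt_norm"]
              else max(5.0, stange_ref - rng.uniform(2.0, 15.0)))
    genchi_ref = norms.genchi_norm_for(age)
    genchi = (genchi_ref + rng.uniform(2.0, 12.0) if present["genchi_gt_norm"]
              else max(3.0, genchi_ref - rng.uniform(2.0, 12.0)))

    offset = rng.uniform(0.5, 4.0)
    chest = 0.5 * body_length + (-offset if present["erisman_lt0"] else offset)

    crab = (rng.uniform(40.0, 58.0) if present["crab_lt60"]
            else rng.uniform(62.0, 90.0))

    return SubjectRecord(
        subject_id=subject_id, group=group,
        age=round(age, 1), body_length=round(body_length, 1),
        body_weight=round(body_weight, 1),
        chest_circumference=round(chest, 1),
        vlc_actual=round(vlc_actual, 2),
        biceps_tense=round(biceps_tense, 1), biceps_rest=round(biceps_rest, 1),
        stange=round(stange, 1), genchi=round(genchi, 1),
        splits=round(splits, 1), crab=round(crab, 1),
        forward_bend=round(forward_bend, 1))


def generate_measurements(spec: CohortSpec, norms: NormTable
                          ) -> list[SubjectRecord]:
    """Generate full measurement records realising the spec's binary
    structure; guaranteed (verified per subject, with bounded retries)
    to binarize back to the generated target profiles."""
    rng = np.random.default_rng(spec.seed)
    mat1, mat2 = _presence_matrix(spec, rng)
    targets = (_profiles_from_matrix(mat1, Group.ATHLETE, "A")
               + _profiles_from_matrix(mat2, Group.CONTROL, "C"))
    records = []
    for profile in targets:
        for attempt in range(_MAX_BACKSOLVE_ATTEMPTS):
            record = _backsolve_record(profile.subject_id, profile.group,
                                       profile.statuses, norms, rng)
            if binarize(record, norms).statuses == dict(profile.statuses):
                records.append(record)
                break
        else:
            raise ValidationError(
                f"could not realise target profile for {profile.subject_id} "
                f"after {_MAX_BACKSOLVE_ATTEMPTS} attempts")
    return records


@dataclass(frozen=True)
class GroupRates:
    """Outcome rates for one simulated group, with MC standard errors."""

    n: int
    success: float
    low_probability: float
    uncertain: float

    def se(self, rate: float) -> float:
        return float(np.sqrt(rate * (1.0 - rate) / self.n))


@dataclass(frozen=True)
class SimulationSummary:
    athletes: GroupRates
    controls: GroupRates

    @property
    def false_success_rate(self) -> float:
        """Controls wrongly concluded to have high success probability."""
        return self.controls.success

    @property
    def false_low_rate(self) -> float:
        """Athletes wrongly concluded to have low success probability."""
        return self.athletes.low_probability


def simulate_error_rates(spec: CohortSpec, table: PrognosticTable,
                         config: DecisionConfig, n_subjects: int,
                         seed: int) -> SimulationSummary:
    """Monte-Carlo check of the threshold's nominal error semantics.

    Draws ``n_subjects`` fresh subjects per group from the spec's
    per-criterion Bernoulli probabilities, classifies each against
    *table* under *config*, and reports per-group outcome rates.  The
    draw stream depends only on the spec and *seed*, not on *config*,
    so thresholds can be compared on common random numbers.
    """
    if spec.probabilities is None:
        raise ValidationError(
            "simulate_error_rates needs a probability-mode CohortSpec")
    if n_subjects < 100:
        raise ValidationError("n_subjects must be >= 100")
    rng = np.random.default_rng(seed)
    sim_spec = CohortSpec(n1=n_subjects, n2=n_subjects,
                          probabilities=spec.probabilities, seed=seed)
    mat1, mat2 = _presence_matrix(sim_spec, rng)
    summaries = []
    for mat, group, prefix in ((mat1, Group.ATHLETE, "simA"),
                               (mat2, Group.CONTROL, "simC")):
        tally = {Outcome.SUCCESS: 0, Outcome.LOW_PROBABILITY: 0,
                 Outcome.UNCERTAIN: 0}
        for profile in _profiles_from_matrix(mat, group, prefix):
            tally[classify(profile, table, config).outcome] += 1
        summaries.append(GroupRates(
            n=n_subjects,
            success=tally[Outcome.SUCCESS] / n_subjects,
            low_probability=tally[Outcome.LOW_PROBABILITY] / n_subjects,
            uncertain=tally[Outcome.UNCERTAIN] / n_subjects))
    return SimulationSummary(athletes=summaries[0], controls=summaries[1])
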