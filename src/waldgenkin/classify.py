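"""Sequential classification by cumulative deciban summation.

An individual prediction walks the prognostic table top-down: for each
criterion the presence coefficient is added when the subject shows it
and the absence coefficient when they do not, and summation stops as
soon as the running total reaches ``+T`` (conclude: high probability of
success) or ``-T`` (low probability).  If the table is exhausted without
crossing either threshold the prediction is *uncertain* and further
examination is advised.  The threshold follows Wald's symmetric
approximation ``T = 10 * log10((1 - alpha) / alpha)`` decibans for an
allowable error probability ``alpha`` — 13 points at 5% error, 30 at
0.1%.

By default summation uses the display-rounded (one-decimal)
coefficients, because the published table *is* the instrument a
practitioner sums from; unrounded summation is available for
sensitivity analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import NamedTuple, Optional

from ._round import round_half_up
from .errors import ValidationError
from .indices import CriterionProfile, Status
from .prognostic import PrognosticTable

_EPS = 1e-9


class Outcome(str, Enum):
    SUCCESS = "success"
    LOW_PROBABILITY = "low_probability"
    UNCERTAIN = "uncertain"


def threshold_from_error(alpha: float) -> int:
    """Deciban threshold (whole points) for an allowable error *alpha*.

    ``round_half_up(10 * log10((1 - alpha) / alpha))``: 0.05 -> 13,
    0.001 -> 30.
    """
    if not 0 < alpha < 0.5:
        raise ValidationError(f"alpha must lie in (0, 0.5), got {alpha!r}")
    return int(round_half_up(10.0 * math.log10((1.0 - alpha) / alpha), 0))


@dataclass(frozen=True)
class DecisionConfig:
    """Stopping rule: symmetric thresholds at ``+/- threshold_points``.

    ``threshold_points`` is derived from ``alpha`` when not given.
    ``use_rounded_coefficients`` selects summation of the printed
    one-decimal coefficients (default) vs full precision.
    """

    alpha: float = 0.05
    threshold_points: Optional[float] = None
    symmetric: bool = True
    use_rounded_coefficients: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 0.5:
            raise ValidationError(
                f"alpha must lie in (0, 0.5), got {self.alpha!r}")
        if self.threshold_points is None:
            object.__setattr__(self, "threshold_points",
                               float(threshold_from_error(self.alpha)))
        if self.threshold_points <= 0:
            raise ValidationError("threshold_points must be positive")


class TraceStep(NamedTuple):
    criterion_id: str
    status: Status
    coefficient: float
    cumulative: float


@dataclass(frozen=True)
class PredictionTrace:
    """Step-by-step record of one subject's sequential prediction."""

    subject_id: str
    steps: tuple[TraceStep, ...]
    skipped: tuple[str, ...]
    outcome: Outcome
    stopping_step: Optional[int]  # 1-based index into steps; None if exhausted
    threshold: float

    @property
    def final_sum(self) -> float:
        return self.steps[-1].cumulative if self.steps else 0.0


def classify(profile: CriterionProfile, table: PrognosticTable,
             config: DecisionConfig = DecisionConfig()) -> PredictionTrace:
    """Sequentially sum coefficients for one subject until a threshold
    is crossed.

    Rows whose status is *missing* are skipped (recorded in
    ``trace.skipped``), never treated as absence: in this instrument an
    observed absence is itself evidence, while a missing measurement is
    not.  Crossing exactly at ``+/-T`` counts as reached.
    """
    if len(table) == 0:
        raise ValidationError("prognostic table is empty")
    threshold = float(config.threshold_points)
    steps: list[TraceStep] = []
    skipped: list[str] = []
    cumulative = 0.0
    outcome = Outcome.UNCERTAIN
    stopping_step: Optional[int] = None
    for row in table:
        status = profile[row.criterion_id]
        if status is Status.MISSING:
            skipped.append(row.criterion_id)
            continue
        if status is Status.PRESENT:
            coefficient = (row.pc_presence_display
                           if config.use_rounded_coefficients
                           else row.pc_presence)
        else:
            coefficient = (row.pc_absence_display
                           if config.use_rounded_coefficients
                           else row.pc_absence)
        cumulative += coefficient
        steps.append(TraceStep(row.criterion_id, status, coefficient,
                               round(cumulative, 10)))
        if cumulative >= threshold - _EPS:
            outcome = Outcome.SUCCESS
            stopping_step = len(steps)
            break
        if cumulative <= -threshold + _EPS:
            outcome = Outcome.LOW_PROBABILITY
            stopping_step = len(steps)
            break
    return PredictionTrace(profile.subject_id, tuple(steps), tuple(skipped),
                           outcome, stopping_step, threshold)
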