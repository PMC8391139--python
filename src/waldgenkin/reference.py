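"""The published artistic-swimming screening table, as printed.

The original study screened 15 trained artistic-swimming athletes
against 15 untrained schoolgirls (average age 12) and published only the
rounded instrument: nine criteria with presence/absence coefficients to
one decimal and informativeness to two.  The underlying per-criterion
counts were not published, but each printed coefficient *pair*
over-determines them: :func:`reference_counts` recovers the unique
integer ``(d1, d2)`` out of 15 vs 15 for every row by exhaustive search,
and :func:`reference_table` rebuilds the full-precision table from those
counts.  Matching all 27 printed numbers after display rounding is the
package's flagship consistency check.
"""

from __future__ import annotations

from typing import NamedTuple

from .prognostic import (GradationCounts, PrognosticTable, build_table,
                         invert_pc_pair)

#: Group sizes of the reference study (athletes, controls).
REFERENCE_GROUP_SIZES = (15, 15)


class PrintedRow(NamedTuple):
    criterion_id: str
    pc_presence: float
    pc_absence: float
    informativeness: float


#: The instrument as printed: criterion, presence/absence coefficients
#: (decibans, 1 decimal), informativeness (2 decimals), in published order.
PRINTED_ROWS: tuple[PrintedRow, ...] = (
    PrintedRow("vlc_ratio_gt1", 10.8, -6.7, 395.70),
    PrintedRow("biceps_gt_6_7pct", 10.0, -4.5, 300.00),
    PrintedRow("weight_deficit", 9.5, -3.7, 254.46),
    PrintedRow("forward_bend_gt10s", 6.7, -10.8, 245.30),
    PrintedRow("splits_lt0", 6.7, -10.8, 245.30),
    PrintedRow("stange_gt_norm", 3.8, -5.2, 88.72),
    PrintedRow("genchi_gt_norm", 3.0, -4.8, 60.21),
    PrintedRow("erisman_lt0", 2.4, -8.5, 48.61),
    PrintedRow("crab_lt60", 1.9, -7.8, 31.98),
)


def reference_counts() -> dict[str, GradationCounts]:
    """Recover each printed row's integer counts by exhaustive inversion."""
    s1, s2 = REFERENCE_GROUP_SIZES
    return {
        row.criterion_id:
            invert_pc_pair(row.pc_presence, row.pc_absence, s1, s2).counts
        for row in PRINTED_ROWS
    }


def reference_table() -> PrognosticTable:
    """The reference screening table rebuilt at full precision from the
    reconstructed counts (no smoothing: all recovered counts are interior)."""
    return build_table(reference_counts(), smoothing=0.0)
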