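import pytest

import waldgenkin as wg

#: Integer counts (d1, d2) out of 15 vs 15 behind each printed row,
#: recovered independently by exhaustive search and frozen here.
EXPECTED_COUNTS = {
    "vlc_ratio_gt1": (12, 1),
    "biceps_gt_6_7pct": (10, 1),
    "weight_deficit": (9, 1),
    "forward_bend_gt10s": (14, 3),
    "splits_lt0": (14, 3),
    "stange_gt_norm": (12, 5),
    "genchi_gt_norm": (12, 6),
    "erisman_lt0": (14, 8),
    "crab_lt60": (14, 9),
}


@pytest.fixture(scope="session")
def norms() -> wg.NormTable:
    return wg.default_norms()


@pytest.fixture(scope="session")
def reference_table() -> wg.PrognosticTable:
    return wg.reference_table()


def make_profile(statuses_by_criterion, subject_id="subj", group=None):
    """Build a CriterionProfile from {criterion: True/False/None}."""
    mapping = {}
    for criterion in wg.CRITERIA:
        value = statuses_by_criterion.get(criterion)
        if value is None:
            mapping[criterion] = wg.Status.MISSING
        else:
            mapping[criterion] = (wg.Status.PRESENT if value
                                  else wg.Status.ABSENT)
    return wg.CriterionProfile(subject_id, mapping, group)


def uniform_profile(present: bool, subject_id="subj", group=None):
    return make_profile({c: present for c in wg.CRITERIA}, subject_id, group)
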