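"""Classify individual candidates by sequential deciban summation.

Walking the table top-down, each observed criterion adds its presence
coefficient and each unmet criterion its (negative) absence
coefficient; summation stops as soon as the running total reaches +13
(high probability of success at 5% allowable error) or -13 (low
probability).  A table exhausted in between means the prediction is
uncertain and further examination is needed.
"""

import waldgenkin as wg
from waldgenkin.indices import Status

table = wg.reference_table()
config = wg.DecisionConfig(alpha=0.05)
print(f"threshold: +/-{config.threshold_points:.0f} decibans\n")

order = [row.criterion_id for row in table]
candidates = {
    "strong": [True] * 9,
    "weak": [False] * 9,
    "ambiguous": [True, False, False, False, True, True, True, True, True],
}

for name, pattern in candidates.items():
    statuses = {c: (Status.PRESENT if met else Status.ABSENT)
                for c, met in zip(order, pattern)}
    profile = wg.CriterionProfile(
        name, {c: statuses[c] for c in wg.CRITERIA})
    trace = wg.classify(profile, table, config)
    sums = " -> ".join(f"{s.cumulative:+.1f}" for s in trace.steps)
    stop = (f"stopped at step {trace.stopping_step}"
            if trace.stopping_step else "table exhausted")
    print(f"{name:<10} {sums}")
    print(f"{'':<10} {stop}; outcome: {trace.outcome.value}\n")

# "strong" crosses +13 after only two criteria, "weak" crosses -13 at
# the third, and "ambiguous" drifts between the thresholds - the three
# possible conclusions of the sequential procedure.
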