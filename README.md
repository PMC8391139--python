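# waldgenkin

Wald–Genkin sequential prognostic tables for two-group morphofunctional
screening, built around the published instrument for artistic-swimming
talent selection.

## The problem

Coaches selecting children for artistic swimming want an early, cheap,
objective screen: given a candidate's anthropometric indices and
functional test results, how likely is she to develop like a trained
athlete?  The Wald–Genkin approach answers this with a *prognostic
table* estimated from two reference cohorts — trained athletes and
untrained peers — and a sequential decision rule that a practitioner
can apply with pencil and paper.

## The method

Each subject is reduced to nine binary criteria (all strict
inequalities): the ratio of actual to proper vital lung capacity
`VLC / pVLC > 1` with `pVLC = 0.041·height − 0.018·age − 3.7` (L),
biceps index `(tense − rest)/rest > 6.7 %`, body-weight deficit
(weight `< M − δ_R` for the height interval), "Forward bend" `> 10 s`,
"Splits" `< 0 cm`, Stange and Genchi breath-holds above the age norm,
Erisman index `chest − height/2 < 0 cm`, and "Crab position" `< 60 cm`.

For a criterion present in `d₁` of `s₁` athletes and `d₂` of `s₂`
controls, the predictive coefficients (decibans) and Kullback
informativeness are

```
PC_presence = 10·log₁₀(P₁/P₂),   PC_absence = 10·log₁₀((1−P₁)/(1−P₂)),
I = ½ · PC_presence · (100·P₁ − 100·P₂),        P_k = d_k/s_k.
```

Criteria with `I < 30.0` are discarded; the rest are ranked by
descending `I`.  An individual prediction sums the (printed,
one-decimal) coefficients top-down — presence coefficient when the
criterion is met, absence coefficient when it is not — and stops at the
first crossing of `±T`, where `T = 10·log₁₀((1−α)/α)` (13 points at
α = 0.05).  Crossing `+T` means high probability of success, `−T` low
probability, and an exhausted table an uncertain prediction.

The published table prints only rounded values, but each coefficient
*pair* over-determines its integer counts: `invert_pc_pair` recovers
them by exhaustive search, which is how the packaged reference table is
reconstructed — and validated against all 27 printed numbers.

## Worked example

```python
import waldgenkin as wg

table = wg.reference_table()          # rebuilt from the printed pairs
row = table.rows[0]
print(row.criterion_id, row.counts.d1, row.counts.d2,
      row.pc_presence_display, row.pc_absence_display,
      row.informativeness_display)
# vlc_ratio_gt1 12 1 10.8 -6.7 395.7
```

12 of 15 athletes but only 1 of 15 controls exceeded a VLC/pVLC ratio
of 1, giving +10.8 decibans when the criterion is observed, −6.7 when
it is not, and informativeness 395.70 — the top-ranked criterion.
Classifying a candidate who meets every criterion:

```python
profile = wg.binarize(record, wg.default_norms())   # a SubjectRecord
trace = wg.classify(profile, table, wg.DecisionConfig(alpha=0.05))
print([s.cumulative for s in trace.steps], trace.outcome.value)
# [10.8, 20.8] success
```

The running sum crosses +13 after only two criteria, so the procedure
stops: high probability of success at 5% allowable error.  The
`examples/` scripts walk through reconstruction, end-to-end table
estimation from a synthetic measurement cohort, sequential prediction,
and a Monte-Carlo check of the threshold's error semantics; the same
pipeline is exposed on the command line via `waldgenkin indices`,
`build-table`, `predict`, `simulate` and `reproduce-reference`.

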