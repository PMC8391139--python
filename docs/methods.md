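# Methods

## Model and procedure

The package implements a two-group sequential prognostic procedure in
the Wald–Genkin tradition.  Nine binary criteria are derived from
anthropometric indices and functional tests; for each criterion the
evidence carried by observing it (or not) is a log-likelihood ratio in
decibans,

    PC_presence = 10 log10(P1 / P2),
    PC_absence  = 10 log10((1 - P1) / (1 - P2)),

with `P_k = d_k / s_k` the presence proportion in group *k* (group 1:
trained athletes, group 2: untrained controls).  Individual prediction
is a sequential probability ratio test over the table rows: the running
deciban sum stops at the first crossing of `±T`,
`T = 10 log10((1 - α)/α)`, giving the three outcomes *success*
(`≥ +T`), *low probability* (`≤ -T`) and *uncertain* (table exhausted).
The procedure assumes criteria are conditionally independent given
group membership — the classical naive-Bayes reading of summing
per-criterion log-likelihood ratios — and that the reference cohorts
are representative of the screened population.

## Informativeness

Criteria are ranked by the presence-gradation Kullback informativeness

    I = 0.5 · PC_presence · (100·P1 − 100·P2),

computed from the *unrounded* coefficient and displayed to two
decimals.  This is the form that reproduces the published instrument
exactly (the (9, 1) row gives 254.46 with the unrounded coefficient vs
253.33 with the printed 9.5 — a deliberate sensitivity check in the
tests).  The full symmetrised Kullback divergence, which adds the
matching absence term, is available via
`informativeness(..., both_gradations=True)`; it is never smaller than
the presence term and is not what published tables of this family
print.  Rows with `I < 30.0` are discarded as insignificant (values
exactly at 30.0 are retained); ranking is by descending `I` with ties
broken deterministically by the fixed criterion order rather than at
random, so identical inputs always yield identical tables.

## Criterion definitions and boundary semantics

Every criterion is a strict inequality in the printed direction; a
value exactly on its threshold scores *absent*.  Specifics worth
noting:

* **VLC ratio** is actual/proper (the direction in which trained
  athletes exceed 1); the proper VLC `0.041·height − 0.018·age − 3.7`
  is meaningful only where positive, and out-of-domain inputs raise an
  error rather than returning a negative capacity.
* **Biceps index** compares the unrounded fraction against 0.067, so
  6.67 % is below the 6.7 % threshold — no intermediate percent
  rounding.
* **Weight deficit** uses the regression-scale rule
  `weight < M − δ_R` for the height interval containing the subject;
  only this branch feeds the table (chest harmony is out of scope).
* **Splits < 0 cm** presumes the bench-elevated athlete protocol in
  which the groin can descend below foot level; for subjects measured
  flat-footed the criterion is simply never present.
* **Missing measurements** produce a *missing* status, and the
  classifier skips that row entirely.  Absence is an informative
  observation in this instrument; a measurement that was never taken is
  not, and defaulting it to absence would inject spurious negative
  evidence.

Norm tables (weight-for-height M ± δ_R, Stange/Genchi age norms) are
runtime configuration loaded from YAML/JSON.  The packaged
`default_norms()` is a synthetic fixture with values plausible for
11–13-year-old girls; it stands in for locale-specific
physical-development standards, which users should supply for real
screening.

## Table reconstruction oracle

Published tables print coefficients to one decimal only, but the
presence/absence pair of a row is a function of the integer counts
`(d1, d2)`, and over group sizes of 15 vs 15 only 256 candidates exist.
`invert_pc_pair` searches them all and returns every pair whose
unrounded coefficients round (half-up, one decimal) to the printed
values.  For all nine rows of the reference instrument the match is
unique, and rebuilding the table from the recovered counts reproduces
all 27 printed numbers — the package's flagship consistency check,
also exercised as a round trip over all 196 interior count pairs.
Degenerate counts (a zero cell) are excluded from the search since
their coefficients are infinite without smoothing.

## Numerical choices

* **Display rounding** is half-up (away from zero on ties) via
  `decimal`, to one decimal for coefficients and two for
  informativeness, matching spreadsheet conventions; Python's banker's
  rounding would disagree on exact halves.
* **Continuity correction**: a zero cell makes the log-ratio infinite.
  `smoothing` (default 0.5) is added Haldane–Anscombe-style to the
  proportions, but *only* when some cell is empty, so interior counts —
  including every reference row — are computed exactly as printed.
  With `smoothing=0` degenerate counts raise an explicit error.
* **Summation** uses the display-rounded coefficients by default,
  because the printed table is the instrument practitioners actually
  sum from; `DecisionConfig(use_rounded_coefficients=False)` switches
  to full precision for sensitivity analysis.  Threshold crossing is
  tested with a 1e-9 tolerance so a sum that equals `±T` exactly (e.g.
  by construction in tests) counts as reached.
* **Thresholds** are whole points, `round_half_up(10·log10((1−α)/α))`:
  α = 0.05 → 13, α = 0.001 → 30.  Note the often-quoted "80 %
  confidence ↔ 8 points" correspondence is not consistent with this
  formula (80 % gives 6 points; 8 points corresponds to ≈ 86 %); the
  package follows the formula.

## Synthetic cohorts

The generator emulates the 15 + 15 two-group design at two tiers.  The
*binary* tier draws criterion profiles directly — either with exact
per-criterion counts (assigned to a seeded random subset, so estimation
must recover them identically) or as independent Bernoulli draws with
per-group probabilities.  The *measurements* tier back-solves full
records: plausible values are drawn per field (normal/uniform choices
with means and spreads appropriate to 12-year-old girls — fixture
choices, not empirical claims) and each field is then placed on the
target side of its criterion threshold, with the realised record
verified by `binarize` and regenerated on the rare rounding-induced
mismatch (bounded retries).

What passing these tests shows: the estimation pipeline is exact on
counts, the index formulas and thresholds are wired correctly end to
end, and the threshold semantics hold *under the generating model*
(independent criteria, stationary probabilities).  What they do not
show: performance on real cohorts, where criteria are correlated
(flexibility tests correlate with each other; respiratory criteria
share physiology), norms may mismatch the population, and the table's
own counts are estimates from only 15 subjects per group.
`simulate_error_rates` uses common random numbers across threshold
settings, so threshold comparisons are paired.

## Known limitations

* Binary gradations only; multi-level features and asymmetric α/β
  thresholds are out of scope.
* No confidence intervals on coefficients — with s = 15 they would be
  wide; the informativeness ranking should be read as descriptive.
* The independence assumption is untested against real data (none were
  published with the reference instrument).
* Monte-Carlo error rates in the tests use 2,000–10,000 subjects per
  group, sizes at which the MC standard error is well below the 5%
  nominal band being checked.
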