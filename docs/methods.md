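# Methods

## The screening model

The pipeline targets a specific signal: probe-level expression that
drifts *monotonically and gradually* with chronological age, as opposed
to a step difference between age groups.  The screen's estimator is
deliberately simple — window averaging followed by correlation — because
at cohort sizes of a few dozen samples a per-sample regression on age is
dominated by inter-individual variability; averaging ten age-adjacent
samples suppresses that variability by roughly √10 before the trend
statistic is computed.

Given samples ordered by age (stable sort: equal ages keep input order,
which matters because window membership — and hence every downstream
number — depends on it), windows of `w` consecutive samples advance by
`step`.  With `n` samples there are `(n − w)//step + 1` windows; for the
reference cohort size (n = 38, w = 10, step 1) that is 29.  Published
descriptions of this design sometimes count one fewer window (dropping
the final slide); the `n_windows` and `drop_last` options reproduce that
counting without silently changing the default arithmetic.

Per probe, the window-mean series is z-scored with the population-sd
convention (the choice does not affect the Pearson correlation, but it
makes each standardized row exactly unit variance).  Trend strength is
the Pearson correlation between the z-row and the windows' mean ages.
Retention requires both correlation and effect size:

* increasing: r ≥ 0.75 and FC ≥ 1.5,
* decreasing: r ≤ −0.75 and FC ≤ 1/1.5,

where FC = 2^(m_last − m_first) is the last/first-window expression
ratio on the linear scale (the matrix is assumed log2; a `linear` mode
divides the window means directly and requires a positive first-window
mean).  Fold changes are rounded to two decimals *before* the threshold
comparison: reference results list values such as 1.497 and 1.498 as
passing the 1.5 cut, so the screen's contract is "1.5 at two-decimal
precision", and the decreasing cut is likewise 0.67.  Probes with a
constant window-mean series have undefined correlation; they are flagged
and never retained.

The candidate cascade downstream (`candidate_filter`) deliberately does
**not** round: its cut ("fold change beyond 2×") compares unrounded
values, so FC 1.998 fails a cut of 2 while FC 0.498 passes the lower
cut.  Rounding there would miscount the reference candidate list; the
two rules differ because they reproduce two differently-behaving printed
tables, and both are stated contracts with tests.

## Trajectories, crossing age, acceleration

The increasing and decreasing sets are each summarized by the unweighted
mean of their members' z-rows.  The *crossing age* formalizes a
judgement usually made by eye on such plots: with
d(k) = mean_z_inc(k) − mean_z_dec(k), each sign change of d is located
by linear interpolation between the bracketing window mean ages (an
exact zero reports the window age itself).  All crossings are reported;
the youngest is primary.  Crossing ages are invariant to swapping the
class labels and to adding a constant to both trajectories (tested).

The *acceleration interval* formalizes "the trend is steepest here":
central-difference slopes |d′| are computed on d against window mean
age, and the interval is the age span of the longest contiguous run of
windows at or above the 0.75 quantile of all slopes.  The quantile is
configurable; 0.75 selects roughly the top quarter of windows, matching
the intuition of an interval a reader would mark on the plot.  If every
slope is equal (linear d) there is no distinguished run and the full age
range is returned with a flag.  No confidence interval is attached — the
uncertainty of the crossing age is only characterized descriptively, by
seed replication in the tests.

## Differential expression

The two-group comparison splits at 50 years (young ≤ 50 < elder —
boundary on the young side, matching the reference cohort's 21/17
split).  The statistic is the equal-variance pooled t with
empirical-Bayes variance moderation: per-probe pooled variances s² with
d residual df are modelled as s² ~ s0²·F(d, d0), and (d0, s0²) are
fitted by matching the mean and variance of log s² (digamma/trigamma
moments, trigamma inverted by Newton iteration).  The moderated
variance s²_mod = (d0·s0² + d·s²)/(d0 + d) and t on d0 + d df follow.
When the observed log-variances are no more dispersed than sampling
alone explains, d0 is infinite and all probes share s0².  With
`prior_df_mode="none"` the ordinary pooled t is recovered exactly
(tested to 1e-9 against scipy), and the eb mode is cross-checked against
the Bioconductor linear-model implementation via Rscript in the test
suite.  Equal-variance (not Welch) pooling is used because the moderated
t is defined through the linear-model residual variance.

BH adjustment is delegated to statsmodels (`fdr_bh`) and verified in
tests against a direct step-up evaluation.  Calls are UP/DOWN only when
the BH-adjusted p is below α = 0.05, with direction from the
elder/young fold change 2^(mean_elder − mean_young).

## Integration and enrichment

Screen comparison is exact string-match set algebra on probeset ids,
reported per sncRNA class (miRNA identified by the `hsa-` prefix
convention of the packaged tables).  Overlap percentages use the union
as denominator; the intersection and union are both reported so either
convention can be checked.

Name matching against literature-derived sets strips the array suffixes
(`_st`, `_x_st`, `_s_st`), rewrites `-star` to `*`, applies a small
static miRBase rename table, and drops the species prefix.  The rename
table is packaged (live nomenclature services are out of scope) and
limited to well-established star→arm renames; suffix stripping alone is
sufficient to reproduce the reference candidate list.

Enrichment is the MSigDB-style overlap test: for a query of n genes and
a set with K genes in a universe of N, p = P(X ≥ k) for hypergeometric
X (scipy's survival function; verified against brute-force tail sums for
N ≤ 30).  The default universe is the union of the GMT's genes —
conservative and self-contained; a larger universe (e.g. all assayed
genes) can be passed explicitly and makes overlaps more significant.
BH runs across all sets; rows with q < 0.05 are returned, best-first,
truncated to 20.

## qPCR quantification

ΔCq referencing uses a single housekeeping assay (default miR-191);
ΔΔCq is the difference of *group mean* ΔCq (Livak convention — medians
would be more robust but the group-mean form is the standard contract),
and RQ = 2^−ΔΔCq, so RQ(elder vs young)·RQ(young vs elder) = 1
identically.  Group comparison uses the Wilcoxon rank-sum test: the
exact permutation distribution when the pooled sample has ≤ 20 untied
observations (enumerable, and oracle-checked by full enumeration in
tests), otherwise the normal approximation with tie and continuity
corrections.  Age-bin summaries assign samples to closed intervals
(default 24–40, 41–60, 61–70, 71–80, 81–90); ages falling in the gaps
between printed bins are left unassigned rather than silently snapped.

## Quantile normalization

Each sample column is mapped onto the across-sample mean of the sorted
columns; ties within a column receive the mean of the reference values
their positions span.  The vendor tool's exact tie rule is unpublished;
average-of-ties is the field convention.  Exact idempotence holds for
tie-free columns (tested); with ties, re-application perturbs values at
the order of the within-tie reference spread, which is why the
idempotence contract is stated tie-free.  Background/detection calls of
the vendor pipeline are not reimplemented; a pre-made keep-list can be
supplied to `filter_probes` instead.

## The synthetic cohort generator

`generate_cohort` emulates the statistical structure the screen assumes:
ages uniform on [24, 79] (an explicit age list can be passed to match a
real cohort's histogram), per-probe log2 trajectories

m_i(age) = b_i ± A_i · L((age − a0)/τ),  L(u) = 1/(1 + e^−u),

with baseline b_i ~ U(6, 10) (typical log2 microarray intensity range),
inflection a0 = 50 y, width τ = 4 y, amplitude A = 1 log2 unit (expected
last/first FC ≈ 2, comfortably above the 1.5 retention cut), and i.i.d.
Gaussian noise σ = 0.3 log2 units — a standard microarray error scale.
Defaults: 38 samples, 500 probes, 10 % increasing / 5 % decreasing /
85 % null.  The logistic shape was chosen over a linear ramp because it
produces both phenomena the trajectory stage measures: a crossing of
the mean z-curves at a0 and a slope maximum (acceleration) around it.

What the generator does *not* emulate: batch effects, probe-level
Affymetrix intensity structure, heteroskedastic noise, correlated
probes, or non-uniform age sampling.  Passing simulation tests therefore
demonstrate correctness of the estimators under the assumed generative
model, not robustness to real-array artefacts.

`generate_cq` draws reference-assay Cq ~ N(20, sd²) and target Cq =
reference + 4 + ΔΔCq·[elder] + noise, so the true RQ is 2^−ΔΔCq by
construction.

## Problem sizes and determinism

Simulation-based checks use 20 seeds at the default cohort size
(500 probes × 38 samples) and 1000-probe null matrices for the
type-I-error calibration; these sizes give Monte-Carlo error well inside
the asserted bands while keeping the full suite and the acceptance
script in the seconds range.  All randomness flows through
`numpy.random.default_rng` seeded from explicit configuration, and
pipeline reruns with the same configuration produce byte-identical
outputs (asserted in tests).

## Known limitations

* The window count convention (29 vs 28 for n = 38) is genuinely
  ambiguous in the field's descriptions; both are supported, neither is
  silently preferred.
* The moderated t matches the reference implementation's default path
  only (no trend/robust variants).
* No uncertainty quantification for the crossing age or acceleration
  interval beyond seed replication.
* Missing values are rejected rather than imputed; the pipeline assumes
  a complete post-normalization matrix.
* Enrichment p-values depend on the universe choice; with the default
  (GMT union) they are not comparable to results computed against a
  whole-genome universe.
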