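# Methods

## Model and selection framework

`K` candidate binary classifiers are screened on known cases. Stage-1
true-positive counts are independent binomials, `X_i ~ Bin(n1_i, s_i)`,
with `s_i` the unknown sensitivity of classifier `i`. The design fixes, per
classifier, a futility cut-off `c_i ≥ 0` (a classifier survives iff
`X_i ≥ c_i`; non-integer cut-offs act through their ceiling, so the
effective bound on a count is `⌈c_i⌉`) and a ranking rule over survivors.
If no classifier survives, the study stops and no estimate is produced —
all inference in this package is *conditional on the trial reaching
stage 2*, which is the estimand users care about: when the study stops, the
candidates were judged inadequate and their precise sensitivity is moot.

The top-ranked survivor `M` is evaluated on `n2` additional cases
(`n2` fixed in advance), giving `Y ~ Bin(n2, s_M)` independent of stage 1.

### Ranking rules

A ranking rule is a per-classifier score `r(x, i)`, strictly increasing in
the count, together with a closed-form *dominance bound* `d(x_j, i, j)`:
the smallest real value such that `r(x_i, i) ≥ r(x_j, j) ⇔ x_i ≥ d`, with
equality exactly at a tie. The bound may depend only on the competitor's
count and per-classifier constants — never on `x_i` — because the
conditionally unbiased estimator needs it to delimit its restricted support
without reference to the quantity being integrated out. Rules of the affine
family `r(x, i) = x / scale_i + offset_i` cover both rules used in
practice: estimated sensitivity (`scale = n1`, zero offsets) and balanced
accuracy with conditioned-on specificities (`offset_i` = specificity of
classifier `i`; the overall factor ½ is monotone and drops out). The
constructor cross-checks score and dominance exhaustively over the
achievable count grid, so an inconsistent custom rule fails fast.

Ties are broken toward the smaller original index — a pre-specified
deterministic order is essential, since no conditionally unbiased estimator
exists under randomised tie-breaking. Cut-offs above `n1_i` are permitted;
such a classifier simply can never survive.

## The conditionally unbiased estimator

The stage-2 proportion `Y/n2` is exactly unbiased for `s_M` given the
selection event `Q` (it is drawn after selection), but wastes stage 1.
Rao–Blackwellising it against the complete sufficient statistic — the
pooled count `Z1 = X_M + Y` together with the other survivors' stage-1
counts — yields the UMVCUE `E[Y/n2 | Z, Q]`. Conditional on `Z1 = z1`, `Y`
is hypergeometric, and `Q` truncates its support:

* base (hypergeometric) support: `max(0, z1 − n1_M) ≤ y ≤ min(z1, n2)`;
* futility: `x_M = z1 − y ≥ ⌈c_M⌉`;
* ranking against the runner-up's observed count `x_2`, through the
  dominance bound `d`: `x_M ≥ d` when a tie is admissible (selected index
  smaller than the runner-up's), `x_M > d` otherwise. The real-valued
  bound converts to an integer count limit by ceiling (tie admitted) or
  floor-plus-one (tie excluded); the arithmetic is exact (rational), so
  boundary cases cannot be lost to rounding.

With a single survivor only the futility bound applies. When more than two
classifiers survive, only the runner-up constrains the support: the
lower-ranked survivors' counts enter the conditioning event only through
their observed values, which the selected classifier's score already
dominates by transitivity of the ranking.

The estimator is then the ratio of hypergeometric-weighted sums over the
restricted support. The weights `C(n2, y)·C(n1_M, z1 − y)` are computed in
exact integer arithmetic (Python's arbitrary-precision integers), so the
ratio is exact to the final floating division at any sample size; a
single-point support returns the forced value `y/n2` directly. When the
restricted support's maximum reaches `n2`, the estimator provably equals
the pooled MLE — the package surfaces this as a no-bias diagnostic.

Correctness is established against an independent brute-force oracle: for
every exhaustively enumerable design in a panel spanning `K ∈ {1,2,3}`,
unequal stage-1 sizes and zero/positive/fractional cut-offs, the estimator
equals the enumeration-based conditional expectation on *every* reachable
conditioning class to 1e-12 relative tolerance, and the enumerated value is
invariant to the truth used to enumerate — the operational signature of
conditioning on a sufficient statistic.

## Confidence intervals

**Exact conditional (Sill–Sampson style).** The pooled count's conditional
pmf given the selection event is `f(z1|s) ∝ h(z1)·s^{z1}(1−s)^{N−z1}` with
`N = n1_M + n2` and `h(z1)` the number-weighted count of admissible
`(x_M, y)` splits at that `z1` (same truncation as above). Two-sided
bounds solve `P(Z1 ≥ z_obs | Δ1) = α1` and `P(Z1 ≤ z_obs | Δ2) = α2`,
`α1 + α2 = α`, by bracketed Brent root-finding on `s ∈ [1e-10, 1−1e-10]`
(absolute tolerance 1e-8; the tails are monotone in `s` but have no
closed-form derivative). An unattainable equation — observed count at the
edge of the conditional support — returns the corresponding bound as 0
or 1. Tail probabilities are accumulated in log space. The default is the
equal split `α1 = α2 = α/2`; the length-optimised variant searches `α1`
by bounded scalar minimisation (tolerance `1e-4·α`) and never returns a
wider interval than the equal split (the incumbent is kept otherwise). The
equal split is the default because the optimised variant costs two
root-finds per candidate split, which compounds heavily inside simulation
studies. When conditioning is vacuous (one classifier, zero cut-off) the
construction coincides with Clopper–Pearson, and the implementation
reproduces that identity numerically.

**Clopper–Pearson.** Standard exact binomial interval for the pooled count
via beta quantiles; cross-checked in the tests against statsmodels.

**Nonparametric bootstrap.** Stage-1 responses of the selected classifier
are resampled with replacement — implemented as `X* ~ Bin(n1_M, x_M/n1_M)`,
which is distributionally identical — and a replicate is accepted only if
`X*` clears the futility ceiling and the dominance bound against the
*original* observed runner-up (mirroring the conditioning event, with the
original tie convention). Stage-2 responses are resampled likewise, the
chosen estimator is recomputed with the original runner-up statistic held
fixed, and the type-7 empirical `α/2`/`1−α/2` quantiles over `B` accepted
replicates form the interval. The acceptance rate is reported; a run that
cannot reach `B` acceptances within a draw cap raises rather than
returning a silently degenerate interval.

## Hypothesis testing

`H0: s_M ≤ s*` is tested by interval inversion: reject iff the one-sided
`(1−α)` lower bound exceeds `s*` strictly (ties favour `H0`). The exact
conditional bound spends the full `α` on the lower tail; the comparison
test uses the one-sided Clopper–Pearson bound on the MLE. Operating
characteristics are estimated by simulation with the conditional /
unconditional distinction made explicit: with `S0 = {s ∈ S : s ≤ s*}`,
conditional rates divide by the replicates where the selected classifier is
truly null (respectively non-null) *and* the trial continued, unconditional
rates divide by all replicates, and a stopped trial never rejects. A
conditioning event that never occurs is reported as absent (`None`), not
as zero — "power" over an empty alternative is vacuous.

## Simulation drivers and problem sizes

The batch simulator vectorises stage-1 draws, selection and the
conditioning bound for affine-score rules. Score comparisons use float
arithmetic: distinct rational scores at these sample sizes differ by far
more than one ulp, and the dominance bound is an integer-by-integer
quotient whose floor/ceiling are exact for correctly-rounded doubles, so
ties and strict orderings are reproduced faithfully. Estimator and interval
values are cached on the conditioning event `(n1_M, x_min, z1)`, so study
cost scales with the number of distinct events (hundreds) rather than with
the replicate count (10⁵). Bias/MSE tables run at 100,000 replicates;
interval-coverage tables at 10,000 continuing trials for the exact methods
and 2,000 continuing trials × B = 2,000 for the bootstrap (the bootstrap
resamples per trial, so its cost is multiplicative); the conservatism sweep
across all seven coverage scenarios runs at 5,000 continuing trials each.
Coverage replication is defined in *continuing* trials because intervals
exist only for continuing trials. Every driver takes an explicit seed and
identical seeds reproduce tables bit-for-bit; Monte-Carlo standard errors
accompany all point summaries.

The closed form `P(continue) = 1 − Π_i P(Bin(n1_i, s_i) < ⌈c_i⌉)` serves as
an independent analytic check on the simulator.

### Correlated-binary generation

For robustness checks against the independence assumption, binary vectors
with given margins and pairwise correlations are generated by the
Emrich–Piedmonte construction: each pair's latent Gaussian correlation is
solved from the bivariate-normal orthant equation by bracketed
root-finding (tolerance 1e-6), the assembled latent matrix is projected to
the nearest positive-definite correlation matrix by eigenvalue clipping if
needed, and thresholded normal draws deliver the binaries. Requested
correlations are validated against the Fréchet bounds for the given
margins, with the offending pair named on failure.

## Questionnaire (FHQ-style) selection

For questionnaire studies the control-side counts (false positives, true
negatives) are held fixed by conditioning — sensitivities are the estimand,
and letting the control margins vary would make the cut-offs
data-dependent and break the estimator's derivation. Under that
conditioning, the "significant by Fisher's exact test" criterion reduces to
a fixed cut-off: the smallest count from which every larger count is
significant (scanned exhaustively; a question for which not even a perfect
count is significant is reported as unattainable and can never survive).
The two-sided p-value uses the point-probability convention of mainstream
software; a mid-p switch is exposed because published analyses do not
always name their convention. Only the upper tail qualifies questions — a
significantly *low* count indicates poor sensitivity and is not evidence in
favour. Balanced-accuracy ranking is the affine rule described above. The
per-condition driver derives thresholds, ranks, verifies that the question
carrying stage-2 data is the one the rules select, and reports stage-wise,
pooled and corrected estimates with exact intervals, plus the
continuity-corrected Pearson χ² stage-concordance p-value (a deliberately
retained legacy diagnostic: it is conspicuously insensitive to the
selection bias the corrected estimator reveals).

The packaged questionnaire fixture is *synthetic* (the published
per-question tables are not machine-readable); it embeds the few printed
counts that are available for the selected breast-cancer question and is
constructed so the analysis exhibits both regimes — conditions where the
restricted support is unrestricted and the corrected estimate equals the
MLE, and one where truncation bites and the estimate drops. The packaged
stage-1 correlation matrix, by contrast, is the published one.

## Median-unbiased estimation

An approximate median-unbiased point estimate solves the two
half-probability equations `P(Z1 ≥ z_obs | s) = ½` and
`P(Z1 ≤ z_obs | s) = ½` under the exact conditional distribution and
returns the midpoint of the two roots (the midpoint convention is an
interpretation; the defining equations pin down only the pair). In
simulation its mean sits slightly below the truth, consistent with its
design target being the median.

## What the synthetic studies do and do not show

The simulation studies emulate the model exactly: independent binomial
stage-1 counts, deterministic selection, a binomial stage-2 count for the
selected classifier only. They validate the estimator's conditional
unbiasedness, the exact intervals' conservative conditional coverage, and
the documented failure modes of the naive MLE-based inference *under the
model*. They do not probe misspecification beyond the correlated-binary
robustness check: real questionnaire responses may be correlated across
items (addressed only in that limited sense), margins may drift between
stages, and stage-2 populations may differ from stage-1 populations —
none of which the design models.

## Known limitations

* One classifier carried to stage 2; two stages only; fixed `n2`.
* Sensitivity only — joint sensitivity/specificity inference would require
  treating the control margins as random, which breaks the present
  conditioning.
* No randomised tie-breaking (no conditionally unbiased estimator exists).
* No combination-of-classifiers (risk model) inference; the questionnaire
  driver deliberately implements single-question selection only.
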