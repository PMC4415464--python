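# twostagedx

Bias-corrected estimation and exact inference for the sensitivity of a
diagnostic classifier selected at the interim analysis of a two-stage
validation study.

## The problem

A validation study screens `K` candidate binary classifiers — biomarkers, or
yes/no questionnaire items — on known cases. Classifier `i` is evaluated on
`n1_i` stage-1 cases, giving a true-positive count `X_i ~ Bin(n1_i, s_i)`
where `s_i` is its unknown sensitivity. A classifier stays in contention only
if `X_i ≥ c_i`, a pre-specified futility cut-off; if every classifier fails,
the study stops. Survivors are ranked by a pre-specified score (estimated
sensitivity `X_i / n1_i` by default, balanced accuracy for questionnaire
studies), ties going to the smallest index, and the top-ranked classifier
`M` proceeds to stage 2, where it is tested on `n2` further cases, giving
`Y ~ Bin(n2, s_M)`.

Because `M` had to look good at stage 1 to get there, the pooled MLE
`(X_M + Y) / (n1_M + n2)` is biased high conditional on the trial reaching
stage 2, and confidence intervals and tests built on it undercover and
over-reject. This package implements the corrected inference for `s_M`:

* **UMVCUE** — the uniformly minimum variance conditionally unbiased
  estimator, obtained by Rao–Blackwellising the (unbiased) stage-2
  proportion `Y / n2` against the complete sufficient statistic. With
  `z1 = X_M + Y`, the estimator is the hypergeometric-weighted mean

  `ŝ = Σ_y (y/n2)·C(n2,y)·C(n1_M, z1−y) / Σ_y C(n2,y)·C(n1_M, z1−y)`,

  the sums running over the stage-2 counts `y` compatible with the selection
  event: `x_M = z1 − y` must clear the futility ceiling `⌈c_M⌉` and the
  ranking bound against the observed runner-up (a score tie being
  admissible only when the selected classifier carries the smaller index).
  When the admissible `y` reach `n2`, the estimator *equals* the MLE — a
  built-in diagnostic that selection exerted no bias.
* **Exact conditional (Sill–Sampson style) confidence intervals** —
  inverting the distribution of `Z1` conditional on the selection event,
  `f(z1|s) ∝ h(z1)·s^{z1}(1−s)^{n1_M+n2−z1}`, with equal or
  length-optimised tail splits; plus Clopper–Pearson intervals for the MLE
  and a selection-aware nonparametric bootstrap.
* **One-sided tests** of `H0: s_M ≤ s*` by interval inversion, with
  conditional/unconditional type-I error and power estimated by simulation.
* **Questionnaire (FHQ-style) selection rules** — Fisher's-exact-test
  cut-offs with fixed control margins, balanced-accuracy ranking, the
  stage-concordance χ² diagnostic, and an end-to-end per-condition analysis.
* **Simulation drivers** — conditional bias/MSE tables, interval-coverage
  tables, and a latent-Gaussian (Emrich–Piedmonte) correlated-binary
  generator for robustness checks.

## Worked example

Two classifiers screened on 50 cases each with cut-offs 35; classifier 2
scores 36/50 and is selected; stage 2 gives 30/50:

```python
from twostagedx import TrialData, TwoStageDesign, mle, umvcue, ss_ci

design = TwoStageDesign(n1=(50, 50), c=(35, 35), n2=50)
trial = TrialData(design=design, x=(35, 36), y=30)
print(f"MLE    {mle(trial):.4f}")
print(f"UMVCUE {umvcue(trial):.4f}")
ci = ss_ci(trial)
print(f"95% exact conditional CI ({ci.lower:.4f}, {ci.upper:.4f})")
```

prints

```
MLE    0.6600
UMVCUE 0.5847
95% exact conditional CI (0.4410, 0.7123)
```

The pooled MLE (66/100) overstates the selected classifier's sensitivity:
to be selected, its stage-1 count had to reach 35 *and* beat its
competitor's 35, so the admissible stage-2 counts are truncated and the
conditionally unbiased estimate drops to 0.585 — much closer to the
untainted stage-2 proportion 30/50. The exact conditional interval is
shifted and widened accordingly relative to the naive Clopper–Pearson
interval for 66/100.

The same analyses are available from the shell:

```sh
twostagedx estimate --input trial.csv --out results/
twostagedx ci --input trial.csv --ci ss --ci boot --seed 1 --out results/
twostagedx simulate --config scenario.yaml --what estimators --seed 1 --out results/
twostagedx fhq --out results/          # packaged synthetic questionnaire fixture
```

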