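"""Trial simulation and Monte-Carlo study drivers.

Simulates the two-stage model (independent stage-1 binomials, futility +
ranking selection, stage-2 binomial for the selected classifier only) and
provides the study drivers that characterise the estimators and intervals:
conditional bias/MSE tables, interval coverage tables, and a correlated-
binary generator for robustness checks against the independence assumption.

The batch simulator is vectorised for ranking rules of the affine-score
family (which includes sensitivity and balanced-accuracy ranking); estimator
and interval computations per replicate are cached on the conditioning event
``(n1_M, x_min, z1)``, so study cost scales with the number of distinct
events rather than with the replicate count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import binom, multivariate_normal, norm

from .design import (
    AffineScoreRule,
    TrialData,
    TwoStageDesign,
    rank_and_select,
)
from .estimators import _umvcue_from_counts
from .intervals import (
    SSConditionalModel,
    bootstrap_ci,
    clopper_pearson,
    ss_ci_optimised,
)

__all__ = [
    "ScenarioSpec",
    "CorrelatedBinarySpec",
    "SimBatch",
    "simulate_trial",
    "continue_probability",
    "estimator_study",
    "EstimatorStudyResult",
    "coverage_study",
    "correlated_binary",
    "correlation_summary",
]


@dataclass(frozen=True)
class ScenarioSpec:
    """A simulation scenario: truth, design and Monte-Carlo sizes."""

    S: tuple
    design: TwoStageDesign
    nsim: int = 100_000
    seed: Optional[int] = None
    B: int = 10_000

    def __post_init__(self):
        object.__setattr__(self, "S", tuple(float(s) for s in self.S))
        if len(self.S) != self.design.K:
            raise ValueError("S must have one entry per classifier")
        if any(not 0.0 < s < 1.0 for s in self.S):
            raise ValueError("sensitivities must lie in (0, 1)")


@dataclass
class SimBatch:
    """Vectorised outcomes of many simulated trials."""

    x_sel: np.ndarray  # stage-1 count of the selected classifier
    y: np.ndarray  # stage-2 count (valid where continued)
    M: np.ndarray  # selected index (valid where continued)
    x_min: np.ndarray  # conditioning bound on x_M (valid where continued)
    continued: np.ndarray

    @property
    def z1(self) -> np.ndarray:
        return self.x_sel + self.y


def simulate_trial(design: TwoStageDesign, S: Sequence[float], rng=None) -> TrialData:
    """Draw one trial; a stopped trial has ``y=None`` and ``continued=False``."""
    rng = np.random.default_rng(rng)
    x = tuple(int(rng.binomial(n, s)) for n, s in zip(design.n1, S))
    sel = rank_and_select(x, design)
    y = int(rng.binomial(design.n2, S[sel.M])) if sel.continued else None
    return TrialData(design=design, x=x, y=y)


def continue_probability(design: TwoStageDesign, S: Sequence[float]) -> float:
    """Closed-form ``P(continue) = 1 − Π_i P(Bin(n1_i, s_i) < ⌈c_i⌉)``."""
    p_all_fail = 1.0
    for n, s, c in zip(design.n1, S, design.c_int):
        p_all_fail *= binom.cdf(c - 1, n, s) if c > 0 else 0.0
    return 1.0 - p_all_fail


def _rank_arrays(design: TwoStageDesign):
    rule = design.ranking
    if not isinstance(rule, AffineScoreRule):
        raise NotImplementedError(
            "vectorised simulation requires an affine-score ranking rule"
        )
    scale = np.array([float(v) for v in rule.scale])
    offset = np.array([float(v) for v in rule.offset])
    return scale, offset


def _simulate_batch(
    design: TwoStageDesign, S: Sequence[float], nsim: int, rng: np.random.Generator
) -> SimBatch:
    """Vectorised stage-1 draws, selection, conditioning bound and stage-2 draw.

    Score comparisons use float arithmetic; with integer counts and the
    modest sample sizes of these designs distinct rational scores are
    separated by far more than one ulp, so exact ties and strict orderings
    are both reproduced faithfully (argmax on equal floats picks the first,
    i.e. smallest, index — the pre-specified tie-break).
    """
    S = np.asarray(S, dtype=float)
    n1 = np.asarray(design.n1)
    cint = np.asarray(design.c_int)
    scale, offset = _rank_arrays(design)

    X = rng.binomial(n1[None, :], S[None, :], size=(nsim, design.K))
    passes = X >= cint[None, :]
    continued = passes.any(axis=1)

    scores = np.where(passes, X / scale[None, :] + offset[None, :], -np.inf)
    M = np.argmax(scores, axis=1)
    rows = np.arange(nsim)

    # runner-up: best remaining survivor (first max = smallest index on ties)
    scores2 = scores.copy()
    scores2[rows, M] = -np.inf
    R = np.argmax(scores2, axis=1)
    has_runner = passes.sum(axis=1) >= 2

    x_min = cint[M].astype(np.int64)
    if has_runner.any():
        hr = has_runner
        b = scale[M[hr]] * (
            X[rows[hr], R[hr]] / scale[R[hr]] + offset[R[hr]] - offset[M[hr]]
        )
        tie_ok = M[hr] < R[hr]
        # smallest integer count >= b (tie admitted) or > b (tie excluded)
        lr = np.where(
            tie_ok, np.ceil(b - 1e-9), np.floor(b + 1e-9) + 1
        ).astype(np.int64)
        x_min[hr] = np.maximum(x_min[hr], lr)
    x_min = np.maximum(x_min, 0)

    y = np.zeros(nsim, dtype=np.int64)
    if continued.any():
        y[continued] = rng.binomial(design.n2, S[M[continued]])
    return SimBatch(
        x_sel=X[rows, M], y=y, M=M, x_min=x_min, continued=continued
    )


@dataclass
class EstimatorStudyResult:
    """Conditional bias/MSE table plus design-level probabilities."""

    table: pd.DataFrame  # index: estimator; columns: bias, mse, bias_se, x100
    p_continue: float
    p_best: float
    n_continuing: int
    nsim: int


def estimator_study(scenario: ScenarioSpec) -> EstimatorStudyResult:
    """Conditional bias and MSE of the four point estimators.

    Replicates the design ``nsim`` times; statistics are computed over the
    continuing replicates against the *selected* classifier's true
    sensitivity.  ``p_best`` is the probability, given continuation, that a
    truly (joint-)best classifier was selected.
    """
    rng = np.random.default_rng(scenario.seed)
    design = scenario.design
    batch = _simulate_batch(design, scenario.S, scenario.nsim, rng)

    cont = batch.continued
    n_cont = int(cont.sum())
    S = np.asarray(scenario.S)
    n1 = np.asarray(design.n1)
    M = batch.M[cont]
    x_sel = batch.x_sel[cont]
    y = batch.y[cont]
    x_min = batch.x_min[cont]
    z1 = x_sel + y
    n1M = n1[M]
    s_true = S[M]

    ests = {
        "mle": z1 / (n1M + design.n2),
        "stage1": x_sel / n1M,
        "stage2": y / design.n2,
    }
    cache: dict = {}
    umv = np.empty(n_cont)
    for i in range(n_cont):
        key = (int(n1M[i]), int(x_min[i]), int(z1[i]))
        v = cache.get(key)
        if v is None:
            v = _umvcue_from_counts(key[0], design.n2, key[2], key[1])
            cache[key] = v
        umv[i] = v
    ests["umvcue"] = umv

    rows = []
    for name, e in ests.items():
        err = e - s_true
        rows.append(
            {
                "estimator": name,
                "bias": err.mean(),
                "mse": (err**2).mean(),
                "bias_se": err.std(ddof=1) / math.sqrt(n_cont),
                "bias_x100": 100.0 * err.mean(),
                "mse_x100": 100.0 * (err**2).mean(),
            }
        )
    table = pd.DataFrame(rows).set_index("estimator")
    best = S.max()
    return EstimatorStudyResult(
        table=table,
        p_continue=n_cont / scenario.nsim,
        p_best=float((s_true == best).mean()) if n_cont else float("nan"),
        n_continuing=n_cont,
        nsim=scenario.nsim,
    )


def _simulate_continuing(
    design: TwoStageDesign,
    S: Sequence[float],
    n_continuing: int,
    rng: np.random.Generator,
) -> SimBatch:
    """Draw batches until ``n_continuing`` continuing trials are collected."""
    parts = []
    got = 0
    p_cont = max(continue_probability(design, S), 1e-6)
    while got < n_continuing:
        need = n_continuing - got
        n_draw = int(need / p_cont * 1.2) + 100
        b = _simulate_batch(design, S, n_draw, rng)
        keep = b.continued
        parts.append(
            SimBatch(
                x_sel=b.x_sel[keep],
                y=b.y[keep],
                M=b.M[keep],
                x_min=b.x_min[keep],
                continued=b.continued[keep],
            )
        )
        got += int(keep.sum())
    cat = lambda f: np.concatenate([getattr(p, f) for p in parts])[:n_continuing]
    return SimBatch(
        x_sel=cat("x_sel"),
        y=cat("y"),
        M=cat("M"),
        x_min=cat("x_min"),
        continued=cat("continued"),
    )


def coverage_study(
    scenario: ScenarioSpec,
    methods: Sequence[str] = ("ss", "cp"),
    alpha: float = 0.05,
    n_continuing: Optional[int] = None,
) -> pd.DataFrame:
    """Empirical coverage and mean width of interval methods.

    ``n_continuing`` continuing trials are simulated (default
    ``scenario.nsim``); intervals exist only for continuing trials, so the
    replication is defined in those terms.  Methods: ``ss``, ``ss-opt``,
    ``cp``, ``boot-mle``, ``boot-umvcue``, ``boot-stage2``.
    """
    if n_continuing is None:
        n_continuing = scenario.nsim
    rng = np.random.default_rng(scenario.seed)
    design = scenario.design
    batch = _simulate_continuing(design, scenario.S, n_continuing, rng)
    S = np.asarray(scenario.S)
    n1 = np.asarray(design.n1)
    s_true = S[batch.M]
    z1 = batch.z1

    out = []
    for method in methods:
        lo = np.empty(n_continuing)
        hi = np.empty(n_continuing)
        if method in ("ss", "ss-opt", "cp"):
            ci_cache: dict = {}
            model_cache: dict = {}
            for i in range(n_continuing):
                n1M = int(n1[batch.M[i]])
                xm = int(batch.x_min[i])
                key = (n1M, xm, int(z1[i]))
                ci = ci_cache.get(key)
                if ci is None:
                    if method == "cp":
                        r = clopper_pearson(key[2], n1M + design.n2, alpha)
                    else:
                        mkey = (n1M, xm)
                        model = model_cache.get(mkey)
                        if model is None:
                            model = SSConditionalModel(n1M, design.n2, xm)
                            model_cache[mkey] = model
                        if method == "ss":
                            a = alpha / 2.0
                            r = (
                                model.solve_lower(key[2], a),
                                model.solve_upper(key[2], a),
                            )
                        else:
                            trial = _trial_from_event(design, batch, i)
                            res = ss_ci_optimised(trial, alpha, model=model)
                            r = (res.lower, res.upper)
                    ci = (r[0], r[1]) if isinstance(r, tuple) else (r.lower, r.upper)
                    ci_cache[key] = ci
                lo[i], hi[i] = ci
        elif method.startswith("boot-"):
            est = method.split("-", 1)[1]
            for i in range(n_continuing):
                trial = _trial_from_event(design, batch, i)
                res = bootstrap_ci(
                    trial, estimator=est, B=scenario.B, alpha=alpha, rng=rng
                )
                lo[i], hi[i] = res.lower, res.upper
        else:
            raise ValueError(f"unknown interval method {method!r}")
        covered = (lo <= s_true) & (s_true <= hi)
        cov = covered.mean()
        out.append(
            {
                "method": method,
                "coverage": cov,
                "width": (hi - lo).mean(),
                "coverage_se": math.sqrt(cov * (1 - cov) / n_continuing),
                "n_continuing": n_continuing,
            }
        )
    return pd.DataFrame(out).set_index("method")


def _trial_from_event(design: TwoStageDesign, batch: SimBatch, i: int) -> TrialData:
    """Reconstruct a TrialData carrying the i-th replicate's conditioning event.

    The non-selected classifiers are set so that selection reproduces the
    simulated event: the runner-up constraint is encoded through ``x_min``,
    so for interval/bootstrap purposes only ``(n1_M, x_min, x_M, y)`` matter.
    A surrogate design with a single classifier and cut-off ``x_min``
    realises exactly that conditioning event.
    """
    n1M = int(design.n1[batch.M[i]])
    surrogate = TwoStageDesign(n1=(n1M,), c=(int(batch.x_min[i]),), n2=design.n2)
    return TrialData(design=surrogate, x=(int(batch.x_sel[i]),), y=int(batch.y[i]))


@dataclass(frozen=True)
class CorrelatedBinarySpec:
    """Margins and target pairwise correlations for binary generation."""

    p: tuple
    R: np.ndarray = field(repr=False)
    n: int = 10_000

    def __post_init__(self):
        object.__setattr__(self, "p", tuple(float(v) for v in self.p))
        R = np.asarray(self.R, dtype=float)
        object.__setattr__(self, "R", R)
        K = len(self.p)
        if R.shape != (K, K):
            raise ValueError("R must be K x K")
        if not np.allclose(R, R.T) or not np.allclose(np.diag(R), 1.0):
            raise ValueError("R must be symmetric with unit diagonal")
        if np.any(np.abs(R) > 1.0):
            raise ValueError("correlations must lie in [-1, 1]")
        for i in range(K):
            for j in range(i + 1, K):
                lo, hi = _frechet_corr_bounds(self.p[i], self.p[j])
                if not lo - 1e-9 <= R[i, j] <= hi + 1e-9:
                    raise ValueError(
                        f"correlation R[{i},{j}]={R[i, j]:.3f} infeasible for "
                        f"margins ({self.p[i]:.3f}, {self.p[j]:.3f}); "
                        f"feasible range [{lo:.3f}, {hi:.3f}]"
                    )


def _frechet_corr_bounds(pi: float, pj: float) -> Tuple[float, float]:
    qi, qj = 1.0 - pi, 1.0 - pj
    lo = max(-math.sqrt(pi * pj / (qi * qj)), -math.sqrt(qi * qj / (pi * pj)))
    hi = min(math.sqrt(pi * qj / (pj * qi)), math.sqrt(pj * qi / (pi * qj)))
    return lo, hi


def _latent_correlation(pi: float, pj: float, r: float) -> float:
    """Solve the bivariate-normal orthant equation for the latent correlation.

    Finds ``rho`` with ``P(Z_i > z_i, Z_j > z_j; rho) = r·sqrt(pq_i·pq_j) +
    p_i·p_j`` where thresholding the latent normals at the margins' upper
    quantiles reproduces the target binary correlation (Emrich–Piedmonte).
    """
    if abs(r) < 1e-12:
        return 0.0
    zi, zj = norm.isf(pi), norm.isf(pj)
    target = r * math.sqrt(pi * (1 - pi) * pj * (1 - pj)) + pi * pj

    def f(rho: float) -> float:
        upper = multivariate_normal.cdf(
            [-zi, -zj], mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]]
        )
        return float(upper) - target

    return brentq(f, -0.9999, 0.9999, xtol=1e-6)


def correlated_binary(spec: CorrelatedBinarySpec, rng=None) -> np.ndarray:
    """Draw an ``n × K`` binary matrix with given margins and correlations.

    Latent multivariate-normal construction: per-pair latent correlations are
    solved from the orthant-probability equation, the resulting matrix is
    projected to the nearest positive-definite correlation matrix if needed,
    and the latent draws are thresholded at the margins' quantiles.
    """
    rng = np.random.default_rng(rng)
    K = len(spec.p)
    latent = np.eye(K)
    for i in range(K):
        for j in range(i + 1, K):
            latent[i, j] = latent[j, i] = _latent_correlation(
                spec.p[i], spec.p[j], spec.R[i, j]
            )
    w, V = np.linalg.eigh(latent)
    if w.min() < 1e-10:  # eigenvalue clipping, then renormalise the diagonal
        w = np.clip(w, 1e-10, None)
        latent = V @ np.diag(w) @ V.T
        d = np.sqrt(np.diag(latent))
        latent = latent / np.outer(d, d)
    Z = rng.multivariate_normal(np.zeros(K), latent, size=spec.n, method="cholesky")
    thresh = norm.isf(spec.p)
    return (Z > thresh[None, :]).astype(np.int8)


def correlation_summary(matrix, labels: Optional[Sequence[str]] = None):
    """Mean absolute pairwise correlation and the largest off-diagonal entry.

    Accepts a square correlation matrix (optionally a labelled DataFrame);
    returns ``(mean_abs, max_value, (label_i, label_j))`` over the strict
    upper triangle.
    """
    if isinstance(matrix, pd.DataFrame):
        if labels is None:
            labels = list(matrix.columns)
        matrix = matrix.to_numpy()
    R = np.asarray(matrix, dtype=float)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise ValueError("correlation matrix must be square")
    K = R.shape[0]
    if labels is None:
        labels = [str(i) for i in range(K)]
    iu = np.triu_indices(K, k=1)
    vals = R[iu]
    mean_abs = float(np.abs(vals).mean()) if vals.size else 0.0
    if vals.size == 0:
        return mean_abs, 0.0, (None, None)
    k = int(np.argmax(vals))
    i, j = iu[0][k], iu[1][k]
    return mean_abs, float(vals[k]), (labels[i], labels[j])
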