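"""Confidence intervals for the selected classifier's sensitivity.

Three constructions:

* **Exact conditional (Sill–Sampson style)** — inverts the distribution of the
  pooled count ``Z1 = X_M + Y`` *conditional on the selection event* (futility
  passed, ranked above the observed runner-up), so its coverage holds given
  that the trial reached stage 2.  The conditional pmf is

      f(z1 | s) ∝ h(z1) s^{z1} (1 − s)^{n1_M + n2 − z1},
      h(z1) = Σ_y C(n2, y) C(n1_M, z1 − y),

  the inner sum running over stage-2 counts compatible with the selection
  event at that ``z1``.  Equal-tail bounds solve ``P(Z1 >= z_obs | Δ1) = α1``
  and ``P(Z1 <= z_obs | Δ2) = α2`` with ``α1 + α2 = α``; the "optimised"
  variant picks the split minimising interval length.

* **Clopper–Pearson** — the classical exact binomial interval for the pooled
  count, i.e. the same construction with the conditioning ignored.

* **Nonparametric bootstrap** — resamples both stages for the selected
  classifier, accepting only stage-1 replicates that would have reproduced
  the selection against the *original* observed runner-up, and takes
  percentile intervals of the re-estimated quantity.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy.optimize import brentq, minimize_scalar
from scipy.special import logsumexp
from scipy.stats import beta as beta_dist

from .design import TrialData
from .estimators import (
    _umvcue_from_counts,
    _x_lower_bound,
    sufficient_statistic,
)

__all__ = [
    "IntervalResult",
    "SSConditionalModel",
    "ss_model",
    "ss_ci",
    "ss_ci_optimised",
    "clopper_pearson",
    "bootstrap_ci",
]

logger = logging.getLogger(__name__)

_S_LO = 1e-10
_S_HI = 1.0 - 1e-10
_XTOL = 1e-8


@dataclass(frozen=True)
class IntervalResult:
    """A confidence interval with its construction metadata."""

    lower: float
    upper: float
    level: float
    method: str
    alpha_split: Optional[Tuple[float, float]] = None
    replicates: Optional[int] = None
    acceptance_rate: Optional[float] = None

    def __post_init__(self):
        if not 0.0 <= self.lower <= self.upper <= 1.0:
            raise ValueError(f"invalid interval [{self.lower}, {self.upper}]")

    @property
    def width(self) -> float:
        return self.upper - self.lower

    def __contains__(self, s: float) -> bool:
        return self.lower <= s <= self.upper


class SSConditionalModel:
    """Conditional distribution of the pooled count given the selection event.

    Parametrised by the selected classifier's stage sizes and the minimal
    stage-1 count ``x_min`` compatible with selection (the futility ceiling
    combined with the dominance bound against the observed runner-up).  With
    ``x_min = 0`` the conditioning is vacuous and the model reduces to
    ``Binomial(n1_M + n2, s)``.
    """

    def __init__(self, n1M: int, n2: int, x_min: int):
        if not 0 <= x_min <= n1M:
            raise ValueError(f"x_min={x_min} outside [0, {n1M}]")
        self.n1M = n1M
        self.n2 = n2
        self.x_min = x_min
        self.N = n1M + n2
        self.support = np.arange(x_min, self.N + 1)
        log_h = []
        for z1 in self.support:
            lo = max(0, z1 - n1M)
            hi = min(z1 - x_min, n2)
            h = sum(
                math.comb(n2, y) * math.comb(n1M, z1 - y) for y in range(lo, hi + 1)
            )
            log_h.append(math.log(h))
        self._log_h = np.asarray(log_h)

    @classmethod
    def from_trial(cls, trial: TrialData) -> "SSConditionalModel":
        trial.require_continued()
        stat = sufficient_statistic(trial)
        return cls(
            n1M=trial.design.n1[stat.M],
            n2=trial.design.n2,
            x_min=_x_lower_bound(stat, trial.design),
        )

    def logpmf(self, s: float) -> np.ndarray:
        terms = (
            self._log_h
            + self.support * math.log(s)
            + (self.N - self.support) * math.log1p(-s)
        )
        return terms - logsumexp(terms)

    def pmf(self, s: float) -> np.ndarray:
        return np.exp(self.logpmf(s))

    def sf(self, s: float, z_obs: int) -> float:
        """Upper tail ``P(Z1 >= z_obs | s)``; nondecreasing in ``s``."""
        lp = self.logpmf(s)
        mask = self.support >= z_obs
        if not mask.any():
            return 1.0
        return float(np.exp(logsumexp(lp[mask])))

    def cdf(self, s: float, z_obs: int) -> float:
        """Lower tail ``P(Z1 <= z_obs | s)``; nonincreasing in ``s``."""
        lp = self.logpmf(s)
        mask = self.support <= z_obs
        if not mask.any():
            return 0.0
        return float(np.exp(logsumexp(lp[mask])))

    def solve_lower(self, z_obs: int, alpha1: float) -> float:
        """Root of ``P(Z1 >= z_obs | s) = alpha1``; 0 when unattainable."""
        if alpha1 <= 0.0:
            return 0.0
        if z_obs <= self.support[0]:
            return 0.0  # upper tail is identically 1
        f = lambda s: self.sf(s, z_obs) - alpha1
        if f(_S_LO) >= 0.0:
            return 0.0
        return brentq(f, _S_LO, _S_HI, xtol=_XTOL)

    def solve_upper(self, z_obs: int, alpha2: float) -> float:
        """Root of ``P(Z1 <= z_obs | s) = alpha2``; 1 when unattainable."""
        if alpha2 <= 0.0:
            return 1.0
        if z_obs >= self.support[-1]:
            return 1.0  # lower tail is identically 1
        f = lambda s: self.cdf(s, z_obs) - alpha2
        if f(_S_HI) >= 0.0:
            return 1.0
        return brentq(f, _S_LO, _S_HI, xtol=_XTOL)


def ss_model(trial: TrialData) -> SSConditionalModel:
    """Conditional model of ``Z1`` for the observed trial's selection event."""
    return SSConditionalModel.from_trial(trial)


def ss_ci(
    trial: TrialData,
    alpha: float = 0.05,
    split: Optional[Tuple[float, float]] = None,
    model: Optional[SSConditionalModel] = None,
) -> IntervalResult:
    """Exact conditional confidence interval for ``s_M``.

    ``split = (α1, α2)`` apportions the two tail errors (default equal
    split).  A bound whose defining equation cannot be attained (observed
    count at the edge of the conditional support) is returned as 0 or 1.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if split is None:
        split = (alpha / 2.0, alpha / 2.0)
    a1, a2 = split
    if a1 < 0 or a2 < 0 or abs(a1 + a2 - alpha) > 1e-12:
        raise ValueError("alpha split must be non-negative and sum to alpha")
    if model is None:
        model = SSConditionalModel.from_trial(trial)
    z = trial.z1
    lower = model.solve_lower(z, a1)
    upper = model.solve_upper(z, a2)
    return IntervalResult(
        lower=lower,
        upper=upper,
        level=1.0 - alpha,
        method="sill-sampson",
        alpha_split=(a1, a2),
    )


def ss_ci_optimised(
    trial: TrialData,
    alpha: float = 0.05,
    model: Optional[SSConditionalModel] = None,
) -> IntervalResult:
    """Exact conditional interval with the length-minimising tail split.

    Searches ``α1`` over ``[ε, α − ε]``; the returned interval is never wider
    than the equal-split interval (the incumbent is kept when the search does
    not improve on it).
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if model is None:
        model = SSConditionalModel.from_trial(trial)
    z = trial.z1
    eps = 1e-6 * alpha

    def width_at(a1: float) -> float:
        return model.solve_upper(z, alpha - a1) - model.solve_lower(z, a1)

    res = minimize_scalar(
        width_at,
        bounds=(eps, alpha - eps),
        method="bounded",
        options={"xatol": 1e-4 * alpha},
    )
    candidates = [(alpha / 2.0, width_at(alpha / 2.0)), (float(res.x), float(res.fun))]
    a1, _ = min(candidates, key=lambda t: t[1])
    a2 = alpha - a1
    return IntervalResult(
        lower=model.solve_lower(z, a1),
        upper=model.solve_upper(z, a2),
        level=1.0 - alpha,
        method="sill-sampson-optimised",
        alpha_split=(a1, a2),
    )


def clopper_pearson(k: int, n: int, alpha: float = 0.05) -> IntervalResult:
    """Exact (Clopper–Pearson) binomial confidence interval for ``k / n``."""
    if not 0 <= k <= n or n <= 0:
        raise ValueError(f"invalid counts k={k}, n={n}")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    lower = 0.0 if k == 0 else float(beta_dist.ppf(alpha / 2.0, k, n - k + 1))
    upper = 1.0 if k == n else float(beta_dist.isf(alpha / 2.0, k + 1, n - k))
    return IntervalResult(
        lower=lower,
        upper=upper,
        level=1.0 - alpha,
        method="clopper-pearson",
        alpha_split=(alpha / 2.0, alpha / 2.0),
    )


_ESTIMATOR_LABELS = ("mle", "umvcue", "stage1", "stage2")


def bootstrap_ci(
    trial: TrialData,
    estimator: str = "umvcue",
    B: int = 10_000,
    alpha: float = 0.05,
    rng=None,
    max_attempts: Optional[int] = None,
) -> IntervalResult:
    """Nonparametric bootstrap percentile interval for the chosen estimator.

    Stage-1 responses of the selected classifier are resampled with
    replacement (equivalently, ``X* ~ Binomial(n1_M, x_M / n1_M)``); a
    replicate is accepted only if ``X*`` still passes the futility cut-off and
    the ranking condition against the *original* observed runner-up.  Stage-2
    responses are then resampled likewise, the estimator is recomputed with
    the original runner-up statistic held fixed, and the empirical
    ``α/2`` / ``1 − α/2`` quantiles over the ``B`` accepted replicates form
    the interval.
    """
    if estimator not in _ESTIMATOR_LABELS:
        raise ValueError(f"estimator must be one of {_ESTIMATOR_LABELS}")
    if B < 1:
        raise ValueError("B must be positive")
    trial.require_continued()
    rng = np.random.default_rng(rng)
    stat = sufficient_statistic(trial)
    n1M = trial.design.n1[stat.M]
    n2 = trial.design.n2
    x_min = _x_lower_bound(stat, trial.design)
    p1 = trial.x[stat.M] / n1M
    p2 = trial.y / n2

    if max_attempts is None:
        max_attempts = max(1_000_000, 1_000 * B)
    accepted = np.empty(B, dtype=np.int64)
    n_acc = 0
    n_drawn = 0
    chunk = max(4 * B, 10_000)
    while n_acc < B:
        if n_drawn >= max_attempts:
            raise RuntimeError(
                f"bootstrap acceptance rate too low: {n_acc} accepted "
                f"in {n_drawn} draws (x_min={x_min}, p1={p1:.3f})"
            )
        xs = rng.binomial(n1M, p1, size=chunk)
        n_drawn += chunk
        ok = xs[xs >= x_min]
        take = min(B - n_acc, ok.size)
        accepted[n_acc : n_acc + take] = ok[:take]
        n_acc += take
    rate = n_acc / n_drawn  # lower bound on the true acceptance rate
    ys = rng.binomial(n2, p2, size=B)
    logger.info(
        "bootstrap: B=%d accepted, acceptance rate >= %.3f", B, rate
    )

    if estimator == "mle":
        est = (accepted + ys) / (n1M + n2)
    elif estimator == "stage1":
        est = accepted / n1M
    elif estimator == "stage2":
        est = ys / n2
    else:  # umvcue with the original runner-up bound
        z1s = accepted + ys
        table = {
            z1: _umvcue_from_counts(n1M, n2, z1, x_min)
            for z1 in range(x_min, n1M + n2 + 1)
        }
        est = np.array([table[z] for z in z1s])

    lower, upper = np.quantile(est, [alpha / 2.0, 1.0 - alpha / 2.0])
    return IntervalResult(
        lower=float(lower),
        upper=float(upper),
        level=1.0 - alpha,
        method=f"bootstrap-{estimator}",
        replicates=B,
        acceptance_rate=rate,
    )
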