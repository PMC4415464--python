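"""One-sided hypothesis testing and operating characteristics.

Tests ``H0: s_M <= s*`` against ``H1: s_M > s*`` by inverting an exact
one-sided lower confidence bound: ``H0`` is rejected iff the bound exceeds
``s*`` (strictly; ties favour ``H0``).  The bound comes either from the exact
conditional (Sill–Sampson) construction with the full ``α`` spent on the
lower tail, or from the Clopper–Pearson interval around the pooled MLE.

Error rates and power are reported both conditionally on the trial reaching
stage 2 and unconditionally: with ``S0 = {s in S : s <= s*}``,

* conditional type I error  = P(reject | s_M in S0, Q)
* unconditional type I error = P(reject, s_M in S0)
* conditional power          = P(reject | s_M in S \\ S0, Q)
* unconditional power        = P(reject, s_M in S \\ S0)

A stopped trial never rejects.  A conditioning event that never occurs in the
simulation (e.g. no selected classifier was truly null) leaves the
corresponding conditional rate undefined, reported as ``None``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

from .design import TrialData, TwoStageDesign
from .intervals import SSConditionalModel, clopper_pearson
from scipy.stats import beta as beta_dist

__all__ = [
    "TestSpec",
    "OperatingCharacteristics",
    "one_sided_lower_bound",
    "one_sided_test",
    "operating_characteristics",
]

_TEST_METHODS = ("ss", "cp")


@dataclass(frozen=True)
class TestSpec:
    """A one-sided test: null boundary, level, and backing interval method."""

    __test__ = False  # not a pytest collection target

    s_star: float
    alpha: float = 0.05
    method: str = "ss"

    def __post_init__(self):
        if not 0.0 < self.s_star < 1.0:
            raise ValueError("s_star must lie in (0, 1)")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.method not in _TEST_METHODS:
            raise ValueError(f"method must be one of {_TEST_METHODS}")


@dataclass(frozen=True)
class OperatingCharacteristics:
    """Monte-Carlo error rates and power for a design, truth and test."""

    conditional_t1: Optional[float]
    unconditional_t1: float
    conditional_power: Optional[float]
    unconditional_power: float
    continue_rate: float
    nsim: int


def one_sided_lower_bound(
    trial: TrialData, alpha: float = 0.05, method: str = "ss"
) -> float:
    """Exact one-sided ``(1 − α)`` lower confidence bound for ``s_M``."""
    trial.require_continued()
    if method == "ss":
        model = SSConditionalModel.from_trial(trial)
        return model.solve_lower(trial.z1, alpha)
    if method == "cp":
        k, n = trial.z1, trial.design.n1[trial.M] + trial.design.n2
        return 0.0 if k == 0 else float(beta_dist.ppf(alpha, k, n - k + 1))
    raise ValueError(f"method must be one of {_TEST_METHODS}")


def one_sided_test(trial: TrialData, spec: TestSpec) -> Tuple[bool, float]:
    """Test ``H0: s_M <= s*``; returns ``(reject, lower_bound)``."""
    lower = one_sided_lower_bound(trial, spec.alpha, spec.method)
    return lower > spec.s_star, lower


def operating_characteristics(
    design: TwoStageDesign,
    S: Sequence[float],
    spec: TestSpec,
    nsim: int = 10_000,
    seed=None,
) -> OperatingCharacteristics:
    """Monte-Carlo type-I error and power, conditional and unconditional.

    Lower bounds are cached by the selected classifier's conditioning event,
    so the cost is governed by the number of distinct events rather than by
    ``nsim``.
    """
    from .simulate import _simulate_batch  # deferred: simulate imports hypotest

    if len(S) != design.K:
        raise ValueError("S must have one entry per classifier")
    if nsim < 1:
        raise ValueError("nsim must be positive")
    rng = np.random.default_rng(seed)
    batch = _simulate_batch(design, S, nsim, rng)
    M, z1, x_min, continued = batch.M, batch.z1, batch.x_min, batch.continued

    S = np.asarray(S, dtype=float)
    n1 = np.asarray(design.n1)
    cache: dict = {}
    reject = np.zeros(nsim, dtype=bool)
    idx = np.flatnonzero(continued)
    for i in idx:
        key = (int(n1[M[i]]), int(x_min[i]), int(z1[i]))
        if key not in cache:
            if spec.method == "ss":
                model = SSConditionalModel(key[0], design.n2, key[1])
                lb = model.solve_lower(key[2], spec.alpha)
            else:
                k, n = key[2], key[0] + design.n2
                lb = 0.0 if k == 0 else float(beta_dist.ppf(spec.alpha, k, n - k + 1))
            cache[key] = lb
        reject[i] = cache[key] > spec.s_star

    s_sel = np.where(continued, S[M], np.nan)
    null = continued & (s_sel <= spec.s_star)
    alt = continued & (s_sel > spec.s_star)
    n_cont = int(continued.sum())

    def _rate(num: np.ndarray, den: np.ndarray) -> Optional[float]:
        d = int(den.sum())
        return float(num.sum() / d) if d > 0 else None

    return OperatingCharacteristics(
        conditional_t1=_rate(reject & null, null),
        unconditional_t1=float((reject & null).sum() / nsim),
        conditional_power=_rate(reject & alt, alt),
        unconditional_power=float((reject & alt).sum() / nsim),
        continue_rate=n_cont / nsim,
        nsim=nsim,
    )
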