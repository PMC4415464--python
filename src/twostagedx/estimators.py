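"""Point estimators for the selected classifier's sensitivity.

The pooled MLE ``(x_M + y) / (n1_M + n2)`` ignores the stage-1 selection and
is biased high, conditional on the trial reaching stage 2.  The stage-2-only
proportion ``y / n2`` is conditionally unbiased but wastes the stage-1 data.
Rao–Blackwellising it against the complete sufficient statistic — the pooled
count ``z1 = x_M + y`` together with the other survivors' stage-1 counts —
yields the uniformly minimum variance conditionally unbiased estimator
(UMVCUE)

    E[Y / n2 | Z, Q] =  Σ_y (y/n2) C(n2, y) C(n1_M, z1 − y)
                       ───────────────────────────────────── ,
                         Σ_y       C(n2, y) C(n1_M, z1 − y)

where the sums run over the stage-2 counts ``y`` compatible with the
selection event ``Q``: conditional on ``z1``, ``Y`` is hypergeometric, and
``Q`` further restricts its support through the futility bound
``x_M = z1 − y >= ⌈c_M⌉`` and the ranking bound against the runner-up (a tie
being admissible only when the selected classifier carries the smaller
original index).  When the restricted support reaches ``n2`` the selection
exerts no bias and the UMVCUE collapses to the MLE.

All hypergeometric weight sums use exact integer arithmetic.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Tuple

from .design import (
    TrialData,
    TwoStageDesign,
    count_at_least,
    int_ceil,
)

__all__ = [
    "SufficientStatistic",
    "ConditionalSupport",
    "sufficient_statistic",
    "restricted_support",
    "mle",
    "stage_estimates",
    "umvcue",
    "median_unbiased",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SufficientStatistic:
    """Complete sufficient statistic of the selection-and-validation trial.

    ``z1`` pools the selected classifier's counts over both stages; ``others``
    records the non-selected survivors' stage-1 counts in ranked order (as
    ``(original_index, count)`` pairs).  The runner-up — the second-ranked
    survivor — supplies the ranking bound on the restricted support;
    ``tie_allowed`` is true when the selected index is smaller than the
    runner-up's, so that an exact score tie is compatible with the observed
    selection.
    """

    M: int
    z1: int
    others: tuple  # ((index, count), ...) in ranked order
    tie_allowed: Optional[bool]  # None when L == 1

    @property
    def L(self) -> int:
        return 1 + len(self.others)

    @property
    def runner_up(self) -> Optional[Tuple[int, int]]:
        return self.others[0] if self.others else None


@dataclass(frozen=True)
class ConditionalSupport:
    """Admissible stage-2 counts ``y`` under the selection event.

    ``kind`` names the published flavour of the set: ``"A"`` (runner-up bound,
    tie excluded), ``"B"`` (runner-up bound, tie admitted) or ``"A'"`` (single
    survivor, futility bound only).  ``x_min`` is the implied lower limit on
    the selected classifier's stage-1 count.
    """

    values: tuple
    kind: str
    x_min: int

    def __contains__(self, y: int) -> bool:
        return y in self.values

    @property
    def lo(self) -> int:
        return self.values[0]

    @property
    def hi(self) -> int:
        return self.values[-1]


def sufficient_statistic(trial: TrialData) -> SufficientStatistic:
    trial.require_continued()
    sel = trial.selection
    others = tuple((i, trial.x[i]) for i in sel.ranked[1:])
    tie_allowed = None
    if others:
        tie_allowed = sel.M < others[0][0]
    return SufficientStatistic(
        M=sel.M, z1=trial.z1, others=others, tie_allowed=tie_allowed
    )


def _x_lower_bound(stat: SufficientStatistic, design: TwoStageDesign) -> int:
    """Minimal stage-1 count of the selected classifier compatible with Q."""
    x_min = max(0, int_ceil(design.c[stat.M]))
    if stat.others:
        j, xj = stat.others[0]
        bound = design.ranking.dominance(xj, stat.M, j)
        x_min = max(x_min, count_at_least(bound, strict=not stat.tie_allowed))
    return x_min


def restricted_support(
    stat: SufficientStatistic, design: TwoStageDesign
) -> ConditionalSupport:
    """Restricted support of ``Y`` given the sufficient statistic and ``Q``.

    Combines the hypergeometric base support
    ``max(0, z1 − n1_M) <= y <= min(z1, n2)`` with the futility and ranking
    bounds on ``x_M = z1 − y``.
    """
    n1M = design.n1[stat.M]
    x_min = _x_lower_bound(stat, design)
    lo = max(0, stat.z1 - n1M)
    hi = min(stat.z1 - x_min, design.n2)
    if hi < lo:
        raise ValueError(
            f"empty conditional support: z1={stat.z1} requires "
            f"x_M >= {x_min} and y in [{lo}, {min(stat.z1, design.n2)}]"
        )
    if not stat.others:
        kind = "A'"
    else:
        kind = "B" if stat.tie_allowed else "A"
    return ConditionalSupport(values=tuple(range(lo, hi + 1)), kind=kind, x_min=x_min)


def mle(trial: TrialData) -> float:
    """Pooled maximum-likelihood estimate ``(x_M + y) / (n1_M + n2)``."""
    trial.require_continued()
    return trial.z1 / (trial.design.n1[trial.M] + trial.design.n2)


def stage_estimates(trial: TrialData) -> Tuple[float, float]:
    """Single-stage proportions ``(x_M / n1_M, y / n2)``.

    The stage-2 proportion is exactly unbiased for ``s_M`` conditional on the
    selection event, since ``Y`` is drawn after selection.
    """
    trial.require_continued()
    return trial.x[trial.M] / trial.design.n1[trial.M], trial.y / trial.design.n2


def umvcue(trial: TrialData) -> float:
    """Uniformly minimum variance conditionally unbiased estimate of ``s_M``."""
    trial.require_continued()
    stat = sufficient_statistic(trial)
    return _umvcue_from_counts(
        trial.design.n1[stat.M],
        trial.design.n2,
        stat.z1,
        _x_lower_bound(stat, trial.design),
    )


def _umvcue_from_counts(n1M: int, n2: int, z1: int, x_min: int) -> float:
    """E[Y/n2 | z1, x_M >= x_min] via exact hypergeometric weight sums."""
    lo = max(0, z1 - n1M)
    hi = min(z1 - x_min, n2)
    if hi < lo:
        raise ValueError("empty conditional support")
    num = 0
    den = 0
    for y in range(lo, hi + 1):
        w = math.comb(n2, y) * math.comb(n1M, z1 - y)
        num += y * w
        den += w
    return num / (n2 * den)


def median_unbiased(trial: TrialData, model=None) -> float:
    """Approximate median-unbiased estimate from the conditional tails.

    Solves ``P(Z1 >= z_obs | s) = 1/2`` and ``P(Z1 <= z_obs | s) = 1/2`` under
    the exact conditional distribution of the pooled count given the selection
    event (``model``, built from the trial when not supplied), and returns the
    midpoint of the two roots.  On a degenerate (single-point) support both
    roots coincide at the forced value.
    """
    from .intervals import SSConditionalModel  # local import avoids a cycle

    trial.require_continued()
    if model is None:
        model = SSConditionalModel.from_trial(trial)
    z = trial.z1
    d1 = model.solve_lower(z, 0.5)
    d2 = model.solve_upper(z, 0.5)
    if d1 > d2:  # numerically crossed roots on a near-degenerate support
        logger.warning("median-unbiased roots crossed (%.6f > %.6f)", d1, d2)
    return 0.5 * (d1 + d2)
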