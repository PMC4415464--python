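"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from scipy.stats import binom

from twostagedx import TrialData, TwoStageDesign, rank_and_select


@pytest.fixture
def design_k1_free() -> TwoStageDesign:
    """Single classifier, no futility: conditioning is vacuous."""
    return TwoStageDesign(n1=(50,), c=(0,), n2=50)


@pytest.fixture
def design_row1() -> TwoStageDesign:
    """Two classifiers, stage-1 sizes 50, cut-offs 35, stage-2 size 50."""
    return TwoStageDesign(n1=(50, 50), c=(35, 35), n2=50)


@pytest.fixture
def design_fig2() -> TwoStageDesign:
    return TwoStageDesign(n1=(50, 50, 50), c=(35, 35, 35), n2=50)


def enumerate_conditional_expectations(design: TwoStageDesign, S):
    """Brute-force E[Y/n2 | Z, Q] over the full joint outcome space.

    Enumerates every (x_1..x_K, y), groups outcomes by the sufficient
    statistic and selection event — (selected index, the other survivors'
    (index, count) pairs in ranked order, pooled count z1) — and returns
    ``{key: (conditional_expectation, exemplar_trial)}``.  Independent of
    the estimator implementation: it only reuses the selection rule, which
    is itself validated against a brute-force argmax.
    """
    K, n2 = design.K, design.n2
    pmf1 = [binom.pmf(np.arange(n + 1), n, s) for n, s in zip(design.n1, S)]
    pmf2 = {i: binom.pmf(np.arange(n2 + 1), n2, S[i]) for i in range(K)}
    acc: dict = {}
    exemplar: dict = {}
    for x in itertools.product(*[range(n + 1) for n in design.n1]):
        sel = rank_and_select(x, design)
        if not sel.continued:
            continue
        px = 1.0
        for i in range(K):
            px *= pmf1[i][x[i]]
        for y in range(n2 + 1):
            p = px * pmf2[sel.M][y]
            key = (sel.M, tuple((i, x[i]) for i in sel.ranked[1:]), x[sel.M] + y)
            num, den = acc.get(key, (0.0, 0.0))
            acc[key] = (num + p * y / n2, den + p)
            exemplar.setdefault(key, (x, y))
    out = {}
    for key, (num, den) in acc.items():
        if den > 0:
            xk, yk = exemplar[key]
            out[key] = (num / den, TrialData(design=design, x=xk, y=yk))
    return out


#: varied panel of exhaustively enumerable designs: K in {1,2,3}, unequal
#: stage-1 sizes, zero / positive / fractional cut-offs
SMALL_DESIGN_PANEL = [
    TwoStageDesign(n1=(5,), c=(0,), n2=5),
    TwoStageDesign(n1=(3,), c=(2,), n2=5),
    TwoStageDesign(n1=(5, 5), c=(0, 0), n2=5),
    TwoStageDesign(n1=(5, 4), c=(2, 1), n2=4),
    TwoStageDesign(n1=(6, 6), c=(3, 3), n2=6),
    TwoStageDesign(n1=(4, 6, 5), c=(2, 3, 2.5), n2=4),
    TwoStageDesign(n1=(6, 5, 4), c=(0, 1.5, 2), n2=3),
]
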