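"""Family-history-questionnaire (FHQ) style selection rules and analysis.

A two-stage questionnaire validation study screens candidate yes/no
questions per condition: a question qualifies when a two-sided Fisher's
exact test of its stage-1 2×2 table (cases × response) is significant, and
the qualifying question with the greatest balanced accuracy is carried to
stage 2.  Because inference targets sensitivity, the control-side counts
(false positives, true negatives) are held fixed by conditioning, which
makes both steps expressible in the fixed-threshold + ranking framework:

* the Fisher test reduces to a fixed cut-off ``c_i`` on the true-positive
  count — the smallest count from which every larger count stays
  significant;
* balanced-accuracy ranking is an affine score ``x_i / n1_i + spec_i``
  (the constant specificities act as per-question offsets), so the dominance
  bound needed by the conditionally unbiased estimator is available in
  closed form.

``fhq_analyze`` runs the whole pipeline per condition and reports the naive
and bias-corrected estimates side by side; identity of the corrected
estimate with the pooled MLE is itself diagnostic — it certifies that the
stage-1 selection exerted no bias on that condition.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from importlib import resources
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency, hypergeom

from .design import AffineScoreRule, TrialData, TwoStageDesign, rank_and_select
from .estimators import mle, restricted_support, stage_estimates, sufficient_statistic, umvcue
from .intervals import IntervalResult, clopper_pearson, ss_ci

__all__ = [
    "QuestionTable",
    "fisher_pvalue",
    "fisher_threshold",
    "balanced_accuracy",
    "balanced_accuracy_rule",
    "stage_concordance_chisq",
    "fhq_analyze",
    "ConditionReport",
    "load_fhq_fixture",
    "load_stage1_correlation",
]


@dataclass(frozen=True)
class QuestionTable:
    """Stage-1 2×2 counts for one question (and stage-2 counts if selected).

    ``tp + fn`` are the stage-1 cases (``n1``), ``fp + tn`` the stage-1
    controls (fixed by conditioning).  ``tp2 / fn2`` are present only for the
    question actually validated in stage 2.
    """

    label: str
    tp: int
    fn: int
    fp: int
    tn: int
    tp2: Optional[int] = None
    fn2: Optional[int] = None

    def __post_init__(self):
        for name in ("tp", "fn", "fp", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def n1(self) -> int:
        return self.tp + self.fn

    @property
    def n2(self) -> Optional[int]:
        if self.tp2 is None:
            return None
        return self.tp2 + (self.fn2 or 0)

    @property
    def specificity(self) -> Fraction:
        m = self.fp + self.tn
        if m == 0:
            raise ValueError(f"question {self.label}: no controls")
        return Fraction(self.tn, m)


def fisher_pvalue(x: int, n1: int, fp: int, tn: int, mid_p: bool = False) -> float:
    """Two-sided Fisher's exact p-value for the table ``[[x, n1−x], [fp, tn]]``.

    Point-probability (minimum-likelihood) two-sided convention, the default
    of mainstream statistical software; ``mid_p=True`` subtracts half the
    probability of tables exactly as likely as the observed one.
    """
    m1 = fp + tn
    if n1 <= 0 or m1 <= 0:
        raise ValueError("both margins must be positive")
    if not 0 <= x <= n1:
        raise ValueError(f"x={x} outside [0, {n1}]")
    k = x + fp  # first-column total; hypergeometric support for the TP cell
    lo, hi = max(0, k - m1), min(k, n1)
    support = np.arange(lo, hi + 1)
    probs = hypergeom.pmf(support, n1 + m1, n1, k)
    p_obs = probs[x - lo]
    tol = 1.0 + 1e-7
    le = probs <= p_obs * tol
    p = float(probs[le].sum())
    if mid_p:
        eq = np.abs(probs - p_obs) <= p_obs * 1e-7
        p -= 0.5 * float(probs[eq].sum())
    return min(p, 1.0)


def fisher_threshold(
    n1: int, fp: int, tn: int, alpha: float = 0.05, mid_p: bool = False
) -> Optional[int]:
    """Smallest cut-off ``c`` with ``p(x) < alpha`` for every ``x in {c..n1}``.

    Returns ``None`` ("unattainable") when not even ``x = n1`` is
    significant.  Only the upper (high-sensitivity) tail is used to qualify
    questions; a low count is never taken as evidence in favour.
    """
    if n1 <= 0 or fp + tn <= 0:
        raise ValueError("degenerate margins: need n1 > 0 and fp + tn > 0")
    if alpha >= 1.0:
        return 0  # every table is "significant" at alpha >= 1
    c = None
    for x in range(n1, -1, -1):
        if fisher_pvalue(x, n1, fp, tn, mid_p=mid_p) < alpha:
            c = x
        else:
            break
    return c


def balanced_accuracy(q: QuestionTable) -> float:
    """Arithmetic mean of stage-1 sensitivity and specificity."""
    if q.n1 == 0:
        raise ValueError(f"question {q.label}: no cases")
    return float((Fraction(q.tp, q.n1) + q.specificity) / 2)


def balanced_accuracy_rule(tables: Sequence[QuestionTable]) -> AffineScoreRule:
    """Ranking rule scoring ``x_i / n1_i + spec_i`` (fixed specificities).

    Monotone-equivalent to balanced accuracy in the true-positive count; its
    dominance bound gives, for the runner-up's observed count, the minimal
    leader count consistent with the observed selection — the quantity the
    restricted support of the unbiased estimator consumes.
    """
    return AffineScoreRule(
        scale=tuple(q.n1 for q in tables),
        offset=tuple(q.specificity for q in tables),
    )


def stage_concordance_chisq(
    stage1: Tuple[int, int], stage2: Tuple[int, int]
) -> float:
    """Pearson χ² p-value comparing the stage-1 and stage-2 sensitivities.

    Continuity-corrected test on the 2×2 stage-by-outcome table; a
    supporting diagnostic only (it is known to be insensitive to the
    selection bias this package corrects).
    """
    (tp1, n1), (tp2, n2) = stage1, stage2
    if not (0 <= tp1 <= n1 and 0 <= tp2 <= n2) or n1 == 0 or n2 == 0:
        raise ValueError("invalid stage counts")
    table = [[tp1, n1 - tp1], [tp2, n2 - tp2]]
    if min(tp1 + tp2, (n1 - tp1) + (n2 - tp2)) == 0:
        raise ValueError("degenerate table: an outcome margin is zero")
    return float(chi2_contingency(table, correction=True).pvalue)


@dataclass
class ConditionReport:
    """Per-condition analysis: selection, estimates and intervals."""

    condition: str
    stopped: bool
    selected: Optional[str] = None
    thresholds: Optional[Dict[str, Optional[int]]] = None
    significant: Optional[List[str]] = None
    estimates: Optional[Dict[str, float]] = None
    intervals: Optional[Dict[str, IntervalResult]] = None
    chisq_p: Optional[float] = None
    selection_bias_detected: Optional[bool] = None
    support: Optional[Tuple[int, int]] = None

    def to_frame(self) -> pd.DataFrame:
        if self.stopped:
            return pd.DataFrame(
                [{"condition": self.condition, "status": "stopped"}]
            )
        rows = []
        for name, est in self.estimates.items():
            ci = self.intervals.get(name)
            rows.append(
                {
                    "condition": self.condition,
                    "question": self.selected,
                    "estimator": name,
                    "estimate": est,
                    "ci_lower": ci.lower if ci else None,
                    "ci_upper": ci.upper if ci else None,
                    "ci_method": ci.method if ci else None,
                }
            )
        return pd.DataFrame(rows)


def fhq_analyze(
    tables: Sequence[QuestionTable],
    condition: str = "",
    alpha: float = 0.05,
    fisher_alpha: float = 0.05,
    mid_p: bool = False,
) -> ConditionReport:
    """End-to-end FHQ-style analysis of one condition.

    Derives the Fisher cut-offs, ranks the significant questions by balanced
    accuracy, confirms that the question carrying stage-2 data is the one the
    rules select, and reports stage-wise, pooled-MLE and conditionally
    unbiased (UMVCUE) estimates with exact 95% intervals — Clopper–Pearson
    for the naive estimators, the exact conditional interval for the UMVCUE.
    """
    if not tables:
        raise ValueError("no question tables supplied")
    thresholds = {
        q.label: fisher_threshold(q.n1, q.fp, q.tn, alpha=fisher_alpha, mid_p=mid_p)
        for q in tables
    }
    # unattainable threshold -> a cut-off the count can never reach
    c = [
        thresholds[q.label] if thresholds[q.label] is not None else q.n1 + 1
        for q in tables
    ]
    design = TwoStageDesign(
        n1=tuple(q.n1 for q in tables),
        c=tuple(c),
        # n2 is a design constant; taken from the stage-2 rows (they agree by
        # construction), or a placeholder when the condition stopped
        n2=next((q.n2 for q in tables if q.n2), 1),
        ranking=balanced_accuracy_rule(tables),
    )
    x = tuple(q.tp for q in tables)
    sel = rank_and_select(x, design)
    if not sel.continued:
        return ConditionReport(condition=condition, stopped=True, thresholds=thresholds)

    selected_q = tables[sel.M]
    with_stage2 = [q.label for q in tables if q.tp2 is not None]
    if with_stage2 != [selected_q.label]:
        raise ValueError(
            f"stage-2 data present for {with_stage2}, but the selection rules "
            f"choose {selected_q.label!r}"
        )
    if selected_q.tp2 is None or selected_q.n2 is None:
        raise ValueError(f"selected question {selected_q.label} lacks stage-2 data")

    trial = TrialData(design=design, x=x, y=selected_q.tp2)
    s1, s2 = stage_estimates(trial)
    est_mle = mle(trial)
    est_umv = umvcue(trial)
    n1M, n2 = selected_q.n1, selected_q.n2
    supp = restricted_support(sufficient_statistic(trial), design)
    intervals = {
        "stage1": clopper_pearson(selected_q.tp, n1M, alpha),
        "stage2": clopper_pearson(selected_q.tp2, n2, alpha),
        "mle": clopper_pearson(trial.z1, n1M + n2, alpha),
        "umvcue": ss_ci(trial, alpha),
    }
    return ConditionReport(
        condition=condition,
        stopped=False,
        selected=selected_q.label,
        thresholds=thresholds,
        significant=[tables[i].label for i in sel.survivors],
        estimates={"stage1": s1, "stage2": s2, "mle": est_mle, "umvcue": est_umv},
        intervals=intervals,
        chisq_p=stage_concordance_chisq(
            (selected_q.tp, n1M), (selected_q.tp2, n2)
        ),
        selection_bias_detected=bool(est_umv < est_mle - 1e-12),
        support=(supp.lo, supp.hi),
    )


def _read_packaged_csv(name: str, **kw) -> pd.DataFrame:
    ref = resources.files("twostagedx").joinpath("data", name)
    with ref.open("r") as fh:
        return pd.read_csv(fh, comment="#", **kw)


def load_fhq_fixture() -> Dict[str, List[QuestionTable]]:
    """Packaged *synthetic* FHQ-like dataset, one question list per condition.

    Synthetic stand-in for a questionnaire study's stage-1/stage-2 count
    tables (the published per-question tables are not machine-readable); it
    reproduces the qualitative structure: several conditions where selection
    exerted no bias, and one where the selected question's stage-1 estimate
    was inflated by the selection rules.
    """
    df = _read_packaged_csv("fhq_synthetic_trial.csv")
    out: Dict[str, List[QuestionTable]] = {}
    for cond, grp in df.groupby("condition", sort=False):
        tables = []
        for row in grp.itertuples():
            if int(row.excluded):
                continue
            tp2 = None if pd.isna(row.tp2) else int(row.tp2)
            fn2 = None if pd.isna(row.fn2) else int(row.fn2)
            tables.append(
                QuestionTable(
                    label=str(row.question),
                    tp=int(row.tp1),
                    fn=int(row.fn1),
                    fp=int(row.fp1),
                    tn=int(row.tn1),
                    tp2=tp2,
                    fn2=fn2,
                )
            )
        out[str(cond)] = tables
    return out


def load_stage1_correlation() -> pd.DataFrame:
    """Published stage-1 pairwise correlation matrix of the FHQ responses."""
    df = _read_packaged_csv("fhq_stage1_correlation.csv", index_col=0)
    return df
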