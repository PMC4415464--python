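"""Two-stage selection/validation designs for binary diagnostic classifiers.

A trial screens ``K`` candidate binary classifiers (biomarkers, yes/no
questionnaire items, ...) on known cases.  Classifier ``i`` is evaluated on
``n1[i]`` stage-1 cases, producing a true-positive count ``x[i] ~
Binomial(n1[i], s_i)`` where ``s_i`` is its unknown sensitivity.  A classifier
stays in contention only if its count reaches a pre-specified futility cut-off
``c[i]``; if every classifier fails, the whole study stops early.  Survivors
are ranked by a pre-specified scoring rule (estimated sensitivity by default),
ties are broken in favour of the smallest original index, and the top-ranked
survivor — index ``M`` — is carried to stage 2, where it is evaluated on
``n2`` further cases giving ``y ~ Binomial(n2, s_M)``.

Everything downstream (conditionally unbiased estimation, exact conditional
intervals) conditions on this selection event, so the design and the selection
are encoded explicitly here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from numbers import Rational
from typing import Optional, Sequence, Union

__all__ = [
    "RankingRule",
    "AffineScoreRule",
    "sensitivity_rule",
    "TwoStageDesign",
    "SelectionOutcome",
    "TrialData",
    "TrialStoppedError",
    "apply_futility",
    "rank_and_select",
    "int_ceil",
    "count_at_least",
]

Real = Union[int, float, Fraction]

#: absolute guard when taking the ceiling of a float cut-off such as 0.7 * 50,
#: which may sit one ulp above an integer.
_CEIL_GUARD = 1e-9


def int_ceil(value: Real) -> int:
    """Smallest integer count satisfying ``count >= value``.

    Exact for integers and :class:`~fractions.Fraction`; floats are guarded
    against representation error one ulp above an integer (cut-offs are
    typically specified as ``rate * n1``).
    """
    if isinstance(value, Rational):
        return math.ceil(value)
    return math.ceil(value - _CEIL_GUARD)


def count_at_least(bound: Real, strict: bool = False) -> int:
    """Smallest integer ``x`` with ``x >= bound`` (or ``x > bound`` if strict).

    Used to convert the real-valued dominance bound of a ranking rule into an
    integer count limit.  Strictness encodes tie admissibility: when a tie in
    the ranking would *not* have selected this classifier, the bound is strict.
    """
    if strict:
        if isinstance(bound, Rational):
            return math.floor(bound) + 1
        return math.floor(bound + _CEIL_GUARD) + 1
    return int_ceil(bound)


class RankingRule:
    """Pre-specified rule ranking surviving classifiers "best" to "worst".

    A rule consists of a per-classifier score ``r(x, i)``, strictly increasing
    in the count ``x``, together with the dominance bound ``d(x_j, i, j)``: the
    smallest real value such that

        ``r(x_i, i) >= r(x_j, j)  <=>  x_i >= d(x_j, i, j)``,

    with equality on the right if and only if the scores tie.  The bound must
    depend only on the competitor's count and the per-classifier constants,
    never on ``x_i`` itself; the conditional-support computation of the
    unbiased estimator consumes it in closed form.
    """

    def score(self, x: int, i: int) -> Fraction:
        raise NotImplementedError

    def dominance(self, x_j: int, i: int, j: int) -> Fraction:
        raise NotImplementedError

    def check_consistency(self, n1: Sequence[int]) -> None:
        """Exhaustively cross-check score vs dominance over the count grid."""
        K = len(n1)
        for i in range(K):
            for j in range(K):
                if i == j:
                    continue
                for xj in range(n1[j] + 1):
                    bound = self.dominance(xj, i, j)
                    sj = self.score(xj, j)
                    for xi in range(n1[i] + 1):
                        si = self.score(xi, i)
                        if (si >= sj) != (xi >= bound):
                            raise ValueError(
                                f"ranking rule inconsistent at i={i}, j={j}, "
                                f"x_i={xi}, x_j={xj}"
                            )
                        if (si == sj) != (xi == bound):
                            raise ValueError(
                                f"dominance bound does not characterise ties "
                                f"at i={i}, j={j}, x_i={xi}, x_j={xj}"
                            )


@dataclass(frozen=True)
class AffineScoreRule(RankingRule):
    """Ranking by ``r(x, i) = x / scale[i] + offset[i]``.

    Covers the two rules used in practice: estimated sensitivity
    (``scale = n1``, zero offsets) and balanced accuracy with fixed
    specificities (``scale = n1``, ``offset[i]`` = specificity of classifier
    ``i``; the factor 1/2 is a monotone transform and drops out).
    """

    scale: tuple
    offset: tuple

    def __post_init__(self):
        object.__setattr__(self, "scale", tuple(Fraction(v) for v in self.scale))
        object.__setattr__(self, "offset", tuple(Fraction(v) for v in self.offset))
        if len(self.scale) != len(self.offset):
            raise ValueError("scale and offset must have equal length")
        if any(v <= 0 for v in self.scale):
            raise ValueError("scale entries must be positive")

    def score(self, x: int, i: int) -> Fraction:
        return Fraction(x) / self.scale[i] + self.offset[i]

    def dominance(self, x_j: int, i: int, j: int) -> Fraction:
        return self.scale[i] * (
            Fraction(x_j) / self.scale[j] + self.offset[j] - self.offset[i]
        )


def sensitivity_rule(n1: Sequence[int]) -> AffineScoreRule:
    """Rank survivors by estimated sensitivity ``x_i / n1_i``."""
    n1 = tuple(int(v) for v in n1)
    return AffineScoreRule(scale=n1, offset=(0,) * len(n1))


@dataclass(frozen=True)
class TwoStageDesign:
    """The fixed design: stage sizes, futility cut-offs and ranking rule.

    Parameters
    ----------
    n1 : sequence of int
        Stage-1 case counts per classifier (positive).
    c : sequence of real
        Futility cut-offs; classifier ``i`` survives iff ``x_i >= c[i]``.
        Non-integer cut-offs act through their ceiling.  A cut-off above
        ``n1[i]`` is permitted — that classifier can never pass.
    n2 : int
        Stage-2 case count, fixed in advance independently of stage 1.
    ranking : RankingRule, optional
        Defaults to ranking by estimated sensitivity.
    """

    n1: tuple
    c: tuple
    n2: int
    ranking: RankingRule = None  # type: ignore[assignment]

    def __post_init__(self):
        object.__setattr__(self, "n1", tuple(int(v) for v in self.n1))
        object.__setattr__(self, "c", tuple(self.c))
        if len(self.n1) != len(self.c):
            raise ValueError("n1 and c must have equal length")
        if any(v < 1 for v in self.n1):
            raise ValueError("stage-1 sizes must be positive")
        if any(v < 0 for v in self.c):
            raise ValueError("futility cut-offs must be non-negative")
        if self.n2 < 1:
            raise ValueError("stage-2 size must be positive")
        if self.ranking is None:
            object.__setattr__(self, "ranking", sensitivity_rule(self.n1))

    @property
    def K(self) -> int:
        return len(self.n1)

    @property
    def c_int(self) -> tuple:
        """Integer-count form of the cut-offs, ``⌈c_i⌉``."""
        return tuple(int_ceil(ci) for ci in self.c)


@dataclass(frozen=True)
class SelectionOutcome:
    """Result of applying futility and ranking to stage-1 counts.

    ``survivors`` keeps original index order; ``ranked`` lists survivor
    indices best-to-worst with exact ties broken towards the smaller original
    index; ``M`` is the selected (top-ranked) index, ``None`` when the trial
    stopped.  All indices are 0-based.
    """

    survivors: tuple
    ranked: tuple
    M: Optional[int]
    continued: bool

    @property
    def L(self) -> int:
        return len(self.survivors)

    @property
    def runner_up(self) -> Optional[int]:
        return self.ranked[1] if len(self.ranked) > 1 else None


class TrialStoppedError(Exception):
    """Raised when an estimate is requested for a trial that stopped early."""


def apply_futility(x: Sequence[int], design: TwoStageDesign) -> tuple:
    """Indices (original order) whose stage-1 count meets its cut-off."""
    if len(x) != design.K:
        raise ValueError(f"expected {design.K} counts, got {len(x)}")
    cint = design.c_int
    for i, xi in enumerate(x):
        if not 0 <= xi <= design.n1[i]:
            raise ValueError(f"count x[{i}]={xi} outside [0, {design.n1[i]}]")
    return tuple(i for i, xi in enumerate(x) if xi >= cint[i])


def rank_and_select(x: Sequence[int], design: TwoStageDesign) -> SelectionOutcome:
    """Apply futility, rank survivors, select the classifier for stage 2.

    An empty survivor set is a valid outcome (the study terminates early),
    reported with ``continued=False``.
    """
    survivors = apply_futility(x, design)
    if not survivors:
        return SelectionOutcome(survivors=(), ranked=(), M=None, continued=False)
    rule = design.ranking
    # sort descending by exact (Fraction) score; stable sort + index key
    # implements the smallest-original-index tie-break
    ranked = tuple(sorted(survivors, key=lambda i: (-rule.score(x[i], i), i)))
    return SelectionOutcome(
        survivors=survivors, ranked=ranked, M=ranked[0], continued=True
    )


@dataclass(frozen=True)
class TrialData:
    """Observed counts of one two-stage trial, with its (recomputed) selection."""

    design: TwoStageDesign
    x: tuple
    y: Optional[int]
    selection: SelectionOutcome = field(init=False)

    def __post_init__(self):
        object.__setattr__(self, "x", tuple(int(v) for v in self.x))
        sel = rank_and_select(self.x, self.design)
        object.__setattr__(self, "selection", sel)
        if sel.continued:
            if self.y is None:
                raise ValueError("trial continued: stage-2 count y is required")
            if not 0 <= self.y <= self.design.n2:
                raise ValueError(f"y={self.y} outside [0, {self.design.n2}]")
        elif self.y is not None:
            raise ValueError("trial stopped at stage 1: y must be None")

    @property
    def continued(self) -> bool:
        return self.selection.continued

    @property
    def M(self) -> Optional[int]:
        return self.selection.M

    @property
    def z1(self) -> int:
        """Pooled true-positive count of the selected classifier, X_M + Y."""
        self.require_continued()
        return self.x[self.selection.M] + self.y

    def require_continued(self) -> None:
        if not self.selection.continued:
            raise TrialStoppedError(
                "all classifiers failed their futility cut-offs; "
                "no stage-2 data and no estimate exist"
            )
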