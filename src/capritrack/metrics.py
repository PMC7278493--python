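"""Concordance scoring and time-budget comparison.

Agreement between a decoded state sequence and the observer's is scored per
behavior (1 = approaching, 2 = standing) at frame level, with a small
temporal tolerance: a behavior frame counts as concordant if the other
sequence shows that behavior within ±`window` frames (default one frame,
i.e. 0.5 s either side).  The tolerance absorbs the slight lag between a
human's reaction to the video and the tracker's.

    TP — observer-behavior frame matched by a prediction inside the window
    FN — observer-behavior frame with no prediction inside the window
    FP — predicted-behavior frame with no observation inside the window
    PC — 100·TP/(TP+FN+FP)

When the behavior occurs in neither sequence, PC is 100% by convention
(nothing to detect, nothing falsely detected); when only the prediction
shows it, PC is 0% with FP at 100%.  Counting is frame-level throughout — no
event segmentation or one-to-one matching.

Time budgets (the share of frames spent in each behavior) are compared
between observer and method across animals with a paired two-sided t-test
(Welch's two-sample variant available).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

BEHAVIORS = (1, 2)


@dataclass
class ConcordanceResult:
    """Windowed frame-agreement counts and percentages for one behavior."""

    animal_id: str
    behavior: int
    TP: int
    FN: int
    FP: int

    @property
    def total(self) -> int:
        return self.TP + self.FN + self.FP

    @property
    def PC(self) -> float:
        return 100.0 * self.TP / self.total if self.total else 100.0

    @property
    def FP_pct(self) -> float:
        return 100.0 * self.FP / self.total if self.total else 0.0

    @property
    def FN_pct(self) -> float:
        return 100.0 * self.FN / self.total if self.total else 0.0


def _window_hit(mask: np.ndarray, window: int) -> np.ndarray:
    """mask dilated by ±window frames (truncated at the edges)."""
    if window == 0:
        return mask.copy()
    hit = mask.copy()
    for w in range(1, window + 1):
        hit[w:] |= mask[:-w]
        hit[:-w] |= mask[w:]
    return hit


def windowed_concordance_counts(
    pred: Sequence[int],
    obs: Sequence[int],
    behavior: int,
    window: int = 1,
) -> tuple[int, int, int]:
    """Frame-level (TP, FN, FP) for one behavior with a ±window tolerance."""
    pred = np.asarray(pred, dtype=int)
    obs = np.asarray(obs, dtype=int)
    if pred.shape != obs.shape:
        raise ValueError("prediction and observation lengths differ")
    if window < 0:
        raise ValueError("window must be >= 0")
    p = pred == behavior
    o = obs == behavior
    p_near = _window_hit(p, window)
    o_near = _window_hit(o, window)
    TP = int((o & p_near).sum())
    FN = int((o & ~p_near).sum())
    FP = int((p & ~o_near).sum())
    return TP, FN, FP


def percentage_concordance(TP: int, FN: int, FP: int) -> float:
    """PC = 100·TP/(TP+FN+FP); 100.0 when all three counts are zero."""
    if TP < 0 or FN < 0 or FP < 0:
        raise ValueError("counts must be non-negative")
    total = TP + FN + FP
    return 100.0 * TP / total if total else 100.0


def score_animal(
    pred: Sequence[int],
    obs: Sequence[int],
    animal_id: str = "",
    window: int = 1,
) -> list[ConcordanceResult]:
    """ConcordanceResult for each behavior (approaching, standing)."""
    return [
        ConcordanceResult(animal_id, b, *windowed_concordance_counts(pred, obs, b, window))
        for b in BEHAVIORS
    ]


@dataclass
class TimeBudget:
    """Share of frames an animal spends in each proceptive behavior (%)."""

    animal_id: str
    approaching_pct: float
    standing_pct: float

    def __getitem__(self, behavior: int) -> float:
        if behavior == 1:
            return self.approaching_pct
        if behavior == 2:
            return self.standing_pct
        raise KeyError(behavior)


def behavior_time_budget(labels: Sequence[int], animal_id: str = "") -> TimeBudget:
    """Percentage of frames labeled 1 (approaching) and 2 (standing)."""
    s = np.asarray(labels, dtype=int)
    if len(s) == 0:
        raise ValueError("empty label sequence")
    return TimeBudget(
        animal_id=animal_id,
        approaching_pct=100.0 * float((s == 1).mean()),
        standing_pct=100.0 * float((s == 2).mean()),
    )


@dataclass
class BudgetTestResult:
    """Two-sided t-test on per-animal budget differences."""

    statistic: float
    pvalue: float
    n: int
    kind: str
    degenerate: bool = False


def compare_budgets_ttest(
    obs_budgets: Sequence[float],
    method_budgets: Sequence[float],
    kind: str = "paired",
) -> BudgetTestResult:
    """Compare observer and method time budgets across animals.

    Budgets are per-animal pairs (the same animal scored two ways), so the
    default is a paired t-test on the differences; ``kind="welch"`` gives the
    unpaired unequal-variance alternative.  Zero-variance differences are
    flagged as degenerate instead of raising.
    """
    a = np.asarray(obs_budgets, dtype=float)
    b = np.asarray(method_budgets, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("budget vectors must be aligned 1-D arrays")
    n = len(a)
    if n < 2:
        return BudgetTestResult(np.nan, np.nan, n, kind, degenerate=True)
    if kind == "paired":
        d = a - b
        if np.allclose(d.std(ddof=1), 0.0):
            return BudgetTestResult(np.nan, np.nan, n, kind, degenerate=True)
        t, p = stats.ttest_rel(a, b)
    elif kind == "welch":
        if np.allclose(a.std(ddof=1), 0.0) and np.allclose(b.std(ddof=1), 0.0):
            return BudgetTestResult(np.nan, np.nan, n, kind, degenerate=True)
        t, p = stats.ttest_ind(a, b, equal_var=False)
    else:
        raise ValueError("kind must be 'paired' or 'welch'")
    return BudgetTestResult(float(t), float(p), n, kind)
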