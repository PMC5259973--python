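"""Study-level statistics: pain AUC, exact small-sample tests, contingency.

With four subjects the classical asymptotic tests are at their limits:
the exact Wilcoxon signed-rank enumeration (minimum one-sided p of
1/2^n = 0.0625 at n = 4) is provided alongside the paired t-test, and
the contingency analysis of measurable inter-forelimb delays uses a
plain Pearson chi-square.  Model-based analyses (ordinal repeated
measures, kinetic mixed models) live in :mod:`pawkit.models`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "pain_auc_above_baseline",
    "exact_signed_rank_p",
    "paired_auc_comparison",
    "PairedComparison",
    "crossing_time",
    "CrossingTime",
    "chisq_2x2",
    "Chi2Result",
]


def pain_auc_above_baseline(
    times_h,
    scores,
    baseline: float,
    floor_negative: bool = False,
) -> float:
    """Trapezoidal area (score·h) of pain score above baseline over time.

    The curve is anchored at (0 h, baseline), i.e. delta 0 at treatment
    time.  Deltas below baseline subtract from the area unless
    ``floor_negative`` is set.
    """
    t = np.asarray(times_h, dtype=float)
    s = np.asarray(scores, dtype=float)
    if t.size != s.size:
        raise ValueError("times and scores must have equal length")
    if t.size < 2:
        raise ValueError("need at least 2 timepoints")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if t[0] < 0:
        raise ValueError("post-treatment times must be non-negative")
    delta = s - baseline
    if floor_negative:
        delta = np.maximum(delta, 0.0)
    if t[0] > 0:
        t = np.concatenate([[0.0], t])
        delta = np.concatenate([[0.0], delta])
    return float(np.trapezoid(delta, t))


def exact_signed_rank_p(paired_diffs, alternative: str = "observed") -> float:
    """Exact one-sided Wilcoxon signed-rank p by complete enumeration.

    All ``2^n`` sign assignments of the ranked absolute differences are
    enumerated (ties get mid-ranks, zeros are dropped).  With
    ``alternative="observed"`` the test is one-sided toward the observed
    direction; "greater"/"less" force a direction.  With four subjects
    all shifted the same way this yields the floor value 1/16 = 0.0625.
    """
    d = np.asarray(paired_diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 1.0
    if n > 20:
        raise ValueError("exact enumeration limited to n <= 20")
    ranks = sps.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    # null distribution of W+ over all sign assignments
    sums = np.zeros(1)
    for r in ranks:
        sums = np.concatenate([sums, sums + r])
    total = sums.size
    if alternative == "observed":
        alternative = "greater" if d.mean() >= 0 else "less"
    if alternative == "greater":
        return float(np.sum(sums >= w_pos - 1e-12) / total)
    if alternative == "less":
        return float(np.sum(sums <= w_pos + 1e-12) / total)
    raise ValueError(f"unknown alternative {alternative!r}")


@dataclass
class PairedComparison:
    mean_diff: float
    t_stat: float
    t_p: float
    signed_rank_p: float
    direction: str


def paired_auc_comparison(auc_control, auc_treatment) -> PairedComparison:
    """Compare per-cat AUCs between arms: paired t plus exact signed rank.

    The difference is control - treatment, so a positive mean difference
    and "control > treatment" direction indicate the treatment lowered
    the pain burden.
    """
    a = np.asarray(auc_control, dtype=float)
    b = np.asarray(auc_treatment, dtype=float)
    if a.size != b.size or a.size < 2:
        raise ValueError("need matched AUC vectors of length >= 2")
    d = a - b
    md = float(d.mean())
    if np.allclose(d, 0):
        t_stat, t_p = 0.0, 1.0
    else:
        sd = d.std(ddof=1)
        if sd == 0:
            t_stat = math.inf if md > 0 else -math.inf
            t_p = 0.0
        else:
            t_stat = md / (sd / math.sqrt(d.size))
            t_p = float(2 * sps.t.sf(abs(t_stat), df=d.size - 1))
    direction = (
        "control > treatment" if md > 0
        else "treatment > control" if md < 0
        else "no difference"
    )
    return PairedComparison(
        mean_diff=md,
        t_stat=float(t_stat),
        t_p=t_p,
        signed_rank_p=exact_signed_rank_p(d),
        direction=direction,
    )


@dataclass
class CrossingTime:
    """First time a probability curve reaches a reference level."""

    time_h: float | None
    label: str  # e.g. "12.0", "< 3", "> 72"

    def __str__(self) -> str:
        return self.label


def crossing_time(times_h, probs, level: float = 0.5) -> CrossingTime:
    """First time the curve reaches ``level``, by linear interpolation.

    If the curve is already at or above the level at the first evaluated
    time, the crossing is reported as "< t_min" (it happened before
    observation started); if it never reaches the level, "> t_max".
    """
    t = np.asarray(times_h, dtype=float)
    p = np.asarray(probs, dtype=float)
    if np.any(p < -1e-9) or np.any(p > 1 + 1e-9):
        raise ValueError("probabilities must lie in [0, 1]")
    if p[0] >= level:
        return CrossingTime(None, f"< {t[0]:g}")
    above = np.nonzero(p >= level)[0]
    if above.size == 0:
        return CrossingTime(None, f"> {t[-1]:g}")
    i = above[0]
    t_cross = t[i - 1] + (level - p[i - 1]) * (t[i] - t[i - 1]) / (p[i] - p[i - 1])
    return CrossingTime(float(t_cross), f"{t_cross:.1f}")


@dataclass
class Chi2Result:
    statistic: float
    pvalue: float
    odds_ratio: float
    haldane_corrected: bool


def chisq_2x2(table, correction: bool = False) -> Chi2Result:
    """Pearson chi-square for a 2x2 table with cross-product odds ratio.

    Continuity correction off by default; the odds ratio uses the
    Haldane +0.5 correction when any cell is zero.
    """
    tab = np.asarray(table, dtype=float)
    if tab.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(tab < 0) or not np.allclose(tab, np.round(tab)):
        raise ValueError("table must hold non-negative integer counts")
    (a, b), (c, d) = tab
    if min(a, b, c, d) == 0:
        a2, b2, c2, d2 = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        haldane = True
    else:
        a2, b2, c2, d2 = a, b, c, d
        haldane = False
    odds = (a2 * d2) / (b2 * c2)
    if np.any(tab.sum(axis=0) == 0) or np.any(tab.sum(axis=1) == 0):
        return Chi2Result(0.0, 1.0, odds, haldane)
    res = sps.chi2_contingency(tab, correction=correction)
    return Chi2Result(float(res.statistic), float(res.pvalue), float(odds), haldane)
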