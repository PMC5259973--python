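"""Derived kinetic statistics: symmetry, landing timing, session summaries.

The forelimb symmetry index (SI) for a gait variable x is

    SI = 100 * (x_op - x_no) / ((x_op + x_no) / 2)

where x_op / x_no are the operated / non-operated forelimb values.  SI is
0 at perfect symmetry and -200 when the operated limb bears no load; it
is antisymmetric and scale-invariant.  SI is computed per trial and then
averaged within a session (mean of ratios), which is the only reading
consistent with published session tables whose SI columns cannot be
recovered from the mean force columns.

Landing timing: Tf1f2 is the signed operated-minus-non-operated forelimb
strike delay (positive = delayed loading of the operated limb); it is
"measurable" when at least one frame (1/60 s) separates the strikes.
Tf1h1 is the delay from first forelimb to first hindlimb strike.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .recording import FORELIMBS, Footfall

__all__ = [
    "symmetry_index",
    "landing_timing",
    "LandingTiming",
    "count_ntf1f2",
    "KineticSummary",
    "session_summary",
    "baseline_adjust",
    "washout_readiness",
]


def symmetry_index(x_op: float, x_no: float) -> float:
    """Forelimb symmetry index on the percent scale.

    Returns NaN when both limbs read zero (undefined); raises on
    negative input.  Negative SI means less weight on the operated limb.
    """
    if x_op < 0 or x_no < 0:
        raise ValueError("gait variables must be non-negative")
    s = x_op + x_no
    if s == 0:
        return float("nan")
    si = 100.0 * (x_op - x_no) / (0.5 * s)
    # mathematically bounded by [-200, 200]; clamp floating-point spill
    return min(200.0, max(-200.0, si))


@dataclass
class LandingTiming:
    tf1f2_s: float | None
    measurable: bool | None
    tf1h1_s: float | None


def landing_timing(
    footfalls: list[Footfall],
    operated_limb: str,
    frame_rate_hz: float = 60.0,
) -> LandingTiming:
    """Signed inter-forelimb delay and fore-hind delay of one landing."""
    if operated_limb not in FORELIMBS:
        raise ValueError(f"operated limb must be a forelimb, got {operated_limb!r}")
    non_operated = "RF" if operated_limb == "LF" else "LF"
    strikes = {}
    for f in footfalls:
        if f.limb and f.limb not in strikes:
            strikes[f.limb] = f.strike_time
    if operated_limb not in strikes or non_operated not in strikes:
        return LandingTiming(None, None, None)
    tf1f2 = strikes[operated_limb] - strikes[non_operated]
    measurable = abs(tf1f2) >= 1.0 / frame_rate_hz - 1e-9
    fore_first = min(strikes[operated_limb], strikes[non_operated])
    hinds = [t for limb, t in strikes.items() if limb in ("LH", "RH")]
    tf1h1 = min(hinds) - fore_first if hinds else None
    return LandingTiming(tf1f2, measurable, tf1h1)


def count_ntf1f2(timings: list[LandingTiming | bool]) -> tuple[int, float]:
    """Count trials with a measurable inter-forelimb strike difference.

    Accepts :class:`LandingTiming` objects or raw booleans; returns
    ``(count, proportion)``.
    """
    flags = [
        t.measurable if isinstance(t, LandingTiming) else bool(t)
        for t in timings
        if not (isinstance(t, LandingTiming) and t.measurable is None)
    ]
    if not flags:
        return 0, float("nan")
    n = sum(flags)
    return n, n / len(flags)


@dataclass
class KineticSummary:
    """Per-session kinetic summary (mean ± SD over selected trials)."""

    n_trials: int
    op_pvf_mean: float
    op_pvf_sd: float
    no_pvf_mean: float
    no_pvf_sd: float
    op_vi_mean: float
    op_vi_sd: float
    no_vi_mean: float
    no_vi_sd: float
    si_pvf_mean: float
    si_pvf_sd: float
    si_vi_mean: float
    si_vi_sd: float
    tf1f2_mean: float | None = None
    tf1f2_sd: float | None = None
    tf1h1_mean: float | None = None
    tf1h1_sd: float | None = None
    ntf1f2: int | None = None

    def __post_init__(self) -> None:
        for v in (self.si_pvf_mean, self.si_vi_mean):
            if not math.isnan(v) and not -200.0 <= v <= 200.0:
                raise ValueError(f"SI out of range: {v}")
        if self.ntf1f2 is not None and self.ntf1f2 > self.n_trials:
            raise ValueError("ntf1f2 cannot exceed the trial count")


def _mean_sd(vals):
    vals = [v for v in vals if v is not None and not (isinstance(v, float) and math.isnan(v))]
    if not vals:
        return float("nan"), float("nan")
    arr = np.asarray(vals, dtype=float)
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    return float(arr.mean()), sd


def session_summary(trials: pd.DataFrame) -> KineticSummary:
    """Summarise one session from a per-trial table.

    ``trials`` needs columns ``op_pvf, no_pvf, op_vi, no_vi`` and, for
    landings, ``tf1f2_s, tf1f2_measurable, tf1h1_s``.  SI is evaluated
    per trial, then averaged.
    """
    si_pvf = [symmetry_index(o, n) for o, n in zip(trials["op_pvf"], trials["no_pvf"])]
    si_vi = [symmetry_index(o, n) for o, n in zip(trials["op_vi"], trials["no_vi"])]
    out = dict(n_trials=len(trials))
    for col, key in [("op_pvf", "op_pvf"), ("no_pvf", "no_pvf"),
                     ("op_vi", "op_vi"), ("no_vi", "no_vi")]:
        m, s = _mean_sd(trials[col].tolist())
        out[f"{key}_mean"], out[f"{key}_sd"] = m, s
    m, s = _mean_sd(si_pvf)
    out["si_pvf_mean"], out["si_pvf_sd"] = m, s
    m, s = _mean_sd(si_vi)
    out["si_vi_mean"], out["si_vi_sd"] = m, s
    if "tf1f2_s" in trials.columns and trials["tf1f2_s"].notna().any():
        m, s = _mean_sd(trials["tf1f2_s"].tolist())
        out["tf1f2_mean"], out["tf1f2_sd"] = m, s
        out["ntf1f2"] = int(trials["tf1f2_measurable"].eq(True).sum())
    if "tf1h1_s" in trials.columns and trials["tf1h1_s"].notna().any():
        m, s = _mean_sd(trials["tf1h1_s"].tolist())
        out["tf1h1_mean"], out["tf1h1_sd"] = m, s
    return KineticSummary(**out)


RESPONSES = ("op_pvf", "no_pvf", "op_vi", "no_vi", "si_pvf", "si_vi", "tf1f2", "tf1h1")


def baseline_adjust(
    summaries: pd.DataFrame,
    responses: tuple[str, ...] = RESPONSES,
) -> pd.DataFrame:
    """Subtract each cat x period's mean baseline from its post-op values.

    ``summaries`` is long-format with one row per cat x period x
    timepoint and one column per response; baseline rows have negative
    ``timepoint_h``.  The two baseline sessions are averaged separately
    per cat and period; if one baseline session is missing the single
    available one is used and the row is flagged
    (``baseline_incomplete``).  Returns the post-op rows with responses
    replaced by deltas.
    """
    responses = [r for r in responses if r in summaries.columns]
    out = []
    for (cat, period), grp in summaries.groupby(["cat", "period"], sort=True):
        base = grp[grp["timepoint_h"] < 0]
        post = grp[grp["timepoint_h"] >= 0]
        if len(base) == 0:
            raise ValueError(f"no baseline sessions for cat {cat} period {period}")
        incomplete = len(base) < 2
        for _, row in post.iterrows():
            rec = row.to_dict()
            for r in responses:
                rec[r] = row[r] - base[r].mean()
            rec["baseline_incomplete"] = incomplete
            out.append(rec)
    return pd.DataFrame(out)


def washout_readiness(
    baseline_pvf_trials,
    current_pvf_trials,
    confidence: float = 0.95,
) -> bool:
    """Is the cat back to baseline loading before the second period?

    Ready iff the current mean PVF lies within the two-sided t-based
    confidence interval of the pooled baseline trial-level PVFs
    (inclusive at the interval edges).
    """
    base = np.asarray(baseline_pvf_trials, dtype=float)
    cur = np.asarray(current_pvf_trials, dtype=float)
    if base.size < 2 or cur.size < 1:
        raise ValueError("need >=2 baseline trials and >=1 current trial")
    m = base.mean()
    se = base.std(ddof=1) / math.sqrt(base.size)
    tq = sps.t.ppf(0.5 + confidence / 2.0, df=base.size - 1)
    lo, hi = m - tq * se, m + tq * se
    return bool(lo <= cur.mean() <= hi)
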