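"""Synthetic pressure-walkway study generator.

Emulates a two-period crossover study of unilateral forelimb onychectomy
in four cats: walking passes and jump-down landings on a
pressure-sensitive walkway (PSW), plus ordinal observational pain scores.
Every generated trial carries a ground-truth sidecar (intended strike
times, peaks and impulses) so the extraction, QC, kinetic and statistical
stages can be tested against known values without any external data.

The generator works at two levels:

* **kinetic ground truth** — per-trial limb peaks, impulses and strike
  times drawn from the configured study conditions (cheap; a full study
  of 1280 trials takes well under a second);
* **rendered recordings** — any single trial can be rendered to a full
  :class:`~pawkit.recording.PressureRecording` (frames of per-sensel
  force) that the extraction stage decodes; rendering is deterministic
  given the trial seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .recording import G, PressureRecording

__all__ = [
    "SimConfig",
    "ForceCurve",
    "GroundTruthFootfall",
    "GroundTruth",
    "SimTrial",
    "PainSeries",
    "StudyDataset",
    "generate_force_curve",
    "simulate_walking_trial",
    "simulate_landing_trial",
    "simulate_pain_scores",
    "simulate_study",
    "DEFAULT_ALLOCATION",
    "KINETIC_TIMEPOINTS_H",
    "PAIN_TIMEPOINTS_H",
    "BASELINE_TIMEPOINTS_H",
]

#: post-operative kinetic session times (hours after treatment)
KINETIC_TIMEPOINTS_H = (6.0, 24.0, 30.0, 48.0, 54.0, 72.0)
#: observational pain-score session times (hours after treatment)
PAIN_TIMEPOINTS_H = (3.0, 6.0, 12.0, 24.0, 30.0, 36.0, 48.0, 54.0, 60.0, 72.0)
#: baseline sessions, hours relative to surgery (negative = pre-op)
BASELINE_TIMEPOINTS_H = (-48.0, -24.0)

#: crossover allocation: cat -> period -> (treatment, operated foot).
#: Cats 1-2 receive saline first, cats 3-4 the analgesic first; feet are
#: counterbalanced left/right within each sequence group.
DEFAULT_ALLOCATION: dict[int, dict[int, tuple[str, str]]] = {
    1: {1: ("control", "L"), 2: ("er_bup", "R")},
    2: {1: ("control", "R"), 2: ("er_bup", "L")},
    3: {1: ("er_bup", "R"), 2: ("control", "L")},
    4: {1: ("er_bup", "L"), 2: ("control", "R")},
}

# Operated-limb force fractions relative to baseline, per treatment and
# post-op hour.  Derived from the ratio of mean operated-limb landing PVF
# at each time to its baseline in the source study conditions.
DEFAULT_LAMENESS: dict[str, dict[float, float]] = {
    "control": {6.0: 0.68, 24.0: 0.66, 30.0: 0.73, 48.0: 0.70, 54.0: 0.56, 72.0: 0.66},
    "er_bup": {6.0: 0.82, 24.0: 0.70, 30.0: 0.77, 48.0: 0.68, 54.0: 0.72, 72.0: 0.71},
}


@dataclass
class SimConfig:
    """Study conditions for the synthetic crossover experiment.

    Defaults reproduce the published study's structure: 4 cats of
    2.2-3.2 kg, a 2.4 m x 0.5 m mat with 4 sensels/cm² sampled at 60 Hz,
    walking at a 0.6 m/s target, landings from a 0.7 m platform, and
    ordinal 0-5 pain scores that never exceed 2 under the default effect
    sizes (the latent noise is bounded, see ``pain_noise_half_width``).
    """

    n_cats: int = 4
    body_weight_kg: tuple[float, ...] = (2.2, 2.6, 2.9, 3.2)
    sequence_allocation: dict[int, dict[int, tuple[str, str]]] = field(
        default_factory=lambda: {c: dict(p) for c, p in DEFAULT_ALLOCATION.items()}
    )
    lameness_factor: dict[str, dict[float, float]] = field(
        default_factory=lambda: {t: dict(m) for t, m in DEFAULT_LAMENESS.items()}
    )

    # walkway hardware
    frame_rate_hz: float = 60.0
    sensel_per_cm2: float = 4.0
    mat_size_m: tuple[float, float] = (2.4, 0.5)
    calibration_range_psi: float = 50.0
    noise_sd: float = 0.01  # per-sensel force noise, newtons (zero-clipped)

    # walking gait
    target_walk_velocity_mps: float = 0.6
    velocity_sd: float = 0.18  # approximate m/s spread; drawn log-normally
    accel_sd: float = 0.06  # m/s² spread of the planted run acceleration
    stride_length_m: float = 0.40
    duty_factor: float = 0.6
    walk_fore_peak_pct_bw: float = 55.0
    walk_hind_peak_pct_bw: float = 40.0
    walk_comp_gain: float = 0.3  # contralateral compensation per unit lameness

    # landing
    jump_height_m: float = 0.7
    land_fore_peak_pct_bw: float = 187.0
    land_hind_peak_pct_bw: float = 60.0
    land_contact_time_s: float = 0.15
    land_comp_gain: float = 0.4
    stagger_prob: float = 0.25  # baseline probability of a >=1-frame Tf1f2
    stagger_lameness_gain: float = 0.7  # added probability per unit lameness
    tf1h1_base_s: float = 0.11
    tf1h1_lameness_gain_s: float = 0.08

    # trial-to-trial variation
    peak_cv: float = 0.10  # per-footfall peak coefficient of variation
    trial_cv: float = 0.08  # shared per-trial multiplicative factor
    land_trial_cv: float = 0.15

    # pain model: latent decaying post-surgical intensity, thresholded
    pain_amplitude: dict[str, float] = field(
        default_factory=lambda: {"control": 1.9, "er_bup": 0.8}
    )
    pain_tau_h: dict[str, float] = field(
        default_factory=lambda: {"control": 40.0, "er_bup": 10.0}
    )
    pain_period_tau_mult: dict[int, float] = field(
        default_factory=lambda: {1: 1.4, 2: 0.6}
    )
    pain_noise_half_width: float = 0.3  # bounded (uniform) latent noise

    # footprint rendering
    paw_sigma_cm: float = 0.8  # Gaussian footprint scale (~3x3 cm blob)

    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    # -- derived geometry ------------------------------------------------
    @property
    def sensel_pitch_cm(self) -> float:
        return 1.0 / math.sqrt(self.sensel_per_cm2)

    @property
    def grid_shape(self) -> tuple[int, int]:
        pitch_m = self.sensel_pitch_cm / 100.0
        return (
            int(round(self.mat_size_m[1] / pitch_m)),  # rows (lateral)
            int(round(self.mat_size_m[0] / pitch_m)),  # cols (travel)
        )

    def validate(self) -> None:
        if self.n_cats < 1:
            raise ValueError("n_cats must be >= 1")
        if len(self.body_weight_kg) < self.n_cats:
            raise ValueError("body_weight_kg must cover every cat")
        if any(w <= 0 for w in self.body_weight_kg):
            raise ValueError("body weights must be positive")
        if self.frame_rate_hz <= 0 or self.sensel_per_cm2 <= 0:
            raise ValueError("frame_rate_hz and sensel_per_cm2 must be positive")
        if self.jump_height_m <= 0:
            raise ValueError("jump_height_m must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        for trt, by_time in self.lameness_factor.items():
            for tp, f in by_time.items():
                if not 0.0 <= f <= 1.0:
                    raise ValueError(
                        f"lameness_factor[{trt!r}][{tp}] = {f} outside [0, 1]"
                    )
        for cat in range(1, self.n_cats + 1):
            periods = self.sequence_allocation.get(cat)
            if not periods or set(periods) != {1, 2}:
                raise ValueError(
                    f"allocation must cover cat {cat} in both periods exactly once"
                )
            for trt, foot in periods.values():
                if trt not in ("control", "er_bup") or foot not in ("L", "R"):
                    raise ValueError(f"bad allocation entry for cat {cat}")

    # -- study bookkeeping ----------------------------------------------
    def treatment(self, cat: int, period: int) -> str:
        return self.sequence_allocation[cat][period][0]

    def operated_limb(self, cat: int, period: int) -> str:
        return self.sequence_allocation[cat][period][1] + "F"

    def lameness(self, cat: int, period: int, timepoint_h: float) -> float:
        if timepoint_h < 0:
            return 1.0
        trt = self.treatment(cat, period)
        return self.lameness_factor[trt][float(timepoint_h)]

    def weight_n(self, cat: int) -> float:
        return self.body_weight_kg[cat - 1] * G


# ---------------------------------------------------------------------------
# force curves
# ---------------------------------------------------------------------------

@dataclass
class ForceCurve:
    """A single footfall's force-time curve with its analytic integral.

    ``samples`` holds the curve sampled once per frame at the frame
    midpoints of the contact window; ``vi`` is the exact time-integral of
    the underlying continuous shape (the ground-truth vertical impulse)
    in the same force units x seconds.
    """

    samples: np.ndarray
    peak: float
    contact_time_s: float
    frame_rate_hz: float
    shape: str

    @property
    def vi(self) -> float:
        if self.shape == "half_sine":
            return 2.0 / math.pi * self.peak * self.contact_time_s
        return 0.5 * self.peak * self.contact_time_s  # triangular

    @property
    def pvf_discretization_tol(self) -> float:
        """Worst-case peak underestimate from frame sampling.

        Bounded by max|f'| x (frame period)/2.
        """
        dt = 1.0 / self.frame_rate_hz
        if self.shape == "half_sine":
            return math.pi * self.peak / self.contact_time_s * dt / 2.0
        return 2.0 * self.peak / self.contact_time_s * dt / 2.0

    def evaluate(self, t: np.ndarray | float) -> np.ndarray:
        """Continuous generating curve on [0, contact_time]."""
        t = np.asarray(t, dtype=float)
        u = np.clip(t / self.contact_time_s, 0.0, 1.0)
        if self.shape == "half_sine":
            f = self.peak * np.sin(np.pi * u)
        else:
            f = self.peak * (1.0 - np.abs(2.0 * u - 1.0))
        return np.where((t < 0) | (t > self.contact_time_s), 0.0, f)


def generate_force_curve(
    peak_pct_bw: float,
    contact_time: float,
    frame_rate: float = 60.0,
    shape: str = "half_sine",
) -> ForceCurve:
    """Sample a single-footfall vertical force curve on the frame grid.

    Parameters
    ----------
    peak_pct_bw : float
        Peak force (any positive unit; %BW by convention).
    contact_time : float
        Stance duration in seconds; must span at least 2 frames.
    shape : {"half_sine", "triangular"}
        Curve family; both have closed-form integrals.
    """
    if peak_pct_bw <= 0:
        raise ValueError("peak must be positive")
    if shape not in ("half_sine", "triangular"):
        raise ValueError(f"unknown curve shape {shape!r}")
    n = int(round(contact_time * frame_rate))
    if n < 2:
        raise ValueError(
            f"contact_time {contact_time} s spans {n} frames at {frame_rate} Hz; "
            "need at least 2"
        )
    # midpoint sampling: every contact frame carries force and the samples
    # are symmetric about the true peak
    u = (np.arange(n) + 0.5) / n
    if shape == "half_sine":
        samples = peak_pct_bw * np.sin(np.pi * u)
    else:
        samples = peak_pct_bw * (1.0 - np.abs(2.0 * u - 1.0))
    return ForceCurve(
        samples=samples,
        peak=float(peak_pct_bw),
        contact_time_s=n / frame_rate,
        frame_rate_hz=frame_rate,
        shape=shape,
    )


# ---------------------------------------------------------------------------
# ground truth containers
# ---------------------------------------------------------------------------

@dataclass
class GroundTruthFootfall:
    limb: str
    strike_time_s: float
    contact_time_s: float
    peak_pct_bw: float
    vi_pct_bw_s: float
    x_cm: float
    y_cm: float
    shape: str = "half_sine"
    pvf_tol_pct_bw: float = 0.0


@dataclass
class GroundTruth:
    """Per-trial sidecar of intended kinetics."""

    footfalls: list[GroundTruthFootfall]
    body_weight_kg: float
    operated_limb: str
    velocity_mps: float | None = None
    accel_mps2: float | None = None
    valid: bool | None = None
    stalled: bool = False
    tf1f2_s: float | None = None
    tf1f2_measurable: bool | None = None
    tf1h1_s: float | None = None

    def mean_peak(self, limb: str) -> float:
        vals = [f.peak_pct_bw for f in self.footfalls if f.limb == limb]
        return float(np.mean(vals)) if vals else float("nan")

    def mean_vi(self, limb: str) -> float:
        vals = [f.vi_pct_bw_s for f in self.footfalls if f.limb == limb]
        return float(np.mean(vals)) if vals else float("nan")

    def to_records(self) -> list[dict]:
        return [
            {
                "limb": f.limb,
                "strike_time_s": f.strike_time_s,
                "contact_time_s": f.contact_time_s,
                "peak_pct_bw": f.peak_pct_bw,
                "vi_pct_bw_s": f.vi_pct_bw_s,
                "x_cm": f.x_cm,
                "y_cm": f.y_cm,
                "shape": f.shape,
            }
            for f in self.footfalls
        ]


# ---------------------------------------------------------------------------
# walking trials
# ---------------------------------------------------------------------------

_WALK_PHASES = {"LF": 0.0, "RH": 0.25, "RF": 0.5, "LH": 0.75}  # lateral-sequence walk
_FORE_OFFSET_CM = 4.0
_HIND_OFFSET_CM = 4.5
_HIND_REGISTER_CM = 2.0  # hind paw lands this far behind the same-side fore print


def _walking_ground_truth(
    config: SimConfig, cat: int, period: int, timepoint_h: float, rng: np.random.Generator
) -> GroundTruth:
    lam = config.lameness(cat, period, timepoint_h)
    operated = config.operated_limb(cat, period)
    other_fore = "RF" if operated == "LF" else "LF"

    target = config.target_walk_velocity_mps
    sigma = config.velocity_sd / target
    v = target * math.exp(rng.normal(0.0, sigma))
    a = rng.normal(0.0, config.accel_sd)
    stride = config.stride_length_m * math.exp(rng.normal(0.0, 0.05))
    stride_t = stride / v
    stance = config.duty_factor * stride_t
    # stance must span >= 4 frames even for fast trials
    stance = max(stance, 4.0 / config.frame_rate_hz)

    mat_len_cm = config.mat_size_m[0] * 100.0
    y_center = config.mat_size_m[1] * 100.0 / 2.0
    wander = rng.normal(0.0, 1.0)  # cm, constant lateral bias of the path
    margin_cm = 8.0
    x0 = 0.10  # m, first forelimb print

    trial_factor = max(0.2, 1.0 + rng.normal(0.0, config.trial_cv))
    comp = 1.0 + config.walk_comp_gain * (1.0 - lam)

    def base_peak(limb: str) -> float:
        if limb in ("LF", "RF"):
            p = config.walk_fore_peak_pct_bw
            if limb == operated:
                p *= lam
            elif limb == other_fore:
                p *= comp
        else:
            p = config.walk_hind_peak_pct_bw
        return p

    side_sign = {"LF": 1.0, "LH": 1.0, "RF": -1.0, "RH": -1.0}
    fore_prints: dict[tuple[str, int], float] = {}
    feet = []
    n_strides = int(math.ceil((mat_len_cm / 100.0) / stride)) + 2
    v_floor = 0.12  # m/s: below this the cat has stalled; no further strides
    for k in range(n_strides):
        for limb in ("LF", "RF"):
            t = (k + _WALK_PHASES[limb]) * stride_t
            if v + a * t < v_floor:
                continue
            x = (x0 + v * t + 0.5 * a * t * t) * 100.0
            fore_prints[(limb[0], k)] = x
            feet.append((limb, t, x, _FORE_OFFSET_CM * side_sign[limb]))
        for limb in ("LH", "RH"):
            t = (k + _WALK_PHASES[limb]) * stride_t
            if v + a * t < v_floor:
                continue
            # the hind paw lands on the same-side fore print that was most
            # recently vacated: stride k if the fore struck earlier in the
            # stride cycle, stride k-1 otherwise
            k_reg = k if _WALK_PHASES[limb] > _WALK_PHASES[limb[0] + "F"] else k - 1
            x = fore_prints.get((limb[0], k_reg))
            if x is None:
                continue
            feet.append((limb, t, x - _HIND_REGISTER_CM, _HIND_OFFSET_CM * side_sign[limb]))

    footfalls = []
    for limb, t, x, dy in feet:
        if not (margin_cm <= x <= mat_len_cm - margin_cm):
            continue
        peak = base_peak(limb) * trial_factor * max(0.2, 1.0 + rng.normal(0.0, config.peak_cv))
        curve = generate_force_curve(peak, stance, config.frame_rate_hz, "half_sine")
        footfalls.append(
            GroundTruthFootfall(
                limb=limb,
                strike_time_s=t,
                contact_time_s=curve.contact_time_s,
                peak_pct_bw=peak,
                vi_pct_bw_s=curve.vi,
                x_cm=x,
                y_cm=y_center + dy + wander,
                shape="half_sine",
                pvf_tol_pct_bw=curve.pvf_discretization_tol,
            )
        )
    if (mat_len_cm - 2 * margin_cm) / 100.0 < 2 * stride:
        raise ValueError(
            "mat too short for two full strides at the configured stride length"
        )
    footfalls.sort(key=lambda f: f.strike_time_s)
    stalled = sum(f.limb in ("LF", "RF") for f in footfalls) < 4
    t_mid = 0.5 * (footfalls[0].strike_time_s + footfalls[-1].strike_time_s)
    v_mid = v + a * t_mid
    # planted QC label, same bounds the QC stage enforces; a stalled run
    # (cat slowed to a stop mid-mat) is invalid regardless
    valid = (
        not stalled and abs(v_mid - target) <= 0.2 and abs(a) <= 0.1
    )
    return GroundTruth(
        footfalls=footfalls,
        body_weight_kg=config.body_weight_kg[cat - 1],
        operated_limb=operated,
        velocity_mps=v_mid,
        accel_mps2=a,
        valid=valid,
        stalled=stalled,
    )


# ---------------------------------------------------------------------------
# landing trials
# ---------------------------------------------------------------------------

def _landing_ground_truth(
    config: SimConfig, cat: int, period: int, timepoint_h: float, rng: np.random.Generator
) -> GroundTruth:
    if config.jump_height_m <= 0:
        raise ValueError("jump_height_m must be positive")
    lam = config.lameness(cat, period, timepoint_h)
    operated = config.operated_limb(cat, period)
    other_fore = "RF" if operated == "LF" else "LF"
    dt = 1.0 / config.frame_rate_hz

    y_center = config.mat_size_m[1] * 100.0 / 2.0
    x_fore = 35.0 + rng.normal(0.0, 3.0)  # cm from mat edge nearest the platform

    # inter-forelimb stagger: probability of a measurable (>=1 frame)
    # difference grows with lameness; the operated limb tends to strike later
    p_meas = min(0.95, config.stagger_prob + config.stagger_lameness_gain * (1.0 - lam))
    measurable = bool(rng.random() < p_meas)
    if measurable:
        frames = int(rng.integers(1, 3))
        if lam < 1.0:
            sign = 1.0 if rng.random() < 0.85 else -1.0
        else:
            sign = 1.0 if rng.random() < 0.5 else -1.0
        stagger = sign * frames * dt
    else:
        stagger = 0.0

    t0 = round(0.25 / dt) * dt  # first forelimb strike, on the frame grid
    strike = {other_fore: t0, operated: t0 + max(stagger, 0.0)}
    if stagger < 0:
        strike = {operated: t0, other_fore: t0 - stagger}

    tf1h1 = (
        config.tf1h1_base_s
        + config.tf1h1_lameness_gain_s * (1.0 - lam)
        + rng.normal(0.0, 0.02)
    )
    tf1h1 = max(2 * dt, round(tf1h1 / dt) * dt)
    t_fore_first = min(strike.values())
    hind_strikes = {
        "LH": t_fore_first + tf1h1,
        "RH": t_fore_first + tf1h1 + int(rng.integers(0, 2)) * dt,
    }

    trial_factor = max(0.2, 1.0 + rng.normal(0.0, config.land_trial_cv))
    comp = 1.0 + config.land_comp_gain * (1.0 - lam)
    peaks = {
        operated: config.land_fore_peak_pct_bw * lam,
        other_fore: config.land_fore_peak_pct_bw * comp,
        "LH": config.land_hind_peak_pct_bw,
        "RH": config.land_hind_peak_pct_bw,
    }
    contact = {
        operated: config.land_contact_time_s,
        other_fore: config.land_contact_time_s,
        "LH": 0.20,
        "RH": 0.20,
    }
    positions = {
        operated: (x_fore, _FORE_OFFSET_CM * (1 if operated == "LF" else -1)),
        other_fore: (x_fore + rng.normal(0.0, 1.5), _FORE_OFFSET_CM * (1 if other_fore == "LF" else -1)),
        "LH": (x_fore - 12.0, _HIND_OFFSET_CM),
        "RH": (x_fore - 12.0, -_HIND_OFFSET_CM),
    }

    footfalls = []
    for limb in ("LF", "RF", "LH", "RH"):
        peak = peaks[limb] * trial_factor * max(0.2, 1.0 + rng.normal(0.0, config.peak_cv))
        curve = generate_force_curve(peak, contact[limb], config.frame_rate_hz, "half_sine")
        t = strike.get(limb, hind_strikes.get(limb))
        x, dy = positions[limb]
        footfalls.append(
            GroundTruthFootfall(
                limb=limb,
                strike_time_s=t,
                contact_time_s=curve.contact_time_s,
                peak_pct_bw=peak,
                vi_pct_bw_s=curve.vi,
                x_cm=x,
                y_cm=y_center + dy,
                shape="half_sine",
                pvf_tol_pct_bw=curve.pvf_discretization_tol,
            )
        )
    footfalls.sort(key=lambda f: (f.strike_time_s, f.limb))
    return GroundTruth(
        footfalls=footfalls,
        body_weight_kg=config.body_weight_kg[cat - 1],
        operated_limb=operated,
        tf1f2_s=stagger,
        tf1f2_measurable=measurable,
        tf1h1_s=tf1h1,
        valid=True,
    )


# ---------------------------------------------------------------------------
# rendering ground truth to pressure frames
# ---------------------------------------------------------------------------

def _paw_kernel(sigma_cm: float, pitch_cm: float) -> np.ndarray:
    """Normalised 2-D Gaussian footprint (sums to exactly 1)."""
    radius = max(3, int(math.ceil(3.0 * sigma_cm / pitch_cm)))
    ax = np.arange(-radius, radius + 1) * pitch_cm
    xx, yy = np.meshgrid(ax, ax)
    k = np.exp(-(xx**2 + yy**2) / (2.0 * sigma_cm**2))
    return k / k.sum()


def render_recording(
    config: SimConfig, gt: GroundTruth, rng: np.random.Generator
) -> PressureRecording:
    """Render ground-truth footfalls to per-sensel force frames.

    Each footfall deposits its force curve through a normalised Gaussian
    footprint, so the summed mat force during a single-limb contact
    equals the limb's curve value exactly (before sensor noise).
    """
    fs = config.frame_rate_hz
    pitch = config.sensel_pitch_cm
    rows, cols = config.grid_shape
    t_end = max(f.strike_time_s + f.contact_time_s for f in gt.footfalls) + 0.15
    n_frames = int(math.ceil(t_end * fs))
    frames = np.zeros((n_frames, rows, cols), dtype=np.float32)

    kernel = _paw_kernel(config.paw_sigma_cm, pitch)
    kr = kernel.shape[0] // 2
    w_n = gt.body_weight_kg * G

    for f in gt.footfalls:
        curve = generate_force_curve(f.peak_pct_bw, f.contact_time_s, fs, f.shape)
        force_n = curve.samples * w_n / 100.0
        r = int(round(f.y_cm / pitch))
        c = int(round(f.x_cm / pitch))
        r0, r1 = max(0, r - kr), min(rows, r + kr + 1)
        c0, c1 = max(0, c - kr), min(cols, c + kr + 1)
        kcrop = kernel[r0 - (r - kr): kernel.shape[0] - ((r + kr + 1) - r1),
                       c0 - (c - kr): kernel.shape[1] - ((c + kr + 1) - c1)]
        s = int(round(f.strike_time_s * fs))
        for i, val in enumerate(force_n):
            if 0 <= s + i < n_frames:
                frames[s + i, r0:r1, c0:c1] += val * kcrop

    if config.noise_sd > 0:
        noise = rng.standard_normal(size=frames.shape, dtype=np.float32)
        noise *= config.noise_sd
        np.clip(noise, 0.0, None, out=noise)
        frames += noise
    return PressureRecording(
        frames=frames,
        frame_rate_hz=fs,
        sensel_pitch_cm=pitch,
        calibration_range_psi=config.calibration_range_psi,
        meta={"body_weight_kg": gt.body_weight_kg, "operated_limb": gt.operated_limb},
    )


# ---------------------------------------------------------------------------
# public trial-level API
# ---------------------------------------------------------------------------

def simulate_walking_trial(
    config: SimConfig,
    cat: int,
    timepoint_h: float,
    seed: int,
    period: int = 1,
) -> tuple[PressureRecording, GroundTruth]:
    """One walking pass across the mat: rendered recording + ground truth."""
    rng = np.random.default_rng(seed)
    gt = _walking_ground_truth(config, cat, period, timepoint_h, rng)
    return render_recording(config, gt, rng), gt


def simulate_landing_trial(
    config: SimConfig,
    cat: int,
    timepoint_h: float,
    seed: int,
    period: int = 1,
) -> tuple[PressureRecording, GroundTruth]:
    """One jump-down landing onto the mat: rendered recording + ground truth."""
    rng = np.random.default_rng(seed)
    gt = _landing_ground_truth(config, cat, period, timepoint_h, rng)
    return render_recording(config, gt, rng), gt


@dataclass
class SimTrial:
    """A study trial: ground truth plus the seed needed to render it."""

    cat: int
    period: int
    timepoint_h: float
    trial_type: str  # "walk" | "land"
    index: int
    seed: int
    ground_truth: GroundTruth

    def render(self, config: SimConfig) -> PressureRecording:
        rng = np.random.default_rng(self.seed)
        if self.trial_type == "walk":
            _walking_ground_truth(config, self.cat, self.period, self.timepoint_h, rng)
        else:
            _landing_ground_truth(config, self.cat, self.period, self.timepoint_h, rng)
        # ground truth was regenerated to advance the rng to the noise state
        return render_recording(config, self.ground_truth, rng)


@dataclass
class PainSeries:
    """Ordinal pain scores for one cat in one period."""

    cat: int
    period: int
    treatment: str
    times_h: np.ndarray
    scores: np.ndarray
    baseline_times_h: np.ndarray
    baseline_scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=int)
        if self.scores.min(initial=0) < 0 or self.scores.max(initial=0) > 5:
            raise ValueError("pain scores must lie in 0..5")

    @property
    def baseline(self) -> float:
        return float(np.mean(self.baseline_scores))

    @property
    def rescue(self) -> bool:
        """Rescue analgesia is triggered by any score of 4 or more."""
        return bool((self.scores >= 4).any())


_PAIN_CUTPOINTS = np.array([0.5, 1.5, 2.5, 3.5, 4.5])


def simulate_pain_scores(
    config: SimConfig, cat: int, period: int, seed: int
) -> PainSeries:
    """Ordinal 0-5 scores from a latent decaying post-surgical intensity.

    The latent intensity ``A * exp(-t/tau)`` plus bounded uniform noise is
    thresholded at fixed cutpoints.  With the default amplitudes the
    latent never reaches the score-3 cutpoint, so no score exceeds 2.
    """
    rng = np.random.default_rng(seed)
    trt = config.treatment(cat, period)
    amp = config.pain_amplitude[trt]
    tau = config.pain_tau_h[trt] * config.pain_period_tau_mult.get(period, 1.0)
    w = config.pain_noise_half_width

    times = np.array(PAIN_TIMEPOINTS_H)
    latent = amp * np.exp(-times / tau)
    if w > 0:
        latent = latent + rng.uniform(-w, w, size=times.shape)
    scores = np.searchsorted(_PAIN_CUTPOINTS, latent, side="left")

    bl_times = np.array(BASELINE_TIMEPOINTS_H)
    bl_latent = rng.uniform(-w, w, size=bl_times.shape) if w > 0 else np.zeros_like(bl_times)
    bl_scores = np.searchsorted(_PAIN_CUTPOINTS, bl_latent, side="left")
    return PainSeries(
        cat=cat,
        period=period,
        treatment=trt,
        times_h=times,
        scores=scores,
        baseline_times_h=bl_times,
        baseline_scores=bl_scores,
    )


# ---------------------------------------------------------------------------
# whole-study simulation
# ---------------------------------------------------------------------------

@dataclass
class StudyDataset:
    """A complete simulated crossover study."""

    config: SimConfig
    trials: list[SimTrial]
    pain: list[PainSeries]

    def trial_table(self) -> pd.DataFrame:
        """Long-format per-trial kinetic table (one row per trial)."""
        rows = []
        for tr in self.trials:
            gt = tr.ground_truth
            op = gt.operated_limb
            no = "RF" if op == "LF" else "LF"
            rows.append(
                {
                    "cat": tr.cat,
                    "period": tr.period,
                    "treatment": self.config.treatment(tr.cat, tr.period),
                    "operated_limb": op,
                    "timepoint_h": tr.timepoint_h,
                    "trial_type": tr.trial_type,
                    "trial_index": tr.index,
                    "seed": tr.seed,
                    "velocity_mps": gt.velocity_mps,
                    "accel_mps2": gt.accel_mps2,
                    "valid": gt.valid,
                    "stalled": gt.stalled,
                    "op_pvf": gt.mean_peak(op),
                    "no_pvf": gt.mean_peak(no),
                    "op_vi": gt.mean_vi(op),
                    "no_vi": gt.mean_vi(no),
                    "tf1f2_s": gt.tf1f2_s,
                    "tf1f2_measurable": gt.tf1f2_measurable,
                    "tf1h1_s": gt.tf1h1_s,
                }
            )
        return pd.DataFrame(rows)

    def pain_table(self) -> pd.DataFrame:
        """Long-format pain observations, baselines included (t < 0)."""
        rows = []
        for ps in self.pain:
            for t, s in zip(ps.baseline_times_h, ps.baseline_scores):
                rows.append(
                    {"cat": ps.cat, "period": ps.period, "treatment": ps.treatment,
                     "time_h": float(t), "score": int(s), "is_baseline": True}
                )
            for t, s in zip(ps.times_h, ps.scores):
                rows.append(
                    {"cat": ps.cat, "period": ps.period, "treatment": ps.treatment,
                     "time_h": float(t), "score": int(s), "is_baseline": False}
                )
        return pd.DataFrame(rows)


def simulate_study(
    config: SimConfig | None = None,
    seed: int | None = None,
    n_walk: int = 10,
    n_land: int = 10,
) -> StudyDataset:
    """Simulate the full crossover study at ground-truth level.

    Per cat x period: two baseline sessions (-48, -24 h) and six post-op
    sessions (6..72 h), each with ``n_walk`` walking and ``n_land``
    landing trials, plus the ordinal pain-score series.  Recordings are
    rendered lazily via :meth:`SimTrial.render`.
    """
    config = config or SimConfig()
    if seed is None:
        seed = config.rng_seed
    sessions = list(BASELINE_TIMEPOINTS_H) + list(KINETIC_TIMEPOINTS_H)
    n_per_session = n_walk + n_land
    n_kinetic = config.n_cats * 2 * len(sessions) * n_per_session
    n_pain = config.n_cats * 2
    seeds = np.random.SeedSequence(seed).generate_state(n_kinetic + n_pain)

    trials: list[SimTrial] = []
    i = 0
    for cat in range(1, config.n_cats + 1):
        for period in (1, 2):
            for tp in sessions:
                for j in range(n_walk):
                    s = int(seeds[i]); i += 1
                    gt = _walking_ground_truth(
                        config, cat, period, tp, np.random.default_rng(s)
                    )
                    trials.append(SimTrial(cat, period, tp, "walk", j, s, gt))
                for j in range(n_land):
                    s = int(seeds[i]); i += 1
                    gt = _landing_ground_truth(
                        config, cat, period, tp, np.random.default_rng(s)
                    )
                    trials.append(SimTrial(cat, period, tp, "land", j, s, gt))

    pain = []
    for cat in range(1, config.n_cats + 1):
        for period in (1, 2):
            s = int(seeds[i]); i += 1
            pain.append(simulate_pain_scores(config, cat, period, s))
    return StudyDataset(config=config, trials=trials, pain=pain)


def null_config(**overrides) -> SimConfig:
    """Study conditions with no treatment effect (both arms identical).

    Used for statistical calibration: the lameness profile and pain
    parameters of the control arm are copied to the treated arm.
    """
    cfg = SimConfig(**overrides)
    return replace(
        cfg,
        lameness_factor={
            "control": dict(cfg.lameness_factor["control"]),
            "er_bup": dict(cfg.lameness_factor["control"]),
        },
        pain_amplitude={"control": cfg.pain_amplitude["control"],
                        "er_bup": cfg.pain_amplitude["control"]},
        pain_tau_h={"control": cfg.pain_tau_h["control"],
                    "er_bup": cfg.pain_tau_h["control"]},
    )
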