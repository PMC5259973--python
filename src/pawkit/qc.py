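"""Trial validity and trial-selection rules.

Walking passes are valid when the run velocity is within ±0.2 m/s of the
0.6 m/s target, acceleration changes stay within ±0.1 m/s², and the path
is straight; per session the five valid trials closest to the target are
analysed.  Landing trials are valid when the cat lands forelimbs first
travelling forward.  The velocity target is configurable per cat
("comfortable-speed" mode replaces the fixed target with the cat's own
median) because cats routinely self-select faster speeds than the
nominal target.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .recording import FORELIMBS, Footfall

__all__ = [
    "TrialQC",
    "compute_velocity_profile",
    "validate_walking_trial",
    "validate_landing_trial",
    "select_best_trials",
]

DEFAULT_TARGET_VELOCITY = 0.6
DEFAULT_VELOCITY_TOL = 0.2
DEFAULT_ACCEL_TOL = 0.1
DEFAULT_STRAIGHTNESS_TOL_CM = 10.0


@dataclass
class TrialQC:
    velocity_mps: float | None
    acceleration_mps2: float | None
    straightness_cm: float | None
    valid: bool
    reasons: list[str] = field(default_factory=list)
    warning: str | None = None

    def __post_init__(self) -> None:
        if self.valid and self.reasons:
            raise ValueError("a valid trial cannot carry failure reasons")


def compute_velocity_profile(
    footfalls: list[Footfall],
) -> tuple[float, float] | tuple[None, None]:
    """Run velocity and acceleration from footfall positions over time.

    Velocity is the least-squares slope of strike x-position versus
    strike time across all footfalls; acceleration is the change between
    the velocities of the first and second halves of the run, divided by
    the time between the half midpoints.  Returns ``(None, None)`` when
    fewer than 3 footfalls are available.
    """
    if len(footfalls) < 3:
        return None, None
    pts = sorted((f.strike_time, f.position[0] / 100.0) for f in footfalls)
    t = np.array([p[0] for p in pts])
    x = np.array([p[1] for p in pts])
    if t[-1] - t[0] <= 0:
        return None, None
    v = float(np.polyfit(t, x, 1)[0])

    # segment velocities between consecutive points, then their trend
    dv = np.diff(x) / np.diff(t)
    tm = 0.5 * (t[1:] + t[:-1])
    if len(dv) >= 2 and tm[-1] > tm[0]:
        a = float(np.polyfit(tm, dv, 1)[0])
    else:
        a = 0.0
    return v, a


def _straightness(footfalls: list[Footfall]) -> float:
    """Maximum lateral deviation (cm) of the body path from a straight line.

    The body path is approximated by midpoints of laterally opposite
    consecutive footfall pairs.
    """
    ys = np.array([f.position[1] for f in footfalls])
    if len(ys) < 4:
        return 0.0
    center = ys.mean()
    side = ys >= center
    mids = []
    for i in range(len(ys) - 1):
        if side[i] != side[i + 1]:
            mids.append(0.5 * (ys[i] + ys[i + 1]))
    if len(mids) < 2:
        return 0.0
    mids = np.asarray(mids)
    return float(np.max(np.abs(mids - np.median(mids))))


def validate_walking_trial(
    trial,
    target: float = DEFAULT_TARGET_VELOCITY,
    vel_tol: float = DEFAULT_VELOCITY_TOL,
    acc_tol: float = DEFAULT_ACCEL_TOL,
    straightness_tol_cm: float = DEFAULT_STRAIGHTNESS_TOL_CM,
) -> TrialQC:
    """Apply the walking validity rules.

    ``trial`` may be a list of footfalls (velocity is computed from
    them), or any object with ``velocity_mps`` / ``accel_mps2``
    attributes (e.g. a simulated trial's ground truth or a trial-table
    row).
    """
    straightness = None
    if isinstance(trial, (list, tuple)):
        v, a = compute_velocity_profile(list(trial))
        straightness = _straightness(list(trial)) if trial else None
    else:
        v = getattr(trial, "velocity_mps", None)
        a = getattr(trial, "accel_mps2", None)

    reasons = []
    if v is None:
        reasons.append("velocity undefined (fewer than 3 footfalls)")
    else:
        if abs(v - target) > vel_tol:
            reasons.append("velocity")
        if a is not None and abs(a) > acc_tol:
            reasons.append("acceleration")
    if straightness is not None and straightness > straightness_tol_cm:
        reasons.append("straightness")
    return TrialQC(
        velocity_mps=v,
        acceleration_mps2=a,
        straightness_cm=straightness,
        valid=not reasons,
        reasons=reasons,
    )


def validate_landing_trial(trial) -> TrialQC:
    """A landing is valid when forelimbs strike first, travelling forward.

    ``trial`` is a list of classified footfalls.  If only forelimbs hit
    the mat the trial remains valid for forelimb metrics but the
    fore-hind delay is undefined (flagged via ``warning``).
    """
    footfalls = list(trial)
    if not footfalls:
        return TrialQC(None, None, None, False, ["no footfalls"])
    fore = [f for f in footfalls if f.limb in FORELIMBS]
    hind = [f for f in footfalls if f.limb and f.limb not in FORELIMBS]
    reasons = []
    if not fore:
        reasons.append("no forelimb strike")
    elif hind and min(h.strike_time for h in hind) < min(f.strike_time for f in fore):
        reasons.append("hindlimb struck first")
    if fore and hind:
        fx = np.mean([f.position[0] for f in fore])
        hx = np.mean([h.position[0] for h in hind])
        if hx > fx:  # facing back toward the platform
            reasons.append("not travelling forward")
    qc = TrialQC(None, None, None, valid=not reasons, reasons=reasons)
    if qc.valid and not hind:
        qc.warning = "no hindlimb strike: fore-hind delay undefined"
    return qc


def select_best_trials(
    valid_trials: list,
    k: int = 5,
    target_velocity: float = DEFAULT_TARGET_VELOCITY,
    velocity_of=None,
    accel_of=None,
) -> tuple[list, str | None]:
    """Pick the ``k`` valid trials closest to the target velocity.

    Ties are broken by smaller absolute acceleration, then by original
    trial order, making the selection deterministic and invariant to
    input permutation.  If fewer than ``k`` trials are available all are
    returned along with a warning.
    """
    velocity_of = velocity_of or (lambda t: t.velocity_mps)
    accel_of = accel_of or (lambda t: getattr(t, "accel_mps2", 0.0) or 0.0)
    indexed = list(enumerate(valid_trials))
    indexed.sort(
        key=lambda it: (
            abs(velocity_of(it[1]) - target_velocity),
            abs(accel_of(it[1])),
            it[0],
        )
    )
    if len(indexed) < k:
        return [t for _, t in indexed], (
            f"only {len(indexed)} valid trials available (requested {k})"
        )
    return [t for _, t in indexed[:k]], None
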