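"""Footfall detection and kinetic extraction from pressure recordings.

Replaces the proprietary walkway software: finds spatiotemporally
connected suprathreshold regions of the sensel grid, labels them as limb
contacts, and computes body-weight-normalised peak vertical force (PVF,
%BW) and vertical impulse (VI, %BW·s) per footfall.

Conventions (documented rather than inherited from any vendor tool):

* a contact event is an 8-connected suprathreshold region in space whose
  footprint overlaps (within one sensel) across consecutive frames;
* events whose time-overlapping centroids are closer than 2 cm are merged
  (pads of a single paw);
* strike time is the first suprathreshold frame, lift time the end of the
  last one — no sub-frame interpolation, so contact times are integer
  multiples of the frame period;
* walking limbs are labelled left/right of the path axis and fore/hind
  from stride registration (a hind paw lands on the same-side fore
  print); on landings the earliest two strikes are the forelimbs.
"""

from __future__ import annotations

import numpy as np
from skimage import measure

from .recording import G, Footfall, PressureRecording

__all__ = ["detect_contacts", "classify_limbs", "extract_kinetics", "extract_trial"]

#: spatial merge distance for pads of one paw, cm
MERGE_DISTANCE_CM = 2.0
#: registration window for hind-on-fore print matching, cm
REGISTER_WINDOW_CM = 6.0


def _default_threshold(frames: np.ndarray) -> float:
    """2x the per-sensel noise SD, estimated from the quiet grid.

    Footprints occupy well under 1% of sensel-frames, so a high quantile
    of all values is dominated by sensor noise (clipped at zero by the
    hardware); the 99th percentile of such noise sits near 2 SD.
    """
    if frames.size == 0:
        return 1e-6
    flat = frames.ravel()
    sample = flat[:: max(1, flat.size // 500_000)]  # noise stats need no full sort
    q99 = float(np.quantile(sample, 0.99))
    peak = float(frames.max())
    return max(q99, 0.005 * peak, 1e-6)


def detect_contacts(
    recording: PressureRecording,
    force_threshold: float | None = None,
    min_frames: int = 3,
    min_peak_force: float | None = None,
) -> list[Footfall]:
    """Find limb-contact events as connected suprathreshold regions.

    Returns unlabelled :class:`Footfall` objects (``limb=None``) ordered
    by strike time; events spanning fewer than ``min_frames`` frames, or
    whose peak summed force stays below ``min_peak_force`` (default 4x
    the detection threshold — rejects persistent noise specks), are
    discarded.  An empty or all-quiet recording yields an empty list.
    """
    if force_threshold is not None and force_threshold <= 0:
        raise ValueError("force_threshold must be positive")
    if min_frames < 2:
        raise ValueError("min_frames must be >= 2")
    frames = recording.frames
    if frames.size == 0:
        return []
    thr = force_threshold if force_threshold is not None else _default_threshold(frames)
    if min_peak_force is None:
        min_peak_force = 4.0 * thr

    # 26-connectivity in (t, row, col): 8-neighbourhood in space plus
    # footprint overlap (within one sensel) across consecutive frames
    labels = measure.label(frames > thr, connectivity=3)
    if labels.max() == 0:
        return []

    coords = np.nonzero(labels)
    lab = labels[coords]
    # a paw contact activates many sensels over many frames; small voxel
    # chains are persistent noise specks — drop them before grouping
    counts = np.bincount(lab)
    keep = counts >= 5 * min_frames
    sel = keep[lab]
    lab = lab[sel]
    if lab.size == 0:
        return []
    force = frames[coords][sel]
    t_idx, r_idx, c_idx = (a[sel].astype(np.int64) for a in coords)

    pitch = recording.sensel_pitch_cm
    fs = recording.frame_rate_hz

    # group voxels by label in one sort
    order = np.argsort(lab, kind="stable")
    lab_s = lab[order]
    starts = np.concatenate([[0], np.nonzero(np.diff(lab_s))[0] + 1, [lab_s.size]])
    events = []
    for a, b in zip(starts[:-1], starts[1:]):
        idx = order[a:b]
        t = t_idx[idx]
        if int(t.max()) - int(t.min()) + 1 < min_frames:
            continue
        events.append({"t": t, "r": r_idx[idx], "c": c_idx[idx], "f": force[idx]})

    events = _merge_close(events, pitch)

    # expected background level per sensel (zero-clipped sensor noise);
    # subtracted from footprint sums so quiet sensels contribute nothing
    # on average
    quiet = frames[frames <= thr]
    bg_mean = float(quiet.mean()) if quiet.size else 0.0

    out = []
    for ev in events:
        ff = _quantify_event(
            ev, frames, thr, bg_mean, pitch, fs, min_frames, min_peak_force
        )
        if ff is not None:
            out.append(ff)
    out.sort(key=lambda e: (e.strike_time, e.position[0]))
    return out


#: footprint dilation (sensels) when summing event force; captures the
#: sub-threshold tails of a paw's pressure distribution
FOOTPRINT_DILATION = 2
#: onset criterion: contact starts/ends where the curve reaches this
#: fraction of its peak (also at least the detection threshold)
ONSET_FRACTION = 0.05


def _quantify_event(
    ev: dict,
    frames: np.ndarray,
    thr: float,
    bg_mean: float,
    pitch: float,
    fs: float,
    min_frames: int,
    min_peak_force: float,
) -> Footfall | None:
    """Force curve and centroid path of one detected event.

    Force per frame is summed over the event's spatial footprint (union
    of suprathreshold sensels, dilated) with the expected background
    level subtracted, so the tails of the pressure blob are captured
    without a noise bias.
    """
    t, r, c = ev["t"], ev["r"], ev["c"]
    t0, t1 = int(t.min()), int(t.max())
    rows, cols = frames.shape[1:]
    rmin = max(0, int(r.min()) - FOOTPRINT_DILATION)
    rmax = min(rows, int(r.max()) + FOOTPRINT_DILATION + 1)
    cmin = max(0, int(c.min()) - FOOTPRINT_DILATION)
    cmax = min(cols, int(c.max()) + FOOTPRINT_DILATION + 1)
    mask = np.zeros((rmax - rmin, cmax - cmin), dtype=bool)
    mask[r - rmin, c - cmin] = True
    from scipy import ndimage

    mask = ndimage.binary_dilation(mask, iterations=FOOTPRINT_DILATION)
    n_fp = int(mask.sum())

    block = frames[t0: t1 + 1, rmin:rmax, cmin:cmax]
    # background subtraction is NOT re-clipped: quiet sensels then
    # contribute zero on average instead of a positive bias
    sig = np.where(mask[None, :, :], block - bg_mean, 0.0)
    curve = sig.sum(axis=(1, 2))
    peak = curve.max()
    if peak < min_peak_force:
        return None

    # trim frames below the onset criterion at both ends
    onset = max(ONSET_FRACTION * peak, thr)
    above = np.nonzero(curve >= onset)[0]
    if above.size == 0 or above[-1] - above[0] + 1 < min_frames:
        return None
    a, b = int(above[0]), int(above[-1])
    curve = curve[a: b + 1]

    rr = np.arange(rmin, rmax, dtype=float)[None, :, None]
    cc = np.arange(cmin, cmax, dtype=float)[None, None, :]
    w = np.maximum(sig[a: b + 1], 0.0)
    tot = w.sum(axis=(1, 2))
    cx = (w * cc).sum(axis=(1, 2)) / tot * pitch
    cy = (w * rr).sum(axis=(1, 2)) / tot * pitch

    # pad one silent frame each side so the trapezoidal impulse includes
    # the rise from and fall to zero
    curve = np.concatenate([[0.0], curve, [0.0]])
    path = np.column_stack(
        [np.concatenate([[cx[0]], cx, [cx[-1]]]),
         np.concatenate([[cy[0]], cy, [cy[-1]]])]
    )
    return Footfall(
        limb=None,
        strike_time=(t0 + a) / fs,
        lift_time=(t0 + b + 1) / fs,
        curve=curve,
        centroid_path=path,
        frame_rate_hz=fs,
    )


def _merge_close(events: list[dict], pitch_cm: float) -> list[dict]:
    """Union events that overlap in time with centroids closer than 2 cm."""
    def summary(ev):
        w = ev["f"].sum()
        return (
            ev["t"].min(), ev["t"].max(),
            (ev["f"] * ev["c"]).sum() / w * pitch_cm,
            (ev["f"] * ev["r"]).sum() / w * pitch_cm,
        )

    merged = True
    while merged and len(events) > 1:
        merged = False
        sums = [summary(e) for e in events]
        for i in range(len(events)):
            for j in range(i + 1, len(events)):
                t0i, t1i, xi, yi = sums[i]
                t0j, t1j, xj, yj = sums[j]
                if t0j <= t1i and t0i <= t1j:
                    if np.hypot(xi - xj, yi - yj) < MERGE_DISTANCE_CM:
                        events[i] = {
                            k: np.concatenate([events[i][k], events[j][k]])
                            for k in ("t", "r", "c", "f")
                        }
                        del events[j]
                        merged = True
                        break
            if merged:
                break
    return events


def classify_limbs(
    footfalls: list[Footfall],
    trial_type: str,
    direction_of_travel: str = "+x",
) -> list[Footfall]:
    """Assign limb labels (LF/RF/LH/RH) to detected contact events.

    Walking: left/right from the lateral offset relative to the path
    axis; an event is a hindlimb if an earlier same-side event printed
    within the registration window (hind paws land on fore prints).
    Landing: the earliest two strikes are forelimbs, later ones
    hindlimbs.  Events with lateral separation below one sensel pitch are
    flagged ``unclassified``.
    """
    if not footfalls:
        raise ValueError("no contact events to classify")
    if trial_type not in ("walk", "land"):
        raise ValueError(f"unknown trial_type {trial_type!r}")
    pitch = 0.5
    xs = np.array([f.position[0] for f in footfalls])
    ys = np.array([f.position[1] for f in footfalls])
    if direction_of_travel == "-x":
        xs = -xs
    order = np.argsort([f.strike_time for f in footfalls], kind="stable")

    if trial_type == "land":
        fore_set = set(order[:2])
        ref_groups = [list(order[:2]), list(order[2:])]
        for group, (fore, hind) in zip(ref_groups, [("LF", "RF"), ("LH", "RH")]):
            if not group:
                continue
            gy = ys[group]
            center = gy.mean()
            for idx, y in zip(group, gy):
                side = "L" if y >= center else "R"
                tier = "F" if idx in fore_set else "H"
                footfalls[idx].limb = side + tier
                if len(group) > 1 and abs(y - center) < pitch / 2:
                    footfalls[idx].unclassified = True
        return footfalls

    center = ys.mean()
    last_prints: dict[str, list[float]] = {"L": [], "R": []}
    for idx in order:
        y = ys[idx]
        side = "L" if y >= center else "R"
        if abs(y - center) < pitch:
            footfalls[idx].unclassified = True
        x = xs[idx]
        is_hind = any(abs(x - px) < REGISTER_WINDOW_CM for px in last_prints[side])
        footfalls[idx].limb = side + ("H" if is_hind else "F")
        if not is_hind:
            last_prints[side].append(x)
    return footfalls


def extract_kinetics(footfall: Footfall, body_weight_kg: float) -> Footfall:
    """Fill %BW-normalised PVF, VI and contact time on a footfall.

    PVF = 100 * max(curve) / weight; VI = 100 * trapz(curve) / weight on
    the frame grid.  Forces in the curve are newtons.
    """
    if body_weight_kg <= 0:
        raise ValueError("body weight must be positive")
    curve = np.asarray(footfall.curve, dtype=float)
    if curve.size == 0:
        raise ValueError("footfall has an empty force curve")
    w = body_weight_kg * G
    footfall.pvf_pct_bw = float(100.0 * curve.max() / w)
    footfall.vi_pct_bw_s = float(
        100.0 * np.trapezoid(curve, dx=1.0 / footfall.frame_rate_hz) / w
    )
    return footfall


def extract_trial(
    recording: PressureRecording,
    body_weight_kg: float,
    trial_type: str,
    force_threshold: float | None = None,
    min_frames: int = 3,
) -> list[Footfall]:
    """Detect, classify and normalise all footfalls of one trial."""
    events = detect_contacts(recording, force_threshold, min_frames)
    if not events:
        return []
    classify_limbs(events, trial_type)
    return [extract_kinetics(f, body_weight_kg) for f in events]
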