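"""Core data containers for pressure-sensitive walkway (PSW) recordings.

A PSW is an instrumented mat that samples vertical force on a grid of
pressure-sensing elements ("sensels") at a fixed frame rate.  The
conventions used throughout the package:

* frames are indexed ``frames[t, row, col]`` with force in newtons per
  sensel;
* the travel axis (``x``) runs along columns, the lateral axis (``y``)
  along rows; the origin is the mat corner at ``(row 0, col 0)``;
* positions are reported in centimetres, times in seconds, frame indices
  are 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: standard gravity, used to convert body mass to weight for %BW scaling
G = 9.80665

LIMBS = ("LF", "RF", "LH", "RH")
FORELIMBS = ("LF", "RF")
HINDLIMBS = ("LH", "RH")


class SchemaError(ValueError):
    """A recording container is missing or has an invalid attribute."""


@dataclass
class PressureRecording:
    """Time-ordered stack of calibrated force grids.

    Parameters
    ----------
    frames : ndarray, shape (n_frames, n_rows, n_cols)
        Vertical force per sensel, newtons.  Must be non-negative.
    frame_rate_hz : float
        Acquisition rate; 60 Hz is the hardware maximum used here.
    sensel_pitch_cm : float
        Centre-to-centre sensel spacing; 0.5 cm at 4 sensels/cm².
    calibration_range_psi : float
        Calibrated sensor range of the mat.
    """

    frames: np.ndarray
    frame_rate_hz: float = 60.0
    sensel_pitch_cm: float = 0.5
    calibration_range_psi: float = 50.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise SchemaError(
                f"frames must be 3-D (t, row, col); got ndim={self.frames.ndim}"
            )
        if not self.frame_rate_hz > 0:
            raise SchemaError(f"frame_rate_hz must be > 0; got {self.frame_rate_hz}")
        if not self.sensel_pitch_cm > 0:
            raise SchemaError(
                f"sensel_pitch_cm must be > 0; got {self.sensel_pitch_cm}"
            )
        if self.frames.size and float(self.frames.min()) < 0:
            raise SchemaError("frames contain negative forces")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    @property
    def dt(self) -> float:
        """Frame period in seconds (0.0167 s at 60 Hz)."""
        return 1.0 / self.frame_rate_hz

    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate_hz

    def total_force(self) -> np.ndarray:
        """Summed mat force per frame (newtons)."""
        return self.frames.sum(axis=(1, 2))


@dataclass
class Footfall:
    """One limb-contact event on the mat.

    ``curve`` is the per-frame total force of the footprint (newtons);
    ``pvf_pct_bw`` / ``vi_pct_bw_s`` are filled by
    :func:`pawkit.extraction.extract_kinetics` once a body weight is known.
    Strike time is the time of the first suprathreshold frame; lift time is
    the end of the last suprathreshold frame, so ``contact_time`` is an
    integer multiple of the frame period.
    """

    limb: str | None
    strike_time: float
    lift_time: float
    curve: np.ndarray
    centroid_path: np.ndarray  # (n_frames_in_event, 2) -> (x_cm, y_cm)
    frame_rate_hz: float = 60.0
    role: str | None = None  # operated / non_operated / hind
    pvf_pct_bw: float | None = None
    vi_pct_bw_s: float | None = None
    unclassified: bool = False

    def __post_init__(self) -> None:
        if self.lift_time <= self.strike_time:
            raise ValueError("lift_time must exceed strike_time")

    @property
    def contact_time(self) -> float:
        return self.lift_time - self.strike_time

    @property
    def position(self) -> tuple[float, float]:
        """Force-weighted mean footprint position (x_cm, y_cm)."""
        w = np.maximum(self.curve, 1e-12)
        xy = (self.centroid_path * w[:, None]).sum(axis=0) / w.sum()
        return float(xy[0]), float(xy[1])

    @property
    def is_forelimb(self) -> bool | None:
        if self.limb is None:
            return None
        return self.limb in FORELIMBS
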