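"""Recording container and configuration I/O.

Recordings are stored as HDF5: dataset ``frames[t, row, col]`` (newtons)
with attributes ``frame_rate_hz``, ``sensel_pitch_cm`` and
``calibration_range_psi``; ground truth travels in a JSON sidecar.  A
legacy CSV-per-frame directory layout can be imported.  Pipeline
configuration round-trips losslessly through YAML.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import yaml

from .recording import PressureRecording, SchemaError
from .simulate import GroundTruth, GroundTruthFootfall, SimConfig

__all__ = [
    "write_recording",
    "read_recording",
    "write_ground_truth",
    "read_ground_truth",
    "import_frames_csv",
    "export_frames_csv",
    "PipelineConfig",
    "load_config",
    "save_config",
]

_REQUIRED_ATTRS = ("frame_rate_hz", "sensel_pitch_cm", "calibration_range_psi")


def write_recording(recording: PressureRecording, path) -> None:
    with h5py.File(path, "w") as h5:
        h5.create_dataset("frames", data=recording.frames, compression="gzip")
        h5.attrs["frame_rate_hz"] = recording.frame_rate_hz
        h5.attrs["sensel_pitch_cm"] = recording.sensel_pitch_cm
        h5.attrs["calibration_range_psi"] = recording.calibration_range_psi
        if recording.meta:
            h5.attrs["meta_json"] = json.dumps(recording.meta, sort_keys=True)


def read_recording(path) -> PressureRecording:
    with h5py.File(path, "r") as h5:
        if "frames" not in h5:
            raise SchemaError("recording file has no 'frames' dataset")
        for name in _REQUIRED_ATTRS:
            if name not in h5.attrs:
                raise SchemaError(f"recording file missing attribute {name!r}")
        meta = {}
        if "meta_json" in h5.attrs:
            meta = json.loads(h5.attrs["meta_json"])
        return PressureRecording(
            frames=h5["frames"][...],
            frame_rate_hz=float(h5.attrs["frame_rate_hz"]),
            sensel_pitch_cm=float(h5.attrs["sensel_pitch_cm"]),
            calibration_range_psi=float(h5.attrs["calibration_range_psi"]),
            meta=meta,
        )


def write_ground_truth(gt: GroundTruth, path) -> None:
    doc = {
        "body_weight_kg": gt.body_weight_kg,
        "operated_limb": gt.operated_limb,
        "velocity_mps": gt.velocity_mps,
        "accel_mps2": gt.accel_mps2,
        "valid": gt.valid,
        "tf1f2_s": gt.tf1f2_s,
        "tf1f2_measurable": gt.tf1f2_measurable,
        "tf1h1_s": gt.tf1h1_s,
        "footfalls": gt.to_records(),
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))


def read_ground_truth(path) -> GroundTruth:
    doc = json.loads(Path(path).read_text())
    feet = [
        GroundTruthFootfall(
            limb=f["limb"],
            strike_time_s=f["strike_time_s"],
            contact_time_s=f["contact_time_s"],
            peak_pct_bw=f["peak_pct_bw"],
            vi_pct_bw_s=f["vi_pct_bw_s"],
            x_cm=f["x_cm"],
            y_cm=f["y_cm"],
            shape=f.get("shape", "half_sine"),
        )
        for f in doc["footfalls"]
    ]
    return GroundTruth(
        footfalls=feet,
        body_weight_kg=doc["body_weight_kg"],
        operated_limb=doc["operated_limb"],
        velocity_mps=doc.get("velocity_mps"),
        accel_mps2=doc.get("accel_mps2"),
        valid=doc.get("valid"),
        tf1f2_s=doc.get("tf1f2_s"),
        tf1f2_measurable=doc.get("tf1f2_measurable"),
        tf1h1_s=doc.get("tf1h1_s"),
    )


def export_frames_csv(recording: PressureRecording, directory) -> None:
    """Write the legacy CSV-per-frame layout (one CSV per frame + meta.yaml)."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    for i, frame in enumerate(recording.frames):
        np.savetxt(d / f"frame_{i:05d}.csv", frame, delimiter=",", fmt="%.6g")
    meta = {
        "frame_rate_hz": float(recording.frame_rate_hz),
        "sensel_pitch_cm": float(recording.sensel_pitch_cm),
        "calibration_range_psi": float(recording.calibration_range_psi),
    }
    (d / "meta.yaml").write_text(yaml.safe_dump(meta))


def import_frames_csv(directory) -> PressureRecording:
    """Read the legacy CSV-per-frame layout into a recording."""
    d = Path(directory)
    meta_path = d / "meta.yaml"
    if not meta_path.exists():
        raise SchemaError("legacy directory missing meta.yaml")
    meta = yaml.safe_load(meta_path.read_text())
    for name in _REQUIRED_ATTRS:
        if name not in meta:
            raise SchemaError(f"legacy meta.yaml missing attribute {name!r}")
    files = sorted(d.glob("frame_*.csv"))
    if not files:
        raise SchemaError("legacy directory holds no frame CSVs")
    frames = np.stack([np.loadtxt(f, delimiter=",", ndmin=2) for f in files])
    return PressureRecording(
        frames=frames,
        frame_rate_hz=float(meta["frame_rate_hz"]),
        sensel_pitch_cm=float(meta["sensel_pitch_cm"]),
        calibration_range_psi=float(meta["calibration_range_psi"]),
    )


# ---------------------------------------------------------------------------
# pipeline configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Everything the end-to-end driver needs, YAML round-trippable."""

    seed: int = 0
    out_dir: str = "pawkit_run"
    n_walk: int = 10
    n_land: int = 10
    extraction_mode: str = "ground_truth"  # or "render" (full frame decoding)
    qc_target_velocity: float = 0.6
    qc_velocity_tol: float = 0.2
    qc_accel_tol: float = 0.1
    qc_mode: str = "fixed"  # or "comfortable": per-cat median replaces target
    k_best: int = 5
    alpha: float = 0.05
    ordinal_method: str = "gee"
    landing_responses: tuple[str, ...] = (
        "op_pvf", "no_pvf", "op_vi", "no_vi", "si_pvf", "si_vi", "tf1f2", "tf1h1"
    )
    walking_responses: tuple[str, ...] = ("si_pvf", "si_vi")
    sim: dict = field(default_factory=dict)  # SimConfig field overrides

    def sim_config(self) -> SimConfig:
        kwargs = dict(self.sim)
        if "sequence_allocation" in kwargs:
            kwargs["sequence_allocation"] = {
                int(c): {int(p): tuple(v) for p, v in per.items()}
                for c, per in kwargs["sequence_allocation"].items()
            }
        if "lameness_factor" in kwargs:
            kwargs["lameness_factor"] = {
                t: {float(k): float(v) for k, v in m.items()}
                for t, m in kwargs["lameness_factor"].items()
            }
        for key in ("body_weight_kg", "mat_size_m"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        kwargs.setdefault("rng_seed", self.seed)
        return SimConfig(**kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["landing_responses"] = list(self.landing_responses)
        d["walking_responses"] = list(self.walking_responses)
        return d


def save_config(config: PipelineConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))


def load_config(path) -> PipelineConfig:
    doc = yaml.safe_load(Path(path).read_text())
    for key in ("landing_responses", "walking_responses"):
        if key in doc:
            doc[key] = tuple(doc[key])
    return PipelineConfig(**doc)
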