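"""File formats: CSV flow/belt signals, NIfTI velocity maps, JSON results.

CSV columns are fixed (``time_s, flow_ml_min`` and ``time_s, belt_au``);
velocity series travel as NIfTI-1 volumes of shape X x Y x 1 x T (float32,
cm/s) with a JSON sidecar carrying VENC, pixel spacing, frame interval and
the positive flow direction. All numeric payloads round-trip losslessly at
the precision they are written.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .breathing import BreathingSignal, PhaseSweepResult
from .cycles import CycleParameters, FlowSeries, ReconstructedQt
from .image import SegmentationMask, VelocityMapSeries
from .synthetic import ImageRenderConfig, SimulationConfig, SyntheticTruth

POSITIVE_DIRECTION = "caudocranial"


# ---------------------------------------------------------------------------
# CSV signals
# ---------------------------------------------------------------------------

def write_flow_csv(flow: FlowSeries, path) -> None:
    pd.DataFrame({"time_s": flow.time, "flow_ml_min": flow.flow}).to_csv(
        path, index=False)


def read_flow_csv(path) -> FlowSeries:
    df = pd.read_csv(path)
    for col in ("time_s", "flow_ml_min"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    return FlowSeries(df["time_s"].to_numpy(), df["flow_ml_min"].to_numpy())


def write_belt_csv(belt: BreathingSignal, path) -> None:
    pd.DataFrame({"time_s": belt.time, "belt_au": belt.amplitude}).to_csv(
        path, index=False)


def read_belt_csv(path) -> BreathingSignal:
    df = pd.read_csv(path)
    for col in ("time_s", "belt_au"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    return BreathingSignal(df["time_s"].to_numpy(), df["belt_au"].to_numpy())


def write_qt_csv(qt: ReconstructedQt, path) -> None:
    pd.DataFrame({"phase_index": np.arange(qt.values.size),
                  "flow_ml_min": qt.values}).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# NIfTI velocity maps + JSON sidecar
# ---------------------------------------------------------------------------

def write_velocity_nifti(series: VelocityMapSeries, image_path, sidecar_path) -> None:
    """Write a velocity series as X x Y x 1 x T float32 + JSON sidecar."""
    # internal frames are T x H x W; NIfTI wants spatial-first
    data = np.transpose(series.frames, (1, 2, 0))[:, :, np.newaxis, :]
    affine = np.diag([series.pixel_spacing, series.pixel_spacing, 1.0, 1.0])
    img = nib.Nifti1Image(data.astype(np.float32), affine)
    img.header.set_zooms((series.pixel_spacing, series.pixel_spacing, 1.0,
                          series.frame_interval))
    nib.save(img, str(image_path))
    sidecar = {
        "venc_cm_s": series.venc,
        "pixel_spacing_mm": series.pixel_spacing,
        "frame_interval_s": series.frame_interval,
        "positive_direction": POSITIVE_DIRECTION,
    }
    Path(sidecar_path).write_text(json.dumps(sidecar, indent=2))


def read_velocity_nifti(image_path, sidecar_path) -> VelocityMapSeries:
    meta = json.loads(Path(sidecar_path).read_text())
    for key in ("venc_cm_s", "pixel_spacing_mm", "frame_interval_s"):
        if key not in meta:
            raise ValueError(f"{sidecar_path}: sidecar missing required field {key!r}")
    data = np.asanyarray(nib.load(str(image_path)).dataobj, dtype=np.float64)
    if data.ndim != 4 or data.shape[2] != 1:
        raise ValueError(f"{image_path}: expected an X x Y x 1 x T volume, "
                         f"got shape {data.shape}")
    frames = np.transpose(data[:, :, 0, :], (2, 0, 1))
    return VelocityMapSeries(frames, float(meta["pixel_spacing_mm"]),
                             float(meta["frame_interval_s"]),
                             float(meta["venc_cm_s"]))


def write_mask_nifti(mask: SegmentationMask, path) -> None:
    affine = np.diag([mask.pixel_spacing, mask.pixel_spacing, 1.0, 1.0])
    nib.save(nib.Nifti1Image(mask.mask.astype(np.uint8), affine), str(path))


# ---------------------------------------------------------------------------
# JSON results and YAML configuration
# ---------------------------------------------------------------------------

def write_json(payload: dict, path) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, default=_to_jsonable))


def _to_jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def write_truth_json(truth: SyntheticTruth, path) -> None:
    write_json(truth.as_dict(), path)


def write_parameters_json(params: CycleParameters, path) -> None:
    write_json(params.as_dict(), path)


def write_sweep_json(result: PhaseSweepResult, path) -> None:
    payload = result.as_dict()
    payload["sign_convention"] = "delta = inspiration - expiration"
    write_json(payload, path)


def load_simulation_yaml(path) -> tuple[SimulationConfig, ImageRenderConfig | None]:
    """Build simulation (and optional rendering) configs from a YAML file.

    Top-level keys map onto :class:`SimulationConfig` fields; an optional
    ``render:`` section maps onto :class:`ImageRenderConfig`. Unknown keys
    are rejected so typos fail loudly.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: top level must be a mapping")
    render_raw = raw.pop("render", None)
    sim_fields = set(SimulationConfig.__dataclass_fields__)
    unknown = set(raw) - sim_fields
    if unknown:
        raise ValueError(f"{path}: unknown simulation keys {sorted(unknown)}")
    if "roi_pixels" in (render_raw or {}):
        render_raw["roi_pixels"] = tuple(tuple(p) for p in render_raw["roi_pixels"])
    if "grid_size" in (render_raw or {}):
        render_raw["grid_size"] = tuple(render_raw["grid_size"])
    sim = SimulationConfig(**raw)
    render = None
    if render_raw is not None:
        unknown = set(render_raw) - set(ImageRenderConfig.__dataclass_fields__)
        if unknown:
            raise ValueError(f"{path}: unknown render keys {sorted(unknown)}")
        render = ImageRenderConfig(**render_raw)
    return sim, render
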