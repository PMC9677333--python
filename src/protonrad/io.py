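"""File formats: TIFF images with JSON sidecars, CSV landmark/ROI tables.

Raw frame stacks are stored as multi-page 16-bit TIFF, corrected
radiographs as 32-bit float TIFF; acquisition metadata (pixel pitch,
frame rate, beam settings, role) travels in a ``<name>.json`` sidecar
next to the image file.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .phantoms import GroundTruth, _jsonify
from .positioning import LandmarkPairs
from .radiography import FrameStack, Radiograph, RoiSpec

__all__ = [
    "save_frames",
    "load_frames",
    "save_radiograph",
    "load_radiograph",
    "save_ground_truth",
    "load_ground_truth",
    "read_rois_csv",
    "write_rois_csv",
    "read_landmarks_csv",
    "write_landmarks_csv",
    "write_json",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def save_frames(path: str | Path, stack: FrameStack, as_uint16: bool = True) -> None:
    path = Path(path)
    data = stack.frames
    if as_uint16:
        data = np.clip(np.round(data), 0, 65535).astype(np.uint16)
    else:
        data = data.astype(np.float32)
    tifffile.imwrite(path, data, photometric="minisblack")
    meta = {
        "pixel_pitch_mm": stack.pixel_pitch_mm,
        "frame_rate_hz": stack.frame_rate_hz,
        "beam": list(stack.beam),
        "role": stack.role,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=2))


def load_frames(path: str | Path) -> FrameStack:
    path = Path(path)
    frames = tifffile.imread(path)
    meta = json.loads(_sidecar(path).read_text())
    return FrameStack(
        frames=frames,
        pixel_pitch_mm=meta["pixel_pitch_mm"],
        frame_rate_hz=meta["frame_rate_hz"],
        beam=tuple(meta["beam"]),
        role=meta["role"],
    )


def save_radiograph(path: str | Path, radio: Radiograph) -> None:
    path = Path(path)
    tifffile.imwrite(path, radio.image.astype(np.float32))
    meta = {
        "pixel_pitch_mm": radio.pixel_pitch_mm,
        "n_frames": radio.n_frames,
        "acquisition_time_s": radio.acquisition_time_s,
        "estimated_dose_mGy": radio.estimated_dose_mGy,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=2))


def load_radiograph(path: str | Path) -> Radiograph:
    path = Path(path)
    image = tifffile.imread(path)
    meta = json.loads(_sidecar(path).read_text())
    return Radiograph(
        image=image,
        pixel_pitch_mm=meta["pixel_pitch_mm"],
        n_frames=meta.get("n_frames", 1),
        acquisition_time_s=meta.get("acquisition_time_s"),
        estimated_dose_mGy=meta.get("estimated_dose_mGy"),
    )


def save_ground_truth(path: str | Path, gt: GroundTruth) -> None:
    Path(path).write_text(json.dumps(gt.to_dict(), indent=2))


def load_ground_truth(path: str | Path) -> GroundTruth:
    return GroundTruth.from_dict(json.loads(Path(path).read_text()))


def write_json(path: str | Path, obj: dict) -> None:
    Path(path).write_text(json.dumps(_jsonify(obj), indent=2))


def read_rois_csv(path: str | Path) -> list[RoiSpec]:
    df = pd.read_csv(path)
    return [
        RoiSpec(int(r.row0), int(r.row1), int(r.col0), int(r.col1), str(r.label))
        for r in df.itertuples()
    ]


def write_rois_csv(path: str | Path, rois: list[RoiSpec]) -> None:
    pd.DataFrame(
        [
            {"label": r.label, "row0": r.row0, "row1": r.row1, "col0": r.col0, "col1": r.col1}
            for r in rois
        ]
    ).to_csv(path, index=False)


def read_landmarks_csv(path: str | Path) -> LandmarkPairs:
    df = pd.read_csv(path)
    return LandmarkPairs(
        plan=df[["plan_row", "plan_col"]].to_numpy(float),
        radio=df[["radio_row", "radio_col"]].to_numpy(float),
        labels=[str(v) for v in df["label"]] if "label" in df else None,
    )


def write_landmarks_csv(path: str | Path, pairs: LandmarkPairs) -> None:
    labels = pairs.labels or [f"L{i}" for i in range(len(pairs.plan))]
    pd.DataFrame(
        {
            "label": labels,
            "plan_row": pairs.plan[:, 0],
            "plan_col": pairs.plan[:, 1],
            "radio_row": pairs.radio[:, 0],
            "radio_col": pairs.radio[:, 1],
        }
    ).to_csv(path, index=False)
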