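"""File I/O: NIfTI volumes, tab-separated event/trial/nuisance tables.

Directory layout is BIDS-like (sub-XX/ with events, behavior, betas,
nuisance) without claiming BIDS compliance.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "save_volume",
    "load_volume",
    "save_events",
    "load_events",
    "save_table",
    "load_table",
    "write_manifest_entry",
]

_EVENT_COLUMNS = [
    "onset",
    "duration",
    "trial_type",
    "block",
    "context",
    "visual_direction",
    "movement_direction",
]


def _affine(voxel_size_mm: float) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = aff[2, 2] = voxel_size_mm
    return aff


def save_volume(path, data: np.ndarray, voxel_size_mm: float = 3.0) -> Path:
    """Write a 3-D or 4-D array as gzipped NIfTI-1."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), _affine(voxel_size_mm))
    nib.save(img, str(path))
    return path


def load_volume(path):
    """Read a NIfTI volume; returns (data, voxel_size_mm)."""
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata())
    voxel = float(img.header.get_zooms()[0])
    return data, voxel


def save_events(path, events_frame: pd.DataFrame) -> Path:
    missing = [c for c in _EVENT_COLUMNS if c not in events_frame.columns]
    if missing:
        raise ValueError(f"events table missing columns: {', '.join(missing)}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    events_frame.to_csv(path, sep="\t", index=False, float_format="%.3f")
    return path


def load_events(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    missing = [c for c in _EVENT_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: events table missing columns: {', '.join(missing)}")
    return frame


def save_table(path, frame: pd.DataFrame) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", index=False)
    return path


def load_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_manifest_entry(manifest_path, entry: dict) -> None:
    """Append one stage record (JSON lines) to the run manifest."""
    manifest_path = Path(manifest_path)
    manifest_path.parent.mkdir(parents=True, exist_ok=True)
    with open(manifest_path, "a") as fh:
        fh.write(json.dumps(entry, sort_keys=True) + "\n")
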