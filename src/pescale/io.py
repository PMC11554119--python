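"""Readers and writers for the pipeline's file formats.

Events tables follow the BIDS events-TSV convention (onset/duration in
seconds); BOLD runs are 4-D NIfTI; RDMs are square TSV matrices with a label
header; configs are YAML; ground truth and manifests are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .design import EVENT_COLUMNS
from .features import RDM
from .synth import BoldRun

REQUIRED_EVENT_COLUMNS = ["onset", "duration", "trial_type"]


def write_events(events: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    events.to_csv(path, sep="\t", index=False, float_format="%.6f")
    return path


def read_events(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in REQUIRED_EVENT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"events table at {path} lacks required columns: {missing}")
    return table


def write_rdm(rdm: RDM, path: str | Path) -> Path:
    path = Path(path)
    frame = pd.DataFrame(rdm.values, index=rdm.labels, columns=rdm.labels)
    frame.to_csv(path, sep="\t")
    return path


def read_rdm(path: str | Path) -> RDM:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return RDM(labels=tuple(frame.columns), values=frame.to_numpy(dtype=float))


def write_bold(run: BoldRun, path: str | Path) -> Path:
    path = Path(path)
    affine = np.diag([run.voxel_mm, run.voxel_mm, run.voxel_mm, 1.0])
    img = nib.Nifti1Image(run.data.astype(np.float32), affine)
    img.header.set_zooms((run.voxel_mm,) * 3 + (run.tr,))
    nib.save(img, path)
    return path


def read_bold(path: str | Path, mask: np.ndarray | None = None) -> BoldRun:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float32)
    zooms = img.header.get_zooms()
    tr = float(zooms[3]) if len(zooms) > 3 else 1.0
    if mask is None:
        mask = np.ones(data.shape[:3], dtype=bool)
    return BoldRun(data=data, tr=tr, mask=mask, voxel_mm=float(zooms[0]))


def write_map(values: np.ndarray, grid: tuple[int, int, int],
              path: str | Path, voxel_mm: float = 2.0) -> Path:
    """Write a flat per-voxel map as a 3-D NIfTI volume."""
    vol = np.asarray(values, dtype=np.float32).reshape(grid)
    img = nib.Nifti1Image(vol, np.diag([voxel_mm] * 3 + [1.0]))
    nib.save(img, Path(path))
    return Path(path)


def write_config(config: dict, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    return path


def read_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)

    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, default=default)
    return path
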