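"""File I/O: multi-page TIFF stacks with JSON metadata sidecars, float32
parameter maps, and JSON run reports."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .stack import AngularStack

__all__ = ["read_stack", "write_stack", "write_maps", "read_map", "write_report"]


def _default_meta_path(path: Path) -> Path:
    return path.with_suffix(".json")


def read_stack(path, meta_path=None) -> AngularStack:
    """Read a multi-page TIFF stack (page k = angle k) and its JSON sidecar
    ``{"modality": ..., "angles_deg": [...], ...}``. The page count must
    match the listed angle count."""
    path = Path(path)
    meta_path = Path(meta_path) if meta_path else _default_meta_path(path)
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    with open(meta_path) as fh:
        meta = json.load(fh)
    try:
        modality = meta.pop("modality")
        angles = meta.pop("angles_deg")
    except KeyError as exc:
        raise ValueError(f"metadata sidecar {meta_path} is missing {exc}") from None
    if len(angles) != data.shape[0]:
        raise ValueError(
            f"stack has {data.shape[0]} pages but metadata lists {len(angles)} angles")
    return AngularStack(np.asarray(data, dtype=float), angles, modality, meta)


def write_stack(stack: AngularStack, path, meta_path=None) -> None:
    """Write a stack as float32 multi-page TIFF plus JSON sidecar (lossless
    round trip for float32 data, NaNs included)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, stack.intensities.astype(np.float32),
                     photometric="minisblack")
    meta = {"modality": stack.modality,
            "angles_deg": [float(a) for a in stack.angles_deg], **stack.meta}
    with open(meta_path or _default_meta_path(path), "w") as fh:
        json.dump(meta, fh, indent=1)


def write_maps(maps: dict[str, np.ndarray], out_dir) -> dict[str, Path]:
    """Write named parameter maps as single-page (or multi-channel) float32
    TIFFs ``<name>.tif`` under ``out_dir``; returns the written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = {}
    for name, arr in maps.items():
        p = out_dir / f"{name}.tif"
        arr = np.asarray(arr).astype(np.float32)
        photometric = "rgb" if arr.ndim == 3 and arr.shape[2] in (3, 4) else "minisblack"
        tifffile.imwrite(p, arr, photometric=photometric)
        written[name] = p
    return written


def read_map(path) -> np.ndarray:
    return np.asarray(tifffile.imread(path), dtype=float)


def write_report(report: dict, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(report, fh, indent=1, default=float)
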