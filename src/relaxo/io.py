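"""NIfTI-1 input/output helpers shared by the CLI commands."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

from .roi_stats import TissueLabelImage

__all__ = ["load_multi_echo", "load_mask", "load_labels", "save_map", "read_echo_times"]


def load_multi_echo(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Load a 4D multi-echo image; returns ``(data, affine)``."""
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4D multi-echo image, got shape {data.shape}")
    return data, img.affine


def load_mask(path: str | Path) -> np.ndarray:
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata())
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D mask image, got shape {data.shape}")
    return data > 0


def load_labels(path: str | Path) -> TissueLabelImage:
    """Load a 3-class tissue label image (0 bg / 1 CSF / 2 GM / 3 WM)."""
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata())
    dims = tuple(float(z) for z in img.header.get_zooms()[:3])
    return TissueLabelImage(np.round(data).astype(np.int16), dims, img.affine)


def save_map(path: str | Path, data: np.ndarray, affine: np.ndarray) -> None:
    """Write a parameter map (or 4D stack) preserving the input affine."""
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine), str(path))


def read_echo_times(arg: str) -> np.ndarray:
    """Echo times from a comma-separated list or a single-column text file."""
    p = Path(arg)
    if p.exists():
        values = [float(x) for x in p.read_text().replace(",", "\n").split()]
    else:
        values = [float(x) for x in arg.split(",")]
    return np.asarray(values, dtype=float)
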