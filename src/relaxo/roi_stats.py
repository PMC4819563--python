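"""Region-of-interest statistics on label images and parameter maps.

A three-class tissue label image (0 background, 1 CSF, 2 gray matter, 3
white matter) defines the ROIs.  Operations: tissue volumes by voxel
counting, ROI-averaged decay curves (the input to the group-level MCMC
analysis), and ROI summaries (mean, SD, n) of scalar parameter maps such as
T2 or MWF maps.  NaN voxels — unmasked or degenerate fits — are always
skipped and accounted for in ``n_valid``.

Conventions: sample standard deviation (n-1 denominator) throughout;
intracranial volume is the sum of the three segmented classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .signal_models import EchoSeries

__all__ = [
    "BACKGROUND",
    "CSF",
    "GM",
    "WM",
    "TISSUE_CODES",
    "TissueLabelImage",
    "SubjectSummary",
    "tissue_volumes",
    "roi_mean_curve",
    "roi_map_summary",
    "resample_labels_nearest",
    "summarize_subject",
    "summaries_to_table",
]

BACKGROUND, CSF, GM, WM = 0, 1, 2, 3
TISSUE_CODES = {"csf": CSF, "gm": GM, "wm": WM}
_VALID_CODES = frozenset({BACKGROUND, CSF, GM, WM})

MM3_PER_LITER = 1e6


@dataclass(frozen=True)
class TissueLabelImage:
    """3D integer label image with voxel geometry.

    Codes: 0 background, 1 CSF, 2 gray matter, 3 white matter.
    """

    labels: np.ndarray
    voxel_dims: tuple[float, float, float]
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim != 3:
            raise ValueError("labels must be a 3D image")
        if not np.issubdtype(lab.dtype, np.integer):
            if not np.all(lab == np.round(lab)):
                raise ValueError("labels must be integer-valued")
            lab = lab.astype(np.int16)
        present = set(np.unique(lab).tolist())
        if not present <= _VALID_CODES:
            raise ValueError(f"unknown label codes: {sorted(present - _VALID_CODES)}")
        dims = tuple(float(d) for d in self.voxel_dims)
        if len(dims) != 3 or any(d <= 0 for d in dims):
            raise ValueError("voxel_dims must be three positive lengths in mm")
        object.__setattr__(self, "labels", lab)
        object.__setattr__(self, "voxel_dims", dims)
        object.__setattr__(self, "affine", np.asarray(self.affine, dtype=float))

    @property
    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.voxel_dims
        return dx * dy * dz


def tissue_volumes(labels: TissueLabelImage) -> dict[str, float]:
    """Per-tissue volumes in liters by voxel counting.

    volume(tissue) = n_voxels * dx*dy*dz, converted mm^3 -> liters.  The
    intracranial volume is the sum of the CSF, GM and WM volumes (exact by
    construction of the three-class segmentation).
    """
    vox_l = labels.voxel_volume_mm3 / MM3_PER_LITER
    out = {}
    for name, code in TISSUE_CODES.items():
        out[f"{name}_volume_l"] = float(np.count_nonzero(labels.labels == code)) * vox_l
    out["icv_l"] = out["csf_volume_l"] + out["gm_volume_l"] + out["wm_volume_l"]
    return out


def _check_grids(shape_a, shape_b) -> None:
    if tuple(shape_a) != tuple(shape_b):
        raise ValueError(f"image grids do not match: {tuple(shape_a)} vs {tuple(shape_b)}")


def roi_mean_curve(multi_echo: np.ndarray, echo_times, labels: TissueLabelImage, tissue: int | str) -> EchoSeries:
    """Arithmetic-mean decay curve over one tissue ROI.

    Per echo, the mean signal over voxels carrying the tissue code; voxels
    with any NaN echo are skipped.  This group/subject-average white-matter
    curve is the data the MCMC posterior analysis consumes.
    """
    code = TISSUE_CODES[tissue] if isinstance(tissue, str) else int(tissue)
    vol = np.asarray(multi_echo, dtype=float)
    if vol.ndim != 4:
        raise ValueError("multi-echo image must be 4D")
    _check_grids(vol.shape[:3], labels.labels.shape)
    roi = labels.labels == code
    curves = vol[roi]
    curves = curves[~np.isnan(curves).any(axis=1)]
    if curves.shape[0] == 0:
        raise ValueError(f"empty ROI: no valid voxels with code {code}")
    return EchoSeries(np.asarray(echo_times, dtype=float), curves.mean(axis=0))


def roi_map_summary(param_map: np.ndarray, labels: TissueLabelImage, tissue: int | str) -> tuple[float, float, int]:
    """(mean, sample SD, n_valid) of a scalar map over one tissue ROI.

    NaN voxels (failed/degenerate fits, unmasked) are excluded; with a single
    valid voxel the SD is reported as 0.
    """
    code = TISSUE_CODES[tissue] if isinstance(tissue, str) else int(tissue)
    pmap = np.asarray(param_map, dtype=float)
    _check_grids(pmap.shape, labels.labels.shape)
    values = pmap[labels.labels == code]
    values = values[~np.isnan(values)]
    n = int(values.size)
    if n == 0:
        raise ValueError(f"empty ROI: no valid voxels with code {code}")
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if n > 1 else 0.0
    return mean, sd, n


def resample_labels_nearest(labels: TissueLabelImage, target_shape, target_affine: np.ndarray) -> TissueLabelImage:
    """Nearest-neighbour transfer of a label image onto a target grid.

    Maps each target voxel center through the affines (target -> world ->
    source), rounds to the nearest source voxel, and copies its code;
    out-of-field voxels become background.  Never introduces codes absent
    from the source.
    """
    target_affine = np.asarray(target_affine, dtype=float)
    src_inv = np.linalg.inv(labels.affine)
    ii, jj, kk = np.meshgrid(*(np.arange(s) for s in target_shape), indexing="ij")
    tgt_vox = np.stack([ii, jj, kk, np.ones_like(ii)], axis=-1).reshape(-1, 4).T
    src_vox = src_inv @ target_affine @ tgt_vox
    idx = np.round(src_vox[:3]).astype(int)
    out = np.zeros(np.prod(target_shape, dtype=int), dtype=labels.labels.dtype)
    inside = np.all((idx >= 0) & (idx < np.array(labels.labels.shape)[:, None]), axis=0)
    out[inside] = labels.labels[idx[0, inside], idx[1, inside], idx[2, inside]]
    new_dims = tuple(float(np.linalg.norm(target_affine[:3, i])) for i in range(3))
    return TissueLabelImage(out.reshape(tuple(target_shape)), new_dims, target_affine)


@dataclass(frozen=True)
class SubjectSummary:
    """One row of the cohort table: per-subject volumes and ROI means."""

    subject_id: str
    group: str  # "preterm" | "term"
    sex: str  # "male" | "female"
    csf_volume_l: float
    gm_volume_l: float
    wm_volume_l: float
    icv_l: float
    csf_t2_ms: float
    gm_t2_ms: float
    wm_t2_ms: float
    wm_mwf: float
    wm_tissue_fraction: float

    def as_row(self) -> dict:
        return asdict(self)


def summarize_subject(
    subject_id: str,
    group: str,
    sex: str,
    labels: TissueLabelImage,
    t2_map: np.ndarray,
    mwf_map: np.ndarray,
    tissue_fraction_map: np.ndarray,
) -> SubjectSummary:
    """Assemble one subject's cohort-table row from maps and labels."""
    if group not in ("preterm", "term"):
        raise ValueError("group must be 'preterm' or 'term'")
    if sex not in ("male", "female"):
        raise ValueError("sex must be 'male' or 'female'")
    vols = tissue_volumes(labels)
    t2 = {t: roi_map_summary(t2_map, labels, t)[0] for t in ("csf", "gm", "wm")}
    wm_mwf = roi_map_summary(mwf_map, labels, "wm")[0]
    wm_tissue = roi_map_summary(tissue_fraction_map, labels, "wm")[0]
    return SubjectSummary(
        subject_id=subject_id,
        group=group,
        sex=sex,
        csf_volume_l=vols["csf_volume_l"],
        gm_volume_l=vols["gm_volume_l"],
        wm_volume_l=vols["wm_volume_l"],
        icv_l=vols["icv_l"],
        csf_t2_ms=t2["csf"],
        gm_t2_ms=t2["gm"],
        wm_t2_ms=t2["wm"],
        wm_mwf=wm_mwf,
        wm_tissue_fraction=wm_tissue,
    )


def summaries_to_table(summaries) -> pd.DataFrame:
    """Stack subject summaries into a cohort table (one row per subject)."""
    df = pd.DataFrame([s.as_row() for s in summaries])
    if df["subject_id"].duplicated().any():
        raise ValueError("duplicate subject_ids in cohort table")
    return df
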