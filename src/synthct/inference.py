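"""Three-orientation synthetic-CT inference and fusion.

The trained generator translates 2D planes, so a 3D MR volume is sliced
along each of the three orthogonal orientations, translated slice by slice,
and restacked — giving three synthetic CT volumes (axial, sagittal,
coronal). Their voxelwise mean is the final synthetic CT; averaging three
independently sliced predictions suppresses the across-slice discontinuities
a single-orientation 2D model produces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import (
    correct_bias_field, mask_exterior, normalize_mr, denormalize_ct,
)
from .volume import Volume, ORIENTATION_AXES, CT_HU_MIN

__all__ = ["SyntheticCTSet", "predict_volume", "fuse", "synthesize"]


@dataclass
class SyntheticCTSet:
    """The three single-orientation synthetic CTs and their voxelwise mean,
    all in HU on the input MR grid."""

    sct_ax: Volume
    sct_sag: Volume
    sct_cor: Volume
    sct_ave: Volume


def predict_volume(g, mr: Volume, orientation: str) -> Volume:
    """Translate every slice along ``orientation``'s axis independently and
    restack; output denormalized to HU. ``mr`` must be normalized to [-1, 1]."""
    if orientation not in ORIENTATION_AXES:
        raise ValueError(f"orientation must be one of {sorted(ORIENTATION_AXES)}")
    vals = np.asarray(mr.values)
    if vals.min() < -1.0 - 1e-6 or vals.max() > 1.0 + 1e-6:
        raise ValueError("MR volume must be normalized to [-1, 1] before prediction")
    axis = ORIENTATION_AXES[orientation]
    moved = np.moveaxis(vals, axis, 0)
    out = np.empty_like(moved, dtype=np.float64)
    for i in range(moved.shape[0]):
        out[i] = np.asarray(g(moved[i])).squeeze()
    pred = np.moveaxis(out, 0, axis)
    hu = denormalize_ct(np.clip(pred, -1.0, 1.0))
    return Volume(hu, mr.spacing, mr.origin, "SCT")


def fuse(ax: Volume, sag: Volume, cor: Volume) -> Volume:
    """Voxelwise arithmetic mean of the three single-orientation volumes."""
    if not (ax.same_grid(sag) and ax.same_grid(cor)):
        raise ValueError("volumes must share one grid")
    mean = (np.asarray(ax.values, dtype=np.float64)
            + np.asarray(sag.values, dtype=np.float64)
            + np.asarray(cor.values, dtype=np.float64)) / 3.0
    return Volume(mean, ax.spacing, ax.origin, "SCT")


def synthesize(g, mr_raw: Volume, body: Volume, bias_sigma_mm: float = 40.0) -> SyntheticCTSet:
    """Full inference chain from a raw MR volume to the fused synthetic CT.

    bias-correct -> mask exterior -> z-score normalize -> predict along the
    three orientations -> fuse; the exterior of every output is forced to
    -1000 HU. Deterministic for a fixed generator and input.
    """
    mr = correct_bias_field(mr_raw, body, sigma_mm=bias_sigma_mm)
    mr = mask_exterior(mr, body)
    mr_n, _ = normalize_mr(mr)
    vals = mr_n.values.copy()
    vals[body.values == 0] = -1.0
    mr_n = mr_n.with_values(vals)

    outside = body.values == 0

    def _predict(orientation):
        v = predict_volume(g, mr_n, orientation)
        out = v.values.copy()
        out[outside] = CT_HU_MIN
        return v.with_values(out)

    sct_ax = _predict("axial")
    sct_sag = _predict("sagittal")
    sct_cor = _predict("coronal")
    sct_ave = fuse(sct_ax, sct_sag, sct_cor)
    ave = sct_ave.values.copy()
    ave[outside] = CT_HU_MIN
    return SyntheticCTSet(sct_ax, sct_sag, sct_cor, sct_ave.with_values(ave))
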