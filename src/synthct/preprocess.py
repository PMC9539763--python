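"""Intensity preprocessing: exterior masking, CT/MR normalization, bias-field correction.

CT intensities live on the Hounsfield scale in [-1000, 3095] and are mapped
affinely to [-1, 1] with the endpoints pinned (-1000 HU -> -1, 3095 HU -> +1).
MR intensities have an arbitrary positive scale and are standardized with a
z-score computed over tissue only (intensity >= ``air_threshold``), then
scaled by 1/3 and clipped so that +/-3 sigma map to +/-1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume import Volume, CT_HU_MIN, CT_HU_MAX

__all__ = [
    "MRNormalizationParams",
    "CTNormalizationParams",
    "mask_exterior",
    "normalize_ct",
    "denormalize_ct",
    "normalize_mr",
    "correct_bias_field",
    "derive_body_mask",
    "preprocess_case",
    "N4_REFERENCE_SETTINGS",
]

#: Settings for an external N4 bias-field correction, recorded for users who
#: plug one in; the built-in correction is the homomorphic stand-in below.
N4_REFERENCE_SETTINGS = {
    "bspline_order": 3,
    "bspline_grid_resolution": (1, 1, 1),
    "shrink_factor": 4,
    "max_iterations": (50, 40, 30),
    "convergence_threshold": 1e-4,
}

_CT_HALF_RANGE = (CT_HU_MAX - CT_HU_MIN) / 2.0  # 2047.5 HU


@dataclass(frozen=True)
class MRNormalizationParams:
    """z-score parameters estimated over the tissue region of one MR volume."""

    mean: float
    sd: float
    air_threshold: float = 40.0
    truncation_sigmas: float = 3.0

    def __post_init__(self):
        if self.sd <= 0:
            raise ValueError("sd must be > 0")
        if self.air_threshold < 0:
            raise ValueError("air_threshold must be >= 0")


@dataclass(frozen=True)
class CTNormalizationParams:
    hu_min: float = CT_HU_MIN
    hu_max: float = CT_HU_MAX

    @property
    def range(self) -> float:
        return self.hu_max - self.hu_min


def mask_exterior(v: Volume, body: Volume) -> Volume:
    """Force voxels outside the body contour to the modality background:
    -1000 HU for CT/SCT, 0 for MR. In-body voxels are untouched; idempotent."""
    if v.modality not in ("MR", "CT", "SCT"):
        raise ValueError(f"mask_exterior expects MR/CT/SCT, got {v.modality}")
    if body.modality != "MASK":
        raise ValueError("body must be a MASK volume")
    if not v.same_grid(body):
        raise ValueError("volume and body mask must share one grid")
    background = 0.0 if v.modality == "MR" else CT_HU_MIN
    out = np.where(body.values > 0, v.values, background)
    return v.with_values(out)


def normalize_ct(hu):
    """Affine map of HU to [-1, 1] pinned by -1000 -> -1 and 3095 -> +1.

    Accepts a scalar, array, or Volume; out-of-range HU are clipped first.
    """
    if isinstance(hu, Volume):
        return hu.with_values(normalize_ct(hu.values))
    arr = np.asarray(hu, dtype=np.float64)
    if not np.isfinite(arr).all():
        raise ValueError("non-finite HU input")
    clipped = np.clip(arr, CT_HU_MIN, CT_HU_MAX)
    out = (clipped - CT_HU_MIN) / _CT_HALF_RANGE - 1.0
    return float(out) if np.isscalar(hu) or out.ndim == 0 else out


def denormalize_ct(x, tol: float = 1e-6):
    """Inverse of :func:`normalize_ct` on [-1, 1]; exact round-trip."""
    if isinstance(x, Volume):
        return x.with_values(denormalize_ct(x.values, tol=tol))
    arr = np.asarray(x, dtype=np.float64)
    if (arr < -1 - tol).any() or (arr > 1 + tol).any():
        raise ValueError("normalized CT values must lie in [-1, 1]")
    out = (np.clip(arr, -1.0, 1.0) + 1.0) * _CT_HALF_RANGE + CT_HU_MIN
    return float(out) if np.isscalar(x) or out.ndim == 0 else out


def normalize_mr(
    v: Volume,
    air_threshold: float = 40.0,
    truncation_sigmas: float = 3.0,
) -> tuple[Volume, MRNormalizationParams]:
    """z-score MR normalization to [-1, 1].

    The mean and SD are computed only over voxels with intensity >=
    ``air_threshold`` (air/gas regions carry no tissue signal on TrueFISP
    images and would bias the statistics). The z-score is divided by
    ``truncation_sigmas`` and clipped, so values beyond +/-3 sigma saturate at
    +/-1; in particular air maps to -1.
    """
    if v.modality != "MR":
        raise ValueError(f"normalize_mr expects an MR volume, got {v.modality}")
    vals = np.asarray(v.values, dtype=np.float64)
    included = vals >= air_threshold
    if included.sum() < 2:
        raise ValueError("fewer than 2 voxels at or above the air threshold")
    mu = float(vals[included].mean())
    sd = float(vals[included].std())
    if sd == 0:
        raise ValueError("included region is constant; z-score undefined")
    z = (vals - mu) / sd
    out = np.clip(z / truncation_sigmas, -1.0, 1.0)
    params = MRNormalizationParams(mu, sd, air_threshold, truncation_sigmas)
    return v.with_values(out), params


def correct_bias_field(
    v: Volume,
    body: Volume,
    sigma_mm: float = 40.0,
    floor: float = 1e-3,
) -> Volume:
    """Homomorphic bias-field correction inside the body contour.

    A smooth multiplicative field is estimated by large-kernel Gaussian
    smoothing of the log-intensities (normalized convolution restricted to
    in-body voxels), divided out, and rescaled so the in-body mean intensity
    is preserved. Voxels outside the body are returned unchanged.

    ``sigma_mm`` sets the smoothing scale; it must be large relative to
    anatomy so tissue contrast survives while the slowly varying field is
    removed.
    """
    if body.modality != "MASK":
        raise ValueError("body must be a MASK volume")
    if not v.same_grid(body):
        raise ValueError("volume and body mask must share one grid")
    mask = body.values > 0
    if not mask.any():
        raise ValueError("empty body mask")

    from scipy.ndimage import gaussian_filter

    vals = np.asarray(v.values, dtype=np.float64)
    log_img = np.where(mask, np.log(np.maximum(vals, floor)), 0.0)
    sigma_vox = [sigma_mm / s for s in v.spacing]
    num = gaussian_filter(log_img, sigma_vox)
    den = gaussian_filter(mask.astype(np.float64), sigma_vox)
    log_field = np.where(den > 1e-12, num / np.maximum(den, 1e-12), 0.0)
    # remove the in-body mean so the field is pure shape, not overall gain
    log_field = log_field - log_field[mask].mean()
    field = np.exp(log_field)
    corrected = np.where(mask, vals / field, vals)
    # preserve the in-body mean intensity
    scale = vals[mask].mean() / corrected[mask].mean()
    corrected = np.where(mask, corrected * scale, vals)
    return v.with_values(corrected)


def preprocess_case(case, bias_sigma_mm: float = 40.0):
    """Full preprocessing chain for one paired case: bias-correct the MR,
    mask both modalities outside the body, and normalize to [-1, 1].

    The normalized exterior is forced to exactly -1 in both modalities (air
    saturates the z-score clip on clinical data; forcing it makes the
    background convention exact on any input, which empty-plane detection in
    the trainer relies on). Returns (preprocessed case, MR z-score params).
    """
    from .phantom import PairedCase

    body = case.body_mask
    mr = correct_bias_field(case.mr, body, sigma_mm=bias_sigma_mm)
    mr = mask_exterior(mr, body)
    mr_n, params = normalize_mr(mr)
    mr_vals = mr_n.values.copy()
    mr_vals[body.values == 0] = -1.0
    ct_n = normalize_ct(mask_exterior(case.ct, body))
    return (
        PairedCase(
            mr=mr_n.with_values(mr_vals),
            ct=ct_n,
            body_mask=body,
            structures=case.structures,
            truth_labels=case.truth_labels,
            dose=case.dose,
        ),
        params,
    )


def derive_body_mask(ct: Volume, threshold_hu: float = -400.0) -> Volume:
    """Body contour from a CT: threshold HU > ``threshold_hu``, keep the
    largest connected component, fill holes. For phantom cases the generated
    mask should be preferred; this is for real inputs without a contour."""
    from scipy.ndimage import binary_fill_holes, label

    fg = np.asarray(ct.values) > threshold_hu
    labels, n = label(fg)
    if n == 0:
        raise ValueError("no voxels above the body threshold")
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    mask = binary_fill_holes(labels == sizes.argmax())
    return Volume(mask.astype(np.uint8), ct.spacing, ct.origin, "MASK")
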