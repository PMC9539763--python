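"""Image-quality evaluation of synthetic CT against a reference CT.

MAE, ME and PSNR are computed over the voxels inside the body contour (MAE
and ME additionally per tissue segment); SSIM is a single global statistic
over the whole grid. Tissue segments come from HU thresholds applied to the
*reference* CT only: air < -200 HU, bone > 200 HU, soft tissue the inclusive
residual [-200, 200] — no morphological post-processing.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .volume import Volume

__all__ = [
    "TissueSegments", "QualityReport",
    "segment_tissues", "mae", "me", "psnr", "ssim_global", "evaluate",
    "PSNR_UNBOUNDED",
]

#: sentinel reported when the two volumes are identical in the ROI (MSE = 0)
PSNR_UNBOUNDED = float("inf")

AIR_THRESHOLD_HU = -200.0
BONE_THRESHOLD_HU = 200.0

# SSIM regularizers: standard (k L)^2 with k1=0.01, k2=0.03 over the CT
# dynamic range L = 4095 HU
_SSIM_L = 4095.0
_SSIM_C1 = (0.01 * _SSIM_L) ** 2
_SSIM_C2 = (0.03 * _SSIM_L) ** 2


@dataclass
class TissueSegments:
    """Disjoint air/soft/bone masks partitioning the body ROI."""

    air: np.ndarray
    soft: np.ndarray
    bone: np.ndarray


@dataclass
class QualityReport:
    mae_whole: float
    mae_air: float
    mae_soft: float
    mae_bone: float
    me_whole: float
    me_air: float
    me_soft: float
    me_bone: float
    psnr: float
    ssim: float
    n_whole: int
    n_air: int
    n_soft: int
    n_bone: int

    def to_dict(self) -> dict:
        return asdict(self)


def segment_tissues(ct: Volume, body: Volume) -> TissueSegments:
    """HU-threshold segmentation of the reference CT inside the body contour."""
    if body.modality != "MASK":
        raise ValueError("body must be a MASK volume")
    if not ct.same_grid(body):
        raise ValueError("ct and body must share one grid")
    inside = body.values > 0
    if not inside.any():
        raise ValueError("empty body mask")
    hu = np.asarray(ct.values)
    return TissueSegments(
        air=inside & (hu < AIR_THRESHOLD_HU),
        soft=inside & (hu >= AIR_THRESHOLD_HU) & (hu <= BONE_THRESHOLD_HU),
        bone=inside & (hu > BONE_THRESHOLD_HU),
    )


def _roi_diff(sct: Volume, ct: Volume, roi: np.ndarray) -> np.ndarray:
    if sct.shape != ct.shape:
        raise ValueError("volumes must share one grid")
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != sct.shape:
        raise ValueError("roi shape mismatch")
    if not roi.any():
        raise ValueError("empty ROI")
    return (np.asarray(sct.values, dtype=np.float64)
            - np.asarray(ct.values, dtype=np.float64))[roi]


def mae(sct: Volume, ct: Volume, roi: np.ndarray) -> float:
    """Mean absolute HU difference over the ROI voxels."""
    return float(np.abs(_roi_diff(sct, ct, roi)).mean())


def me(sct: Volume, ct: Volume, roi: np.ndarray) -> float:
    """Signed mean HU difference (synthetic minus reference) over the ROI."""
    return float(_roi_diff(sct, ct, roi).mean())


def psnr(sct: Volume, ct: Volume, roi: np.ndarray) -> float:
    """10·log10(MAX_CT² / MSE) in dB, with MSE over the ROI voxels and
    MAX_CT the maximum reference-CT value in the whole volume. Returns the
    ``PSNR_UNBOUNDED`` sentinel when MSE is zero."""
    d = _roi_diff(sct, ct, roi)
    mse = float((d ** 2).mean())
    if mse == 0.0:
        return PSNR_UNBOUNDED
    max_ct = float(np.asarray(ct.values).max())
    return float(10.0 * np.log10(max_ct ** 2 / mse))


def ssim_global(sct: Volume, ct: Volume, windowed: bool = False) -> float:
    """Structural similarity as one global statistic over the whole grid:

        SSIM = (2 μa μb + c1)(2 σab + c2) / ((μa² + μb² + c1)(σa² + σb² + c2))

    with c1 = (0.01·4095)², c2 = (0.03·4095)². With ``windowed=True`` the
    conventional sliding-window mean SSIM (scikit-image) is returned instead.
    """
    if sct.shape != ct.shape:
        raise ValueError("volumes must share one grid")
    a = np.asarray(sct.values, dtype=np.float64)
    b = np.asarray(ct.values, dtype=np.float64)
    if windowed:
        from skimage.metrics import structural_similarity

        return float(structural_similarity(a, b, data_range=_SSIM_L))
    mu_a, mu_b = a.mean(), b.mean()
    var_a, var_b = a.var(), b.var()
    cov = ((a - mu_a) * (b - mu_b)).mean()
    num = (2 * mu_a * mu_b + _SSIM_C1) * (2 * cov + _SSIM_C2)
    den = (mu_a ** 2 + mu_b ** 2 + _SSIM_C1) * (var_a + var_b + _SSIM_C2)
    return float(num / den)


def evaluate(sct: Volume, ct: Volume, body: Volume) -> QualityReport:
    """Assemble the full quality report for one synthetic-vs-reference pair."""
    seg = segment_tissues(ct, body)
    inside = np.asarray(body.values) > 0

    def seg_stats(mask):
        if mask.any():
            return mae(sct, ct, mask), me(sct, ct, mask), int(mask.sum())
        return float("nan"), float("nan"), 0

    mae_air, me_air, n_air = seg_stats(seg.air)
    mae_soft, me_soft, n_soft = seg_stats(seg.soft)
    mae_bone, me_bone, n_bone = seg_stats(seg.bone)
    return QualityReport(
        mae_whole=mae(sct, ct, inside),
        mae_air=mae_air, mae_soft=mae_soft, mae_bone=mae_bone,
        me_whole=me(sct, ct, inside),
        me_air=me_air, me_soft=me_soft, me_bone=me_bone,
        psnr=psnr(sct, ct, inside),
        ssim=ssim_global(sct, ct),
        n_whole=int(inside.sum()),
        n_air=n_air, n_soft=n_soft, n_bone=n_bone,
    )
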