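"""Procedural paired MR/CT pelvis phantoms with structure masks and analytic dose.

The phantom is a deliberately simple male-pelvis stand-in: an elliptical body
with a subcutaneous fat rim, a bony pelvic ring plus femoral-head spheres, an
MR-bright bladder, a rectal tube with an optional gas pocket, a prostate/PTV
sphere between bladder and rectum, and a thin urethra. CT values follow a
per-class HU lookup with partial-volume smoothing and Gaussian noise; MR
values follow a per-class lookup modulated by a smooth multiplicative bias
field with Rician noise. Outside the body contour CT is exactly -1000 HU and
MR is exactly 0.

Because CT is (up to noise) a monotone function of the tissue class, and the
class is recoverable from MR contrast, a learnable MR->CT mapping exists by
construction — which is what makes desk-scale training smoke tests
meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.ndimage import gaussian_filter

from .volume import Volume

__all__ = [
    "CLASS_NAMES",
    "PhantomSpec",
    "PairedCase",
    "generate_paired_case",
    "generate_dose",
    "perturb_dose",
]

# tissue class ids in truth_labels
AIR, GAS, FAT, MUSCLE, BLADDER, PROSTATE, BONE = range(7)
CLASS_NAMES = ("air", "gas", "fat", "muscle", "bladder", "prostate", "bone")

DEFAULT_CT_MEANS = {
    "air": -1000.0, "gas": -800.0, "fat": -90.0, "muscle": 45.0,
    "bladder": 15.0, "prostate": 40.0, "bone": 700.0,
}
# arbitrary units; TrueFISP-like ordering: bladder brightest, fat > muscle,
# bone and gas near zero (below the air threshold used in MR normalization)
DEFAULT_MR_MEANS = {
    "air": 0.0, "gas": 5.0, "fat": 450.0, "muscle": 300.0,
    "bladder": 800.0, "prostate": 330.0, "bone": 20.0,
}


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one procedural paired case; deterministic given ``seed``."""

    seed: int = 0
    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (6.0, 6.0, 4.0)
    class_ct_means: dict = field(default_factory=lambda: dict(DEFAULT_CT_MEANS))
    class_mr_means: dict = field(default_factory=lambda: dict(DEFAULT_MR_MEANS))
    noise_sd_ct: float = 20.0
    noise_sd_mr: float = 15.0
    bias_amplitude: float = 0.2
    gas_pocket: bool = True

    def __post_init__(self):
        cm = self.class_ct_means
        for k in ("air", "gas"):
            if cm[k] >= -200:
                raise ValueError(f"CT mean for {k} must be < -200 HU")
        for k in ("fat", "muscle", "bladder", "prostate"):
            if not -200 <= cm[k] <= 200:
                raise ValueError(f"CT mean for soft class {k} must lie in [-200, 200] HU")
        if cm["bone"] <= 200:
            raise ValueError("CT mean for bone must be > 200 HU")
        mm = self.class_mr_means
        if mm["bone"] >= 40 or mm["gas"] >= 40:
            raise ValueError("MR means for bone and gas must sit below the air threshold (40)")
        if mm["bladder"] != max(mm.values()):
            raise ValueError("bladder must be the brightest MR class")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        for key in ("shape", "spacing"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class PairedCase:
    """Co-registered MR + CT with body contour, structure masks, truth labels
    and (optionally) a dose grid; the unit of training and evaluation."""

    mr: Volume
    ct: Volume
    body_mask: Volume
    structures: dict  # name -> Volume(MASK): PTV, rectum, bladder, urethra
    truth_labels: np.ndarray | None = None
    dose: Volume | None = None


def _normalized_coords(shape, spacing):
    """Per-axis coordinates in [-1, 1] at voxel centers."""
    axes = []
    for n, s in zip(shape, spacing):
        extent = n * s
        centers = (np.arange(n) + 0.5) * s - extent / 2.0
        axes.append(centers / (extent / 2.0))
    return np.meshgrid(*axes, indexing="ij")


def _ellipsoid(u, v, w, center, radii):
    terms = ((u - center[0]) / radii[0]) ** 2 + ((v - center[1]) / radii[1]) ** 2
    if radii[2] is not None:
        terms = terms + ((w - center[2]) / radii[2]) ** 2
    return terms <= 1.0


def generate_paired_case(spec: PhantomSpec) -> PairedCase:
    """Build one paired pelvis phantom; identical output for identical spec."""
    shape = tuple(spec.shape)
    if any(n < 32 for n in shape):
        raise ValueError(f"shape too small to place organs; need >= 32 per axis, got {shape}")
    rng = np.random.default_rng(spec.seed)
    u, v, w = _normalized_coords(shape, spec.spacing)

    # body: elliptical cylinder; axis u = left-right, v = anterior-posterior
    r_body = np.sqrt((u / 0.85) ** 2 + (v / 0.75) ** 2)
    body = r_body <= 1.0

    labels = np.full(shape, AIR, dtype=np.uint8)
    labels[body] = MUSCLE
    labels[body & (r_body >= 0.82)] = FAT  # subcutaneous fat rim

    # pelvic bone ring (central band in z) + femoral heads
    r_ring = np.sqrt((u / 0.62) ** 2 + (v / 0.55) ** 2)
    ring = (r_ring >= 0.80) & (r_ring <= 1.0) & (np.abs(w) <= 0.55)
    labels[ring & body] = BONE
    for side in (-1, 1):
        head = _ellipsoid(u, v, w, (side * 0.58, 0.05, 0.0), (0.12, 0.14, 0.22))
        labels[head & body] = BONE

    bladder = _ellipsoid(u, v, w, (0.0, -0.28, 0.05), (0.20, 0.18, 0.30))
    labels[bladder] = BLADDER

    # rectal tube (muscle wall) with optional gas pocket inside
    rectum = np.sqrt(((u - 0.0) / 0.10) ** 2 + ((v - 0.42) / 0.10) ** 2) <= 1.0
    gas = np.zeros(shape, dtype=bool)
    if spec.gas_pocket:
        gas = _ellipsoid(u, v, w, (0.0, 0.42, 0.10), (0.07, 0.07, 0.18))
        labels[gas] = GAS

    prostate = _ellipsoid(u, v, w, (0.0, 0.10, 0.0), (0.13, 0.12, 0.18))
    labels[prostate & ~gas] = PROSTATE

    urethra = (np.sqrt((u / 0.05) ** 2 + ((v - 0.10) / 0.05) ** 2) <= 1.0) & (np.abs(w) <= 0.35)
    urethra &= prostate
    if not urethra.any():  # guarantee a nonempty structure at coarse grids
        ci = tuple(n // 2 for n in shape)
        urethra[ci[0], ci[1], ci[2]] = True

    ct_lut = np.array([spec.class_ct_means[k] for k in CLASS_NAMES])
    mr_lut = np.array([spec.class_mr_means[k] for k in CLASS_NAMES])

    ct = ct_lut[labels]
    ct = gaussian_filter(ct, 0.5)  # partial-volume smoothing at class boundaries
    ct = ct + rng.normal(0.0, spec.noise_sd_ct, shape)
    ct = np.clip(ct, -1000.0, 3095.0)
    ct[~body] = -1000.0

    mr = mr_lut[labels]
    mr = gaussian_filter(mr, 0.5)
    bias = _bias_field(shape, (u, v, w), spec.bias_amplitude, rng)
    mr = mr * bias
    # Rician noise: magnitude of a complex Gaussian around the clean signal
    n1 = rng.normal(0.0, spec.noise_sd_mr, shape)
    n2 = rng.normal(0.0, spec.noise_sd_mr, shape)
    mr = np.sqrt((mr + n1) ** 2 + n2 ** 2)
    mr[~body] = 0.0

    mk = lambda arr, mod="MASK": Volume(arr.astype(np.uint8), spec.spacing, (0.0, 0.0, 0.0), mod)
    structures = {
        "PTV": mk(prostate & body),
        "rectum": mk(rectum & body),
        "bladder": mk(bladder & body),
        "urethra": mk(urethra & body),
    }
    return PairedCase(
        mr=Volume(mr, spec.spacing, (0.0, 0.0, 0.0), "MR"),
        ct=Volume(ct, spec.spacing, (0.0, 0.0, 0.0), "CT"),
        body_mask=mk(body),
        structures=structures,
        truth_labels=labels,
    )


def _bias_field(shape, coords, amplitude, rng):
    """exp of a random low-order polynomial in normalized coords, scaled so the
    multiplicative range stays within [1/(1+a), 1+a]."""
    if amplitude <= 0:
        return np.ones(shape)
    u, v, w = coords
    terms = [u, v, w, u * v, u * w, v * w, u ** 2, v ** 2, w ** 2]
    coef = rng.uniform(-1.0, 1.0, len(terms))
    log_f = sum(c * t for c, t in zip(coef, terms))
    peak = np.abs(log_f).max()
    if peak > 0:
        log_f = log_f * (np.log1p(amplitude) / peak)
    return np.exp(log_f)


def generate_dose(case: PairedCase, prescription: float = 36.25, falloff_mm: float = 40.0) -> Volume:
    """Analytic pseudo-dose: the prescription at the PTV centroid voxel with an
    isotropic Gaussian falloff (``falloff_mm`` = 1 SD), clipped at 0. A stand-in
    for a planned dose distribution; deterministic."""
    ptv = case.structures["PTV"].values > 0
    if not ptv.any():
        raise ValueError("empty PTV")
    spacing = np.asarray(case.ct.spacing)
    idx = np.argwhere(ptv)
    centroid_vox = np.round(idx.mean(axis=0)).astype(int)
    grids = np.meshgrid(*[np.arange(n) for n in case.ct.shape], indexing="ij")
    r2 = sum(((g - c) * s) ** 2 for g, c, s in zip(grids, centroid_vox, spacing))
    dose = prescription * np.exp(-r2 / (2.0 * falloff_mm ** 2))
    return Volume(np.maximum(dose, 0.0), case.ct.spacing, case.ct.origin, "DOSE")


def perturb_dose(
    dose: Volume,
    scale: float = 1.0,
    shift_mm: tuple[float, float, float] = (0.0, 0.0, 0.0),
    interpolate: bool = False,
) -> Volume:
    """Scaled and/or spatially translated copy of a dose grid, for building
    controlled gamma-analysis test pairs. Without ``interpolate`` the shift
    must be an integer number of voxels; with it, linear interpolation is
    used. Regions shifted in from outside the grid are 0 Gy."""
    vals = np.asarray(dose.values, dtype=np.float64)
    if not np.isfinite(vals).all():
        raise ValueError("dose contains non-finite values")
    shift_vox = [s / sp for s, sp in zip(shift_mm, dose.spacing)]
    if any(abs(s) > 1e-12 for s in shift_vox):
        if interpolate:
            from scipy.ndimage import shift as nd_shift

            vals = nd_shift(vals, shift_vox, order=1, mode="constant", cval=0.0)
        else:
            ints = [round(s) for s in shift_vox]
            if any(abs(s - i) > 1e-9 for s, i in zip(shift_vox, ints)):
                raise ValueError(
                    f"shift {shift_mm} mm is not a voxel multiple of spacing {dose.spacing};"
                    " pass interpolate=True"
                )
            out = np.zeros_like(vals)
            src = [slice(max(0, -i), min(n, n - i)) for i, n in zip(ints, vals.shape)]
            dst = [slice(max(0, i), min(n, n + i)) for i, n in zip(ints, vals.shape)]
            out[tuple(dst)] = vals[tuple(src)]
            vals = out
    return dose.with_values(vals * scale)
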