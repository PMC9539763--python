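"""Dosimetric comparison: cumulative DVHs, D95%/D2% metrics, and 3D gamma analysis.

The DVH is exact (built from the sorted in-structure voxel doses, no binning).
Dx% — the minimum dose received by the hottest x% of a structure — is read
off by linear interpolation between order statistics. The gamma index uses
global normalization: the dose criterion is a percentage of the maximum
reference dose, evaluated inside the ROI where the reference dose exceeds a
threshold fraction (default 10%) of that maximum. For each reference voxel,

    gamma = min over nearby points r of sqrt((Δd/ΔD)² + (|r|/dta)²)

with sub-voxel evaluation of the compared distribution by trilinear
interpolation; a voxel passes when gamma <= 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates

from .volume import Volume

__all__ = [
    "DVHCurve", "GammaCriteria",
    "compute_dvh", "dvh_metric", "dose_difference_report", "gamma_pass_rate",
]


@dataclass(frozen=True)
class GammaCriteria:
    """Gamma-analysis configuration: dose difference (% of the maximum
    reference dose), distance-to-agreement (mm), and the low-dose ROI
    threshold (fraction of maximum reference dose)."""

    dose_percent: float = 2.0
    dta_mm: float = 2.0
    low_dose_threshold: float = 0.10

    def __post_init__(self):
        if self.dose_percent <= 0 or self.dta_mm <= 0 or self.low_dose_threshold <= 0:
            raise ValueError("all gamma criteria must be positive")


@dataclass
class DVHCurve:
    """Cumulative dose-volume curve: fraction of structure volume receiving
    at least each dose. Non-increasing, starts at 1 and ends at 0."""

    dose_axis: np.ndarray
    cumulative_fraction: np.ndarray
    structure_name: str
    voxel_count: int
    _sorted_doses: np.ndarray = field(repr=False, default=None)

    def fraction_at(self, d: float) -> float:
        """Fraction of the structure receiving >= d Gy (exact count)."""
        return float((self._sorted_doses >= d).sum() / self.voxel_count)


def compute_dvh(dose: Volume, structure: Volume, name: str = "") -> DVHCurve:
    """Exact cumulative DVH from the sorted in-structure voxel doses."""
    if not dose.same_grid(structure):
        raise ValueError("dose and structure must share one grid")
    mask = np.asarray(structure.values) > 0
    if not mask.any():
        raise ValueError("empty structure")
    doses = np.sort(np.asarray(dose.values, dtype=np.float64)[mask])
    n = doses.size
    # step curve: fraction receiving >= d; append a terminal point at the
    # maximum dose where the fraction has dropped to 0
    axis = np.concatenate([[0.0], doses, [doses[-1]]])
    frac = np.concatenate([[1.0], (n - np.arange(n)) / n, [0.0]])
    return DVHCurve(axis, frac, name, n, _sorted_doses=doses)


def dvh_metric(curve: DVHCurve, metric) -> float:
    """Dx% — greatest dose received by at least x% of the structure volume.

    ``metric`` is "D95%", "D2", or a numeric x in (0, 100); computed as the
    (1 - x/100) quantile of the voxel doses with linear interpolation.
    """
    if isinstance(metric, str):
        m = metric.strip().upper().lstrip("D").rstrip("%")
        x = float(m)
    else:
        x = float(metric)
    if not 0 < x < 100:
        raise ValueError(f"Dx%: x must lie in (0, 100), got {x}")
    return float(np.quantile(curve._sorted_doses, 1.0 - x / 100.0))


def dose_difference_report(reference_metrics: dict, evaluated_metrics: dict,
                           prescription: float) -> dict:
    """Per-metric absolute (Gy) and relative (% of prescription) differences,
    evaluated minus reference."""
    if set(reference_metrics) != set(evaluated_metrics):
        raise ValueError(
            f"metric names differ: {sorted(reference_metrics)} vs {sorted(evaluated_metrics)}"
        )
    out = {}
    for name in sorted(reference_metrics):
        ref, ev = float(reference_metrics[name]), float(evaluated_metrics[name])
        out[name] = {
            "reference_gy": ref,
            "evaluated_gy": ev,
            "diff_gy": ev - ref,
            "diff_pct": 100.0 * (ev - ref) / prescription,
        }
    return out


def _sphere_offsets(step_mm: float, radius_mm: float, include_zero: bool = False):
    """Physical offsets on a cubic lattice within a sphere, sorted by length."""
    k = int(np.floor(radius_mm / step_mm + 1e-9))
    ax = np.arange(-k, k + 1) * step_mm
    ox, oy, oz = np.meshgrid(ax, ax, ax, indexing="ij")
    offs = np.stack([ox.ravel(), oy.ravel(), oz.ravel()], axis=1)
    r = np.linalg.norm(offs, axis=1)
    keep = r <= radius_mm + 1e-9
    if not include_zero:
        keep &= r > 1e-12
    offs, r = offs[keep], r[keep]
    order = np.argsort(r, kind="stable")
    return offs[order], r[order]


def gamma_pass_rate(reference: Volume, evaluated: Volume,
                    criteria: GammaCriteria = GammaCriteria()) -> float:
    """Percent of ROI voxels with gamma index <= 1.

    Two-stage search: a coarse lattice (dta/2 steps out to 2×dta) bounds
    gamma from above everywhere; voxels still failing are re-searched on a
    fine lattice (dta/10 steps, out to dta — beyond one DTA the spatial term
    alone exceeds 1, so no farther point can flip a failure). The compared
    dose is trilinearly interpolated at sub-voxel positions.
    """
    if not reference.same_grid(evaluated):
        raise ValueError("dose grids must match; resample first")
    ref = np.asarray(reference.values, dtype=np.float64)
    ev = np.asarray(evaluated.values, dtype=np.float64)
    max_ref = float(ref.max())
    if max_ref <= 0:
        raise ValueError("reference dose is all zero")
    roi = ref > criteria.low_dose_threshold * max_ref
    if not roi.any():
        raise ValueError("empty ROI after low-dose thresholding")
    delta_d = criteria.dose_percent / 100.0 * max_ref
    dta = criteria.dta_mm
    spacing = np.asarray(reference.spacing)

    idx = np.argwhere(roi).astype(np.float64)  # voxel indices of ROI points
    ref_d = ref[roi]
    g2 = ((ev[roi] - ref_d) / delta_d) ** 2  # zero-offset gamma^2

    def sweep(offsets, radii, coords_idx, ref_vals, best):
        for off, r in zip(offsets, radii):
            spatial = (r / dta) ** 2
            if spatial >= best.max():
                break
            sample = map_coordinates(ev, (coords_idx + off / spacing).T,
                                     order=1, mode="nearest")
            cand = ((sample - ref_vals) / delta_d) ** 2 + spatial
            np.minimum(best, cand, out=best)
        return best

    coarse_offs, coarse_r = _sphere_offsets(dta / 2.0, 2.0 * dta)
    g2 = sweep(coarse_offs, coarse_r, idx, ref_d, g2)

    failing = g2 > 1.0
    if failing.any():
        fine_offs, fine_r = _sphere_offsets(dta / 10.0, dta)
        sub_idx, sub_ref = idx[failing], ref_d[failing]
        sub_best = g2[failing].copy()
        for off, r in zip(fine_offs, fine_r):
            spatial = (r / dta) ** 2
            still = sub_best > 1.0
            # a point farther than one DTA cannot flip a failing voxel
            # (gamma^2 >= spatial > 1); the boundary |r| == dta can, when the
            # dose difference there is exactly zero, so keep spatial == 1
            if not still.any() or spatial > 1.0 + 1e-12:
                break
            sample = map_coordinates(ev, (sub_idx[still] + off / spacing).T,
                                     order=1, mode="nearest")
            cand = ((sample - sub_ref[still]) / delta_d) ** 2 + spatial
            tmp = sub_best[still]
            np.minimum(tmp, cand, out=tmp)
            sub_best[still] = tmp
        g2[failing] = sub_best

    return float(100.0 * (g2 <= 1.0).sum() / g2.size)
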