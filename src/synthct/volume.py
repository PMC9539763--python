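"""Volume data model, NIfTI/NRRD I/O, and grid resampling.

Grid axis convention (fixed throughout the package):

* axis 0 — left–right (slicing along it yields **sagittal** planes)
* axis 1 — anterior–posterior (**coronal** planes)
* axis 2 — superior–inferior (**axial** planes)

Physical-space mapping is corner-anchored with half-open voxel extents: the
corner of voxel (0,0,0) sits at ``origin`` and the *center* of voxel ``i``
is at ``origin + (i + 0.5) * spacing``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Volume",
    "MODALITIES",
    "ORIENTATION_AXES",
    "read_volume",
    "write_volume",
    "resample",
]

MODALITIES = ("MR", "CT", "SCT", "DOSE", "MASK")

#: orientation label -> grid axis along which 2D planes are extracted
ORIENTATION_AXES = {"sagittal": 0, "coronal": 1, "axial": 2}

CT_HU_MIN = -1000.0
CT_HU_MAX = 3095.0


@dataclass
class Volume:
    """A 3D scalar grid with voxel spacing (mm), origin (mm) and a modality tag.

    ``values`` hold HU for CT/SCT, arbitrary positive units for MR, Gy for
    DOSE, and exactly {0, 1} for MASK.
    """

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    modality: str = "CT"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"Volume requires a 3D grid, got ndim={self.values.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or len(self.origin) != 3:
            raise ValueError("spacing and origin must have 3 components")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"all spacing components must be > 0, got {self.spacing}")
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}; expected one of {MODALITIES}")
        if self.modality == "MASK":
            u = np.unique(self.values)
            if not np.isin(u, (0, 1)).all():
                raise ValueError("MASK volumes must contain only 0 and 1")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def same_grid(self, other: "Volume", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )

    def with_values(self, values: np.ndarray, modality: str | None = None) -> "Volume":
        """New Volume on the same grid with replaced values (and optionally modality)."""
        return replace(self, values=values, modality=modality or self.modality)

    def astype(self, dtype) -> "Volume":
        return self.with_values(self.values.astype(dtype))


def _infer_format(path: str, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in ("nifti", "nrrd"):
            raise ValueError(f"format must be 'nifti' or 'nrrd', got {fmt!r}")
        return fmt
    lower = str(path).lower()
    if lower.endswith((".nii", ".nii.gz")):
        return "nifti"
    if lower.endswith((".nrrd", ".nhdr")):
        return "nrrd"
    raise ValueError(f"cannot infer format from {path!r}; pass format explicitly")


def read_volume(path: str, format: str | None = None, modality: str = "CT") -> Volume:
    """Read a 3D scalar image from NIfTI-1 or NRRD.

    Spacing and origin are taken from the header. The array axis order is the
    package convention (x=LR, y=AP, z=SI); SimpleITK's z-fastest ordering is
    transposed on load. Raises on missing files and on non-3D images.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)
    if fmt == "nifti":
        import nibabel as nib

        img = nib.load(path)
        data = np.asarray(img.dataobj)
        if data.ndim != 3:
            raise ValueError(f"expected a 3D image, got ndim={data.ndim}")
        zooms = img.header.get_zooms()[:3]
        origin = tuple(float(t) for t in img.affine[:3, 3])
        return Volume(data, tuple(float(z) for z in zooms), origin, modality)
    else:
        import SimpleITK as sitk

        img = sitk.ReadImage(str(path))
        if img.GetDimension() != 3:
            raise ValueError(f"expected a 3D image, got ndim={img.GetDimension()}")
        if img.GetNumberOfComponentsPerPixel() != 1:
            raise ValueError("expected scalar voxels")
        data = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
        return Volume(data, img.GetSpacing(), img.GetOrigin(), modality)


def write_volume(v: Volume, path: str, format: str | None = None) -> None:
    """Write a Volume to NIfTI-1 or NRRD; round-trips bit-exactly through
    :func:`read_volume` at the stored precision."""
    if not np.isfinite(v.values).all():
        raise ValueError("volume contains non-finite values; refuse to write")
    fmt = _infer_format(path, format)
    if fmt == "nifti":
        import nibabel as nib

        affine = np.diag(list(v.spacing) + [1.0])
        affine[:3, 3] = v.origin
        img = nib.Nifti1Image(np.asarray(v.values), affine)
        img.header.set_zooms(v.spacing)
        nib.save(img, path)
    else:
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(np.ascontiguousarray(np.asarray(v.values).transpose(2, 1, 0)))
        img.SetSpacing(v.spacing)
        img.SetOrigin(v.origin)
        sitk.WriteImage(img, str(path))


def resample(
    v: Volume,
    target_shape: tuple[int, int, int],
    target_spacing: tuple[float, float, float],
    method: str = "linear",
) -> Volume:
    """Resample onto a new grid sharing the input's origin (corner-anchored).

    ``method`` is ``linear`` (MR/CT/dose) or ``nearest`` (masks; keeps the
    value set a subset of the input's). The output voxel center at physical
    position p is interpolated at fractional input index (p - origin)/spacing - 0.5.
    """
    target_shape = tuple(int(n) for n in target_shape)
    target_spacing = tuple(float(s) for s in target_spacing)
    if any(n <= 0 for n in target_shape):
        raise ValueError(f"target_shape must be positive, got {target_shape}")
    if any(s <= 0 for s in target_spacing):
        raise ValueError(f"target_spacing must be positive, got {target_spacing}")
    if method not in ("linear", "nearest"):
        raise ValueError(f"method must be 'linear' or 'nearest', got {method!r}")

    if target_shape == v.shape and np.allclose(target_spacing, v.spacing):
        return Volume(v.values.copy(), v.spacing, v.origin, v.modality)

    from scipy.ndimage import map_coordinates

    coords = []
    for ax in range(3):
        centers_mm = (np.arange(target_shape[ax]) + 0.5) * target_spacing[ax]
        coords.append(centers_mm / v.spacing[ax] - 0.5)
    grid = np.meshgrid(*coords, indexing="ij")
    order = 1 if method == "linear" else 0
    out = map_coordinates(
        np.asarray(v.values, dtype=np.float64),
        np.stack([g.ravel() for g in grid]),
        order=order,
        mode="nearest",
    ).reshape(target_shape)
    if method == "nearest":
        out = out.astype(v.values.dtype)
    return Volume(out, target_spacing, v.origin, v.modality)
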