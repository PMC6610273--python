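"""Core volumetric data types, geometry conventions, and NIfTI I/O.

Conventions used throughout the package
---------------------------------------
* Arrays are indexed ``(x, y, z)`` with 0-based indices; ``x`` is the
  anatomical left-right axis, ``y`` anterior-posterior (dorsal-volar) and
  ``z`` proximal-distal.  Larger ``z`` is more distal.
* Geometry is axis-aligned: the physical position of voxel ``(i, j, k)``
  is ``origin + (i*sx, j*sy, k*sz)`` (voxel centers, half-open extents).
  No direction-cosine generality.
* Intensities are floating point after load; label maps are integer.
* A ``VolumetricImage`` carries its acquisition plane.  Acquired scans are
  anisotropic: an axial scan stacks thick slices along ``z``, a coronal
  scan along ``y``.  The slice gap is folded into the through-slice
  spacing (effective spacing = thickness + gap) while the averaging
  window of each slice covers the thickness only.
"""

from __future__ import annotations

import dataclasses
import re
import warnings
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np

__all__ = [
    "PLANES",
    "Grid",
    "VolumetricImage",
    "RegionLabelMap",
    "VisualScoreSheet",
    "TENDON_REGIONS",
    "LABEL_CODES",
    "TENDON_LABELS",
    "BONE_LABELS",
    "ValidationError",
    "GeometryError",
    "DimensionalityError",
    "load_volume",
    "save_volume",
    "load_labels",
    "save_labels",
    "mirror_horizontal",
    "resample_labels_nearest",
]

PLANES = ("axial", "coronal", "isotropic-SRR")

#: through-slice array axis per acquisition plane (isotropic volumes have none)
_SLICE_AXIS = {"axial": 2, "coronal": 1, "isotropic-SRR": None}

#: the ten scored tendon regions: six extensor compartments, four flexor regions
TENDON_REGIONS = (
    "extensor_I",
    "extensor_II",
    "extensor_III",
    "extensor_IV",
    "extensor_V",
    "extensor_VI",
    "flexor_1",
    "flexor_2",
    "flexor_3",
    "flexor_4",
)

#: closed label vocabulary for RegionLabelMap
LABEL_CODES: Mapping[str, int] = {
    "background": 0,
    **{r: i + 1 for i, r in enumerate(TENDON_REGIONS)},
    "carpal_bones": 11,
    "hamate": 12,
    "radius": 13,
    "ulna": 14,
}

LABEL_NAMES = {v: k for k, v in LABEL_CODES.items()}
TENDON_LABELS = tuple(range(1, 11))
BONE_LABELS = (11, 12, 13, 14)
_VALID_CODES = frozenset(LABEL_CODES.values())


class ValidationError(ValueError):
    """Input violates a documented contract (bad values, bad vocabulary)."""


class GeometryError(ValueError):
    """Grids or shapes are geometrically incompatible."""


class DimensionalityError(ValidationError):
    """Payload is not a 3D scalar volume."""


@dataclasses.dataclass(frozen=True)
class Grid:
    """Axis-aligned sampling grid: shape, per-axis spacing (mm) and origin (mm)."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(n) <= 0 for n in self.shape):
            raise GeometryError(f"grid shape must be 3 positive ints, got {self.shape}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise GeometryError(f"spacing must be 3 positive floats, got {self.spacing}")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def axis_coords(self, axis: int) -> np.ndarray:
        """Physical coordinates (mm) of voxel centers along one axis."""
        return self.origin[axis] + self.spacing[axis] * np.arange(self.shape[axis])

    def extent(self, axis: int) -> tuple[float, float]:
        """Half-open physical extent [lo, hi) along one axis (voxel edges)."""
        lo = self.origin[axis] - 0.5 * self.spacing[axis]
        return lo, lo + self.shape[axis] * self.spacing[axis]

    def overlaps(self, other: "Grid") -> bool:
        return all(
            self.extent(a)[0] < other.extent(a)[1] and other.extent(a)[0] < self.extent(a)[1]
            for a in range(3)
        )


def as_grid(obj) -> Grid:
    """Coerce a Grid, VolumetricImage or RegionLabelMap to a Grid."""
    if isinstance(obj, Grid):
        return obj
    return Grid(tuple(obj.voxels.shape) if hasattr(obj, "voxels") else tuple(obj.labels.shape),
                tuple(obj.spacing), tuple(obj.origin))


@dataclasses.dataclass
class VolumetricImage:
    """A 3D scalar image on an axis-aligned grid.

    Parameters
    ----------
    voxels
        3D floating-point array indexed (x, y, z).
    spacing
        Per-axis voxel spacing in mm.  For acquired scans the through-slice
        spacing is the effective spacing (slice thickness + gap).
    origin
        Physical coordinate (mm) of voxel (0, 0, 0).
    plane
        ``"axial"``, ``"coronal"`` or ``"isotropic-SRR"``.
    slice_thickness
        Averaging window (mm) of each acquired slice along the through-slice
        axis; ``None`` for isotropic volumes.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    plane: str = "isotropic-SRR"
    slice_thickness: float | None = None

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise DimensionalityError(f"expected 3D volume, got {self.voxels.ndim}D")
        if not np.issubdtype(self.voxels.dtype, np.floating):
            self.voxels = self.voxels.astype(np.float64)
        if not np.isfinite(self.voxels).all():
            raise ValidationError("volume contains non-finite intensities")
        if self.plane not in PLANES:
            raise ValidationError(f"plane must be one of {PLANES}, got {self.plane!r}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValidationError(f"spacing must be 3 positive floats, got {self.spacing}")

    @property
    def grid(self) -> Grid:
        return Grid(self.voxels.shape, self.spacing, self.origin)

    @property
    def slice_axis(self) -> int | None:
        """Array axis along which acquired slices stack (None if isotropic)."""
        return _SLICE_AXIS[self.plane]

    @property
    def voxel_volume_mm3(self) -> float:
        return self.grid.voxel_volume_mm3


@dataclasses.dataclass
class RegionLabelMap:
    """Integer label volume over the closed tendon/bone vocabulary."""

    labels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise DimensionalityError(f"expected 3D label map, got {self.labels.ndim}D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            if np.issubdtype(self.labels.dtype, np.floating) and np.all(
                self.labels == np.round(self.labels)
            ):
                self.labels = self.labels.astype(np.int16)
            else:
                raise ValidationError("label map must be integer-valued")
        present = set(np.unique(self.labels).tolist())
        unknown = present - _VALID_CODES
        if unknown:
            raise ValidationError(f"unknown label codes {sorted(unknown)}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValidationError(f"spacing must be positive, got {self.spacing}")

    @property
    def grid(self) -> Grid:
        return Grid(self.labels.shape, self.spacing, self.origin)

    def mask(self, codes: int | Sequence[int]) -> np.ndarray:
        codes = (codes,) if np.isscalar(codes) else tuple(codes)
        return np.isin(self.labels, codes)


@dataclasses.dataclass
class VisualScoreSheet:
    """Per-region tenosynovitis grades (mean of two readers).

    Grades live on a 0-3 scale in steps of 0.5 (after averaging two integer
    readers): 0 normal, 1 peritendinous enhancement < 2 mm thick, 2 for
    2-5 mm, 3 for >= 5 mm.
    """

    grades: Mapping[str, float]

    def __post_init__(self) -> None:
        missing = set(TENDON_REGIONS) - set(self.grades)
        if missing:
            raise ValidationError(f"missing grades for regions {sorted(missing)}")
        extra = set(self.grades) - set(TENDON_REGIONS)
        if extra:
            raise ValidationError(f"unknown regions {sorted(extra)}")
        self.grades = {r: float(self.grades[r]) for r in TENDON_REGIONS}
        for r, g in self.grades.items():
            if not (0.0 <= g <= 3.0):
                raise ValidationError(f"grade for {r} out of [0, 3]: {g}")
            if abs(g * 2 - round(g * 2)) > 1e-9:
                raise ValidationError(f"grade for {r} not a multiple of 0.5: {g}")

    @property
    def total(self) -> float:
        """Total tenosynovitis score: sum of the 10 per-region grades (0-30)."""
        return float(sum(self.grades.values()))

    @property
    def v_max(self) -> float:
        """Maximum per-region grade, used for severity stratification."""
        return float(max(self.grades.values()))


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def _affine(spacing, origin) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0])
    aff[:3, 3] = origin
    return aff


def _descrip(plane: str, slice_thickness: float | None) -> bytes:
    s = f"plane={plane}"
    if slice_thickness is not None:
        s += f";thick={slice_thickness:g}"
    return s.encode()


def _parse_descrip(raw: bytes) -> tuple[str | None, float | None]:
    text = raw.decode(errors="ignore") if isinstance(raw, bytes) else str(raw)
    plane = None
    thick = None
    m = re.search(r"plane=([\w\-]+)", text)
    if m and m.group(1) in PLANES:
        plane = m.group(1)
    m = re.search(r"thick=([\d.eE+\-]+)", text)
    if m:
        thick = float(m.group(1))
    return plane, thick


def save_volume(img: VolumetricImage, path) -> None:
    """Write a volume as NIfTI-1; plane/slice-thickness metadata go in descrip."""
    nii = nib.Nifti1Image(np.asarray(img.voxels, dtype=np.float32), _affine(img.spacing, img.origin))
    nii.header["descrip"] = _descrip(img.plane, img.slice_thickness)
    nib.save(nii, str(path))


def load_volume(path, plane: str | None = None) -> VolumetricImage:
    """Load a 3D NIfTI volume.

    Spacing and origin come from the header; the acquisition plane is read
    from the descrip field when present (override with ``plane``).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    nii = nib.load(str(path))
    data = np.asanyarray(nii.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise DimensionalityError(f"{path}: expected 3D payload, got {data.ndim}D")
    data = np.asarray(data, dtype=np.float64)
    if not np.isfinite(data).all():
        raise ValidationError(f"{path}: non-finite voxel intensities")
    spacing = tuple(float(z) for z in nii.header.get_zooms()[:3])
    origin = tuple(float(v) for v in nii.affine[:3, 3])
    hdr_plane, thick = _parse_descrip(nii.header["descrip"].tobytes())
    if plane is None:
        plane = hdr_plane or "isotropic-SRR"
    return VolumetricImage(data, spacing, origin, plane=plane, slice_thickness=thick)


def save_labels(lab: RegionLabelMap, path) -> None:
    nii = nib.Nifti1Image(np.asarray(lab.labels, dtype=np.int16), _affine(lab.spacing, lab.origin))
    nib.save(nii, str(path))


def load_labels(path) -> RegionLabelMap:
    """Load a label map; codes outside the vocabulary are rejected."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    nii = nib.load(str(path))
    data = np.asanyarray(nii.dataobj)
    if data.ndim != 3:
        raise DimensionalityError(f"{path}: expected 3D payload, got {data.ndim}D")
    spacing = tuple(float(z) for z in nii.header.get_zooms()[:3])
    origin = tuple(float(v) for v in nii.affine[:3, 3])
    return RegionLabelMap(np.asarray(data), spacing, origin)


# ---------------------------------------------------------------------------
# Geometric operations
# ---------------------------------------------------------------------------

def mirror_horizontal(img):
    """Reverse a volume or label map along the left-right (x) axis.

    Used to reuse a right-wrist atlas on left wrists.  Mirroring is about
    the grid center; spacing and origin are unchanged.  Involutive.
    """
    if isinstance(img, RegionLabelMap):
        return RegionLabelMap(img.labels[::-1].copy(), img.spacing, img.origin)
    return VolumetricImage(
        img.voxels[::-1].copy(), img.spacing, img.origin,
        plane=img.plane, slice_thickness=img.slice_thickness,
    )


def resample_labels_nearest(lab: RegionLabelMap, target) -> RegionLabelMap:
    """Resample a label map onto a target grid by nearest physical neighbor.

    Each target voxel takes the label of the physically nearest source voxel
    (clipped to the source extent).  Never invents labels absent from the
    source.
    """
    tgt = as_grid(target)
    src = lab.grid
    if not src.overlaps(tgt):
        raise GeometryError("source and target grids have disjoint physical extents")
    idx = []
    for a in range(3):
        phys = tgt.axis_coords(a)
        i = np.round((phys - src.origin[a]) / src.spacing[a]).astype(np.int64)
        idx.append(np.clip(i, 0, src.shape[a] - 1))
    out = lab.labels[np.ix_(idx[0], idx[1], idx[2])]
    return RegionLabelMap(out.copy(), tgt.spacing, tgt.origin)
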