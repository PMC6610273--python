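"""Tendon segmentation: markers from atlas labels, watershed, rejection rules.

The fused atlas labels are only landmarks; the actual tendon boundaries
are recovered by flooding the gradient-magnitude image from markers
(eroded atlas tendon labels inside, the dilated complement outside).
Surviving catchment basins are then filtered with the two rejection
rules for this task: a region is dropped if its mean intensity exceeds
75 (tendons are dark on T1-Gd) or its volume is below 0.01 ml.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
from scipy.ndimage import distance_transform_edt, gaussian_gradient_magnitude
from skimage.segmentation import watershed

from .image_model import (
    TENDON_LABELS,
    GeometryError,
    RegionLabelMap,
    VolumetricImage,
)

__all__ = [
    "OUTSIDE_MARKER",
    "MarkerImage",
    "SegmentedRegion",
    "make_markers",
    "watershed_segment",
    "filter_regions",
    "precision_recall",
]

#: marker code for the "definitely not tendon" flooding seed
OUTSIDE_MARKER = 99


@dataclasses.dataclass
class MarkerImage:
    """Watershed seeds: positive tendon codes, OUTSIDE_MARKER, 0 elsewhere."""

    markers: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.markers.ndim != 3:
            raise ValueError("marker image must be 3D")
        self.markers = np.asarray(self.markers, dtype=np.int16)


@dataclasses.dataclass
class SegmentedRegion:
    """One watershed catchment: tendon code, voxels, mean intensity, volume."""

    label: int
    mask: np.ndarray
    mean_intensity: float
    volume_ml: float


def make_markers(
    fused: RegionLabelMap,
    erosion_mm: float = 0.4,
    dilation_mm: float = 1.0,
) -> MarkerImage:
    """Build watershed markers from fused atlas labels.

    Each tendon marker is the label eroded by ``erosion_mm`` (physical
    distance, so anisotropic grids behave); if erosion empties a label,
    the innermost voxel (distance-transform maximum) is kept instead,
    with a warning.  The outside marker is the complement of the tendon
    union dilated by ``dilation_mm``.
    """
    spacing = fused.spacing
    markers = np.zeros(fused.labels.shape, dtype=np.int16)
    union = np.zeros(fused.labels.shape, dtype=bool)
    any_tendon = False
    for code in TENDON_LABELS:
        m = fused.labels == code
        if not m.any():
            continue
        any_tendon = True
        union |= m
        inside = distance_transform_edt(m, sampling=spacing)
        eroded = inside > erosion_mm
        if not eroded.any():
            warnings.warn(
                f"tendon label {code} vanished under {erosion_mm} mm erosion; "
                "falling back to its innermost voxel"
            )
            idx = np.unravel_index(np.argmax(inside), inside.shape)
            markers[idx] = code
        else:
            markers[eroded] = code
    if not any_tendon:
        raise ValueError("fused label map contains no tendon labels")
    dist_out = distance_transform_edt(~union, sampling=spacing)
    outside = dist_out > dilation_mm
    markers[outside & (markers == 0)] = OUTSIDE_MARKER
    return MarkerImage(markers, spacing, fused.origin)


def watershed_segment(
    img: VolumetricImage,
    markers: MarkerImage,
    gradient_sigma_mm: float = 0.3,
) -> list[SegmentedRegion]:
    """Marker-based watershed of the gradient-magnitude image.

    Floods the Gaussian-derivative gradient magnitude (sigma in physical
    mm) from the markers; voxels captured by the outside marker are
    discarded and each surviving catchment becomes one region per tendon
    code, carrying its mean intensity and volume in ml.
    """
    if not (markers.markers > 0).any():
        raise ValueError("marker image is empty")
    if img.voxels.shape != markers.markers.shape:
        raise GeometryError("image and marker grids differ")
    sigma_vox = [gradient_sigma_mm / s for s in img.spacing]
    grad = gaussian_gradient_magnitude(img.voxels, sigma=sigma_vox)
    ws = watershed(grad, markers=markers.markers.astype(np.int32))
    regions = []
    vox_ml = img.voxel_volume_mm3 / 1000.0
    for code in TENDON_LABELS:
        mask = ws == code
        if not mask.any():
            continue
        regions.append(
            SegmentedRegion(
                label=int(code),
                mask=mask,
                mean_intensity=float(img.voxels[mask].mean()),
                volume_ml=float(mask.sum() * vox_ml),
            )
        )
    return regions


def filter_regions(
    regions: Sequence[SegmentedRegion],
    grid_like,
    intensity_max: float = 75.0,
    min_volume_ml: float = 0.01,
) -> RegionLabelMap:
    """Apply the rejection rules and write survivors to a label map.

    A region is removed if its mean intensity exceeds ``intensity_max``
    (not a tendon: tendons are dark on T1-Gd) or its volume is below
    ``min_volume_ml``.  An empty result is allowed.
    """
    from .image_model import as_grid

    g = as_grid(grid_like)
    out = np.zeros(g.shape, dtype=np.int16)
    for r in regions:
        if r.mean_intensity > intensity_max or r.volume_ml < min_volume_ml:
            continue
        out[r.mask] = r.label
    return RegionLabelMap(out, g.spacing, g.origin)


def precision_recall(auto: np.ndarray, manual: np.ndarray):
    """Voxel-overlap precision and recall of an automatic segmentation.

    precision = |auto ∩ manual| / |auto|, recall = |auto ∩ manual| / |manual|.
    An empty mask makes the corresponding rate undefined (None), not 0.
    """
    auto = np.asarray(auto, dtype=bool)
    manual = np.asarray(manual, dtype=bool)
    if auto.shape != manual.shape:
        raise GeometryError("masks are on different grids")
    inter = float(np.logical_and(auto, manual).sum())
    n_auto = float(auto.sum())
    n_manual = float(manual.sum())
    precision = inter / n_auto if n_auto > 0 else None
    recall = inter / n_manual if n_manual > 0 else None
    return precision, recall
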