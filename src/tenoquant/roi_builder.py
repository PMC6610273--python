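"""Measurement-ROI construction around the segmented tendons.

The ROI is the set of voxels within Euclidean distance D (mm) of any
segmented tendon that (a) carry no other structure label, (b) lie inside
the skin-bounded hand extent, and (c) fall between two rule-derived
axial slices: proximally the slice where the radius and ulna are closest
in-plane, distally the slice holding the most hamate voxels (the hook of
the hamate).  Distances honor anisotropic spacing.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import ndimage
from scipy.ndimage import distance_transform_edt

from .image_model import (
    LABEL_CODES,
    GeometryError,
    RegionLabelMap,
    ValidationError,
    VolumetricImage,
)

__all__ = [
    "MeasurementROI",
    "hand_mask",
    "proximal_boundary",
    "distal_boundary",
    "tendon_distance_mm",
    "build_roi",
]


@dataclasses.dataclass
class MeasurementROI:
    """Binary measurement mask plus the parameters that produced it."""

    mask: np.ndarray
    distance_mm: float
    proximal: int
    distal: int

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())


def hand_mask(
    img: VolumetricImage,
    background_tolerance: float | None = None,
) -> np.ndarray:
    """Skin-bounded hand extent by corner-seeded background growing.

    Air background is grown from the four corners of every axial slice
    (voxels below the tolerance, connected to a corner seed); the
    complement's largest connected component is the hand.  The default
    tolerance adapts to the image: 10% of the 99th intensity percentile.
    Corner seeds that land on tissue are skipped with a warning; if every
    seed is skipped, an error is raised.
    """
    vox = img.voxels
    if background_tolerance is None:
        background_tolerance = 0.1 * float(np.percentile(vox, 99))
    candidate = vox < background_tolerance
    nx, ny, nz = vox.shape
    corners = [(0, 0), (0, ny - 1), (nx - 1, 0), (nx - 1, ny - 1)]
    seeds = []
    skipped = 0
    for z in range(nz):
        for cx, cy in corners:
            if candidate[cx, cy, z]:
                seeds.append((cx, cy, z))
            else:
                skipped += 1
    if skipped:
        warnings.warn(f"{skipped} corner seeds fell on tissue and were skipped")
    if not seeds:
        raise ValidationError("no usable background seeds: all slice corners are tissue")
    comp, _ = ndimage.label(candidate)
    seed_ids = {comp[s] for s in seeds} - {0}
    background = np.isin(comp, sorted(seed_ids))
    foreground, n_fg = ndimage.label(~background)
    if n_fg == 0:
        raise ValidationError("no foreground component: image is all background")
    counts = np.bincount(foreground.ravel())
    counts[0] = 0
    return foreground == int(np.argmax(counts))


def proximal_boundary(labels: RegionLabelMap) -> int:
    """Axial slice where the radius and ulna are closest in-plane.

    For every slice containing both bones, the minimum in-plane physical
    distance between their voxels is found via a 2D distance transform;
    the slice with the smallest such distance wins, the most distal slice
    on ties.
    """
    radius = labels.labels == LABEL_CODES["radius"]
    ulna = labels.labels == LABEL_CODES["ulna"]
    if not radius.any():
        raise ValidationError("radius label absent")
    if not ulna.any():
        raise ValidationError("ulna label absent")
    sx, sy, _ = labels.spacing
    nz = labels.labels.shape[2]
    best_z, best_d = None, np.inf
    for z in range(nz):
        r2d = radius[:, :, z]
        u2d = ulna[:, :, z]
        if not (r2d.any() and u2d.any()):
            continue
        dist_to_radius = distance_transform_edt(~r2d, sampling=(sx, sy))
        d = float(dist_to_radius[u2d].min())
        if d <= best_d:  # ties resolve to the most distal slice (later z)
            best_d, best_z = d, z
    if best_z is None:
        raise ValidationError("no axial slice contains both radius and ulna")
    return best_z


def distal_boundary(labels: RegionLabelMap) -> int:
    """Axial slice with the largest hamate voxel count (ties: most distal)."""
    hamate = labels.labels == LABEL_CODES["hamate"]
    if not hamate.any():
        raise ValidationError("hamate label absent")
    counts = hamate.sum(axis=(0, 1))
    best = int(np.flatnonzero(counts == counts.max())[-1])
    return best


def tendon_distance_mm(tendons: RegionLabelMap) -> np.ndarray:
    """Euclidean distance (mm) of every voxel to the nearest tendon voxel."""
    union = np.isin(tendons.labels, range(1, 11))
    if not union.any():
        raise ValidationError("tendon label map is empty")
    return distance_transform_edt(~union, sampling=tendons.spacing)


def build_roi(
    tendons: RegionLabelMap,
    all_labels: RegionLabelMap,
    hand: np.ndarray,
    distance_mm: float,
    bounds: tuple[int, int],
    distance_field: np.ndarray | None = None,
) -> MeasurementROI:
    """Assemble the measurement ROI.

    ``distance_field`` may carry a precomputed tendon distance transform
    (so several D values reuse one transform).  The distance inequality
    is inclusive (<= D).  An empty result is legal but warned about.
    """
    proximal, distal = bounds
    if distance_mm <= 0:
        raise ValidationError("distance must be positive")
    if proximal > distal:
        raise ValidationError("proximal bound exceeds distal bound")
    if distance_field is None:
        distance_field = tendon_distance_mm(tendons)
    mask = distance_field <= distance_mm
    mask &= tendons.labels == 0
    mask &= all_labels.labels == 0
    mask &= np.asarray(hand, dtype=bool)
    z_idx = np.arange(mask.shape[2])
    z_ok = (z_idx >= proximal) & (z_idx <= distal)
    mask &= z_ok[None, None, :]
    if not mask.any():
        warnings.warn("measurement ROI is empty")
    return MeasurementROI(mask=mask, distance_mm=float(distance_mm),
                          proximal=int(proximal), distal=int(distal))
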