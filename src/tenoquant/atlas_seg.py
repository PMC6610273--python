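"""Multi-atlas segmentation: affine registration, label transfer, majority vote.

Each atlas case (image + manual-style label map) is registered onto the
target image; its labels are carried over by nearest-neighbor resampling
and the candidates are fused by per-voxel plurality vote (ties resolve
to background).  All atlas cases are right wrists: left-wrist targets
are handled by mirroring the atlas before registration.

Registration is a pluggable component.  The shipped provider is an
affine (12-parameter) registration on the mean-squared intensity
difference, optimized multi-resolution with gradient descent via
SimpleITK.  Registration never worsens the similarity: if optimization
ends worse than the identity transform, a RegistrationFailure carrying
the identity transform is raised.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Sequence

import numpy as np
import SimpleITK as sitk

from .image_model import (
    GeometryError,
    Grid,
    RegionLabelMap,
    VolumetricImage,
    as_grid,
    mirror_horizontal,
)

__all__ = [
    "SpatialTransform",
    "AtlasSet",
    "RegistrationFailure",
    "register",
    "transfer_labels",
    "majority_vote",
    "prepare_for_handedness",
    "segment_with_atlas",
]


class RegistrationFailure(RuntimeError):
    """Optimization could not improve on the identity transform.

    Carries the identity ``transform`` so callers may fall back to it.
    """

    def __init__(self, message: str, transform: "SpatialTransform"):
        super().__init__(message)
        self.transform = transform


@dataclasses.dataclass
class SpatialTransform:
    """Affine map from target physical coordinates to atlas physical coordinates.

    ``matrix`` is the 3x3 linear part (row-major), ``translation`` the
    offset, ``center`` the fixed rotation center; together these are the
    12 affine parameters.  ``similarity`` is the mean squared intensity
    difference achieved on the target grid.
    """

    matrix: np.ndarray
    translation: np.ndarray
    center: np.ndarray = dataclasses.field(default_factory=lambda: np.zeros(3))
    similarity: float = float("nan")

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        self.center = np.asarray(self.center, dtype=float).reshape(3)
        if abs(np.linalg.det(self.matrix)) < 1e-12:
            raise ValueError("affine matrix is singular")

    @classmethod
    def identity(cls, similarity: float = float("nan")) -> "SpatialTransform":
        return cls(np.eye(3), np.zeros(3), similarity=similarity)

    def as_sitk(self) -> sitk.AffineTransform:
        t = sitk.AffineTransform(3)
        t.SetMatrix(self.matrix.ravel().tolist())
        t.SetCenter(self.center.tolist())
        t.SetTranslation(self.translation.tolist())
        return t

    def apply_point(self, p: np.ndarray) -> np.ndarray:
        p = np.asarray(p, dtype=float)
        return self.matrix @ (p - self.center) + self.center + self.translation


@dataclasses.dataclass
class AtlasSet:
    """Paired (image, label map) atlas cases, all of the same handedness."""

    entries: list[tuple[VolumetricImage, RegionLabelMap]]
    handedness: str = "right"

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("atlas set must be non-empty")
        if self.handedness not in ("left", "right"):
            raise ValueError("handedness must be 'left' or 'right'")
        for img, lab in self.entries:
            if img.voxels.shape != lab.labels.shape:
                raise GeometryError("atlas image and label map shapes differ")

    def __len__(self) -> int:
        return len(self.entries)


def _to_sitk(img: VolumetricImage) -> sitk.Image:
    # SimpleITK arrays index (z, y, x); ours index (x, y, z)
    out = sitk.GetImageFromArray(np.ascontiguousarray(img.voxels.T.astype(np.float32)))
    out.SetSpacing(img.spacing)
    out.SetOrigin(img.origin)
    return out


def _labels_to_sitk(lab: RegionLabelMap) -> sitk.Image:
    out = sitk.GetImageFromArray(np.ascontiguousarray(lab.labels.T.astype(np.int16)))
    out.SetSpacing(lab.spacing)
    out.SetOrigin(lab.origin)
    return out


def register(
    atlas_img: VolumetricImage,
    target_img: VolumetricImage,
    shrink_factors: Sequence[int] = (4, 2, 1),
    smoothing_sigmas: Sequence[float] = (2.0, 1.0, 0.0),
    iterations: int = 150,
) -> SpatialTransform:
    """Affine registration of an atlas image onto the target image.

    Minimizes mean squared intensity difference over a multi-resolution
    pyramid with gradient descent.  Returns the transform from target
    physical coordinates to atlas physical coordinates; its ``similarity``
    never exceeds the identity transform's.
    """
    tg = target_img.grid
    ag = atlas_img.grid
    if not tg.overlaps(ag):
        raise GeometryError("atlas and target extents are disjoint")
    fixed = _to_sitk(target_img)
    moving = _to_sitk(atlas_img)

    center = [
        tg.origin[a] + 0.5 * tg.spacing[a] * (tg.shape[a] - 1) for a in range(3)
    ]
    init = sitk.AffineTransform(3)
    init.SetCenter(center)

    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMeanSquares()
    reg.SetMetricSamplingStrategy(reg.NONE)  # full sampling: deterministic
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=1.0,
        minStep=1e-4,
        numberOfIterations=iterations,
        relaxationFactor=0.6,
    )
    reg.SetOptimizerScalesFromPhysicalShift()
    reg.SetShrinkFactorsPerLevel(list(shrink_factors))
    reg.SetSmoothingSigmasPerLevel(list(smoothing_sigmas))
    reg.SmoothingSigmasAreSpecifiedInPhysicalUnitsOn()
    reg.SetInitialTransform(init, inPlace=True)

    identity_cost = _metric_value(fixed, moving, sitk.AffineTransform(3))
    final = reg.Execute(fixed, moving)
    final_cost = _metric_value(fixed, moving, final)

    if final_cost > identity_cost:
        raise RegistrationFailure(
            f"registration worsened similarity ({final_cost:.4g} > {identity_cost:.4g})",
            SpatialTransform.identity(similarity=identity_cost),
        )
    affine = sitk.AffineTransform(final)
    return SpatialTransform(
        matrix=np.array(affine.GetMatrix()).reshape(3, 3),
        translation=np.array(affine.GetTranslation()),
        center=np.array(affine.GetCenter()),
        similarity=final_cost,
    )


def _metric_value(fixed: sitk.Image, moving: sitk.Image, transform: sitk.Transform) -> float:
    """Mean squared difference between fixed and transformed moving image."""
    resampled = sitk.Resample(
        moving, fixed, transform, sitk.sitkLinear, 0.0, sitk.sitkFloat32
    )
    a = sitk.GetArrayViewFromImage(fixed).astype(np.float64)
    b = sitk.GetArrayViewFromImage(resampled).astype(np.float64)
    return float(np.mean((a - b) ** 2))


def transfer_labels(
    t: SpatialTransform, atlas_lab: RegionLabelMap, target
) -> RegionLabelMap:
    """Carry atlas labels onto the target grid through a spatial transform.

    Nearest-neighbor interpolation; coordinates that map outside the
    atlas extent become background.
    """
    tgt = as_grid(target)
    ref = sitk.Image(tgt.shape, sitk.sitkInt16)
    ref.SetSpacing(tgt.spacing)
    ref.SetOrigin(tgt.origin)
    out = sitk.Resample(
        _labels_to_sitk(atlas_lab), ref, t.as_sitk(), sitk.sitkNearestNeighbor, 0
    )
    return RegionLabelMap(
        sitk.GetArrayFromImage(out).T.copy(), tgt.spacing, tgt.origin
    )


def majority_vote(candidates: Sequence[RegionLabelMap]) -> RegionLabelMap:
    """Fuse candidate label maps by per-voxel plurality.

    The label with the highest count wins; any tie for the top count
    (including ties with background) resolves to background — the
    conservative "or neither" reading.  Permutation-invariant.
    """
    if len(candidates) < 1:
        raise ValueError("at least one candidate is required")
    g0 = candidates[0].grid
    for c in candidates[1:]:
        if c.grid != g0:
            raise GeometryError("candidate label maps are on different grids")
    stack = np.stack([c.labels for c in candidates])
    values = np.unique(stack)
    best_count = np.zeros(g0.shape, dtype=np.int32)
    second_count = np.zeros(g0.shape, dtype=np.int32)
    best_label = np.zeros(g0.shape, dtype=np.int16)
    for v in values:
        cnt = (stack == v).sum(axis=0).astype(np.int32)
        better = cnt > best_count
        second_count = np.where(better, best_count, np.maximum(second_count, cnt * ~better))
        best_label = np.where(better, np.int16(v), best_label)
        best_count = np.where(better, cnt, best_count)
    tie = second_count == best_count
    fused = np.where(tie, np.int16(0), best_label)
    return RegionLabelMap(fused, g0.spacing, g0.origin)


def prepare_for_handedness(atlas: AtlasSet, target_handedness: str) -> AtlasSet:
    """Mirror the (right-wrist) atlas when the target is a left wrist."""
    if target_handedness not in ("left", "right"):
        raise ValueError("target_handedness must be 'left' or 'right'")
    if target_handedness == atlas.handedness:
        return AtlasSet(list(atlas.entries), handedness=atlas.handedness)
    flipped = [
        (mirror_horizontal(img), mirror_horizontal(lab)) for img, lab in atlas.entries
    ]
    return AtlasSet(flipped, handedness=target_handedness)


def segment_with_atlas(
    target_img: VolumetricImage,
    atlas: AtlasSet,
    target_handedness: str = "right",
    register_fn: Callable[..., SpatialTransform] | None = None,
    **register_kwargs,
) -> RegionLabelMap:
    """Full multi-atlas pipeline: handedness, per-case registration, fusion.

    ``register_fn`` makes the registration engine pluggable; the default
    is the affine provider.  A case whose registration fails falls back
    to the identity transform rather than being dropped.
    """
    register_fn = register_fn or register
    prepared = prepare_for_handedness(atlas, target_handedness)
    candidates = []
    for img, lab in prepared.entries:
        try:
            t = register_fn(img, target_img, **register_kwargs)
        except RegistrationFailure as exc:
            t = exc.transform
        candidates.append(transfer_labels(t, lab, target_img.grid))
    return majority_vote(candidates)
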