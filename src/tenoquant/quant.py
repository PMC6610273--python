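"""Intensity-adaptive tenosynovitis quantification.

Intensity ranges of enhancing tissue vary per acquisition, so instead of
fixed intensity cutoffs a two-cluster fuzzy C-means is fitted to all
voxel intensities of each image.  Let C2 be the cluster with the higher
center: its membership map highlights synovial tissue.  Zeroing voxels
whose intensity falls below the C2 center ("one-sided C2 map") isolates
hyper-enhancing tissue, and tenosynovitis is quantified as the fraction
of measurement-ROI voxels whose one-sided membership p_C2 satisfies
T_L <= p_C2 < T_H.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from .image_model import GeometryError, VolumetricImage
from .roi_builder import MeasurementROI

__all__ = [
    "FuzzyClusterModel",
    "OneSidedC2Map",
    "QuantResult",
    "DegenerateClusteringError",
    "fit_fcm2",
    "one_sided_map",
    "tenosynovitis_fraction",
]


class DegenerateClusteringError(ValueError):
    """Clustering is meaningless (constant image / coincident centers)."""


@dataclasses.dataclass
class FuzzyClusterModel:
    """Two-cluster fuzzy C-means fit on scalar intensities.

    Centers are sorted (c1 < c2).  Memberships for any intensity follow
    the standard FCM formula with fuzziness exponent m; u1 + u2 = 1
    everywhere, and a point exactly on a center gets full membership.
    """

    c1: float
    c2: float
    m: float
    iterations: int
    objective: float
    objective_history: tuple[float, ...] = ()

    def membership_c2(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        d1 = np.abs(x - self.c1)
        d2 = np.abs(x - self.c2)
        p = 2.0 / (self.m - 1.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            u2 = 1.0 / (1.0 + (d2 / d1) ** p)
        u2 = np.where(d2 == 0, 1.0, u2)
        u2 = np.where((d1 == 0) & (d2 > 0), 0.0, u2)
        return u2


def _fcm_objective(x: np.ndarray, centers: np.ndarray, m: float) -> float:
    d = np.abs(x[None, :] - centers[:, None])
    p = 2.0 / (m - 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = d ** (-p)
    inv = np.where(np.isfinite(inv), inv, 0.0)
    denom = inv.sum(axis=0)
    u = np.where(denom > 0, inv / np.where(denom == 0, 1.0, denom), 0.0)
    exact = d == 0
    if exact.any():
        cols = exact.any(axis=0)
        u[:, cols] = exact[:, cols].astype(float)
    return float(np.sum(u**m * d**2))


def fit_fcm2(
    intensities: np.ndarray,
    m: float = 2.0,
    tol: float = 1e-5,
    max_iter: int = 300,
    seed: int | None = None,
) -> FuzzyClusterModel:
    """Fit two fuzzy C-means clusters to a bag of intensities.

    Deterministic: centers initialize at the 25th/75th intensity
    percentiles (``seed`` is accepted for interface symmetry but unused).
    Iterates the standard membership/center updates until the centers
    move less than ``tol``; non-convergence at ``max_iter`` returns the
    model with a warning.  Centers are returned sorted, c1 < c2.
    """
    x = np.asarray(intensities, dtype=np.float64).ravel()
    if x.size < 2 or np.unique(x).size < 2:
        raise DegenerateClusteringError("need at least two distinct intensity values")
    centers = np.percentile(x, [25.0, 75.0])
    if centers[0] == centers[1]:
        lo, hi = float(x.min()), float(x.max())
        centers = np.array([lo, hi], dtype=np.float64)
    p = 2.0 / (m - 1.0)
    history = []
    it = 0
    for it in range(1, max_iter + 1):
        d = np.abs(x[None, :] - centers[:, None])
        with np.errstate(divide="ignore", invalid="ignore"):
            inv = d ** (-p)
        exact = d == 0
        inv = np.where(np.isfinite(inv), inv, 0.0)
        denom = inv.sum(axis=0)
        u = inv / np.where(denom == 0, 1.0, denom)
        if exact.any():
            cols = exact.any(axis=0)
            u[:, cols] = exact[:, cols].astype(float)
        um = u**m
        new_centers = (um @ x) / um.sum(axis=1)
        history.append(float(np.sum(um * d**2)))
        move = float(np.abs(new_centers - centers).max())
        centers = new_centers
        if move < tol:
            break
    else:
        warnings.warn(f"FCM did not converge within {max_iter} iterations")
    if centers[0] == centers[1]:
        raise DegenerateClusteringError("cluster centers collapsed")
    c1, c2 = sorted(float(c) for c in centers)
    return FuzzyClusterModel(
        c1=c1, c2=c2, m=m, iterations=it,
        objective=history[-1], objective_history=tuple(history),
    )


@dataclasses.dataclass
class OneSidedC2Map:
    """High-cluster membership, zeroed where intensity < c2.

    Voxels with intensity exactly at the C2 center are retained ("lower
    than" is read strictly), so the map equals u2 there.
    """

    values: np.ndarray
    c2: float

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if ((v < 0) | (v > 1)).any():
            raise ValueError("one-sided map values must lie in [0, 1]")


def one_sided_map(img: VolumetricImage, model: FuzzyClusterModel) -> OneSidedC2Map:
    """Per-voxel one-sided C2 probability map on the image grid."""
    u2 = model.membership_c2(img.voxels)
    values = np.where(img.voxels >= model.c2, u2, 0.0)
    return OneSidedC2Map(values=values, c2=model.c2)


@dataclasses.dataclass
class QuantResult:
    """The quantitative tenosynovitis measurement for one patient."""

    fraction: float
    roi_voxels: int
    qualifying_voxels: int
    distance_mm: float
    t_low: float
    t_high: float
    empty_roi: bool = False


def tenosynovitis_fraction(
    pmap: OneSidedC2Map,
    roi: MeasurementROI,
    t_low: float,
    t_high: float,
) -> QuantResult:
    """Fraction of ROI voxels with T_L <= p_C2 < T_H (half-open interval)."""
    if not (0.0 <= t_low < t_high <= 1.0):
        raise ValueError("thresholds must satisfy 0 <= T_L < T_H <= 1")
    if pmap.values.shape != roi.mask.shape:
        raise GeometryError("probability map and ROI are on different grids")
    n_roi = int(roi.mask.sum())
    if n_roi == 0:
        return QuantResult(0.0, 0, 0, roi.distance_mm, t_low, t_high, empty_roi=True)
    p = pmap.values[roi.mask]
    qualifying = int(np.count_nonzero((p >= t_low) & (p < t_high)))
    return QuantResult(
        fraction=qualifying / n_roi,
        roi_voxels=n_roi,
        qualifying_voxels=qualifying,
        distance_mm=roi.distance_mm,
        t_low=float(t_low),
        t_high=float(t_high),
    )
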