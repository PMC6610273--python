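"""Synthetic wrist phantoms with ground truth for end-to-end testing.

A phantom emulates the appearance of a contrast-enhanced (T1-Gd,
fat-saturated) wrist MR volume: dark tendon tubes on a brighter synovial
background, bright peritendinous inflammation sheaths of controlled
maximum thickness, carpal bones (with a distinguishable hamate), the
distal radius and ulna converging toward a narrowest inter-bone gap,
thin bright blood vessels, and a skin-bounded hand extent surrounded by
air.  Geometry is topological, not anatomical: ten tendon tubes (six
dorsal, four volar) around an ellipsoidal carpus is all the pipeline
needs.

The module also simulates the two anisotropic clinical acquisitions
(coronal: 2 mm slices + 0.2 mm gap along y; axial: 3 mm slices + 0.3 mm
gap along z) and visual tenosynovitis grades derived from the nominal
sheath thickness of each region (grade 0: none; 1: < 2 mm; 2: 2-5 mm;
3: >= 5 mm), optionally with simulated reader disagreement.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
from scipy.ndimage import distance_transform_edt, gaussian_filter

from . import srr
from .image_model import (
    LABEL_CODES,
    TENDON_REGIONS,
    GeometryError,
    Grid,
    RegionLabelMap,
    ValidationError,
    VisualScoreSheet,
    VolumetricImage,
)

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "AXIAL_THICKNESS_MM",
    "AXIAL_GAP_MM",
    "CORONAL_THICKNESS_MM",
    "CORONAL_GAP_MM",
    "generate_phantom",
    "simulate_acquisition",
    "simulate_visual_scores",
    "grade_from_thickness",
    "measured_sheath_thickness",
    "generate_cohort",
]

# clinical acquisition geometry (mm)
AXIAL_THICKNESS_MM = 3.0
AXIAL_GAP_MM = 0.3
CORONAL_THICKNESS_MM = 2.0
CORONAL_GAP_MM = 0.2

DEFAULT_INTENSITIES = {
    "air": 0.0,
    "synovium": 100.0,
    "tendon": 30.0,
    "bone": 55.0,
    "inflammation": 200.0,
    "vessel": 230.0,
}


@dataclasses.dataclass
class PhantomSpec:
    """Full geometric and photometric description of one synthetic wrist.

    All coordinates are physical mm in the canonical (unposed) frame;
    ``pose_translation``/``pose_scale`` apply a global rigid+scale jitter
    so that atlas registration has real work to do.  ``sheath_thickness``
    maps region name to the nominal maximum inflammation-sheath thickness
    w_r in mm and is the severity dial of the phantom.
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    tendon_xy: Mapping[str, tuple[float, float]]
    tendon_radius_mm: float
    tendon_zrange: tuple[float, float]
    #: gentle in-plane meander of each tendon centerline along z: the
    #: center at height z is xy + amplitude*(sin, cos)(2*pi*z/period + phase)
    tendon_curve_amplitude_mm: float
    tendon_curve_period_mm: float
    tendon_curve_phases: Mapping[str, float]
    sheath_zrange: tuple[float, float]
    hand_center: tuple[float, float]
    hand_semiaxes: tuple[float, float]
    carpal_ellipsoids: Sequence[tuple[tuple[float, float, float], tuple[float, float, float]]]
    hamate_ellipsoid: tuple[tuple[float, float, float], tuple[float, float, float]]
    forearm_bone_radius_mm: float
    forearm_zrange: tuple[float, float]
    forearm_gap_min_mm: float
    forearm_gap_z_mm: float
    forearm_gap_slope: float
    vessels: Sequence[tuple[float, float, float, tuple[float, float]]]
    sheath_thickness: Mapping[str, float] = dataclasses.field(default_factory=dict)
    #: Gaussian point-spread (mm) applied to intensities before noise, making
    #: the truth band-limited like a real acquisition; labels stay crisp
    edge_smoothing_mm: float = 0.4
    intensities: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_INTENSITIES)
    )
    noise_sd: float = 5.0
    seed: int = 0
    pose_translation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    pose_scale: float = 1.0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.spacing):
            raise ValidationError("spacing must be positive")
        ints = self.intensities
        if not (ints["tendon"] < ints["synovium"] < ints["inflammation"]):
            raise ValidationError(
                "intensity ordering tendon < synovium < inflammation required"
            )
        for r, w in self.sheath_thickness.items():
            if r not in TENDON_REGIONS:
                raise ValidationError(f"unknown tendon region {r!r}")
            if w < 0:
                raise ValidationError(f"sheath thickness for {r} must be >= 0")
        if self.pose_scale <= 0:
            raise ValidationError("pose_scale must be > 0")

    @property
    def grid(self) -> Grid:
        return Grid(self.shape, self.spacing)

    def thickness(self, region: str) -> float:
        return float(self.sheath_thickness.get(region, 0.0))

    @classmethod
    def default(
        cls,
        field_mm: float = 48.0,
        spacing_mm: float = 0.5,
        sheath_thickness: Mapping[str, float] | None = None,
        noise_sd: float = 5.0,
        seed: int = 0,
        pose_translation: tuple[float, float, float] = (0.0, 0.0, 0.0),
        pose_scale: float = 1.0,
        n_vessels: int = 2,
    ) -> "PhantomSpec":
        """Canonical wrist layout scaled to a cubic field of view.

        Positions are fixed fractions of the field size so the same
        topology is available at any resolution.
        """
        F = field_mm
        c = F / 2
        n = int(round(F / spacing_mm))
        dorsal_y = c - 0.25 * F
        volar_y = c + 0.25 * F
        tendon_xy = {
            "extensor_I": (c - 0.25 * F, dorsal_y),
            "extensor_II": (c - 0.15 * F, dorsal_y),
            "extensor_III": (c - 0.05 * F, dorsal_y),
            "extensor_IV": (c + 0.05 * F, dorsal_y),
            "extensor_V": (c + 0.15 * F, dorsal_y),
            "extensor_VI": (c + 0.25 * F, dorsal_y),
            "flexor_1": (c - 0.20 * F, volar_y),
            "flexor_2": (c - 0.067 * F, volar_y),
            "flexor_3": (c + 0.067 * F, volar_y),
            "flexor_4": (c + 0.20 * F, volar_y),
        }
        carpal = [
            ((c - 0.17 * F, c, 0.58 * F), (0.08 * F, 0.07 * F, 0.10 * F)),
            ((c, c, 0.58 * F), (0.08 * F, 0.07 * F, 0.10 * F)),
            ((c + 0.17 * F, c, 0.58 * F), (0.08 * F, 0.07 * F, 0.10 * F)),
        ]
        hamate = ((c + 0.12 * F, c + 0.06 * F, 0.75 * F), (0.07 * F, 0.06 * F, 0.09 * F))
        vessel_hosts = ["extensor_II", "flexor_2", "extensor_V", "flexor_4"]
        vessels = []
        for host in vessel_hosts[: max(0, n_vessels)]:
            x, y = tendon_xy[host]
            vessels.append((x + 1.5 + 1.2, y, 0.6, (0.15 * F, 0.85 * F)))
        phases = {r: 2 * np.pi * i / len(TENDON_REGIONS) for i, r in enumerate(TENDON_REGIONS)}
        return cls(
            shape=(n, n, n),
            spacing=(spacing_mm,) * 3,
            tendon_xy=tendon_xy,
            tendon_radius_mm=1.5,
            tendon_zrange=(0.04 * F, 0.96 * F),
            tendon_curve_amplitude_mm=0.025 * F,
            tendon_curve_period_mm=2.0 * F,
            tendon_curve_phases=phases,
            sheath_zrange=(0.25 * F, 0.73 * F),
            hand_center=(c, c),
            hand_semiaxes=(0.44 * F, 0.33 * F),
            carpal_ellipsoids=carpal,
            hamate_ellipsoid=hamate,
            forearm_bone_radius_mm=0.085 * F,
            forearm_zrange=(0.0, 0.42 * F),
            forearm_gap_min_mm=0.04 * F,
            forearm_gap_z_mm=0.21 * F,
            forearm_gap_slope=0.35,
            vessels=vessels,
            sheath_thickness=dict(sheath_thickness or {}),
            noise_sd=noise_sd,
            seed=seed,
            pose_translation=pose_translation,
            pose_scale=pose_scale,
        )


@dataclasses.dataclass
class PhantomTruth:
    """A generated phantom plus everything a test needs as ground truth."""

    image: VolumetricImage
    labels: RegionLabelMap
    inflammation: np.ndarray  # bool mask, disjoint from tendon and bone labels
    sheath_thickness: Mapping[str, float]  # nominal per-region max thickness (mm)
    spec: PhantomSpec


def _canonical_coords(spec: PhantomSpec):
    """Open-grid physical coordinates in the canonical (unposed) frame."""
    g = spec.grid
    center = [g.origin[a] + 0.5 * g.spacing[a] * (g.shape[a] - 1) for a in range(3)]
    out = []
    for a in range(3):
        p = g.axis_coords(a)
        q = center[a] + (p - center[a] - spec.pose_translation[a]) / spec.pose_scale
        shape = [1, 1, 1]
        shape[a] = -1
        out.append(q.reshape(shape))
    return out


def generate_phantom(spec: PhantomSpec) -> PhantomTruth:
    """Voxelize a phantom spec: intensities, labels, inflammation mask.

    Deterministic given ``spec.seed``.  Intensities are region mean plus
    Gaussian noise, clipped at zero.  Raises GeometryError if tendon
    tubes overlap.
    """
    X, Y, Z = _canonical_coords(spec)
    ints = spec.intensities

    hx, hy = spec.hand_center
    ax, by = spec.hand_semiaxes
    hand = np.broadcast_to(
        ((X - hx) / ax) ** 2 + ((Y - hy) / by) ** 2 <= 1.0, spec.shape
    ).copy()

    # tendon tubes with a gentle in-plane meander along z; pairwise overlap
    # is checked analytically (the offset difference of two meandering
    # centerlines has constant magnitude 2A|sin(dphi/2)|)
    names = list(spec.tendon_xy)
    r_t = spec.tendon_radius_mm
    A = spec.tendon_curve_amplitude_mm
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            pi = np.array(spec.tendon_xy[names[i]])
            pj = np.array(spec.tendon_xy[names[j]])
            dphi = spec.tendon_curve_phases.get(names[i], 0.0) - spec.tendon_curve_phases.get(
                names[j], 0.0
            )
            closest = np.linalg.norm(pi - pj) - 2 * A * abs(np.sin(dphi / 2))
            if closest < 2 * r_t:
                raise GeometryError(f"tendon tubes {names[i]} and {names[j]} overlap")
    z_lo, z_hi = spec.tendon_zrange
    in_tendon_z = (Z >= z_lo) & (Z <= z_hi)

    def _tendon_d2(name: str) -> np.ndarray:
        tx, ty = spec.tendon_xy[name]
        theta = 2 * np.pi * Z / spec.tendon_curve_period_mm + spec.tendon_curve_phases.get(
            name, 0.0
        )
        cx = tx + A * np.sin(theta)
        cy = ty + A * np.cos(theta)
        return (X - cx) ** 2 + (Y - cy) ** 2

    tendon_masks = {
        name: (_tendon_d2(name) <= r_t**2) & in_tendon_z for name in names
    }

    # forearm bones: two tubes whose gap narrows linearly toward z = gap_z
    rb = spec.forearm_bone_radius_mm
    fz_lo, fz_hi = spec.forearm_zrange
    halfgap = 0.5 * (
        spec.forearm_gap_min_mm + spec.forearm_gap_slope * np.abs(Z - spec.forearm_gap_z_mm)
    )
    in_forearm_z = (Z >= fz_lo) & (Z <= fz_hi)
    x_radius = hx - halfgap - rb
    x_ulna = hx + halfgap + rb
    radius_mask = ((X - x_radius) ** 2 + (Y - hy) ** 2 <= rb**2) & in_forearm_z
    ulna_mask = ((X - x_ulna) ** 2 + (Y - hy) ** 2 <= rb**2) & in_forearm_z

    def ellipsoid(center, semi):
        return (
            ((X - center[0]) / semi[0]) ** 2
            + ((Y - center[1]) / semi[1]) ** 2
            + ((Z - center[2]) / semi[2]) ** 2
            <= 1.0
        )

    carpal_mask = np.zeros(spec.shape, dtype=bool)
    for center, semi in spec.carpal_ellipsoids:
        carpal_mask |= ellipsoid(center, semi)
    hamate_mask = ellipsoid(*spec.hamate_ellipsoid)
    carpal_mask &= ~hamate_mask

    labels = np.zeros(spec.shape, dtype=np.int16)
    labels[carpal_mask] = LABEL_CODES["carpal_bones"]
    labels[hamate_mask] = LABEL_CODES["hamate"]
    labels[radius_mask] = LABEL_CODES["radius"]
    labels[ulna_mask] = LABEL_CODES["ulna"]
    bone_mask = labels > 0
    for name, m in tendon_masks.items():
        labels[m & ~bone_mask] = LABEL_CODES[name]
    tendon_union = np.zeros(spec.shape, dtype=bool)
    for m in tendon_masks.values():
        tendon_union |= m

    # inflammation sheaths: annulus of thickness w_r around each tendon
    s_lo, s_hi = spec.sheath_zrange
    in_sheath_z = (Z >= s_lo) & (Z <= s_hi)
    inflammation = np.zeros(spec.shape, dtype=bool)
    for name in TENDON_REGIONS:
        w = spec.thickness(name)
        if w <= 0 or name not in spec.tendon_xy:
            continue
        inflammation |= (_tendon_d2(name) <= (r_t + w) ** 2) & in_sheath_z
    inflammation &= hand & ~tendon_union & ~bone_mask & (labels == 0)

    vessel_mask = np.zeros(spec.shape, dtype=bool)
    for vx, vy, vr, (vz_lo, vz_hi) in spec.vessels:
        vessel_mask |= (
            ((X - vx) ** 2 + (Y - vy) ** 2 <= vr**2) & (Z >= vz_lo) & (Z <= vz_hi)
        )
    vessel_mask &= hand & ~tendon_union & ~bone_mask

    vox = np.full(spec.shape, ints["air"], dtype=np.float64)
    vox[hand] = ints["synovium"]
    vox[bone_mask] = ints["bone"]
    vox[tendon_union] = ints["tendon"]
    vox[inflammation] = ints["inflammation"]
    vox[vessel_mask] = ints["vessel"]
    if spec.edge_smoothing_mm > 0:
        vox = gaussian_filter(vox, sigma=[spec.edge_smoothing_mm / s for s in spec.spacing])
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        vox = np.clip(vox + rng.normal(0.0, spec.noise_sd, size=vox.shape), 0.0, None)

    image = VolumetricImage(vox, spec.spacing, plane="isotropic-SRR")
    label_map = RegionLabelMap(labels, spec.spacing)
    return PhantomTruth(
        image=image,
        labels=label_map,
        inflammation=inflammation,
        sheath_thickness={r: spec.thickness(r) for r in TENDON_REGIONS},
        spec=spec,
    )


def measured_sheath_thickness(truth: PhantomTruth, region: str) -> float:
    """Maximum radial extent (mm) of the inflammation mask around one tendon.

    Inflammation voxels are assigned to their nearest tendon; the result
    is the largest distance from an assigned voxel to that tendon's
    surface.  Zero if no inflammation is assigned to the region.
    """
    code = LABEL_CODES[region]
    lab = truth.labels.labels
    spacing = truth.labels.spacing
    dists = {}
    for r in TENDON_REGIONS:
        m = lab == LABEL_CODES[r]
        if m.any():
            dists[r] = distance_transform_edt(~m, sampling=spacing)
    if region not in dists:
        return 0.0
    stack = np.stack([dists[r] for r in dists])
    names = list(dists)
    nearest = np.argmin(stack, axis=0)
    own = names.index(region)
    sel = truth.inflammation & (nearest == own)
    if not sel.any():
        return 0.0
    return float(dists[region][sel].max())


def simulate_acquisition(truth: PhantomTruth, plane: str) -> VolumetricImage:
    """Simulate one anisotropic clinical scan from the high-resolution truth.

    Each output slice is the box average of the truth over that slice's
    thickness window; slices are sampled at thickness+gap spacing (2.2 mm
    coronal along y, 3.3 mm axial along z).  The in-plane grid of the
    truth is preserved.
    """
    if plane == "axial":
        axis, thickness, gap = 2, AXIAL_THICKNESS_MM, AXIAL_GAP_MM
    elif plane == "coronal":
        axis, thickness, gap = 1, CORONAL_THICKNESS_MM, CORONAL_GAP_MM
    else:
        raise ValueError(f"plane must be 'axial' or 'coronal', got {plane!r}")
    g = truth.image.grid
    if g.spacing[axis] >= thickness + gap:
        raise GeometryError("truth grid must be finer than the through-slice spacing")
    step = thickness + gap
    lo, hi = g.extent(axis)
    n_slices = int(np.floor((hi - lo - thickness) / step)) + 1
    if n_slices < 1:
        raise GeometryError("truth extent shorter than one slice")
    slice0 = lo + thickness / 2

    shape = list(g.shape)
    shape[axis] = n_slices
    spacing = list(g.spacing)
    spacing[axis] = step
    origin = list(g.origin)
    origin[axis] = slice0
    mat = srr.axis_average_matrix(
        g.shape[axis], g.spacing[axis], g.origin[axis],
        n_slices, step, slice0, thickness,
    )
    vox = srr._apply_1d(mat, truth.image.voxels, axis)
    return VolumetricImage(
        vox, tuple(spacing), tuple(origin), plane=plane, slice_thickness=thickness
    )


def grade_from_thickness(w_mm: float) -> int:
    """Visual grade from maximum sheath thickness: 0 none, <2, 2-5, >=5 mm."""
    if w_mm < 0:
        raise ValidationError(f"negative sheath thickness {w_mm}")
    if w_mm == 0:
        return 0
    if w_mm < 2.0:
        return 1
    if w_mm < 5.0:
        return 2
    return 3


def simulate_visual_scores(
    truth: PhantomTruth,
    reader_noise: bool = False,
    noise_prob: float = 0.1,
    seed: int | None = None,
) -> VisualScoreSheet:
    """Derive the visual score sheet from the nominal sheath thicknesses.

    With ``reader_noise`` each of two simulated readers independently
    perturbs the grade by +-1 with probability ``noise_prob`` (clipped to
    [0, 3]); the reported grade is the two-reader mean, so grades land on
    the 0.5 grid just like averaged human scores.
    """
    grades = {}
    rng = np.random.default_rng(seed)
    for r in TENDON_REGIONS:
        g = grade_from_thickness(truth.sheath_thickness.get(r, 0.0))
        if reader_noise:
            readings = []
            for _ in range(2):
                delta = 0
                if rng.random() < noise_prob:
                    delta = int(rng.choice([-1, 1]))
                readings.append(float(np.clip(g + delta, 0, 3)))
            grades[r] = sum(readings) / 2
        else:
            grades[r] = float(g)
    return VisualScoreSheet(grades)


def _vmax_category(v_max: float) -> int:
    if v_max == 0:
        return 0
    if v_max <= 1:
        return 1
    return 2


def generate_cohort(
    n: int,
    severity_mix: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3),
    seed: int = 0,
    field_mm: float = 48.0,
    spacing_mm: float = 0.5,
    noise_sd: float = 5.0,
    reader_noise: bool = False,
    pose_jitter: bool = True,
) -> list[tuple[PhantomTruth, VisualScoreSheet]]:
    """Generate a cohort of phantoms spanning the three severity categories.

    Category counts follow ``severity_mix`` by largest remainder; each
    phantom draws its own sheath thicknesses so its maximum visual grade
    V_max lands in the requested category (0: V_max = 0; 1: 0 < V_max <= 1;
    2: 1 < V_max <= 3).  Deterministic given ``seed``.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    mix = np.asarray(severity_mix, dtype=float)
    if mix.shape != (3,) or abs(mix.sum() - 1.0) > 1e-9 or (mix < 0).any():
        raise ValueError("severity_mix must be three non-negative proportions summing to 1")
    raw = mix * n
    counts = np.floor(raw).astype(int)
    remainder = raw - counts
    for i in np.argsort(-remainder)[: n - counts.sum()]:
        counts[i] += 1
    categories = np.repeat(np.arange(3), counts)
    rng = np.random.default_rng(seed)
    rng.shuffle(categories)

    cohort = []
    for cat in categories:
        sub = int(rng.integers(0, 2**31 - 1))
        sub_rng = np.random.default_rng(sub)
        thickness: dict[str, float] = {}
        if cat == 1:
            k = int(sub_rng.integers(1, 4))
            for r in sub_rng.choice(TENDON_REGIONS, size=k, replace=False):
                thickness[str(r)] = float(sub_rng.uniform(0.8, 1.9))
        elif cat == 2:
            main = str(sub_rng.choice(TENDON_REGIONS))
            thickness[main] = float(sub_rng.uniform(2.2, 5.8))
            for r in sub_rng.choice(TENDON_REGIONS, size=int(sub_rng.integers(0, 3)), replace=False):
                thickness.setdefault(str(r), float(sub_rng.uniform(0.8, 1.9)))
        pose_t = tuple(sub_rng.uniform(-1.5, 1.5, size=3)) if pose_jitter else (0.0, 0.0, 0.0)
        pose_s = float(sub_rng.uniform(0.96, 1.04)) if pose_jitter else 1.0
        spec = PhantomSpec.default(
            field_mm=field_mm,
            spacing_mm=spacing_mm,
            sheath_thickness=thickness,
            noise_sd=noise_sd,
            seed=sub,
            pose_translation=pose_t,
            pose_scale=pose_s,
        )
        truth = generate_phantom(spec)
        sheet = simulate_visual_scores(truth, reader_noise=reader_noise, seed=sub + 1)
        cohort.append((truth, sheet))
    return cohort
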