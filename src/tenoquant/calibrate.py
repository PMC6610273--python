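"""Parameter calibration against ordinal visual scores.

The measurement has three free parameters: the ROI shell distance D and
the membership window (T_L, T_H).  They are calibrated by exhaustive
grid search — D over {1..6} mm, thresholds over the 0.01 grid with
T_L < T_H — maximizing the Pearson correlation between the total visual
tenosynovitis score and the total quantitative measurement over a
training set.  Because severe tenosynovitis is rare, the training set is
stratified: patients are binned by their maximum per-region grade V_max
(0; (0,1]; (1,3]) and sampled uniformly within each bin.

The threshold sweep operates on per-patient membership histograms, so
after one histogramming pass per (patient, D) its cost is independent of
image size.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .atlas_seg import AtlasSet
from .image_model import VisualScoreSheet
from .tendon_seg import precision_recall

__all__ = [
    "ParameterSet",
    "UndefinedCorrelationError",
    "categorize_vmax",
    "build_cohort_table",
    "sample_training_set",
    "pearson",
    "HistogramFractionMeasure",
    "grid_search",
    "loocv_atlas",
]

DEFAULT_DISTANCES_MM = (1.0, 2.0, 3.0, 4.0, 5.0, 6.0)
THRESHOLD_STEP = 0.01


class UndefinedCorrelationError(ValueError):
    """Correlation cannot be computed (constant input or too few points)."""


@dataclasses.dataclass(frozen=True)
class ParameterSet:
    """A calibrated (D, T_L, T_H) triple and the training correlation."""

    distance_mm: float
    t_low: float
    t_high: float
    pearson_r: float = float("nan")

    def __post_init__(self) -> None:
        if not self.t_low < self.t_high:
            raise ValueError("T_L must be strictly below T_H")


def categorize_vmax(scores: VisualScoreSheet) -> int:
    """Severity category from V_max: 0 (= 0), 1 (0 < V <= 1), 2 (1 < V <= 3)."""
    v = scores.v_max
    if v == 0:
        return 0
    if v <= 1:
        return 1
    return 2


def build_cohort_table(
    scores: Mapping[str, VisualScoreSheet] | Sequence[VisualScoreSheet],
) -> pd.DataFrame:
    """Per-patient table: total visual score, V_max, severity category."""
    if not isinstance(scores, Mapping):
        scores = {f"p{i:03d}": s for i, s in enumerate(scores)}
    rows = [
        {
            "patient_id": pid,
            "total_score": sheet.total,
            "v_max": sheet.v_max,
            "category": categorize_vmax(sheet),
        }
        for pid, sheet in scores.items()
    ]
    return pd.DataFrame(rows).set_index("patient_id")


def sample_training_set(
    cohort: pd.DataFrame,
    n_per_category: int = 20,
    seed: int = 0,
) -> tuple[list, list]:
    """Stratified training split: n patients from each severity category.

    Sampling is uniform without replacement within each category and
    deterministic given the seed; the validation set is the complement.
    """
    rng = np.random.default_rng(seed)
    train: list = []
    for cat in (0, 1, 2):
        members = sorted(cohort.index[cohort["category"] == cat].tolist())
        if len(members) < n_per_category:
            raise ValueError(
                f"severity category {cat} has only {len(members)} patients, "
                f"need {n_per_category}"
            )
        chosen = rng.choice(len(members), size=n_per_category, replace=False)
        train.extend(members[i] for i in sorted(chosen))
    train_set = set(train)
    validation = [pid for pid in cohort.index if pid not in train_set]
    return train, validation


def pearson(x, y) -> tuple[float, float]:
    """Product-moment correlation with two-sided p from the t transform."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise UndefinedCorrelationError("need two equal-length vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("correlation undefined for constant input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


class HistogramFractionMeasure:
    """Image-size-independent fraction measure backed by p_C2 histograms.

    Constructed from a callable returning the one-sided C2 membership
    values inside a patient's ROI at a given D.  Values are binned at the
    threshold step, so every window fraction on the threshold grid is an
    exact count ratio.  Each (patient, D) is histogrammed once and cached.
    """

    def __init__(
        self,
        p_values: Callable[[object, float], np.ndarray],
        step: float = THRESHOLD_STEP,
    ):
        self._p_values = p_values
        self.step = step
        self.n_bins = int(round(1.0 / step))
        self._cache: dict[tuple, tuple[np.ndarray, int]] = {}

    def fraction_table(self, patient_id, distance_mm: float):
        """Cumulative counts C with C[k] = #{p < k*step}, and the ROI size."""
        key = (patient_id, float(distance_mm))
        if key not in self._cache:
            p = np.asarray(self._p_values(patient_id, distance_mm), dtype=float)
            # round before flooring so values on a bin edge land in the upper bin
            bins = np.minimum(
                np.floor(np.round(p / self.step, 9)).astype(np.int64), self.n_bins
            )
            counts = np.bincount(bins, minlength=self.n_bins + 1)
            cum = np.concatenate([[0], np.cumsum(counts)])
            self._cache[key] = (cum, int(p.size))
        return self._cache[key]

    def __call__(self, patient_id, distance_mm, t_low, t_high) -> float:
        cum, n = self.fraction_table(patient_id, distance_mm)
        if n == 0:
            return 0.0
        i = int(round(t_low / self.step))
        j = int(round(t_high / self.step))
        return float(cum[j] - cum[i]) / n


def grid_search(
    measure,
    training: pd.DataFrame,
    distances_mm: Sequence[float] = DEFAULT_DISTANCES_MM,
    step: float = THRESHOLD_STEP,
) -> ParameterSet:
    """Exhaustive (D, T_L, T_H) search maximizing Pearson r on training.

    ``measure`` is called as measure(patient_id, D, T_L, T_H) -> fraction;
    a HistogramFractionMeasure enables the vectorized sweep in which all
    threshold windows for one D are evaluated from cached histograms.
    Ties resolve to the lexicographically smallest (D, T_L, T_H).
    """
    y = training["total_score"].to_numpy(dtype=float)
    if np.unique(y).size < 2:
        raise UndefinedCorrelationError("training set has a single distinct visual total")
    pids = list(training.index)
    n_bins = int(round(1.0 / step))
    pairs = [(i, j) for i in range(n_bins + 1) for j in range(i + 1, n_bins + 1)]

    best = None  # (r, D, t_low, t_high)
    any_defined = False
    yc = y - y.mean()
    sy = float(np.sqrt(np.sum(yc**2)))
    for D in distances_mm:
        if hasattr(measure, "fraction_table"):
            tables = [measure.fraction_table(pid, D) for pid in pids]
            cums = np.stack([c for c, _ in tables]).astype(float)
            sizes = np.array([max(n, 1) for _, n in tables], dtype=float)
            # fractions for every window: (patients, pairs)
            i_idx = np.array([p[0] for p in pairs])
            j_idx = np.array([p[1] for p in pairs])
            M = (cums[:, j_idx] - cums[:, i_idx]) / sizes[:, None]
            Mc = M - M.mean(axis=0)
            sx = np.sqrt(np.sum(Mc**2, axis=0))
            with np.errstate(invalid="ignore", divide="ignore"):
                r = (yc @ Mc) / (sx * sy)
            valid = sx > 0
            any_defined |= bool(valid.any())
            for k in np.flatnonzero(valid):
                rk = float(r[k])
                if best is None or rk > best[0]:
                    best = (rk, D, i_idx[k] * step, j_idx[k] * step)
        else:
            for i, j in pairs:
                tl, th = i * step, j * step
                vals = np.array([measure(pid, D, tl, th) for pid in pids], dtype=float)
                if np.ptp(vals) == 0:
                    continue
                any_defined = True
                rk, _ = pearson(vals, y)
                if best is None or rk > best[0]:
                    best = (rk, D, tl, th)
    if best is None or not any_defined:
        raise UndefinedCorrelationError("all grid points yielded undefined correlations")
    r, D, tl, th = best
    return ParameterSet(distance_mm=float(D), t_low=float(round(tl, 10)),
                        t_high=float(round(th, 10)), pearson_r=float(r))


def loocv_atlas(atlas: AtlasSet, segmenter) -> dict:
    """Leave-one-out cross-validation of tendon segmentation accuracy.

    Each atlas case in turn serves as the target, segmented with the
    remaining cases; precision/recall against the held-out labels are
    summarized as per-region medians and IQRs.  Runs that produce an
    empty segmentation for a region count as failures for that region
    and are excluded from the medians.

    ``segmenter(target_image, atlas_subset) -> RegionLabelMap`` is the
    pipeline handle under evaluation.
    """
    from .image_model import TENDON_REGIONS, LABEL_CODES

    if len(atlas) < 2:
        raise ValueError("leave-one-out needs at least two atlas cases")
    per_region: dict[str, dict] = {
        r: {"precision": [], "recall": [], "failures": 0, "n": 0} for r in TENDON_REGIONS
    }
    for i, (img, truth_lab) in enumerate(atlas.entries):
        rest = AtlasSet(
            [e for j, e in enumerate(atlas.entries) if j != i],
            handedness=atlas.handedness,
        )
        auto = segmenter(img, rest)
        for region in TENDON_REGIONS:
            code = LABEL_CODES[region]
            manual = truth_lab.labels == code
            if not manual.any():
                continue
            stats_r = per_region[region]
            stats_r["n"] += 1
            auto_mask = auto.labels == code
            if not auto_mask.any():
                stats_r["failures"] += 1
                continue
            prec, rec = precision_recall(auto_mask, manual)
            stats_r["precision"].append(prec)
            stats_r["recall"].append(rec)

    def _summary(vals):
        if not vals:
            return {"median": None, "iqr": (None, None)}
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        return {"median": float(med), "iqr": (float(q1), float(q3))}

    return {
        region: {
            "precision": _summary(d["precision"]),
            "recall": _summary(d["recall"]),
            "failures": d["failures"],
            "n": d["n"],
        }
        for region, d in per_region.items()
    }
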