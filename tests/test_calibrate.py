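import numpy as np
import pandas as pd
import pytest

from tenoquant.calibrate import (
    HistogramFractionMeasure,
    ParameterSet,
    UndefinedCorrelationError,
    build_cohort_table,
    categorize_vmax,
    grid_search,
    loocv_atlas,
    pearson,
    sample_training_set,
)
from tenoquant.image_model import TENDON_REGIONS, VisualScoreSheet


def _sheet(**grades):
    g = {r: 0.0 for r in TENDON_REGIONS}
    g.update(grades)
    return VisualScoreSheet(g)


class TestCategorize:
    @pytest.mark.parametrize("vmax,cat", [
        (0.0, 0), (0.5, 1), (1.0, 1), (1.5, 2), (3.0, 2)])
    def test_boundaries(self, vmax, cat):
        assert categorize_vmax(_sheet(flexor_1=vmax)) == cat


class TestCohortTable:
    def test_columns_and_values(self):
        sheets = {"a": _sheet(flexor_1=2.0, flexor_2=1.0), "b": _sheet()}
        t = build_cohort_table(sheets)
        assert t.loc["a", "total_score"] == 3.0
        assert t.loc["a", "v_max"] == 2.0
        assert t.loc["a", "category"] == 2
        assert t.loc["b", "category"] == 0

    def test_sequence_input_gets_ids(self):
        t = build_cohort_table([_sheet(), _sheet(flexor_1=1.0)])
        assert list(t.index) == ["p000", "p001"]


class TestSampleTrainingSet:
    def _cohort(self, n_per_cat=6):
        sheets = {}
        for c, vmax in [(0, 0.0), (1, 1.0), (2, 2.0)]:
            for i in range(n_per_cat):
                sheets[f"c{c}_{i}"] = _sheet(flexor_1=vmax)
        return build_cohort_table(sheets)

    def test_stratified_counts(self):
        cohort = self._cohort()
        train, val = sample_training_set(cohort, n_per_category=4, seed=1)
        assert len(train) == 12 and len(val) == 6
        got = cohort.loc[train, "category"].value_counts()
        assert all(got[c] == 4 for c in (0, 1, 2))

    def test_partition(self):
        cohort = self._cohort()
        train, val = sample_training_set(cohort, n_per_category=3, seed=2)
        assert set(train) | set(val) == set(cohort.index)
        assert not set(train) & set(val)

    def test_deterministic(self):
        cohort = self._cohort()
        a = sample_training_set(cohort, n_per_category=3, seed=5)
        b = sample_training_set(cohort, n_per_category=3, seed=5)
        assert a == b

    def test_insufficient_category_raises(self):
        cohort = self._cohort(n_per_cat=2)
        with pytest.raises(ValueError):
            sample_training_set(cohort, n_per_category=3)


class TestPearson:
    def test_perfect_linear(self):
        r, p = pearson([1, 2, 3, 4], [2, 4, 6, 8])
        assert r == pytest.approx(1.0)

    def test_matches_manual_formula(self, rng):
        x = rng.normal(size=30)
        y = 0.4 * x + rng.normal(size=30)
        r, _ = pearson(x, y)
        xc, yc = x - x.mean(), y - y.mean()
        manual = float(np.sum(xc * yc) / np.sqrt(np.sum(xc**2) * np.sum(yc**2)))
        assert r == pytest.approx(manual, rel=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            pearson([1, 1, 1], [1, 2, 3])

    def test_too_short_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            pearson([1, 2], [3, 4])


class TestHistogramFractionMeasure:
    def test_matches_direct_count(self, rng):
        pools = {"a": rng.uniform(0, 1, 997), "b": rng.uniform(0, 1, 503)}
        hm = HistogramFractionMeasure(lambda pid, D: pools[pid])
        for pid in pools:
            for tl, th in [(0.0, 1.0), (0.25, 0.75), (0.82, 0.94), (0.99, 1.0)]:
                direct = np.mean((pools[pid] >= tl) & (pools[pid] < th))
                assert hm(pid, 3.0, tl, th) == pytest.approx(direct)

    def test_grid_edge_values_bin_upward(self):
        # a value exactly at T lands in [T, ...), not below it
        hm = HistogramFractionMeasure(lambda pid, D: np.array([0.82]))
        assert hm("p", 1.0, 0.82, 0.94) == 1.0
        assert hm("p", 1.0, 0.80, 0.82) == 0.0

    def test_value_one_counts_in_top_window(self):
        hm = HistogramFractionMeasure(lambda pid, D: np.array([1.0]))
        assert hm("p", 1.0, 0.99, 1.0) == 0.0  # 1.0 is excluded (p < 1.0)

    def test_cache_prevents_recomputation(self):
        calls = []

        def pv(pid, D):
            calls.append((pid, D))
            return np.array([0.5])

        hm = HistogramFractionMeasure(pv)
        hm("p", 3.0, 0.1, 0.9)
        hm("p", 3.0, 0.2, 0.8)
        hm("p", 4.0, 0.1, 0.9)
        assert calls == [("p", 3.0), ("p", 4.0)]

    def test_empty_pool_gives_zero(self):
        hm = HistogramFractionMeasure(lambda pid, D: np.array([]))
        assert hm("p", 3.0, 0.1, 0.9) == 0.0


class TestGridSearch:
    def _training(self, scores):
        sheets = {f"p{i}": _sheet(flexor_1=s) for i, s in enumerate(scores)}
        return build_cohort_table(sheets)

    def test_planted_optimum_recovered(self):
        # patients' p-values concentrated in [0.4, 0.6) at D=2 only,
        # proportional to their visual scores
        scores = [0.0, 1.0, 2.0, 3.0]
        training = self._training(scores)

        def pv(pid, D):
            i = int(pid[1:])
            n_in = int(100 * scores[i]) if D == 2.0 else 0
            return np.concatenate([np.full(n_in, 0.5), np.full(400 - n_in, 0.05)])

        hm = HistogramFractionMeasure(pv)
        best = grid_search(hm, training, distances_mm=(1.0, 2.0, 3.0))
        assert best.distance_mm == 2.0
        assert best.t_low <= 0.5 < best.t_high
        assert best.pearson_r == pytest.approx(1.0)

    def test_tie_break_lexicographic(self):
        # identical data for every D: smallest D and window must win
        training = self._training([0.0, 1.0, 2.0])

        def pv(pid, D):
            i = int(pid[1:])
            return np.concatenate([np.full(i * 10, 0.5), np.full(30, 0.05)])

        hm = HistogramFractionMeasure(pv)
        best = grid_search(hm, training, distances_mm=(1.0, 2.0))
        assert best.distance_mm == 1.0

    def test_generic_measure_agrees_with_histogram(self):
        scores = [0.0, 1.0, 3.0]
        training = self._training(scores)
        pools = {
            f"p{i}": np.concatenate(
                [np.full(20 * int(s), 0.45), np.full(100, 0.05)])
            for i, s in enumerate(scores)
        }
        hm = HistogramFractionMeasure(lambda pid, D: pools[pid])

        def generic(pid, D, tl, th):
            p = pools[pid]
            return float(np.mean((p >= tl) & (p < th)))

        a = grid_search(hm, training, distances_mm=(3.0,))
        b = grid_search(generic, training, distances_mm=(3.0,))
        assert (a.distance_mm, a.t_low, a.t_high) == (b.distance_mm, b.t_low, b.t_high)
        assert a.pearson_r == pytest.approx(b.pearson_r)

    def test_constant_scores_rejected(self):
        training = self._training([1.0, 1.0, 1.0])
        hm = HistogramFractionMeasure(lambda pid, D: np.array([0.5]))
        with pytest.raises(UndefinedCorrelationError):
            grid_search(hm, training)

    def test_json_serializable_output(self):
        import json

        training = self._training([0.0, 1.0, 2.0])
        hm = HistogramFractionMeasure(
            lambda pid, D: np.concatenate(
                [np.full(10 * int(pid[1:]), 0.5), np.full(40, 0.05)]))
        best = grid_search(hm, training, distances_mm=(1.0,))
        json.dumps(best.__dict__)  # must not raise


class TestParameterSet:
    def test_invalid_window_rejected(self):
        with pytest.raises(ValueError):
            ParameterSet(distance_mm=3.0, t_low=0.9, t_high=0.8)


class TestLoocvAtlas:
    def test_perfect_segmenter_scores_one(self, small_truth, clean_truth):
        from tenoquant.atlas_seg import AtlasSet

        atlas = AtlasSet([
            (small_truth.image, small_truth.labels),
            (clean_truth.image, clean_truth.labels),
        ])
        # oracle segmenter: returns the held-out case's own truth
        truths = {
            id(small_truth.image): small_truth.labels,
            id(clean_truth.image): clean_truth.labels,
        }
        report = loocv_atlas(atlas, lambda img, rest: truths[id(img)])
        for region in ("flexor_1", "extensor_VI"):
            assert report[region]["precision"]["median"] == 1.0
            assert report[region]["recall"]["median"] == 1.0
            assert report[region]["failures"] == 0

    def test_empty_segmenter_counts_failures(self, small_truth, clean_truth):
        from tenoquant.atlas_seg import AtlasSet
        from tenoquant.image_model import RegionLabelMap

        atlas = AtlasSet([
            (small_truth.image, small_truth.labels),
            (clean_truth.image, clean_truth.labels),
        ])

        def empty(img, rest):
            return RegionLabelMap(
                np.zeros(img.voxels.shape, dtype=np.int16), img.spacing, img.origin)

        report = loocv_atlas(atlas, empty)
        assert report["flexor_1"]["failures"] == report["flexor_1"]["n"] > 0
        assert report["flexor_1"]["precision"]["median"] is None

    def test_single_case_rejected(self, small_truth):
        from tenoquant.atlas_seg import AtlasSet

        atlas = AtlasSet([(small_truth.image, small_truth.labels)])
        with pytest.raises(ValueError):
            loocv_atlas(atlas, lambda img, rest: None)
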