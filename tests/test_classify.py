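import numpy as np
import pandas as pd
import pytest

from emmap import (
    FeatureSpec,
    LabeledFeatures,
    accuracy_table,
    assemble_features,
    class_count,
    knn_loso_cv,
)
from emmap.classify import CVError, SpecError, _ancestor_index
from emmap.measures import ParameterError


class TestFeatureSpec:
    @pytest.mark.parametrize(
        "levels, measures, dim, ncl",
        [
            ((1, 2, 3), ("ApEn", "FuzEn", "LLE"), 9, 16),
            ((1, 2), ("ApEn", "FuzEn", "LLE"), 6, 16),
            ((2, 3), ("ApEn", "FuzEn", "LLE"), 6, 8),
            ((1,), ("ApEn",), 1, 16),
            ((4,), ("LLE",), 1, 2),
            ((2, 3, 4), ("FuzEn",), 3, 8),
        ],
    )
    def test_dimension_and_class_count(self, levels, measures, dim, ncl):
        spec = FeatureSpec(levels=levels, measures=measures)
        assert spec.n_features == dim
        assert spec.n_classes() == ncl

    def test_class_count_formula(self):
        assert [class_count(lx) for lx in (1, 2, 3, 4)] == [16, 8, 4, 2]

    def test_name_round_trip(self):
        for name in ("set64_ApEn", "set64_128_256_ApEn_FuzEn_LLE", "set128_256_FuzEn"):
            assert FeatureSpec.from_name(name).name() == name

    @pytest.mark.parametrize(
        "levels, measures",
        [
            ((1, 3), ("ApEn",)),          # not contiguous
            ((1, 2, 3, 4), ("ApEn",)),    # too many levels
            ((5,), ("ApEn",)),            # level 5 is the whole series
            ((1,), ()),                   # no measures
            ((1,), ("SampEn",)),          # unknown measure
        ],
    )
    def test_invalid_specs_rejected(self, levels, measures):
        with pytest.raises(SpecError):
            FeatureSpec(levels=levels, measures=measures)

    def test_ancestor_indexing(self):
        # class 5 at level 1 sits inside cell 3 at level 2 and cell 2 at level 3
        assert _ancestor_index(5, 1, 1) == 5
        assert _ancestor_index(5, 1, 2) == 3
        assert _ancestor_index(5, 1, 3) == 2
        assert _ancestor_index(16, 1, 4) == 2


class TestAssembleFeatures:
    def test_row_counts_and_unit_interval(self, demo_collection):
        spec = FeatureSpec.from_name("set64_128_256_ApEn_FuzEn_LLE")
        data = assemble_features(demo_collection, spec)
        n_series = len(demo_collection.series_meta)
        assert data.X.shape[1] == 9
        assert data.X.shape[0] + data.n_dropped == n_series * 16
        assert ((data.X >= 0) & (data.X <= 1)).all()
        # every surviving series contributes labels 1..16
        assert set(np.unique(data.y)) == set(range(1, 17))

    def test_features_are_ancestor_cells(self, demo_collection):
        spec = FeatureSpec.from_name("set64_128_ApEn")
        data = assemble_features(demo_collection, spec)
        row = np.flatnonzero(data.y == 5)[0]
        sid = data.series_ids[row]
        idx = list(demo_collection.series_meta["series_id"]).index(sid)
        mm = demo_collection.normalized["ApEn"][idx]
        assert data.X[row, 0] == mm.cell(1, 5)
        assert data.X[row, 1] == mm.cell(2, 3)

    def test_requires_normalized_collection(self, demo_collection):
        import copy

        bare = copy.copy(demo_collection)
        bare.normalized = None
        with pytest.raises(SpecError):
            assemble_features(bare, FeatureSpec.from_name("set64_ApEn"))


def synthetic_features(
    n_groups=6, per_class=4, n_classes=8, noise=0.01, seed=0, separation=1.0
):
    """Well-separated synthetic features: value = class index * separation + noise."""
    rng = np.random.default_rng(seed)
    X, y, groups = [], [], []
    for g in range(n_groups):
        for cls in range(1, n_classes + 1):
            for _ in range(per_class):
                X.append([cls * separation + rng.normal(0, noise)])
                y.append(cls)
                groups.append(f"g{g}")
    spec = FeatureSpec(levels=(2,), measures=("ApEn",))
    return LabeledFeatures(
        X=np.asarray(X), y=np.asarray(y), groups=np.asarray(groups),
        series_ids=np.asarray(groups), spec=spec,
    )


class TestKnnLosoCv:
    def test_separable_classes_perfect_accuracy(self):
        report = knn_loso_cv(synthetic_features(), k=3)
        np.testing.assert_array_equal(report.per_class_accuracy, 1.0)
        assert report.n_folds == 6
        assert np.trace(report.confusion) == report.confusion.sum()

    def test_confusion_rows_sum_to_test_counts(self):
        data = synthetic_features()
        report = knn_loso_cv(data, k=3)
        np.testing.assert_array_equal(report.confusion.sum(axis=1), 6 * 4)

    def test_fold_exclusivity_via_group_totals(self):
        # every sample is tested exactly once: pooled confusion counts all rows
        data = synthetic_features(n_groups=4, per_class=3)
        report = knn_loso_cv(data, k=3)
        assert report.confusion.sum() == data.X.shape[0]

    def test_permuted_labels_at_chance(self):
        rng = np.random.default_rng(42)
        data = synthetic_features(n_groups=8, per_class=6, n_classes=8)
        accs = []
        for _ in range(10):
            shuffled = LabeledFeatures(
                X=data.X, y=rng.permutation(data.y), groups=data.groups,
                series_ids=data.series_ids, spec=data.spec,
            )
            accs.append(knn_loso_cv(shuffled, k=15).per_class_accuracy.mean())
        mean_acc = np.mean(accs)
        chance = 1.0 / 8
        se = np.sqrt(chance * (1 - chance) / (len(accs) * 8 * 6 * 8))
        assert abs(mean_acc - chance) < 3 * se + 0.02

    def test_deterministic_tie_break_lowest_class(self):
        # two identical training points with labels 1 and 2: tie goes to class 1
        spec = FeatureSpec(levels=(4,), measures=("ApEn",))
        data = LabeledFeatures(
            X=np.full((6, 1), 0.5),
            y=np.array([1, 2, 1, 2, 1, 2]),
            groups=np.array(["a", "a", "b", "b", "c", "c"]),
            series_ids=np.array(["a", "a", "b", "b", "c", "c"]),
            spec=spec,
        )
        report = knn_loso_cv(data, k=2)
        assert report.confusion[:, 0].sum() == report.confusion.sum()

    def test_k_must_fit_training_fold(self):
        with pytest.raises(ParameterError):
            knn_loso_cv(synthetic_features(n_groups=2, per_class=1), k=64)

    def test_single_group_rejected(self):
        data = synthetic_features(n_groups=1)
        with pytest.raises(CVError):
            knn_loso_cv(data, k=3)

    def test_identical_runs_identical_reports(self):
        data = synthetic_features(noise=0.3)
        r1, r2 = knn_loso_cv(data, k=7), knn_loso_cv(data, k=7)
        np.testing.assert_array_equal(r1.confusion, r2.confusion)

    def test_saccade_segments_detected_above_chance(self, demo_collection):
        """End-to-end on synthetic maps: the saccade-bearing classes (segments
        3-4 at level 1) are recognised well above the 1/16 chance level."""
        spec = FeatureSpec.from_name("set64_128_256_ApEn_FuzEn_LLE")
        data = assemble_features(demo_collection, spec)
        report = knn_loso_cv(data, k=63)
        chance = 1.0 / 16
        assert report.per_class_accuracy[2] >= 3 * chance
        assert report.per_class_accuracy[3] >= 3 * chance


class TestAccuracyTable:
    def test_single_report_shape(self):
        report = knn_loso_cv(synthetic_features(), k=3)
        table = accuracy_table([report], first_n_segments=4)
        assert table.shape == (4, 1)

    def test_matches_report_lookups(self):
        reports = [knn_loso_cv(synthetic_features(noise=0.3), k=k) for k in (3, 7, 15)]
        table = accuracy_table(reports, first_n_segments=4)
        for report in reports:
            col = f"{report.spec_name}_k{report.k}"
            np.testing.assert_array_equal(
                table[col].to_numpy(), report.per_class_accuracy[:4]
            )

    def test_csv_round_trip_at_six_decimals(self, tmp_path):
        report = knn_loso_cv(synthetic_features(noise=0.5), k=3)
        table = accuracy_table([report], first_n_segments=4)
        path = tmp_path / "table.csv"
        table.round(6).to_csv(path, float_format="%.6f")
        loaded = pd.read_csv(path, index_col="segment")
        np.testing.assert_array_equal(loaded.to_numpy(), table.round(6).to_numpy())

    def test_spec_misalignment_rejected(self):
        report = knn_loso_cv(synthetic_features(), k=3)
        wrong = FeatureSpec(levels=(1,), measures=("LLE",))
        with pytest.raises(SpecError):
            accuracy_table([report], specs=[wrong])
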