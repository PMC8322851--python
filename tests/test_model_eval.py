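"""Classifier registry, cross-validation plumbing, feature ranking and
selection, and the statistical comparisons."""

import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.dummy import DummyClassifier

import myoface as mf
from myoface.features import FEATURE_NAMES
from myoface.model_eval import (
    MODEL_NAMES,
    fold_plan,
    make_registry,
    normalize_removal_order,
    paired_ttest,
)
from myoface.segmentation import LabeledWindow
from myoface.types import LABELS


def blob_matrix(n_per_class=30, n_classes=7, sep=10.0, seed=0):
    """Noisy one-hot class markers: perfectly separable toy data."""
    rng = np.random.default_rng(seed)
    X, y = [], []
    for c in range(n_classes):
        center = np.zeros(n_classes)
        center[c] = sep
        X.append(center + rng.standard_normal((n_per_class, n_classes)))
        y += [LABELS[c]] * n_per_class
    X = np.vstack(X)
    return mf.FeatureMatrix(
        X=pd.DataFrame(X, columns=[f"f{i}" for i in range(n_classes)]),
        y=np.array(y),
        mode="toy",
    )


def noise_windows(scales, n_per_class=24, n=40, seed=0):
    """Windows whose classes differ only in amplitude scale."""
    rng = np.random.default_rng(seed)
    wins = []
    for label, s in scales.items():
        for _ in range(n_per_class):
            wins.append(
                LabeledWindow(
                    samples=s * rng.standard_normal((n, 6)),
                    label=label, round_index=0, prompt_index=0, start_s=0.0,
                )
            )
    return wins


class TestRegistry:
    def test_twelve_models_present(self):
        reg = make_registry(seed=1)
        assert tuple(reg) == MODEL_NAMES
        assert len(reg) == 12

    def test_every_model_solves_separable_toy(self):
        fm = blob_matrix()
        scores = mf.run_cv(fm, make_registry(0), k=5, seed=0)
        for name, s in scores.items():
            assert s.mean == pytest.approx(1.0), name


class TestRunCV:
    def test_fold_conservation(self, ef_matrix):
        plan = fold_plan(ef_matrix, k=5, seed=0)
        assert len(plan) == 5
        assert sum(p["n_test"] for p in plan) == ef_matrix.n_rows
        for p in plan:
            assert p["n_train"] + p["n_test"] == ef_matrix.n_rows

    def test_stratification_exact_when_divisible(self, ef_matrix):
        # 4 rounds: 80 windows per action, 96 REST; both divide by 5
        plan = fold_plan(ef_matrix, k=5, seed=0)
        for p in plan:
            for mov in ("LEb", "Bk", "TML"):
                assert p["train_per_class"][mov] == 64
                assert p["test_per_class"][mov] == 16

    def test_small_class_rejected(self):
        fm = blob_matrix(n_per_class=3)
        with pytest.raises(ValueError, match="at least k"):
            mf.run_cv(fm, {"LDA": make_registry(0)["LDA"]}, k=5)


class TestFeatureRanking:
    def test_scale_only_signal_ranks_shape_features_worst(self):
        wins = noise_windows({"REST": 0.05, "LEBO": 0.4, "Bk": 1.5})
        reg = {k: v for k, v in make_registry(0).items() if k in ("LDA", "DT")}
        order, table = mf.rank_single_features(wins, reg, k=3, seed=0)
        assert len(order) == 8
        assert set(table.index) == set(FEATURE_NAMES)
        # amplitude-blind features cannot separate scale-only classes
        assert set(order[:3]) == {"MC", "ZC", "ARC"}

    def test_tie_break_follows_declared_order(self):
        wins = noise_windows({"REST": 1.0, "Bk": 1.0}, n_per_class=12)
        reg = {"dummy": DummyClassifier(strategy="most_frequent")}
        order, _ = mf.rank_single_features(wins, reg, k=3, seed=0)
        assert order == list(FEATURE_NAMES)  # all tied at chance level


@pytest.fixture(scope="module")
def curve(small_windows):
    wins = small_windows[:144]
    reg = make_registry(0)
    return mf.feature_reduction_curve(
        wins, "MC,ZC,ARC,WAV,MAX,VAR,RMS,MAC".split(","),
        model=reg["LDA"], k=3, seed=0,
    )


class TestReductionCurve:
    def test_curve_shape(self, curve):
        assert list(curve["n_features"]) == [8, 7, 6, 5, 4, 3, 2, 1]

    def test_elected_features_survive_at_three(self, curve):
        at3 = curve.loc[curve["n_features"] == 3, "features"].iloc[0]
        assert set(at3) == {"VAR", "RMS", "MAC"}
        assert tuple(curve["features"].iloc[-1]) == ("MAC",)

    def test_feature_time_drops_without_ar_fit(self, curve):
        assert curve["feature_time_s"].iloc[0] > curve["feature_time_s"].iloc[-1]

    def test_wav_alias_and_bad_orders(self):
        assert normalize_removal_order(["MC", "ZC", "ARC", "WAV", "MAX", "VAR",
                                        "RMS", "MAC"])[3] == "MAV"
        with pytest.raises(ValueError):
            normalize_removal_order(["MC"] * 8)


class TestCompareModes:
    def test_identical_vectors_give_p_one(self):
        acc = {m: np.array([0.9, 0.92, 0.91]) for m in MODEL_NAMES}
        rep = mf.compare_modes(acc, acc, acc)
        assert len(rep) == 12
        assert np.all(rep["p_sf_vs_af"] == 1.0)
        assert np.all(rep["p_ef_vs_af"] == 1.0)

    def test_constant_shift_is_significant(self):
        rng = np.random.default_rng(0)
        sf = {m: rng.uniform(0.8, 0.9, size=7) for m in MODEL_NAMES}
        af = {m: v + 0.05 for m, v in sf.items()}
        rep = mf.compare_modes(sf, af, af)
        assert np.all(rep["p_sf_vs_af"] < 0.01)

    def test_mismatched_pairing_rejected(self):
        a = {m: np.ones(3) for m in MODEL_NAMES}
        b = {m: np.ones(4) for m in MODEL_NAMES}
        with pytest.raises(ValueError):
            mf.compare_modes(a, b, b)


class TestPairedTTest:
    def test_matches_scipy_on_regular_data(self):
        from scipy import stats

        rng = np.random.default_rng(5)
        a, b = rng.standard_normal(10), rng.standard_normal(10)
        assert paired_ttest(a, b) == pytest.approx(stats.ttest_rel(a, b).pvalue)

    def test_degenerate_limits(self):
        assert paired_ttest(np.ones(5), np.ones(5)) == 1.0
        assert paired_ttest(np.ones(5), np.ones(5) + 0.05) == 0.0


class TestPermutationTest:
    def test_identical_groups_give_p_one(self):
        assert mf.permutation_test([3.0, 3.0, 3.0], [3.0, 3.0, 3.0]) == 1.0

    def test_extreme_separation_exact_value(self):
        # only the 2 extreme assignments of C(10,5)=252 reach |diff| = 8
        p = mf.permutation_test([1] * 5, [9] * 5)
        assert p == pytest.approx(2 / 252)

    def test_matches_independent_enumeration(self):
        rng = np.random.default_rng(2)
        a = list(rng.normal(0, 1, 5))
        b = list(rng.normal(1, 1, 6))
        pooled = a + b
        obs = abs(np.mean(a) - np.mean(b))
        hits = total = 0
        for pick in itertools.combinations(range(11), 5):
            ga = [pooled[i] for i in pick]
            gb = [pooled[i] for i in range(11) if i not in pick]
            hits += abs(np.mean(ga) - np.mean(gb)) >= obs - 1e-12
            total += 1
        assert mf.permutation_test(a, b) == pytest.approx(hits / total)

    def test_monte_carlo_bounds_and_determinism(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 1, 30), rng.normal(0.1, 1, 30)
        p1 = mf.permutation_test(a, b, n_perm=999, seed=11)
        p2 = mf.permutation_test(a, b, n_perm=999, seed=11)
        assert p1 == p2
        assert 1 / 1000 <= p1 <= 1.0

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            mf.permutation_test([], [1.0])
        with pytest.raises(ValueError):
            mf.permutation_test([1.0], [2.0], n_perm=0)
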