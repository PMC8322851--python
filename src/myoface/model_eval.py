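"""Offline model and feature selection.

Twelve classifiers are compared by stratified 5-fold cross-validation
on the three feature-assembly modes; single-feature performance ranks
the eight features; a sequential feature-removal curve justifies the
elected subset; paired t-tests compare assembly modes and a permutation
test compares online task times.

Folds are stratified so the per-class train/test counts match exact
80/20 splits (2,304/576 rows overall, 320/80 per action, 384/96 REST on
the full 20-round acquisition).  All classifiers run with library
defaults, a shared seed, and a standardising scaler in front.
"""

from __future__ import annotations

import time
from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import clone
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.ensemble import (
    AdaBoostClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.linear_model import LogisticRegression, RidgeClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from lightgbm import LGBMClassifier

from .features import FEATURE_NAMES, FeatureMatrix, assemble_features
from .segmentation import LabeledWindow

__all__ = [
    "MODEL_NAMES",
    "make_registry",
    "CVScores",
    "run_cv",
    "fold_plan",
    "rank_single_features",
    "feature_reduction_curve",
    "compare_modes",
    "paired_ttest",
    "permutation_test",
]

MODEL_NAMES: tuple[str, ...] = (
    "LR", "NB", "DT", "SVM", "MLP", "Ridge",
    "RF", "QDA", "Ada", "GBC", "LDA", "LGBM",
)


def make_registry(seed: int = 0) -> dict[str, Pipeline]:
    """The 12 named classifiers, each behind a standardising scaler."""
    base = {
        "LR": LogisticRegression(max_iter=1000),
        "NB": GaussianNB(),
        "DT": DecisionTreeClassifier(random_state=seed),
        "SVM": SVC(kernel="linear", random_state=seed),
        "MLP": MLPClassifier(random_state=seed, max_iter=500),
        "Ridge": RidgeClassifier(),
        "RF": RandomForestClassifier(random_state=seed, n_jobs=1),
        "QDA": QuadraticDiscriminantAnalysis(),
        "Ada": AdaBoostClassifier(random_state=seed),
        "GBC": GradientBoostingClassifier(random_state=seed),
        "LDA": LinearDiscriminantAnalysis(),
        "LGBM": LGBMClassifier(random_state=seed, verbose=-1, n_jobs=1),
    }
    return {
        name: Pipeline([("scale", StandardScaler()), ("clf", est)])
        for name, est in base.items()
    }


@dataclass
class CVScores:
    """Cross-validation outcome of one (model, design-matrix) pair."""

    fold_accuracies: np.ndarray        # (k,)
    fold_counts: list[tuple[int, int]]  # (n_train, n_test) per fold

    @property
    def mean(self) -> float:
        return float(self.fold_accuracies.mean())

    @property
    def std(self) -> float:
        return float(self.fold_accuracies.std(ddof=1))


def run_cv(
    matrix: FeatureMatrix,
    registry: Mapping[str, Pipeline],
    k: int = 5,
    seed: int = 0,
) -> dict[str, CVScores]:
    """Stratified k-fold CV of every registry model on one design matrix."""
    X = matrix.X.to_numpy()
    y = matrix.y
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        raise ValueError(
            f"every class needs at least k={k} samples (smallest has {counts.min()})"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))

    out: dict[str, CVScores] = {}
    for name, est in registry.items():
        accs, counts_ = [], []
        for train_idx, test_idx in splits:
            model = clone(est)
            model.fit(X[train_idx], y[train_idx])
            accs.append(float(model.score(X[test_idx], y[test_idx])))
            counts_.append((len(train_idx), len(test_idx)))
        out[name] = CVScores(np.array(accs), counts_)
    return out


def fold_plan(
    matrix: FeatureMatrix, k: int = 5, seed: int = 0
) -> list[dict]:
    """Per-fold row counts of the stratified split, overall and per class.

    Uses the same splitter as :func:`run_cv`, so the reported counts are
    exactly what every model trains and tests on.
    """
    X = matrix.X.to_numpy()
    y = matrix.y
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    plan = []
    for i, (train_idx, test_idx) in enumerate(skf.split(X, y)):
        tr = pd.Series(y[train_idx]).value_counts().to_dict()
        te = pd.Series(y[test_idx]).value_counts().to_dict()
        plan.append(
            {
                "fold": i,
                "n_train": len(train_idx),
                "n_test": len(test_idx),
                "train_per_class": {str(k_): int(v) for k_, v in tr.items()},
                "test_per_class": {str(k_): int(v) for k_, v in te.items()},
            }
        )
    return plan


def rank_single_features(
    windows: Sequence[LabeledWindow],
    registry: Mapping[str, Pipeline],
    k: int = 5,
    seed: int = 0,
) -> tuple[list[str], pd.DataFrame]:
    """Order the 8 features by model-averaged single-feature CV accuracy.

    Returns the ordering (ascending, worst first — the removal order for
    the reduction curve) and a feature × model accuracy table.  Ties
    break by the declared feature order.
    """
    table = {}
    for feat in FEATURE_NAMES:
        fm = assemble_features(windows, (feat,))
        scores = run_cv(fm, registry, k=k, seed=seed)
        table[feat] = {m: s.mean for m, s in scores.items()}
    df = pd.DataFrame(table).T  # features x models
    avg = df.mean(axis=1)
    order = sorted(FEATURE_NAMES, key=lambda f: (avg[f], FEATURE_NAMES.index(f)))
    return order, df


def normalize_removal_order(order: Sequence[str]) -> list[str]:
    """Map reported feature aliases onto canonical names (WAV -> MAV)."""
    fixed = ["MAV" if f.upper() == "WAV" else f.upper() for f in order]
    if sorted(fixed) != sorted(FEATURE_NAMES):
        raise ValueError(
            f"removal order must be a permutation of {FEATURE_NAMES}, got {order}"
        )
    return fixed


def feature_reduction_curve(
    windows: Sequence[LabeledWindow],
    removal_order: Sequence[str],
    model: Pipeline | None = None,
    k: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Drop features one by one and track CV accuracy and feature time.

    Starting from all 8 features, each step removes the next feature in
    ``removal_order`` and records the retained set, the mean CV accuracy
    of ``model`` (a fresh seeded gradient-boosting classifier by
    default) and the wall-clock time to compute the retained features.
    The curve has 8 points (8 features down to 1).
    """
    removal = normalize_removal_order(removal_order)
    if model is None:
        model = make_registry(seed)["GBC"]

    records = []
    remaining = list(FEATURE_NAMES)
    for step in range(len(removal)):
        t0 = time.perf_counter()
        fm = assemble_features(windows, tuple(remaining))
        feat_time = time.perf_counter() - t0
        scores = run_cv(fm, {"model": model}, k=k, seed=seed)["model"]
        records.append(
            {
                "n_features": len(remaining),
                "features": tuple(remaining),
                "mean_accuracy": scores.mean,
                "std_accuracy": scores.std,
                "feature_time_s": feat_time,
            }
        )
        remaining.remove(removal[step])
    return pd.DataFrame(records)


def paired_ttest(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided paired t-test p-value with a degenerate-case contract.

    Degenerate cases take their limiting values: if every paired
    difference is exactly zero the samples are indistinguishable and
    p = 1; a non-zero constant shift drives the t statistic to infinity
    and p to 0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = a - b
    if np.isclose(d.std(ddof=1) if d.size > 1 else 0.0, 0.0):
        return 1.0 if np.allclose(d, 0.0) else 0.0
    return float(stats.ttest_rel(a, b).pvalue)


def compare_modes(
    results_sf: Mapping[str, np.ndarray],
    results_af: Mapping[str, np.ndarray],
    results_ef: Mapping[str, np.ndarray],
) -> pd.DataFrame:
    """Per-model comparison of the three assembly modes.

    Each mapping gives, per model, a vector of matched accuracies (one
    entry per subject or per fold; for SF, the best single feature per
    subject).  Returns means ± sd per mode and paired t-test p-values
    for SF vs AF and EF vs AF.
    """
    models = list(results_af)
    if set(results_sf) != set(models) or set(results_ef) != set(models):
        raise ValueError("the three result sets must cover the same models")
    rows = []
    for m in models:
        sf, af, ef = (
            np.asarray(results_sf[m], float),
            np.asarray(results_af[m], float),
            np.asarray(results_ef[m], float),
        )
        if not (sf.shape == af.shape == ef.shape):
            raise ValueError(f"mismatched pairing for model {m!r}")
        rows.append(
            {
                "model": m,
                "sf_mean": sf.mean(), "sf_sd": sf.std(ddof=1) if sf.size > 1 else 0.0,
                "af_mean": af.mean(), "af_sd": af.std(ddof=1) if af.size > 1 else 0.0,
                "ef_mean": ef.mean(), "ef_sd": ef.std(ddof=1) if ef.size > 1 else 0.0,
                "p_sf_vs_af": paired_ttest(sf, af),
                "p_ef_vs_af": paired_ttest(ef, af),
            }
        )
    return pd.DataFrame(rows).set_index("model")


def permutation_test(
    times_a: Sequence[float],
    times_b: Sequence[float],
    n_perm: int = 10_000,
    seed: int = 0,
    max_exhaustive: int = 10**6,
) -> float:
    """Two-sided permutation test on the difference in group means.

    Labels are exchanged between the two groups; the p-value is the
    fraction of arrangements whose absolute mean difference is at least
    the observed one.  When the number of distinct arrangements is at
    most ``max_exhaustive`` the test enumerates all of them exactly;
    otherwise it draws ``n_perm`` seeded random permutations and applies
    the add-one correction (b+1)/(m+1), so the p-value always lies in
    [1/(n_perm+1), 1].
    """
    a = np.asarray(times_a, dtype=float)
    b = np.asarray(times_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")

    pooled = np.concatenate([a, b])
    n, na = pooled.size, a.size
    observed = abs(a.mean() - b.mean())
    eps = 1e-12 * max(1.0, observed)

    if comb(n, na) <= max_exhaustive:
        total = hits = 0
        idx = np.arange(n)
        for pick in combinations(idx, na):
            mask = np.zeros(n, dtype=bool)
            mask[list(pick)] = True
            diff = abs(pooled[mask].mean() - pooled[~mask].mean())
            hits += diff >= observed - eps
            total += 1
        return hits / total

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        diff = abs(perm[:na].mean() - perm[na:].mean())
        hits += diff >= observed - eps
    return (hits + 1) / (n_perm + 1)
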