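"""Feature definitions against a naive loop-based oracle, symmetry and
scaling properties, AR parameter recovery, and design-matrix layout."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import myoface as mf
from myoface.features import (
    AR_ORDER,
    EF_FEATURES,
    FEATURE_NAMES,
    compute_feature_set,
    feature_row,
)

NON_ARC = tuple(f for f in FEATURE_NAMES if f != "ARC")


# ---------------------------------------------------------------------------
# independent oracle: pure-python loops, no numpy vectorisation
# ---------------------------------------------------------------------------

def naive_features(x):
    x = [float(v) for v in x]
    n = len(x)
    mean = sum(x) / n
    out = {
        "MAV": sum(abs(v) for v in x) / n,
        "RMS": (sum(v * v for v in x) / n) ** 0.5,
        "MC": sum(x[i + 1] - x[i] for i in range(n - 1)) / n,
        "MAC": sum(abs(x[i + 1] - x[i]) for i in range(n - 1)) / n,
        "MAX": max(x),
        "ZC": sum(1 for i in range(n - 1) if -x[i] * x[i + 1] > 0),
        "VAR": sum((v - mean) ** 2 for v in x) / (n - 1),
    }
    return out


def naive_yule_walker(x, order=AR_ORDER):
    x = np.asarray(x, float)
    n = x.size
    xc = x - x.mean()
    r = [float(np.dot(xc[: n - k], xc[k:]) / n) for k in range(order + 1)]
    R = np.array([[r[abs(i - j)] for j in range(order)] for i in range(order)])
    return np.linalg.solve(R, np.array(r[1 : order + 1]))


def single_channel(x):
    """Wrap a 1-D vector as a (n, 6) window repeating it on every channel."""
    return np.tile(np.asarray(x, float)[:, None], (1, 6))


class TestFeatureDefinitions:
    def test_three_point_hand_values(self):
        # frozen by hand: x = [1, -1, 2]
        row = feature_row(single_channel([1.0, -1.0, 2.0]), NON_ARC)
        got = dict(zip(NON_ARC, row[: len(NON_ARC)]))
        assert got["MAV"] == pytest.approx(4 / 3)
        assert got["RMS"] == pytest.approx(np.sqrt(2))
        assert got["MC"] == pytest.approx(1 / 3)
        assert got["MAC"] == pytest.approx(5 / 3)
        assert got["MAX"] == pytest.approx(2.0)
        assert got["ZC"] == 2
        assert got["VAR"] == pytest.approx(7 / 3)

    def test_constant_window(self):
        fs = compute_feature_set(np.full(50, 3.0))
        assert (fs.mav, fs.rms, fs.max) == (3.0, 3.0, 3.0)
        assert fs.mc == fs.mac == fs.var == 0.0
        assert fs.zc == 0
        assert np.all(fs.arc == 0)  # no AR structure in a constant

    def test_sign_flip_symmetry(self, rng):
        x = rng.standard_normal(80)
        a = compute_feature_set(x)
        b = compute_feature_set(-x)
        for name in ("mav", "rms", "mac", "zc", "var"):
            assert getattr(a, name) == pytest.approx(getattr(b, name))
        assert b.mc == pytest.approx(-a.mc)
        assert b.max == pytest.approx(-float(np.min(x)))

    def test_var_as_printed_truncates(self):
        x = np.array([1.0, 2.0, -3.0, 0.5, 4.0])
        full = compute_feature_set(x).var
        trunc = compute_feature_set(x, var_as_printed=True).var
        mean = x.mean()
        assert trunc == pytest.approx(np.sum((x[:-1] - mean) ** 2) / (len(x) - 1))
        assert trunc != pytest.approx(full)

    def test_rejects_degenerate_input(self):
        with pytest.raises(ValueError):
            compute_feature_set(np.array([1.0, 2.0, 3.0]))  # too short for AR(3)
        with pytest.raises(ValueError):
            compute_feature_set(np.array([1.0, np.nan, 2.0, 3.0]))


class TestOracleEquivalence:
    def test_thousand_random_windows(self, rng):
        for _ in range(1000):
            x = rng.standard_normal(64) * rng.uniform(0.1, 10)
            fs = compute_feature_set(x)
            ref = naive_features(x)
            for name in NON_ARC:
                got = float(fs.value(name)[0])
                assert got == pytest.approx(ref[name], rel=1e-10, abs=1e-12), name

    def test_arc_matches_naive_toeplitz_solve(self, rng):
        for _ in range(50):
            x = rng.standard_normal(200)
            assert np.allclose(
                compute_feature_set(x).arc, naive_yule_walker(x), rtol=1e-8
            )

    def test_mc_telescopes(self, rng):
        for _ in range(100):
            x = rng.standard_normal(200)
            assert compute_feature_set(x).mc == pytest.approx(
                (x[-1] - x[0]) / len(x), rel=1e-10, abs=1e-14
            )


@settings(max_examples=60, derandomize=True, deadline=None)
@given(
    x=st.lists(
        st.floats(-100, 100, allow_nan=False).filter(lambda v: abs(v) > 1e-6),
        min_size=8, max_size=64,
    ),
    lam=st.floats(0.01, 100.0),
)
def test_positive_scaling_homogeneity(x, lam):
    """λ>0 scales MAV/RMS/MAC/MAX linearly, VAR quadratically, fixes ZC."""
    x = np.asarray(x)
    a = compute_feature_set(x)
    b = compute_feature_set(lam * x)
    assert b.mav == pytest.approx(lam * a.mav, rel=1e-9)
    assert b.rms == pytest.approx(lam * a.rms, rel=1e-9)
    assert b.mac == pytest.approx(lam * a.mac, rel=1e-9)
    assert b.max == pytest.approx(lam * a.max, rel=1e-9)
    assert b.var == pytest.approx(lam**2 * a.var, rel=1e-9)
    assert b.zc == a.zc


class TestArcRecovery:
    def test_recovers_known_ar3_process(self):
        # stable AR(3) with poles 0.6 and 0.5 +/- 0.3i
        poles = [0.6, 0.5 + 0.3j, 0.5 - 0.3j]
        a_true = -np.real(np.poly(poles))[1:]
        rng = np.random.default_rng(77)
        n = 20000
        x = np.zeros(n)
        e = 0.1 * rng.standard_normal(n)
        for t in range(3, n):
            x[t] = a_true @ x[t - 3 : t][::-1] + e[t]
        for method in ("yule_walker", "lstsq"):
            est = compute_feature_set(x, ar_method=method).arc
            assert np.allclose(est, a_true, atol=0.05), (method, est, a_true)


class TestAssembly:
    def test_mode_widths(self, small_windows):
        wins = small_windows[:20]
        assert mf.assemble(wins, "AF").X.shape[1] == 60
        assert mf.assemble(wins, "EF").X.shape[1] == 18
        assert mf.assemble(wins, "SF:RMS").X.shape[1] == 6
        assert mf.assemble(wins, "SF:ARC").X.shape[1] == 18

    def test_channel_major_layout(self, small_windows):
        fm = mf.assemble(small_windows[:5], "EF")
        assert list(fm.X.columns[:3]) == ["ch1_var", "ch1_rms", "ch1_mac"]
        assert list(fm.X.columns[3:6]) == ["ch2_var", "ch2_rms", "ch2_mac"]
        # rows match per-window recomputation
        row = feature_row(small_windows[0].samples, EF_FEATURES)
        assert np.allclose(fm.X.iloc[0].to_numpy(), row)

    def test_labels_align(self, small_windows):
        fm = mf.assemble(small_windows[:30], "EF")
        assert list(fm.y) == [w.label for w in small_windows[:30]]

    def test_unknown_mode_rejected(self, small_windows):
        with pytest.raises(ValueError):
            mf.assemble(small_windows[:5], "XF")
        with pytest.raises(ValueError):
            mf.assemble(small_windows[:5], "SF:WAV")
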