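"""Time-domain window features and design-matrix assembly.

Eight features are computed per 200 ms window per channel.  For a
window ``x_1 .. x_N``:

* MAV  — mean absolute value, ``(1/N) Σ |x_i|``
* RMS  — root mean square, ``sqrt((1/N) Σ x_i²)``
* MC   — mean change, ``(1/N) Σ_{i<N} (x_{i+1} − x_i)`` — telescopes to
  ``(x_N − x_1)/N``
* MAC  — mean absolute change, ``(1/N) Σ_{i<N} |x_{i+1} − x_i|``
* MAX  — signed maximum, ``max x_i``
* ZC   — zero crossings, the number of strict sign changes
  (``−x_i·x_{i+1} > 0``; exact zeros never count)
* VAR  — sample variance with denominator N−1 (an ``as_printed`` switch
  reproduces a truncated variant that sums only the first N−1 terms)
* ARC  — the three coefficients of an order-3 autoregressive model
  ``x_i = Σ_k a_k x_{i−k} + e_i``, fitted by Yule-Walker on the biased
  autocovariance (a least-squares covariance method is selectable)

Design matrices come in three assembly modes: ``SF:<feat>`` (one
feature type on all six channels), ``AF`` (all features, 60 columns),
and ``EF`` (the elected subset {VAR, RMS, MAC}, 18 columns).  Columns
are channel-major, feature-minor, so each channel's block is contiguous.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from statsmodels.regression.linear_model import yule_walker

from .segmentation import LabeledWindow
from .types import N_CHANNELS

__all__ = [
    "FEATURE_NAMES",
    "EF_FEATURES",
    "AR_ORDER",
    "FeatureSet",
    "FeatureMatrix",
    "compute_feature_set",
    "feature_row",
    "assemble",
    "assemble_features",
    "feature_width",
]

#: declared feature order (also the tie-break order for rankings)
FEATURE_NAMES: tuple[str, ...] = (
    "MAV", "RMS", "MC", "MAC", "MAX", "ZC", "VAR", "ARC",
)
#: the elected subset used online
EF_FEATURES: tuple[str, ...] = ("VAR", "RMS", "MAC")
AR_ORDER: int = 3


@dataclass
class FeatureSet:
    """All eight features of one single-channel window."""

    mav: float
    rms: float
    mc: float
    mac: float
    max: float
    zc: int
    var: float
    arc: np.ndarray  # (AR_ORDER,)

    def value(self, name: str) -> np.ndarray:
        """Feature by canonical name, always as a 1-D array."""
        if name == "ARC":
            return np.asarray(self.arc, dtype=float)
        return np.atleast_1d(float(getattr(self, name.lower())))


def _arc(x: np.ndarray, method: str) -> np.ndarray:
    if x.size < AR_ORDER + 1:
        raise ValueError(
            f"AR({AR_ORDER}) needs at least {AR_ORDER + 1} samples, got {x.size}"
        )
    # degenerate (constant) windows have no AR structure
    if np.var(x) < 1e-30:
        return np.zeros(AR_ORDER)
    if method == "yule_walker":
        rho, _ = yule_walker(x, order=AR_ORDER, method="mle")
        return np.asarray(rho, dtype=float)
    if method == "lstsq":
        xc = x - x.mean()
        y = xc[AR_ORDER:]
        lag = np.column_stack([xc[AR_ORDER - k : len(xc) - k] for k in range(1, AR_ORDER + 1)])
        coef, *_ = np.linalg.lstsq(lag, y, rcond=None)
        return coef
    raise ValueError(f"unknown AR method {method!r}")


def _check_window(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-D single-channel window")
    if x.size < 2:
        raise ValueError(f"need at least 2 samples, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise ValueError("window contains non-finite samples")
    return x


def _compute_one(
    x: np.ndarray, name: str, var_as_printed: bool, ar_method: str
) -> np.ndarray:
    n = x.size
    if name == "MAV":
        v = np.mean(np.abs(x))
    elif name == "RMS":
        v = np.sqrt(np.mean(x**2))
    elif name == "MC":
        v = np.sum(np.diff(x)) / n
    elif name == "MAC":
        v = np.sum(np.abs(np.diff(x))) / n
    elif name == "MAX":
        v = np.max(x)
    elif name == "ZC":
        v = np.count_nonzero(-x[:-1] * x[1:] > 0)
    elif name == "VAR":
        if var_as_printed:
            # truncated sum: first N-1 deviations only, denominator N-1
            v = np.sum((x[:-1] - x.mean()) ** 2) / (n - 1)
        else:
            v = np.var(x, ddof=1)
    elif name == "ARC":
        return _arc(x, ar_method)
    else:
        raise ValueError(f"unknown feature {name!r}")
    return np.atleast_1d(float(v))


def compute_feature_set(
    window_channel: np.ndarray,
    var_as_printed: bool = False,
    ar_method: str = "yule_walker",
) -> FeatureSet:
    """All eight features of one channel of one window.

    Requires at least ``AR_ORDER + 1`` finite samples.
    """
    x = _check_window(window_channel)
    vals = {
        f: _compute_one(x, f, var_as_printed, ar_method) for f in FEATURE_NAMES
    }
    return FeatureSet(
        mav=float(vals["MAV"][0]),
        rms=float(vals["RMS"][0]),
        mc=float(vals["MC"][0]),
        mac=float(vals["MAC"][0]),
        max=float(vals["MAX"][0]),
        zc=int(vals["ZC"][0]),
        var=float(vals["VAR"][0]),
        arc=vals["ARC"],
    )


def feature_row(
    window: np.ndarray,
    features: Sequence[str],
    var_as_printed: bool = False,
    ar_method: str = "yule_walker",
) -> np.ndarray:
    """One design-matrix row for a multichannel window.

    Channel-major, feature-minor ordering — the row layout of
    :func:`assemble_features`.  Only the requested features are
    computed (the AR fit is skipped unless ARC is asked for).
    """
    window = np.asarray(window, dtype=float)
    if window.ndim != 2 or window.shape[1] != N_CHANNELS:
        raise ValueError(f"window must be (n, {N_CHANNELS})")
    parts = []
    for ch in range(N_CHANNELS):
        x = _check_window(window[:, ch])
        parts.extend(
            _compute_one(x, f, var_as_printed, ar_method) for f in features
        )
    return np.concatenate(parts)


def feature_width(features: Iterable[str]) -> int:
    """Total columns per channel for a feature list (ARC counts 3)."""
    return sum(AR_ORDER if f == "ARC" else 1 for f in features)


def _column_names(features: Sequence[str]) -> list[str]:
    cols = []
    for ch in range(1, N_CHANNELS + 1):
        for f in features:
            if f == "ARC":
                cols.extend(f"ch{ch}_arc{k}" for k in range(1, AR_ORDER + 1))
            else:
                cols.append(f"ch{ch}_{f.lower()}")
    return cols


@dataclass
class FeatureMatrix:
    """Per-window design matrix with labels.

    ``X`` is a DataFrame (one row per window, named columns in
    channel-major order), ``y`` the movement label per row.
    """

    X: pd.DataFrame
    y: np.ndarray
    mode: str

    @property
    def n_rows(self) -> int:
        return len(self.X)


def assemble_features(
    windows: Sequence[LabeledWindow],
    features: Sequence[str],
    var_as_printed: bool = False,
    ar_method: str = "yule_walker",
) -> FeatureMatrix:
    """Design matrix for an explicit feature list (channel-major columns)."""
    if not windows:
        raise ValueError("no windows to assemble")
    unknown = set(features) - set(FEATURE_NAMES)
    if unknown:
        raise ValueError(f"unknown features {sorted(unknown)}")

    rows = np.empty((len(windows), N_CHANNELS * feature_width(features)))
    for i, w in enumerate(windows):
        rows[i] = feature_row(
            w.samples, features, var_as_printed=var_as_printed, ar_method=ar_method
        )

    X = pd.DataFrame(rows, columns=_column_names(features))
    y = np.array([w.label for w in windows])
    return FeatureMatrix(X=X, y=y, mode="+".join(features))


def assemble(windows: Sequence[LabeledWindow], mode: str, **kw) -> FeatureMatrix:
    """Assemble a design matrix in mode ``AF``, ``EF`` or ``SF:<FEAT>``.

    AF uses all eight features (60 columns), EF the elected
    {VAR, RMS, MAC} (18 columns), and ``SF:RMS`` (say) one feature type
    on every channel (6 columns; 18 for ``SF:ARC``).
    """
    if mode == "AF":
        feats: Sequence[str] = FEATURE_NAMES
    elif mode == "EF":
        feats = EF_FEATURES
    elif mode.startswith("SF:"):
        feat = mode[3:]
        if feat not in FEATURE_NAMES:
            raise ValueError(f"unknown single feature {feat!r}")
        feats = (feat,)
    else:
        raise ValueError(f"unknown assembly mode {mode!r}")
    fm = assemble_features(windows, feats, **kw)
    fm.mode = mode
    return fm
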