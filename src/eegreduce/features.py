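"""Time-domain feature extraction per channel window.

Thirteen descriptors are computed on every 1-s window of every channel:
simple order statistics (mean, Median, Maximum, Minimum, amplitude), the
Hjorth parameters (Activity, Mobility, Complexity), Energy and RMS, a
percentile coefficient of kurtosis, Pearson mode skewness, and a
zero-crossing count.  An attribute is one feature on one channel, named
``<Feature>_<Channel>`` (e.g. ``Minimum_Fz``); 19 channels x 13 features
yield 247 attributes.

Conventions
-----------
* Standard deviations and variances use the N-1 denominator.
* The signal derivative is realised as first differences ``x[i+1]-x[i]``
  without sampling-rate scaling; Mobility and Complexity are ratios, so a
  constant fs factor cancels.
* Quantiles interpolate linearly between order statistics.
* The mode of a real-valued window is the half-sample mode; the exact
  discrete mode is used when repeated values exist.
* Degenerate windows (zero variance, collapsed percentiles) yield undefined
  values: the scalar API raises, the matrix path records NaN and reports the
  count so affected windows can be dropped from modelling, never silently
  zeroed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .types import FeatureMatrix, WindowedDataset

log = logging.getLogger(__name__)


@dataclass
class SignalWindow:
    """One fixed-length window of one channel."""

    x: np.ndarray
    channel: str = ""
    fs: float = 500.0

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=np.float64).ravel()
        if self.x.size < 2:
            raise ValueError("a window needs at least 2 samples")


@dataclass
class DescriptiveStats:
    mean: float
    std: float
    mode: float
    q1: float
    q3: float
    p10: float
    p90: float
    x_max: float
    x_min: float


@dataclass
class HjorthTriple:
    """Activity (variance), Mobility and Complexity of a window."""

    activity: float
    mobility: float
    complexity: float


class UndefinedFeatureError(ValueError):
    """A feature is undefined on this window (zero variance, flat quantiles)."""


def _arr(w) -> np.ndarray:
    return w.x if isinstance(w, SignalWindow) else np.asarray(w, dtype=np.float64).ravel()


# ---------------------------------------------------------------------------
# scalar API


def _hsm_scan(x: np.ndarray, last_tie: bool) -> float:
    while x.size > 3:
        m = x.size // 2 + 1
        widths = x[m - 1:] - x[: x.size - m + 1]
        if last_tie:
            i = widths.size - 1 - int(np.argmin(widths[::-1]))
        else:
            i = int(np.argmin(widths))
        x = x[i : i + m]
    if x.size == 3:
        if x[2] - x[1] < x[1] - x[0]:
            return float((x[1] + x[2]) / 2)
        if x[2] - x[1] > x[1] - x[0]:
            return float((x[0] + x[1]) / 2)
        return float(x[1])
    return float(x.mean())


def half_sample_mode(x: np.ndarray) -> float:
    """Deterministic, symmetric half-sample mode of a 1-D sample.

    Repeatedly keeps the narrowest half of the sorted data until three or
    fewer points remain.  Width ties are resolved twice — leftmost and
    rightmost — and the two estimates averaged, so the estimator is exactly
    unbiased on mirror-symmetric samples while staying deterministic.
    """
    x = np.sort(np.asarray(x, dtype=np.float64).ravel())
    left = _hsm_scan(x, last_tie=False)
    right = _hsm_scan(x, last_tie=True)
    return 0.5 * (left + right)


def window_mode(x: np.ndarray) -> float:
    """Discrete mode when repeated values exist, otherwise half-sample mode.

    The discrete mode takes the most frequent value, smallest first on tied
    counts.
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    vals, counts = np.unique(x, return_counts=True)
    if counts.max() > 1:
        return float(vals[np.argmax(counts)])
    return half_sample_mode(x)


def basic_stats(w) -> tuple[DescriptiveStats, dict[str, float]]:
    """Order statistics plus {mean, Median, Maximum, Minimum, amplitude}."""
    x = _arr(w)
    if x.size == 0:
        raise ValueError("empty window")
    stats = DescriptiveStats(
        mean=float(x.mean()),
        std=float(x.std(ddof=1)) if x.size > 1 else 0.0,
        mode=window_mode(x),
        q1=float(np.percentile(x, 25)),
        q3=float(np.percentile(x, 75)),
        p10=float(np.percentile(x, 10)),
        p90=float(np.percentile(x, 90)),
        x_max=float(x.max()),
        x_min=float(x.min()),
    )
    feats = {
        "mean": stats.mean,
        "Median": float(np.median(x)),
        "Maximum": stats.x_max,
        "Minimum": stats.x_min,
        "amplitude": stats.x_max - stats.x_min,
    }
    return stats, feats


def hjorth(w) -> HjorthTriple:
    """Hjorth Activity, Mobility and Complexity.

    activity = var(x) (N-1); mobility = sqrt(var(dx)/var(x));
    complexity = mobility(dx)/mobility(x) with dx the first differences.
    """
    x = _arr(w)
    if x.size < 3:
        raise ValueError("Hjorth parameters need at least 3 samples")
    var_x = x.var(ddof=1)
    if var_x == 0:
        raise UndefinedFeatureError("mobility undefined: zero-variance window")
    dx = np.diff(x)
    var_dx = dx.var(ddof=1)
    mobility = float(np.sqrt(var_dx / var_x))
    if var_dx == 0:
        raise UndefinedFeatureError("complexity undefined: linear-ramp window")
    ddx = np.diff(dx)
    mob_dx = float(np.sqrt(ddx.var(ddof=1) / var_dx))
    return HjorthTriple(
        activity=float(var_x), mobility=mobility, complexity=mob_dx / mobility
    )


def energy_rms(w) -> dict[str, float]:
    """Energy = mean(x^2); RMS = sqrt(Energy)."""
    x = _arr(w)
    if x.size == 0:
        raise ValueError("empty window")
    energy = float(np.mean(x * x))
    return {"Energy": energy, "RMS": float(np.sqrt(energy))}


def percentile_kurtosis(w) -> float:
    """Percentile coefficient of kurtosis: (Q3-Q1) / (2*(P90-P10)).

    ~0.263 for Gaussian data.  Undefined when P90 == P10.
    """
    x = _arr(w)
    q1, q3, p10, p90 = np.percentile(x, [25, 75, 10, 90])
    if p90 == p10:
        raise UndefinedFeatureError("kurtosis undefined: P90 == P10")
    return float((q3 - q1) / (2.0 * (p90 - p10)))


def mode_skewness(w) -> float:
    """Pearson mode skewness: (mean - mode) / std (N-1)."""
    x = _arr(w)
    sd = x.std(ddof=1)
    if sd == 0:
        raise UndefinedFeatureError("skewness undefined: zero-variance window")
    return float((x.mean() - window_mode(x)) / sd)


def zero_crossing(w, mode: str = "conventional") -> float:
    """Zero-crossing feature of a window of K samples.

    Consecutive pairs where either sample is exactly zero are excluded.  In
    ``conventional`` mode the result is the number of sign changes
    ``C = 1/2 * sum |s_i - s_{i+1}|`` with ``s_i = x_i/|x_i|``; in
    ``as_printed`` mode the literal complement ``(K-1) - C`` is returned.
    """
    if mode not in ("conventional", "as_printed"):
        raise ValueError(f"unknown zero-crossing mode {mode!r}")
    x = _arr(w)
    s = np.sign(x)
    valid = (s[:-1] != 0) & (s[1:] != 0)
    excluded = int((~valid).sum())
    if excluded:
        log.debug("zero_crossing: %d zero-sample pairs excluded", excluded)
    crossings = 0.5 * np.abs(s[:-1][valid] - s[1:][valid]).sum()
    if mode == "as_printed":
        return float((x.size - 1) - crossings)
    return float(crossings)


# ---------------------------------------------------------------------------
# vectorised extraction over a window stack

def _v_hjorth(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    var_x = X.var(axis=1, ddof=1)
    dX = np.diff(X, axis=1)
    var_dx = dX.var(axis=1, ddof=1)
    ddX = np.diff(dX, axis=1)
    var_ddx = ddX.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        mob = np.sqrt(var_dx / var_x)
        mob_d = np.sqrt(var_ddx / var_dx)
        comp = mob_d / mob
    mob[var_x == 0] = np.nan
    comp[(var_x == 0) | (var_dx == 0)] = np.nan
    return var_x, mob, comp


def _v_kurtosis(X: np.ndarray) -> np.ndarray:
    q1, q3, p10, p90 = np.percentile(X, [25, 75, 10, 90], axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        k = (q3 - q1) / (2.0 * (p90 - p10))
    k[p90 == p10] = np.nan
    return k


def _v_skewness(X: np.ndarray) -> np.ndarray:
    sd = X.std(axis=1, ddof=1)
    modes = np.array([window_mode(row) for row in X])
    with np.errstate(divide="ignore", invalid="ignore"):
        s = (X.mean(axis=1) - modes) / sd
    s[sd == 0] = np.nan
    return s


def _v_zero_crossing(X: np.ndarray, mode: str) -> np.ndarray:
    s = np.sign(X)
    valid = (s[:, :-1] != 0) & (s[:, 1:] != 0)
    c = 0.5 * (np.abs(s[:, :-1] - s[:, 1:]) * valid).sum(axis=1)
    if mode == "as_printed":
        return (X.shape[1] - 1) - c
    return c


#: Canonical feature names, in the order they are introduced in the method.
FEATURE_NAMES: tuple[str, ...] = (
    "amplitude", "skewness", "Activity", "Complexity", "Zero crossing",
    "kurtosis", "Energy", "Maximum", "mean", "Median", "Minimum",
    "Mobility", "RMS",
)

_FEATURE_FUNCS: dict[str, Callable[[np.ndarray, str], np.ndarray]] = {
    "amplitude": lambda X, zc: X.max(axis=1) - X.min(axis=1),
    "skewness": lambda X, zc: _v_skewness(X),
    "Activity": lambda X, zc: _v_hjorth(X)[0],
    "Complexity": lambda X, zc: _v_hjorth(X)[2],
    "Zero crossing": lambda X, zc: _v_zero_crossing(X, zc),
    "kurtosis": lambda X, zc: _v_kurtosis(X),
    "Energy": lambda X, zc: (X * X).mean(axis=1),
    "Maximum": lambda X, zc: X.max(axis=1),
    "mean": lambda X, zc: X.mean(axis=1),
    "Median": lambda X, zc: np.median(X, axis=1),
    "Minimum": lambda X, zc: X.min(axis=1),
    "Mobility": lambda X, zc: _v_hjorth(X)[1],
    "RMS": lambda X, zc: np.sqrt((X * X).mean(axis=1)),
}

#: Accepts either the canonical name or its underscore form in configs.
_CANONICAL = {name.replace(" ", "_"): name for name in FEATURE_NAMES}
_CANONICAL.update({name: name for name in FEATURE_NAMES})


def canonical_feature(name: str) -> str:
    """Resolve a feature name (space or underscore form) to its canonical form."""
    try:
        return _CANONICAL[name]
    except KeyError:
        raise KeyError(
            f"unknown feature {name!r}; known: {list(FEATURE_NAMES)}"
        ) from None


def attribute_name(feature: str, channel: str) -> str:
    """``<Feature>_<Channel>`` with spaces in the feature name underscored."""
    return f"{canonical_feature(feature).replace(' ', '_')}_{channel}"


def parse_attribute(name: str) -> tuple[str, str]:
    """Split an attribute name back into (canonical feature, channel)."""
    feat, _, channel = name.rpartition("_")
    if feat in _CANONICAL and channel:
        return _CANONICAL[feat], channel
    raise ValueError(f"attribute name {name!r} does not parse as <Feature>_<Channel>")


def extract_features(
    ds: WindowedDataset,
    feature_set: Sequence[str] | None = None,
    *,
    zc_mode: str = "conventional",
    channels: Sequence[str] | None = None,
) -> FeatureMatrix:
    """Assemble the windows x attributes matrix.

    Columns are ordered feature-major (all channels of the first feature,
    then the next feature), named ``<Feature>_<Channel>``.  Undefined values
    are stored as NaN and their count logged.
    """
    features = [canonical_feature(f) for f in (feature_set or FEATURE_NAMES)]
    if channels is None:
        chan_idx = list(range(len(ds.channel_names)))
    else:
        chan_idx = [ds.channel_names.index(c) for c in channels]
    chan_names = [ds.channel_names[i] for i in chan_idx]

    names: list[str] = []
    cols: list[np.ndarray] = []
    for feat in features:
        func = _FEATURE_FUNCS[feat]
        for ci, cname in zip(chan_idx, chan_names):
            names.append(attribute_name(feat, cname))
            cols.append(func(ds.windows[:, ci, :], zc_mode))
    values = np.column_stack(cols) if cols else np.empty((ds.n_windows, 0))
    n_undef = int(np.isnan(values).sum())
    if n_undef:
        log.warning("extract_features: %d undefined attribute values (NaN)", n_undef)
    return FeatureMatrix(tuple(names), values, ds.labels)
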