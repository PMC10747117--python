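"""Feature operators: hand-derived values, formula oracles, invariances."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from eegreduce.features import (
    FEATURE_NAMES,
    SignalWindow,
    UndefinedFeatureError,
    attribute_name,
    basic_stats,
    canonical_feature,
    energy_rms,
    extract_features,
    hjorth,
    mode_skewness,
    parse_attribute,
    percentile_kurtosis,
    zero_crossing,
)
from eegreduce.types import WindowedDataset

from .oracles import oracle_feature

# ---------------------------------------------------------------------------
# hand-derived examples


def test_basic_stats_hand_values():
    _, f = basic_stats([1, 5, 3])
    assert f == {
        "mean": 3.0, "Median": 3.0, "Maximum": 5.0, "Minimum": 1.0, "amplitude": 4.0,
    }
    _, f = basic_stats([1, 2, 3, 4])
    assert f["Median"] == 2.5  # even-N branch
    _, f = basic_stats([7.0, 7.0, 7.0])
    assert f["amplitude"] == 0.0 and f["mean"] == f["Median"] == 7.0


def test_hjorth_hand_values():
    # the ramp [1,2,3,4,5] has Activity 2.5 but an undefined Complexity
    assert oracle_like(np.array([1.0, 2, 3, 4, 5]), "Activity") == pytest.approx(2.5)
    with pytest.raises(UndefinedFeatureError):
        hjorth([2.0, 2.0, 2.0, 2.0])
    with pytest.raises(UndefinedFeatureError, match="linear-ramp"):
        hjorth(np.arange(10.0))  # zero-variance first difference
    t = hjorth([1.0, 2.0, 1.5, 3.0, 2.5])
    assert t.activity == pytest.approx(np.var([1, 2, 1.5, 3, 2.5], ddof=1))
    assert t.mobility > 0 and t.complexity > 0


def test_energy_rms_hand_values():
    assert energy_rms([1, -1, 1, -1]) == {"Energy": 1.0, "RMS": 1.0}
    out = energy_rms([3, 4])
    assert out["Energy"] == pytest.approx(12.5)
    assert out["RMS"] == pytest.approx(np.sqrt(12.5))
    assert energy_rms([0.0, 0.0]) == {"Energy": 0.0, "RMS": 0.0}


def test_mode_skewness_discrete_mode():
    # window [1,2,2,3,10]: discrete mode 2, mean 3.6, sample std sqrt(13.3)
    s = mode_skewness([1, 2, 2, 3, 10])
    assert s == pytest.approx((3.6 - 2) / np.sqrt(13.3), rel=1e-12)
    # mirrored pairs around 0 with a single 0: symmetric, skewness ~ 0
    sym = [-2.0, -1.0, 0.0, 1.0, 2.0]
    assert abs(mode_skewness(sym)) < 1e-12
    with pytest.raises(UndefinedFeatureError):
        mode_skewness([4.0, 4.0, 4.0])


def test_percentile_kurtosis_degenerate():
    with pytest.raises(UndefinedFeatureError):
        percentile_kurtosis([1.0] * 10)


def test_zero_crossing_modes():
    assert zero_crossing([1, -1, 1, -1]) == 3
    assert zero_crossing([1, -1, 1, -1], mode="as_printed") == 0
    assert zero_crossing([1, 2, 3]) == 0
    # zero samples excluded from pair counting
    assert zero_crossing([1, 0, -1, 1]) == 1


def test_zero_crossing_sine_five_hz():
    t = np.arange(500) / 500.0
    x = np.sin(2 * np.pi * 5 * t + 0.1)  # phase offset avoids exact zeros
    assert zero_crossing(x) == 10  # 2 crossings per cycle x 5 cycles


# ---------------------------------------------------------------------------
# closed-form limits


def test_sine_mobility_complexity_closed_form():
    fs = 500.0
    t = np.arange(int(fs)) / fs
    for f in (5.0, 10.0, 40.0):
        x = np.sin(2 * np.pi * f * t)
        expect = 2 * np.sin(np.pi * f / fs)
        h = hjorth(SignalWindow(x, fs=fs))
        assert h.mobility == pytest.approx(expect, rel=0.01)
        assert h.complexity == pytest.approx(1.0, rel=0.01)


def test_sine_mobility_monotone_in_frequency():
    fs = 500.0
    t = np.arange(int(fs)) / fs
    freqs = [2, 5, 10, 20, 50, 100, 150, 200, 240]
    mobs = [hjorth(np.sin(2 * np.pi * f * t + 0.3)).mobility for f in freqs]
    assert all(a < b for a, b in zip(mobs, mobs[1:]))


def test_gaussian_and_uniform_kurtosis_limits():
    rng = np.random.default_rng(42)
    g = percentile_kurtosis(rng.standard_normal(100_000))
    assert g == pytest.approx(1.3490 / (2 * 2.5631), abs=0.01)
    u = percentile_kurtosis(rng.uniform(0, 1, 100_000))
    assert u == pytest.approx(0.5 / 1.6, abs=0.01)


# ---------------------------------------------------------------------------
# oracle equivalence on random windows


def _random_windows(n: int, length: int, seed: int) -> np.ndarray:
    """Mixed window population: Gaussian, uniform, scaled, and tied-value."""
    rng = np.random.default_rng(seed)
    out = np.empty((n, length))
    for i in range(n):
        kind = i % 4
        if kind == 0:
            out[i] = rng.standard_normal(length)
        elif kind == 1:
            out[i] = rng.uniform(-3, 3, length) * rng.uniform(0.1, 50)
        elif kind == 2:
            out[i] = rng.standard_normal(length) + rng.uniform(-10, 10)
        else:  # repeated values exercise the discrete-mode branch
            out[i] = rng.integers(-5, 6, length).astype(float)
    return out


@pytest.mark.parametrize("feature", FEATURE_NAMES)
def test_matches_formula_oracle_on_random_windows(feature):
    windows = _random_windows(1000, 64, seed=101)
    ds = WindowedDataset(
        windows[:, None, :], np.zeros(1000), ("X1",), fs=64.0
    )
    col = extract_features(ds, [feature]).values[:, 0]
    tol = 1e-8 if feature in ("kurtosis", "skewness") else 1e-10
    for i in range(1000):
        expected = oracle_feature(windows[i], feature)
        assert col[i] == pytest.approx(expected, rel=tol, abs=tol), (feature, i)


# ---------------------------------------------------------------------------
# invariance properties

_window = st.integers(0, 2**31 - 1).map(
    lambda s: np.random.default_rng(s).standard_normal(50)
)


@given(_window, st.floats(0.1, 100.0))
def test_scale_equivariance(x, a):
    f0 = {n: oracle_like(x, n) for n in FEATURE_NAMES}
    f1 = {n: oracle_like(a * x, n) for n in FEATURE_NAMES}
    assert f1["Activity"] == pytest.approx(a**2 * f0["Activity"], rel=1e-9)
    assert f1["Energy"] == pytest.approx(a**2 * f0["Energy"], rel=1e-9)
    assert f1["RMS"] == pytest.approx(a * f0["RMS"], rel=1e-9)
    assert f1["amplitude"] == pytest.approx(a * f0["amplitude"], rel=1e-9)
    for inv in ("Mobility", "Complexity", "Zero crossing", "skewness", "kurtosis"):
        assert f1[inv] == pytest.approx(f0[inv], rel=1e-7), inv


@given(_window, st.floats(-50.0, 50.0))
def test_shift_invariance(x, c):
    for inv in ("Mobility", "Complexity", "amplitude", "Activity"):
        assert oracle_like(x + c, inv) == pytest.approx(
            oracle_like(x, inv), rel=1e-7, abs=1e-9
        ), inv


def oracle_like(x, name):
    """Evaluate one feature through the production extraction path."""
    ds = WindowedDataset(x[None, None, :], np.zeros(1), ("Z",), fs=50.0)
    return float(extract_features(ds, [name]).values[0, 0])


@given(_window)
def test_rms_squared_is_energy(x):
    out = energy_rms(x)
    assert out["RMS"] ** 2 == pytest.approx(out["Energy"], rel=1e-12)


# ---------------------------------------------------------------------------
# attribute assembly


def test_full_montage_yields_247_attributes(small_split):
    from eegreduce.preprocess import binarize_labels

    train, _ = binarize_labels(small_split, 1.0)
    fm = extract_features(train)
    assert fm.n_attributes == 19 * 13 == 247
    assert len(set(fm.attribute_names)) == 247
    assert "Minimum_Fz" in fm.attribute_names
    assert "Zero_crossing_Fp2" in fm.attribute_names


def test_single_channel_yields_13_columns():
    rng = np.random.default_rng(0)
    ds = WindowedDataset(rng.normal(size=(4, 1, 100)), np.zeros(4), ("Fz",), 100.0)
    fm = extract_features(ds)
    assert fm.n_attributes == 13


def test_restricted_feature_channel_grid():
    rng = np.random.default_rng(0)
    chans = ("Fz", "C4", "T5", "F3", "Fp2", "O1")
    ds = WindowedDataset(
        rng.normal(size=(3, 6, 100)), np.zeros(3), chans, 100.0
    )
    fm = extract_features(
        ds,
        ["Activity", "Complexity", "Mobility", "Energy"],
        channels=("Fz", "C4", "T5", "F3", "Fp2"),
    )
    assert fm.n_attributes == 20
    assert "Activity_Fz" in fm.attribute_names


def test_attribute_names_round_trip():
    for feat in FEATURE_NAMES:
        name = attribute_name(feat, "T5")
        assert parse_attribute(name) == (feat, "T5")
    with pytest.raises(ValueError):
        parse_attribute("NotAFeature_Fz")
    with pytest.raises(KeyError):
        canonical_feature("variance")


def test_undefined_values_recorded_as_nan_not_zero():
    windows = np.zeros((2, 1, 50))
    windows[1, 0, :] = np.random.default_rng(1).normal(size=50)
    ds = WindowedDataset(windows, np.zeros(2), ("C3",), 50.0)
    fm = extract_features(ds, ["Mobility", "skewness"])
    assert np.isnan(fm.values[0]).all()  # flat window: undefined, not zero
    assert np.isfinite(fm.values[1]).all()
    cleaned, dropped = fm.dropna()
    assert dropped == 1 and cleaned.n_rows == 1
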