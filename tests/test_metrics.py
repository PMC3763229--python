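"""Oxygenation proportion, total-Hb normalization, time bins and peaks."""

import numpy as np
import pytest

from nirspeech import (
    ConfigurationError,
    HrfParams,
    MetricError,
    bin_mean,
    canonical_hrf,
    find_second_peak,
    normalize_hbt,
    oxygenation_proportion,
    shift_window_to_peak,
    total_hb,
)

FS = 250.0


# -- oxygenation proportion --------------------------------------------------

def test_balanced_chromophores_give_zero_change():
    x = np.full(100, 2.0)
    prop = oxygenation_proportion(x, x)
    np.testing.assert_allclose(prop.values, 0.0)
    assert prop.onset_proportion == 0.5


def test_saturated_case_is_flat():
    o2 = np.linspace(1.0, 3.0, 50)
    prop = oxygenation_proportion(o2, np.zeros(50))
    np.testing.assert_allclose(prop.values, 0.0, atol=1e-12)


def test_hand_computed_percent_change():
    o2 = np.array([2.0, 3.0])
    hh = np.array([2.0, 1.0])
    divisive = oxygenation_proportion(o2, hh)
    assert divisive.values[1] == pytest.approx(50.0)  # 0.5 -> 0.75
    additive = oxygenation_proportion(o2, hh, convention="additive")
    assert additive.values[1] == pytest.approx(25.0)  # percentage points


def test_ratio_invariant_under_common_rescaling(rng):
    o2 = rng.uniform(30, 50, 200)
    hh = rng.uniform(10, 25, 200)
    a = oxygenation_proportion(o2, hh)
    b = oxygenation_proportion(5.0 * o2, 5.0 * hh)
    np.testing.assert_allclose(a.values, b.values, rtol=1e-12)


def test_low_hbt_samples_flagged_not_dropped():
    o2 = np.array([2.0, 1e-6, 2.0])
    hh = np.array([2.0, -1e-6, 2.0])
    prop = oxygenation_proportion(o2, hh, hbt_floor=1e-3)
    assert prop.n_flagged == 1
    assert np.isnan(prop.values[1]) and np.isfinite(prop.values[2])


def test_onset_below_floor_is_an_error():
    with pytest.raises(MetricError):
        oxygenation_proportion(np.array([1e-6, 1.0]), np.array([-1e-6, 1.0]))


# -- total Hb and its normalization -----------------------------------------

def test_total_hb_is_exact_sum(rng):
    o2 = rng.normal(size=50)
    hh = rng.normal(size=50)
    np.testing.assert_array_equal(total_hb(o2, hh), o2 + hh)
    # additivity under channel averaging: mean of sums = sum of means
    np.testing.assert_allclose(
        total_hb(o2, hh).mean(), o2.mean() + hh.mean())


def test_normalize_forced_arithmetic():
    out = normalize_hbt(np.array([0.0, 2.0]))
    np.testing.assert_allclose(out.values, [-1.0, 1.0])  # mean 1, variance 1
    assert out.mean == 1.0 and out.divisor_value == 1.0


def test_normalize_round_trips_exactly(rng):
    x = rng.normal(2.0, 3.0, size=300)
    for divisor in ("variance", "sd"):
        out = normalize_hbt(x, divisor=divisor)
        np.testing.assert_allclose(out.reconstruct(), x, rtol=1e-12)
        assert abs(out.values.mean()) < 1e-12


def test_normalize_affine_invariance(rng):
    """With the variance divisor, normalize(a + b·x) = normalize(x)/b."""
    x = rng.normal(size=200)
    b = 2.5
    direct = normalize_hbt(3.0 + b * x).values
    np.testing.assert_allclose(direct, normalize_hbt(x).values / b, rtol=1e-9)


def test_constant_series_rejected():
    with pytest.raises(MetricError):
        normalize_hbt(np.full(10, 4.2))


# -- binning -----------------------------------------------------------------

def test_bin_mean_constant_and_ramp():
    assert bin_mean(np.full(int(16 * FS), 3.3), FS, (4.0, 7.0)) == pytest.approx(3.3)
    t = np.arange(int(16 * FS)) / FS
    got = bin_mean(t, FS, (4.0, 7.0))
    # half-open [4, 7): mean of the sample grid = 5.5 minus half a sample
    assert got == pytest.approx(5.5 - 0.5 / FS, abs=1e-12)
    dense = np.arange(int(16 * 25000)) / 25000.0
    oracle = dense[(dense >= 4.0) & (dense < 7.0)].mean()
    assert got == pytest.approx(oracle, abs=0.5 / FS + 1e-6)


def test_bin_decomposes_into_weighted_halves():
    rng = np.random.default_rng(3)
    x = rng.normal(size=int(16 * FS))
    whole = bin_mean(x, FS, (4.0, 7.0))
    left = bin_mean(x, FS, (4.0, 5.5))
    right = bin_mean(x, FS, (5.5, 7.0))
    assert whole == pytest.approx(0.5 * left + 0.5 * right, abs=1e-12)


def test_empty_window_rejected():
    with pytest.raises(MetricError):
        bin_mean(np.zeros(100), FS, (30.0, 33.0))


# -- window shifting ---------------------------------------------------------

def test_shift_centers_on_peak():
    t = np.arange(int(16 * FS)) / FS
    series = np.exp(-0.5 * ((t - 5.5) / 0.8) ** 2)
    res = shift_window_to_peak(series, FS, (3.0, 7.0), (2.0, 9.0))
    assert res.window[0] == pytest.approx(3.5, abs=1 / FS)
    assert res.window[1] == pytest.approx(7.5, abs=1 / FS)
    assert res.shift == pytest.approx(0.5, abs=1 / FS)
    assert not res.clipped and not res.flat


def test_shift_clips_at_epoch_edge():
    t = np.arange(int(16 * FS)) / FS
    series = np.exp(-0.5 * ((t - 15.0) / 0.5) ** 2)
    res = shift_window_to_peak(series, FS, (4.0, 10.0), (10.0, 16.0))
    assert res.clipped
    assert res.window[1] <= 16.0 + 1e-9


def test_flat_series_shift_flagged():
    res = shift_window_to_peak(np.zeros(int(16 * FS)), FS, (4.0, 7.0),
                               (2.0, 9.0))
    assert res.flat and res.shift == 0.0 and res.window == (4.0, 7.0)


def test_shift_recovers_early_nonspeech_peak():
    t = np.arange(int(16 * FS)) / FS
    series = canonical_hrf(t, HrfParams(peak_time=4.8))
    res = shift_window_to_peak(series, FS, (4.0, 7.0), (2.0, 9.0))
    center = 0.5 * (res.window[0] + res.window[1])
    assert center == pytest.approx(4.8, abs=1 / FS)


# -- second peak -------------------------------------------------------------

def test_second_peak_matches_dense_grid_oracle():
    t = np.arange(int(16 * FS)) / FS
    hrf = HrfParams(peak_time=5.5)
    lobe = canonical_hrf(t, hrf)
    series = lobe + np.concatenate([np.zeros(int(2 * FS)),
                                    lobe])[: t.size]
    got = find_second_peak(series, FS, window=(6.0, 16.0))
    dense = np.arange(0.0, 16.0, 1e-3)
    dl = canonical_hrf(dense, hrf)
    dsum = dl + np.concatenate([np.zeros(2000), dl])[: dense.size]
    m = (dense >= 6.0) & (dense <= 16.0)
    t_oracle = dense[m][dsum[m].argmax()]
    assert got.found
    assert got.time == pytest.approx(t_oracle, abs=1 / FS)


def test_decaying_series_has_no_second_peak():
    t = np.arange(int(16 * FS)) / FS
    series = canonical_hrf(t, HrfParams(peak_time=5.0, undershoot_ratio=0.0))
    res = find_second_peak(series, FS, window=(8.0, 16.0))
    assert not res.found and np.isnan(res.time)


def test_second_peak_location_invariant_under_added_constant():
    t = np.arange(int(16 * FS)) / FS
    lobe = canonical_hrf(t)
    series = lobe + np.concatenate([np.zeros(int(2 * FS)), lobe])[: t.size]
    a = find_second_peak(series, FS, window=(6.0, 16.0))
    b = find_second_peak(series + 7.0, FS, window=(6.0, 16.0))
    assert a.time == b.time
    assert b.amplitude == pytest.approx(a.amplitude + 7.0)


def test_unknown_conventions_rejected():
    with pytest.raises(ConfigurationError):
        oxygenation_proportion(np.ones(4), np.ones(4), convention="relative")
    with pytest.raises(ConfigurationError):
        normalize_hbt(np.arange(4.0), divisor="mad")
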