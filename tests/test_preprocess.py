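"""Filtering, spatial averaging, epoching and trial averaging."""

import numpy as np
import pytest

from nirspeech import (
    CONDITIONS,
    ConfigurationError,
    DataError,
    average_ipsilateral,
    combine_epochs,
    condition_average,
    epoch_series,
    estimate_hrf,
    filter_magnitude,
    lowpass,
    lowpass_series,
    null_effects,
    simulate_truth,
)
from nirspeech.recording import ChannelInfo, ChromophoreSeries

FS = 250.0


def _series(o2hb, hhb=None, fs=FS, channels=None):
    o2hb = np.atleast_2d(o2hb)
    hhb = o2hb.copy() if hhb is None else np.atleast_2d(hhb)
    if channels is None:
        channels = [ChannelInfo("left", 0), ChannelInfo("right", 0)][: o2hb.shape[0]]
    return ChromophoreSeries(fs, channels, o2hb, hhb)


# -- low-pass filter ---------------------------------------------------------

def test_dc_gain_is_unity():
    x = np.full(5000, 3.7)
    np.testing.assert_allclose(lowpass(x, FS), x, atol=1e-9)
    assert lowpass(x, FS).shape == x.shape


def test_magnitude_at_cutoff_is_half_power():
    assert filter_magnitude(10.0, 10.0, FS)[0] == pytest.approx(
        1.0 / np.sqrt(2.0), abs=1e-9)


def test_stopband_magnitude_matches_closed_form():
    """The designed digital Butterworth matches its bilinear-transform closed
    form |H| = 1/sqrt(1 + (tan(pi f/fs)/tan(pi fc/fs))^(2n)) everywhere; at
    50 Hz that is about -76 dB (the analog idealization gives about -70 dB)."""
    fc, f = 10.0, 50.0
    got = filter_magnitude(f, fc, FS)[0]
    expected = 1.0 / np.sqrt(
        1.0 + (np.tan(np.pi * f / FS) / np.tan(np.pi * fc / FS)) ** 10)
    assert got == pytest.approx(expected, abs=1e-6)
    assert 20 * np.log10(got) < -69.0


def test_cutoff_at_or_above_nyquist_rejected():
    with pytest.raises(ConfigurationError):
        lowpass(np.zeros(100), FS, cutoff_hz=125.0)


def test_filter_epoch_commute_away_from_edges(tiny_schedule):
    rng = np.random.default_rng(0)
    truth = simulate_truth(tiny_schedule, null_effects(), FS)
    noisy = truth.copy_with(o2hb=truth.o2hb + rng.normal(0, 0.1, truth.o2hb.shape),
                            hhb=truth.hhb + rng.normal(0, 0.1, truth.hhb.shape))
    filtered_then_epoched = epoch_series(lowpass_series(noisy), tiny_schedule)
    margin = int(2.0 * FS)
    for cond in filtered_then_epoched.conditions:
        onset = [e.onset for e in tiny_schedule.entries if e.condition == cond][0]
        start = int(np.ceil(onset * FS))
        raw_epoch = np.stack([noisy.o2hb[:, start:start + int(16 * FS)],
                              noisy.hhb[:, start:start + int(16 * FS)]], axis=1)
        epoch_then_filtered = lowpass(raw_epoch, FS)
        a = filtered_then_epoched.trials[cond][0][..., margin:-margin]
        b = epoch_then_filtered[..., margin:-margin]
        assert np.max(np.abs(a - b)) < 1e-9


# -- ipsilateral averaging ---------------------------------------------------

def test_identical_channels_average_to_themselves(rng):
    x = rng.normal(size=100)
    chans = [ChannelInfo("left", 1), ChannelInfo("left", 2),
             ChannelInfo("right", 1), ChannelInfo("right", 2)]
    s = _series(np.vstack([x, x, -x, -x]), channels=chans)
    avg = average_ipsilateral(s)
    np.testing.assert_allclose(avg.o2hb[0], x)
    np.testing.assert_allclose(avg.o2hb[1], -x)


def test_opposite_channels_cancel(rng):
    x = rng.normal(size=100)
    chans = [ChannelInfo("left", 1), ChannelInfo("left", 2),
             ChannelInfo("right", 1)]
    s = _series(np.vstack([x, -x, x]), channels=chans)
    np.testing.assert_allclose(average_ipsilateral(s).o2hb[0], 0.0, atol=1e-15)


def test_averaging_reduces_noise_sd_by_sqrt2(rng):
    n = 20_000
    chans = [ChannelInfo("left", 1), ChannelInfo("left", 2),
             ChannelInfo("right", 1), ChannelInfo("right", 2)]
    noise = rng.normal(0, 1.0, size=(4, n))
    avg = average_ipsilateral(_series(noise, channels=chans))
    assert np.std(avg.o2hb[0]) == pytest.approx(1.0 / np.sqrt(2), rel=0.05)


def test_missing_hemisphere_rejected(rng):
    s = _series(rng.normal(size=(1, 50)),
                channels=[ChannelInfo("left", 1)])
    with pytest.raises(DataError, match="right"):
        average_ipsilateral(s)


# -- epoching ----------------------------------------------------------------

def test_constant_series_gives_constant_epochs(tiny_schedule):
    n = int(96 * FS)
    s = _series(np.full((2, n), 1.5))
    epochs = epoch_series(s, tiny_schedule)
    for c in epochs.conditions:
        assert np.all(epochs.trials[c] == 1.5)
    assert epochs.n_rejected == 0


def test_impulse_alignment(tiny_schedule):
    n = int(96 * FS)
    data = np.zeros((2, n))
    onset = tiny_schedule.onsets(1)[2]
    cond = tiny_schedule.run_entries(1)[2].condition
    data[0, int((onset + 5.0) * FS)] = 1.0
    epochs = epoch_series(_series(data), tiny_schedule)
    trial = epochs.trials[cond][0]
    assert trial[0, 0].argmax() == int(5.0 * FS)
    for other in epochs.conditions:
        if other != cond:
            assert not epochs.trials[other].any()


def test_out_of_range_onsets_rejected_and_counted(tiny_schedule):
    n = int(60 * FS)  # room for the first two trials only
    epochs = epoch_series(_series(np.zeros((2, n))), tiny_schedule)
    kept = sum(epochs.n_trials(c) for c in epochs.conditions)
    assert kept == 2
    assert epochs.n_rejected == 3


def test_noise_free_epochs_identical_across_trials(full_schedule):
    """With 16-s spacing and a response that decays below 1 % of peak within
    a trial, all 20 epochs of a category equal the single-trial response."""
    fs = 50.0
    effects = null_effects()
    parts = []
    for run in full_schedule.run_indices:
        truth = simulate_truth(full_schedule, effects, fs, run_index=run)
        parts.append(epoch_series(truth, full_schedule, run_index=run))
    epochs = combine_epochs(parts)
    amp = 0.25
    for c in epochs.conditions:
        arr = epochs.trials[c][:, 0, 0]  # left O2Hb
        assert arr.shape[0] == 20
        spread = np.max(np.abs(arr - arr.mean(axis=0)))
        assert spread < 0.015 * amp


# -- condition averaging and HRF estimation ---------------------------------

def test_single_trial_average_is_the_trial(tiny_schedule):
    n = int(96 * FS)
    rng = np.random.default_rng(1)
    s = _series(rng.normal(size=(2, n)))
    epochs = epoch_series(s, tiny_schedule)
    avg = condition_average(epochs)
    c = epochs.conditions[0]
    np.testing.assert_array_equal(avg.mean[c], epochs.trials[c][0])
    np.testing.assert_array_equal(avg.sd[c], 0.0)


def test_average_converges_at_root_n(rng):
    truth = np.sin(np.linspace(0, 3, 400))
    sd = 0.5
    n_trials = 20
    trials = truth + rng.normal(0, sd, size=(n_trials, 2, 2, 400))
    from nirspeech.preprocess import EpochSet
    import pandas as pd
    epochs = EpochSet(window=(0.0, 16.0), sampling_rate=25.0,
                      trials={"word": trials},
                      provenance=pd.DataFrame({"condition": ["word"] * n_trials}))
    avg = condition_average(epochs)
    rms = np.sqrt(np.mean((avg.mean["word"] - truth) ** 2))
    assert rms < sd / np.sqrt(n_trials) * 1.5


def test_condition_average_permutation_invariant(rng):
    import pandas as pd
    from nirspeech.preprocess import EpochSet
    trials = rng.normal(size=(8, 2, 2, 100))
    perm = rng.permutation(8)
    make = lambda arr: EpochSet(window=(0.0, 4.0), sampling_rate=25.0,
                                trials={"word": arr},
                                provenance=pd.DataFrame({"condition": ["word"] * 8}))
    a = condition_average(make(trials))
    b = condition_average(make(trials[perm]))
    np.testing.assert_allclose(a.mean["word"], b.mean["word"])
    np.testing.assert_allclose(a.sd["word"], b.sd["word"])


def test_hrf_ttp_recovers_generator_peak(single_run_schedule):
    fs = 250.0
    truth = simulate_truth(single_run_schedule, null_effects(), fs)
    epochs = epoch_series(truth, single_run_schedule)
    est = estimate_hrf(epochs)
    assert est.ttp("left", "o2hb") == pytest.approx(5.5, abs=1 / fs)
    assert est.n_trials == 25


def test_monotone_input_flags_boundary_peak(tiny_schedule):
    n = int(96 * FS)
    drift = np.tile(np.linspace(0, 1, n), (2, 1))
    epochs = epoch_series(_series(drift), tiny_schedule)
    est = estimate_hrf(epochs, search_window=(3.0, 9.0))
    assert est.boundary.all()
    assert est.ttp("left", "o2hb") == pytest.approx(9.0, abs=1 / FS)


def test_ttp_invariant_under_positive_affine_scaling(single_run_schedule):
    fs = 50.0
    truth = simulate_truth(single_run_schedule, null_effects(), fs)
    scaled = truth.copy_with(o2hb=3.0 * truth.o2hb + 2.0,
                             hhb=3.0 * truth.hhb + 2.0)
    a = estimate_hrf(epoch_series(truth, single_run_schedule))
    b = estimate_hrf(epoch_series(scaled, single_run_schedule))
    np.testing.assert_array_equal(a.time_to_peak, b.time_to_peak)


def test_flat_series_flagged(tiny_schedule):
    n = int(96 * FS)
    epochs = epoch_series(_series(np.zeros((2, n))), tiny_schedule)
    est = estimate_hrf(epochs)
    assert est.flat.all()
    assert np.isnan(est.time_to_peak).all()
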