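"""Estimate the hemodynamic response from event-locked trial averages.

Simulates one noisy 25-trial run, filters (10-Hz zero-phase Butterworth),
averages the two ipsilateral optode pairs per hemisphere, epochs at stimulus
onsets and averages all trials.  The grand-average time-to-peak lands in the
5–6 s range typical of auditory responses.
"""

import numpy as np

from nirspeech import (
    CONDITIONS,
    NoiseSpec,
    average_ipsilateral,
    epoch_series,
    estimate_hrf,
    generate_schedule,
    lowpass_series,
    null_effects,
    replicate_channels,
    simulate_truth,
    add_noise,
)

rng = np.random.default_rng(3)
schedule = generate_schedule(1, 25, CONDITIONS, 5, rng=rng)
truth = simulate_truth(schedule, null_effects(), 250.0, rng=rng)
channels = replicate_channels(truth, pairs_per_hemisphere=2)
noisy = add_noise(channels, NoiseSpec(white_sd=0.3), rng=rng)

filtered = lowpass_series(noisy)
averaged = average_ipsilateral(filtered)
epochs = epoch_series(averaged, schedule)
est = estimate_hrf(epochs)

print(f"trials averaged: {est.n_trials}")
for hemi in ("left", "right"):
    print(f"{hemi:>5} O2Hb time-to-peak: {est.ttp(hemi, 'o2hb'):.3f} s")
# The generator peak is 5.5 s; averaging 25 noisy trials recovers it to within
# a few samples despite cardiac/respiratory oscillations and white noise.
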