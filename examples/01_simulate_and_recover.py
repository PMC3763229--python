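"""Simulate a run, push it through the optical forward model, and invert it.

Builds a 5-trial run with one 0.5-µM word response, converts the chromophore
truth to two-wavelength attenuation with the modified Beer–Lambert law, and
inverts it back.  The round-trip error is at numerical precision and the
recovered left-hemisphere O₂Hb course peaks at the configured amplitude one
HRF peak time after the word onset.
"""

import numpy as np

from nirspeech import (
    CONDITIONS,
    EffectSpec,
    ExtinctionMatrix,
    convert_recording,
    forward_attenuation,
    generate_schedule,
    simulate_truth,
)
from nirspeech.simulate import ConditionEffect

zero = {"left": 0.0, "right": 0.0}
effects = EffectSpec(conditions={
    c: ConditionEffect(o2hb={"left": 0.5, "right": 0.0} if c == "word" else zero,
                       hhb=zero)
    for c in CONDITIONS})

schedule = generate_schedule(1, 5, CONDITIONS, 1, seed=7)
truth = simulate_truth(schedule, effects, sampling_rate=250.0)

eps = ExtinctionMatrix.default()
recording = forward_attenuation(truth, eps)
recovered = convert_recording(recording, eps)

err = np.max(np.abs(recovered.o2hb - truth.o2hb))
onset = [e.onset for e in schedule.entries if e.condition == "word"][0]
left = recovered.o2hb[0]
t_peak = recovered.times[left.argmax()]

print(f"word onset: {onset:.0f} s")
print(f"MBLL round-trip max abs error: {err:.3e} µM")
print(f"recovered peak: {left.max():.4f} µM at {t_peak:.3f} s "
      f"(= onset + 5.5 s HRF peak)")
# The round-trip error is floating-point noise; the peak equals the configured
# 0.5 µM amplitude at onset + 5.5 s because attenuation and inversion are an
# exact linear pair.
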