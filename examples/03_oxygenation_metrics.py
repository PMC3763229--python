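"""Oxygenation-proportion and total-Hb metrics on condition averages.

Simulates one subject with the default condition effects (noise off for a
clean picture), averages trials per category and prints the 4–7 s binned
percent change of O₂Hb over total Hb — the left-lateralized speech effect —
plus the late production-locked peak of the speech categories.
"""

from dataclasses import replace

import numpy as np

from nirspeech import (
    NoiseSpec,
    default_effects,
    find_second_peak,
    generate_schedule,
    oxygenation_proportion,
    bin_mean,
)
from nirspeech.design import CONDITIONS, SPEECH_CONDITIONS
from nirspeech.experiments import (
    BASELINE_HHB_UM,
    BASELINE_O2HB_UM,
    simulate_subject_averages,
)

rng = np.random.default_rng(11)
schedule = generate_schedule(4, 25, CONDITIONS, 20, rng=rng)
effects = replace(default_effects(), subject_sd_o2hb=0.0, subject_sd_hhb=0.0)
averages = simulate_subject_averages(schedule, effects, NoiseSpec.zero(),
                                     50.0, rng)

print("percent change of O2Hb over total Hb, 4-7 s bin:")
for cond in CONDITIONS:
    row = []
    for hemi in ("left", "right"):
        o2 = averages.course(cond, hemi, "o2hb") + BASELINE_O2HB_UM
        hh = averages.course(cond, hemi, "hhb") + BASELINE_HHB_UM
        prop = oxygenation_proportion(o2, hh)
        row.append(bin_mean(prop.values, 50.0, (4.0, 7.0)))
    print(f"  {cond:>16}: left {row[0]:+.3f} %   right {row[1]:+.3f} %")

print("\nlate (production-locked) peak, left hemisphere:")
for cond in SPEECH_CONDITIONS + ("natural",):
    o2 = averages.course(cond, "left", "o2hb") + BASELINE_O2HB_UM
    hh = averages.course(cond, "left", "hhb") + BASELINE_HHB_UM
    prop = oxygenation_proportion(o2, hh)
    peak = find_second_peak(prop.values, 50.0, window=(6.0, 16.0))
    print(f"  {cond:>16}: "
          + (f"{peak.time:.2f} s ({peak.amplitude:+.3f} %)" if peak.found
             else "absent"))
# Speech categories carry a clear positive 4-7 s proportion change on the left
# (pseudoword > word) and a late ~1 % peak from the repetition response; for
# passively heard categories the detector at most picks up a near-zero wiggle
# of the flat proportion course.
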