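"""End-to-end synthetic experiments: simulate → convert → preprocess → bin.

These helpers run the whole pipeline in memory and return the time-binned
observation table the group statistics consume.  They are the workhorses of
the package's self-calibration: the type-I error of the condition test under a
null generator, and the power of the left-hemisphere pseudoword − word
contrast as a function of the configured effect size.

Monte-Carlo calibration runs use a reduced simulation rate (25 Hz by default;
all modeled noise components sit far below that Nyquist) and the reduced
designs noted in each function; single-run spot checks elsewhere in the
package use the full 250 Hz acquisition rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import (
    CONDITIONS,
    NONSPEECH_CONDITIONS,
    EventSchedule,
    generate_schedule,
)
from .mbll import ExtinctionMatrix, convert_recording, forward_attenuation
from .metrics import (
    WINDOWS,
    bin_mean,
    normalize_hbt,
    oxygenation_proportion,
    shift_window_to_peak,
    total_hb,
)
from .preprocess import (
    ConditionAverages,
    average_ipsilateral,
    combine_epochs,
    condition_average,
    epoch_series,
    lowpass_series,
)
from .recording import HEMISPHERES, replicate_channels
from .simulate import (
    EffectSpec,
    NoiseSpec,
    add_noise,
    default_effects,
    null_effects,
    perturb_effects,
    simulate_truth,
)
from .stats import paired_contrast, two_way_anova

#: Baseline resting concentrations (µM) added before forming the oxygenation
#: proportion: ~60 µM total hemoglobin at ~70 % saturation, typical of adult
#: frontal cortex.  The proportion of bare concentration *changes* is
#: ill-posed where ΔHbT crosses zero.
BASELINE_O2HB_UM = 42.0
BASELINE_HHB_UM = 18.0


@dataclass(frozen=True)
class AnalysisOptions:
    """Knobs of the analysis stages (defaults follow the acquisition spec)."""

    cutoff_hz: float = 10.0
    filter_order: int = 5
    epoch_window: tuple[float, float] = (0.0, 16.0)
    windows: dict = field(default_factory=lambda: dict(WINDOWS))
    convention: str = "divisive"
    divisor: str = "variance"
    hbt_floor: float = 1e-3
    baseline_o2hb: float = BASELINE_O2HB_UM
    baseline_hhb: float = BASELINE_HHB_UM
    shift_nonspeech: bool = False
    shift_search: tuple[float, float] = (2.0, 9.0)


def subject_binned_rows(subject: str, averages: ConditionAverages,
                        options: AnalysisOptions | None = None) -> list[dict]:
    """One scalar per (condition, hemisphere, measure, window) for a subject.

    Measures emitted: ``proportion`` (peak and early bins), ``hbt_norm``
    (2–6 s bin) and the raw ``o2hb`` / ``hhb`` / ``hbt`` peak-bin means.  When
    ``shift_nonspeech`` is on, the peak-dependent bins of the passively heard
    categories are re-centered on each course's observed peak (their responses
    peak earlier than speech).
    """
    options = options or AnalysisOptions()
    fs = averages.sampling_rate
    t0 = averages.window[0]
    rows: list[dict] = []

    def add(condition, hemisphere, measure, window_name, value):
        rows.append(dict(subject=subject, condition=condition,
                         hemisphere=hemisphere, measure=measure,
                         window=window_name, value=value))

    for condition in sorted(averages.mean):
        for hemisphere in HEMISPHERES:
            o2 = averages.course(condition, hemisphere, "o2hb")
            hh = averages.course(condition, hemisphere, "hhb")
            prop = oxygenation_proportion(
                o2 + options.baseline_o2hb, hh + options.baseline_hhb,
                onset_index=0, hbt_floor=options.hbt_floor,
                convention=options.convention)
            hbtn = normalize_hbt(total_hb(o2, hh), divisor=options.divisor)

            shiftable = (options.shift_nonspeech
                         and condition in NONSPEECH_CONDITIONS)

            def window_for(series, name):
                base = options.windows[name]
                if shiftable and name in ("peak_bin", "hbt_bin"):
                    span = (averages.window[0], averages.window[1])
                    return shift_window_to_peak(
                        series, fs, base, options.shift_search,
                        t0=t0, epoch_span=span).window
                return base

            add(condition, hemisphere, "proportion", "peak_bin",
                bin_mean(prop.values, fs, window_for(prop.values, "peak_bin"), t0))
            add(condition, hemisphere, "proportion", "early_bin",
                bin_mean(prop.values, fs, options.windows["early_bin"], t0))
            add(condition, hemisphere, "hbt_norm", "hbt_bin",
                bin_mean(hbtn.values, fs, window_for(hbtn.values, "hbt_bin"), t0))
            for measure, series in (("o2hb", o2), ("hhb", hh),
                                    ("hbt", total_hb(o2, hh))):
                add(condition, hemisphere, measure, "peak_bin",
                    bin_mean(series, fs, options.windows["peak_bin"], t0))
    return rows


def simulate_subject_averages(schedule: EventSchedule, effects: EffectSpec,
                              noise: NoiseSpec, sampling_rate: float,
                              rng: np.random.Generator, *,
                              pairs_per_hemisphere: int = 2,
                              extinction: ExtinctionMatrix | None = None,
                              options: AnalysisOptions | None = None
                              ) -> ConditionAverages:
    """Full forward + analysis chain for one subject, returning trial averages.

    The subject's amplitudes are an independent draw around ``effects``; each
    run is simulated, pushed through the optical forward model, inverted,
    filtered, spatially averaged and epoched; epochs from all runs are pooled.
    """
    options = options or AnalysisOptions()
    extinction = extinction or ExtinctionMatrix.default()
    perturbed = perturb_effects(effects, rng)
    epoch_sets = []
    for run in schedule.run_indices:
        truth = simulate_truth(schedule, perturbed, sampling_rate,
                               run_index=run, rng=rng,
                               trial_jitter_sd=noise.trial_jitter_sd)
        channels = replicate_channels(truth, pairs_per_hemisphere)
        noisy = add_noise(channels, noise, rng=rng)
        recording = forward_attenuation(noisy, extinction)
        conc = convert_recording(recording, extinction)
        filtered = lowpass_series(conc, options.cutoff_hz, options.filter_order)
        averaged = average_ipsilateral(filtered)
        epoch_sets.append(epoch_series(averaged, schedule, run_index=run,
                                       window=options.epoch_window))
    return condition_average(combine_epochs(epoch_sets))


def simulate_binned_table(n_subjects: int, effects: EffectSpec,
                          noise: NoiseSpec, *,
                          n_runs: int = 4, trials_per_run: int = 25,
                          trials_per_condition: int = 20,
                          sampling_rate: float = 250.0,
                          seed: int = 0,
                          pairs_per_hemisphere: int = 2,
                          extinction: ExtinctionMatrix | None = None,
                          options: AnalysisOptions | None = None
                          ) -> pd.DataFrame:
    """Simulate a whole group and return the binned observation table.

    Every subject gets an independent seed stream (schedule order, amplitude
    draw, trial jitter and noise), derived deterministically from ``seed``.
    """
    extinction = extinction or ExtinctionMatrix.default()
    streams = np.random.SeedSequence(seed).spawn(n_subjects)
    rows: list[dict] = []
    for s, stream in enumerate(streams, start=1):
        rng = np.random.default_rng(stream)
        schedule = generate_schedule(n_runs, trials_per_run, CONDITIONS,
                                     trials_per_condition, rng=rng)
        averages = simulate_subject_averages(
            schedule, effects, noise, sampling_rate, rng,
            pairs_per_hemisphere=pairs_per_hemisphere,
            extinction=extinction, options=options)
        rows.extend(subject_binned_rows(f"S{s:02d}", averages, options))
    return pd.DataFrame(rows)


def _proportion_peak_table(table: pd.DataFrame) -> pd.DataFrame:
    return table[(table.measure == "proportion") & (table.window == "peak_bin")]


def type_one_error_rate(n_experiments: int = 1000, *,
                        n_subjects: int = 5, n_runs: int = 1,
                        trials_per_run: int = 25, trials_per_condition: int = 5,
                        sampling_rate: float = 25.0,
                        noise: NoiseSpec | None = None,
                        alpha: float = 0.05,
                        strategy: str = "subject_blocked",
                        seed: int = 0) -> dict:
    """Rejection rate of the condition main effect under the full synthetic null.

    Every experiment uses a generator with identical responses for all five
    categories (realistic noise on) and runs the complete pipeline down to the
    condition × hemisphere ANOVA on the 4–7 s oxygenation-proportion bin.
    With a valid test the rate estimates α.
    """
    noise = noise or NoiseSpec()
    effects = null_effects()
    master = np.random.SeedSequence(seed).spawn(n_experiments)
    rejections = 0
    for stream in master:
        exp_seed = int(stream.generate_state(1)[0] % (2**31))
        table = simulate_binned_table(
            n_subjects, effects, noise, n_runs=n_runs,
            trials_per_run=trials_per_run,
            trials_per_condition=trials_per_condition,
            sampling_rate=sampling_rate, seed=exp_seed)
        res = two_way_anova(_proportion_peak_table(table),
                            strategy=strategy, alpha=alpha)
        if res.effect("condition").p < alpha:
            rejections += 1
    return dict(rate=rejections / n_experiments, n=n_experiments,
                alpha=alpha, n_subjects=n_subjects)


def contrast_power(n_experiments: int = 200, *,
                   pseudoword_excess: float = 0.30,
                   n_subjects: int = 15, n_runs: int = 1,
                   trials_per_run: int = 25, trials_per_condition: int = 5,
                   sampling_rate: float = 25.0,
                   noise: NoiseSpec | None = None,
                   alpha: float = 0.05,
                   seed: int = 0) -> dict:
    """Empirical power of the left-hemisphere pseudoword − word paired contrast.

    The generator places a pseudoword O₂Hb excess of ``pseudoword_excess`` µM
    at the left hemisphere only; the contrast tests the 4–7 s binned
    oxygenation proportion across subjects.
    """
    noise = noise or NoiseSpec()
    effects = default_effects(pseudoword_excess=pseudoword_excess)
    master = np.random.SeedSequence(seed).spawn(n_experiments)
    rejections = 0
    for stream in master:
        exp_seed = int(stream.generate_state(1)[0] % (2**31))
        table = simulate_binned_table(
            n_subjects, effects, noise, n_runs=n_runs,
            trials_per_run=trials_per_run,
            trials_per_condition=trials_per_condition,
            sampling_rate=sampling_rate, seed=exp_seed)
        res = paired_contrast(_proportion_peak_table(table),
                              ("pseudoword", "word"), hemisphere="left")
        if res.p < alpha:
            rejections += 1
    return dict(power=rejections / n_experiments, n=n_experiments,
                pseudoword_excess=pseudoword_excess, alpha=alpha,
                n_subjects=n_subjects)
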