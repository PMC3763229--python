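"""Synthetic verbal-repetition experiments with a recoverable ground truth.

The generator reproduces the study design — 15 subjects × 4 runs × 25 trials,
20 trials per category, 16-s trials after a 16-s dummy — and drives a linear
forward model: every trial adds ``amplitude × HRF`` shifted to its onset, and
the two speech categories add a second, production-locked response 2 s later.
Physiological noise (cardiac, respiratory and Mayer-wave oscillations, slow
drift) plus white instrument noise is added per channel, and the noisy
chromophore series are pushed through the forward Beer–Lambert model to yield
two-wavelength optical recordings whose analysis should recover the configured
condition effects.

Between-subject variability is modeled as independent normal perturbations of
every response amplitude; the default amplitudes below place a clear
left-lateralized pseudoword > word oxygenation effect on top of weak right-
hemisphere responses, with balanced O₂Hb/HHb increases (a total-Hb response
without an oxygenation-proportion response) for the passively heard categories.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy.signal import fftconvolve

from .design import (
    CONDITIONS,
    NONSPEECH_CONDITIONS,
    PRODUCTION_DELAY,
    SPEECH_CONDITIONS,
    EventSchedule,
)
from .exceptions import ConfigurationError, DataError
from .hrf import DEFAULT_HRF, HrfParams, hrf_kernel
from .recording import HEMISPHERES, ChannelInfo, ChromophoreSeries

CHROMOPHORES = ("o2hb", "hhb")


@dataclass(frozen=True)
class ConditionEffect:
    """Peak response amplitudes (µM) for one stimulus category.

    ``o2hb`` / ``hhb`` map hemisphere → perception-locked peak amplitude.
    ``production_o2hb`` / ``production_hhb`` are the production-locked second
    response (speech categories only); ``None`` disables it.
    """

    o2hb: Mapping[str, float]
    hhb: Mapping[str, float]
    production_o2hb: Mapping[str, float] | None = None
    production_hhb: Mapping[str, float] | None = None
    hrf: HrfParams = DEFAULT_HRF

    def amplitude(self, phase: str, chromophore: str, hemisphere: str) -> float:
        table = getattr(self, chromophore if phase == "perception"
                        else f"production_{chromophore}")
        if table is None:
            return 0.0
        return float(table[hemisphere])

    @property
    def has_production(self) -> bool:
        return self.production_o2hb is not None or self.production_hhb is not None


@dataclass(frozen=True)
class EffectSpec:
    """Ground-truth response specification for a whole experiment."""

    conditions: Mapping[str, ConditionEffect]
    production_delay: float = PRODUCTION_DELAY
    subject_sd_o2hb: float = 0.07
    subject_sd_hhb: float = 0.03

    def __post_init__(self) -> None:
        for name, eff in self.conditions.items():
            for table in (eff.o2hb, eff.hhb, eff.production_o2hb, eff.production_hhb):
                if table is not None and any(not np.isfinite(v) for v in table.values()):
                    raise ConfigurationError(f"non-finite amplitude for {name!r}")
            if eff.has_production and name not in SPEECH_CONDITIONS:
                raise ConfigurationError(
                    f"production response defined for non-speech condition {name!r}"
                )


@dataclass(frozen=True)
class NoiseSpec:
    """Additive noise model: physiological sinusoids, drift and white noise.

    Amplitudes are in µM (white sd per sample at the simulation rate); the
    drift slope is µM/s.  ``trial_jitter_sd`` multiplies each trial's response
    amplitudes by ``1 + N(0, sd)``.
    """

    cardiac_hz: float = 1.1
    cardiac_amp: float = 0.06
    respiratory_hz: float = 0.25
    respiratory_amp: float = 0.04
    mayer_hz: float = 0.1
    mayer_amp: float = 0.05
    drift_slope: float = 2e-4
    white_sd: float = 0.2
    trial_jitter_sd: float = 0.1

    def validate(self, sampling_rate: float) -> None:
        amps = (self.cardiac_amp, self.respiratory_amp, self.mayer_amp,
                self.white_sd, self.trial_jitter_sd)
        if any(a < 0 for a in amps):
            raise ConfigurationError("noise amplitudes must be nonnegative")
        nyquist = sampling_rate / 2.0
        for f in (self.cardiac_hz, self.respiratory_hz, self.mayer_hz):
            if not 0 < f < nyquist:
                raise ConfigurationError(
                    f"noise component at {f} Hz is outside (0, Nyquist={nyquist} Hz)"
                )

    @classmethod
    def zero(cls) -> "NoiseSpec":
        return cls(cardiac_amp=0.0, respiratory_amp=0.0, mayer_amp=0.0,
                   drift_slope=0.0, white_sd=0.0, trial_jitter_sd=0.0)

    @property
    def components(self) -> tuple[tuple[float, float], ...]:
        return ((self.cardiac_hz, self.cardiac_amp),
                (self.respiratory_hz, self.respiratory_amp),
                (self.mayer_hz, self.mayer_amp))


_SPEECH_HRF = DEFAULT_HRF
_NONSPEECH_HRF = replace(DEFAULT_HRF, peak_time=4.8)


def default_effects(pseudoword_excess: float = 0.30) -> EffectSpec:
    """Study-scale condition effects.

    Speech categories drive a left-lateralized oxygenation response (pseudoword
    exceeding word by ``pseudoword_excess`` µM of O₂Hb) with a production-locked
    second response equal to the perception response; passive categories raise
    O₂Hb and HHb together (total-Hb response, flat oxygenation proportion) and
    peak slightly earlier (4.8 s vs 5.5 s).
    """
    word_o2, word_hh = 0.25, -0.08
    pwd_o2 = word_o2 + pseudoword_excess
    # HHb dips scale with the oxygenation excess; zero excess makes the two
    # speech categories identical, giving a clean effect-size axis.
    pwd_hh = word_hh - (2.0 / 15.0) * pseudoword_excess
    conditions = {
        "natural": ConditionEffect(
            o2hb={"left": 0.15, "right": -0.05},
            hhb={"left": 0.12, "right": -0.04},
            hrf=_NONSPEECH_HRF,
        ),
        "animal": ConditionEffect(
            o2hb={"left": 0.12, "right": -0.05},
            hhb={"left": 0.10, "right": -0.04},
            hrf=_NONSPEECH_HRF,
        ),
        "human_nonspeech": ConditionEffect(
            o2hb={"left": 0.18, "right": 0.06},
            hhb={"left": 0.14, "right": 0.05},
            hrf=_NONSPEECH_HRF,
        ),
        "pseudoword": ConditionEffect(
            o2hb={"left": pwd_o2, "right": 0.05},
            hhb={"left": pwd_hh, "right": 0.02},
            production_o2hb={"left": pwd_o2, "right": 0.05},
            production_hhb={"left": pwd_hh, "right": 0.02},
            hrf=_SPEECH_HRF,
        ),
        "word": ConditionEffect(
            o2hb={"left": word_o2, "right": 0.05},
            hhb={"left": word_hh, "right": 0.02},
            production_o2hb={"left": word_o2, "right": 0.05},
            production_hhb={"left": word_hh, "right": 0.02},
            hrf=_SPEECH_HRF,
        ),
    }
    return EffectSpec(conditions=conditions)


def null_effects(o2hb: tuple[float, float] = (0.25, 0.05),
                 hhb: tuple[float, float] = (-0.08, 0.02),
                 hrf: HrfParams = DEFAULT_HRF) -> EffectSpec:
    """All five categories share one response: no condition effect anywhere."""
    eff = ConditionEffect(
        o2hb={"left": o2hb[0], "right": o2hb[1]},
        hhb={"left": hhb[0], "right": hhb[1]},
        hrf=hrf,
    )
    return EffectSpec(conditions={c: eff for c in CONDITIONS})


def perturb_effects(spec: EffectSpec, rng: np.random.Generator) -> EffectSpec:
    """One subject's draw: independent normal jitter on every amplitude."""
    new = {}
    for name, eff in spec.conditions.items():
        def jitter(table, sd):
            if table is None:
                return None
            return {h: v + rng.normal(0.0, sd) for h, v in table.items()}
        new[name] = ConditionEffect(
            o2hb=jitter(eff.o2hb, spec.subject_sd_o2hb),
            hhb=jitter(eff.hhb, spec.subject_sd_hhb),
            production_o2hb=jitter(eff.production_o2hb, spec.subject_sd_o2hb),
            production_hhb=jitter(eff.production_hhb, spec.subject_sd_hhb),
            hrf=eff.hrf,
        )
    return replace(spec, conditions=new)


def effects_truth(spec: EffectSpec) -> list[dict]:
    """Flat ground-truth rows (condition, hemisphere, chromophore, phase, amplitude)."""
    rows = []
    for name in sorted(spec.conditions):
        eff = spec.conditions[name]
        for hemi in HEMISPHERES:
            for chrom in CHROMOPHORES:
                rows.append(dict(condition=name, hemisphere=hemi,
                                 chromophore=chrom, phase="perception",
                                 amplitude=eff.amplitude("perception", chrom, hemi),
                                 hrf_peak=eff.hrf.peak_time))
                if eff.has_production:
                    rows.append(dict(condition=name, hemisphere=hemi,
                                     chromophore=chrom, phase="production",
                                     amplitude=eff.amplitude("production", chrom, hemi),
                                     hrf_peak=eff.hrf.peak_time))
    return rows


def simulate_truth(schedule: EventSchedule, effects: EffectSpec,
                   sampling_rate: float = 250.0, *,
                   run_index: int | None = None,
                   seed: int | None = None,
                   rng: np.random.Generator | None = None,
                   trial_jitter_sd: float = 0.0) -> ChromophoreSeries:
    """Noise-free forward model of one run: superposed HRF-shaped responses.

    Each trial contributes ``amplitude × HRF`` at its onset; speech trials add a
    second response shifted by the production delay.  Contributions from all
    trials sum linearly.  With ``trial_jitter_sd`` > 0 each trial's amplitudes
    are scaled by an independent ``1 + N(0, sd)`` factor (seed-deterministic).

    Returns a 2-channel (one per hemisphere) ChromophoreSeries.
    """
    if sampling_rate <= 0:
        raise ConfigurationError("sampling rate must be positive")
    runs = schedule.run_indices
    if run_index is None:
        if len(runs) != 1:
            raise ConfigurationError("run_index required for multi-run schedules")
        run_index = runs[0]
    if run_index not in runs:
        raise ConfigurationError(f"schedule has no run {run_index}")
    entries = schedule.run_entries(run_index)
    n = int(round(schedule.run_span(run_index) * sampling_rate))
    last_needed = max(e.onset for e in entries) + schedule.trial_duration
    if last_needed > schedule.run_span(run_index) + 1e-9:
        raise ConfigurationError("schedule extends past the run span")
    if rng is None:
        rng = np.random.default_rng(seed)

    series = {(h, c): np.zeros(n) for h in HEMISPHERES for c in CHROMOPHORES}
    delay = effects.production_delay
    for name in sorted({e.condition for e in entries}):
        eff = effects.conditions[name]
        kernel = hrf_kernel(sampling_rate, eff.hrf)
        onsets = [e.onset for e in entries if e.condition == name]
        scales = 1.0 + rng.normal(0.0, trial_jitter_sd, size=len(onsets)) \
            if trial_jitter_sd > 0 else np.ones(len(onsets))
        train_perc = np.zeros(n)
        train_prod = np.zeros(n)
        for onset, s in zip(onsets, scales):
            train_perc[int(round(onset * sampling_rate))] += s
            if eff.has_production:
                j = int(round((onset + delay) * sampling_rate))
                if j < n:
                    train_prod[j] += s
        resp_perc = fftconvolve(train_perc, kernel)[:n]
        resp_prod = fftconvolve(train_prod, kernel)[:n] if eff.has_production else None
        for h in HEMISPHERES:
            for c in CHROMOPHORES:
                series[(h, c)] += eff.amplitude("perception", c, h) * resp_perc
                if resp_prod is not None:
                    series[(h, c)] += eff.amplitude("production", c, h) * resp_prod

    channels = [ChannelInfo(h, 0) for h in HEMISPHERES]
    return ChromophoreSeries(
        sampling_rate=sampling_rate,
        channels=channels,
        o2hb=np.vstack([series[(h, "o2hb")] for h in HEMISPHERES]),
        hhb=np.vstack([series[(h, "hhb")] for h in HEMISPHERES]),
    )


def add_noise(series: ChromophoreSeries, noise: NoiseSpec,
              seed: int | None = None,
              rng: np.random.Generator | None = None) -> ChromophoreSeries:
    """Add physiological sinusoids (random phase), linear drift and white noise.

    Noise is independent across channels and chromophores; the input is left
    untouched.  A ``NoiseSpec`` with all amplitudes zero returns an exact copy.
    """
    if not np.all(np.isfinite(series.o2hb)) or not np.all(np.isfinite(series.hhb)):
        raise DataError("input series must be finite")
    noise.validate(series.sampling_rate)
    if rng is None:
        rng = np.random.default_rng(seed)
    t = series.times
    out = {}
    for chrom in CHROMOPHORES:
        data = series.measure(chrom).copy()
        for i in range(data.shape[0]):
            for freq, amp in noise.components:
                if amp > 0:
                    phase = rng.uniform(0.0, 2.0 * np.pi)
                    data[i] += amp * np.sin(2.0 * np.pi * freq * t + phase)
            if noise.drift_slope != 0.0:
                data[i] += noise.drift_slope * t
            if noise.white_sd > 0:
                data[i] += rng.normal(0.0, noise.white_sd, size=t.size)
        out[chrom] = data
    return series.copy_with(o2hb=out["o2hb"], hhb=out["hhb"])
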