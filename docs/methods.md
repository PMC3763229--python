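# Methods

## Signal model

A continuous-wave NIRS channel measures attenuation changes at two
wavelengths straddling the hemoglobin isosbestic point.  The modified
Beer–Lambert law used throughout is

    ΔOD(λ) = [ε_O₂Hb(λ)·ΔC_O₂Hb + ε_HHb(λ)·ΔC_HHb] · d · DPF

with ε the decadic specific extinction coefficients (1/(mM·cm)), d the
source–detector separation (3.5 cm) and DPF the differential pathlength
factor (4, wavelength-independent; a per-wavelength DPF is accepted but
defaults equal).  Scattering-loss and partial-volume terms are out of scope:
only concentration *changes* are modeled, so the constant attenuation offset
cancels.  The 2 × 2 system is solved per sample; a condition number above
1e6 (configurable) is refused rather than amplified into the chromophores.
Extinction coefficients are not a geometry property and are shipped as a
plain-text table (`nirspeech/data/extinction_default.tsv`, values
interpolated from the standard compiled hemoglobin absorption spectra) that
users can replace with an instrument calibration table.  Both entry points —
ΔOD input and concentration input — are supported, since many instruments
export concentrations directly.

## Hemodynamic response

The response to a brief stimulus is a double gamma: a positive lobe peaking
at `peak_time` (default 5.5 s, the midpoint of the 5–6 s auditory range;
passively heard categories default to 4.8 s, slightly earlier than speech)
minus an undershoot scaled by `undershoot_ratio`.  Two deliberate numerical
choices:

* The curve is normalized to a maximum of exactly 1 **at the parameterized
  peak time**.  The undershoot's rising flank pulls the raw argmax of
  g₁ − r·g₂ a few tens of milliseconds early, so the positive-lobe mode is
  corrected by a short fixed-point iteration on a 1-ms grid before
  normalization.  Amplitudes elsewhere in the package are therefore true
  peak concentrations in µM.
* The default undershoot is earlier and shallower than the fMRI convention
  (time 10 s, dispersion 0.8 s, ratio 0.1) so that the whole response decays
  below 1 % of its peak within one 16-s trial.  With the paradigm's fixed
  16-s spacing, an undershoot peaking at ~15 s would leak ~10 % of peak into
  the next trial and make single-trial amplitudes unrecoverable by design;
  the package treats non-overlapping trials as part of the paradigm's logic.

Speech categories add a second, production-locked response at onset + 2 s
(amplitude defaulting to the perception amplitude).  With the default lobe
width the two responses merge into a single late-shifted maximum; the late
peak detector is therefore validated against a dense-grid argmax of the
analytic two-lobe sum rather than against a nominal latency.  The published-latency
late-window convention (8–16 s) is the function default, but generator-truth
checks pass a 6–16 s window because the synthetic production lobe peaks near
onset + 7.5 s minus the lobe-overlap shift.

## Synthetic experiments

The generator reproduces the block design: per subject, 4 runs × 25 trials
(20 per category pooled and permuted with a seeded generator), onsets on a
16-s grid after a 16-s dummy, 416-s runs.  Default condition effects (µM at
the response peak, left/right):

| category | O₂Hb | HHb | comment |
|---|---|---|---|
| word | 0.25 / 0.05 | −0.08 / 0.02 | + equal production response |
| pseudoword | 0.55 / 0.05 | −0.12 / 0.02 | + equal production response |
| natural | 0.15 / −0.05 | 0.12 / −0.04 | balanced rise: HbT up, proportion flat |
| animal | 0.12 / −0.05 | 0.10 / −0.04 | as above |
| human non-speech | 0.18 / 0.06 | 0.14 / 0.05 | bilateral HbT rise |

The pseudoword − word O₂Hb excess (default 0.30 µM) is the package's
effect-size axis; the pseudoword HHb dip scales with it so zero excess makes
the two speech categories identical.  These magnitudes were fixed by an
a-priori design calculation: with the default between-subject amplitude sd
(0.07 µM O₂Hb, 0.03 µM HHb, independent normal per amplitude) the left 4–7 s
proportion contrast has a standardized within-subject effect around dz ≈ 1
at n = 15, i.e. closed-form paired-t power well above 0.8 — mirroring a
clearly detectable left-lateralized effect.  Noise defaults: cardiac 1.1 Hz
(0.06 µM), respiratory 0.25 Hz (0.04 µM), Mayer 0.1 Hz (0.05 µM), linear
drift 2e-4 µM/s, white noise sd 0.2 µM per sample, per-trial amplitude
jitter sd 0.1 — conventions, not reconstructions; the study reports neither
its SNR nor between-subject variability.  Sinusoid phases are random per
channel and chromophore.  One master seed spawns independent per-subject
streams (schedule order, amplitude draw, jitter, noise).

What the generator does *not* emulate: photon transport (no Monte-Carlo
tissue model), motion-artifact spikes, serial correlation of physiological
noise beyond pure sinusoids, and any nonlinearity between neural activity
and the vascular response.  Passing tests therefore demonstrate that the
analysis recovers effects under an additive, linear, stationary world — not
that real recordings satisfy those assumptions.

## Preprocessing

Filtering is the 10-Hz 5th-order Butterworth applied forward–backward
(zero-phase): peak-latency statements at 5–6 s would otherwise absorb the
filter's group delay.  The effective attenuation order doubles; edges use
scipy's default odd-reflection padding.  Ipsilateral channels are averaged
pointwise per hemisphere (SNR gain √2 for two pairs).  Epochs span 0–16 s
from onset, the onset sample being the nearest sample at or after onset time
(≤ 4 ms error at 250 Hz); epochs that would leave the recording are rejected
and counted, never silently dropped.  Baseline subtraction is deliberately
deferred to the metrics: "change versus the onset value" is a metric-level
convention, not a preprocessing step.

## Metrics

The oxygenation proportion is p(t) = O₂Hb/(O₂Hb + HHb) expressed as percent
change against the onset sample.  Two conventions are implemented —
divisive, 100·(p−p₀)/p₀ (default), and additive, 100·(p−p₀) in percentage
points; with p₀ near 0.5 they differ by about 2×, and neither can be
asserted as "the" published convention, so the choice is recorded in every
artifact.  The ratio of bare concentration changes is ill-posed where ΔHbT
crosses zero; the pipeline therefore adds configurable resting baselines
(42 µM O₂Hb, 18 µM HHb: ~60 µM HbT at ~70 % saturation, typical adult
frontal cortex) before forming the ratio, and samples with |HbT| under a
floor (1e-3 µM) are flagged NaN, never clamped.

Normalized HbT subtracts the course mean and divides by its population
variance — the literal convention, with the dimensionally cleaner sd divisor
available and recorded in the output; the stored constants reconstruct the
raw course exactly.  Display min–max scaling to [0, 1] is a plotting
concern, not part of the statistic.

Bins are half-open [start, end) so 1–4 s and 4–7 s tile without overlap.
Because the passive categories peak earlier than speech, the peak-dependent
bins may be re-centered on the course's argmax inside a 2–9 s search window
(shift magnitude reported, windows clipped to the epoch and flagged).  The
shift is applied only in the study-mirroring contrasts: centering a window
on a noisy argmax is a max-statistic selection, and applying it inside the
null calibration would bias the shifted cells and corrupt the type-I rate.

## Group statistics

Observations are one scalar per (subject, condition, hemisphere); designs
are balanced by construction and validated.  Two error strategies:

* **subject_blocked** (default): each effect tested against its own
  effect × subject interaction — the textbook two-way repeated-measures
  decomposition.  A 2 × 2 design with 15 subjects gives F(1, 14).
* **pooled**: subjects as independent replicates, one residual error with
  df = ab(n−1).

For a 3-level factor the subject-blocked error df is 2(n−1) = 28 at n = 15;
published reports quoting F(2, 14) under such a design are not reproducible
by any single textbook scheme, so both strategies are exposed and the
discrepancy documented rather than silently resolved.  Degenerate inputs
(all observations equal, zero-variance paired differences) are flagged, with
F defined as 0 when the effect sum of squares is 0.  p-values come from the
F distribution; no permutation option and no sphericity correction in this
version, and no multiple-testing correction — reports state the number of
tests run.

## Calibration problem sizes

The package's self-calibration uses reduced designs chosen as its own
convention: the type-I rate of the condition main effect is estimated from
1000 experiments of 5 subjects × 1 run, and contrast power from 200
experiments of 15 subjects × 1 run (120 per point on the effect grid), both
simulated at a 25-Hz rate (every modeled noise component sits far below that
Nyquist; the acquisition-rate spot checks run at 250 Hz).  The acceptance
band for the type-I rate, [0.035, 0.065], is the two-sided binomial
tolerance around α = 0.05 at 1000 replicates.

## Reproducibility

Artifacts are headered TSV with fixed float formatting; every analysis
artifact embeds the resolved configuration hash.  The run log records
stages, seeds and row counts but no wall-clock times, so identical
(config, seed) pairs yield byte-identical artifact trees.

## Known limitations

* No motion-artifact correction beyond the low-pass; no detrending or
  band-pass stage; no short-separation regression.
* Absolute saturation is never computed — baselines enter only to make the
  proportion well-posed, and conclusions should rest on relative changes.
* The subject-blocked F test is exact under compound symmetry; the
  generator's independent cell noise satisfies it, real data need not.
* SNIRF or vendor binary containers are not read; the native format is the
  package's own text TSV.
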