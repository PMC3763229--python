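"""Hemodynamic summary metrics.

Two headline signals summarize the event-locked responses:

* the oxygenation proportion — the percent change, relative to its value at
  stimulus onset, of O₂Hb over total hemoglobin (O₂Hb + HHb), a correlate of
  oxygen saturation and blood-flow change;
* normalized total hemoglobin — the total-Hb course centered by its mean and
  divided by its variance, a blood-volume correlate put on a common dynamic
  range across categories.

Scalar summaries are means over registered time bins: the 4–7 s peak window
for the proportion contrasts, the 1–4 s window preceding it, and the 2–6 s
window used for total-Hb contrasts.  Because passively heard categories peak
slightly earlier than speech, a comparison window can be re-centered on the
observed peak before binning.

The proportion of concentration *changes* is ill-posed where ΔHbT crosses
zero, so the ratio supports two modes: pass absolute concentrations (baseline
plus change — the default throughout the pipeline, with a configurable resting
baseline) or flag the samples whose |HbT| falls below a floor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ConfigurationError, MetricError

#: Registered analysis windows (seconds from stimulus onset, half-open).
WINDOWS: dict[str, tuple[float, float]] = {
    "peak_bin": (4.0, 7.0),
    "early_bin": (1.0, 4.0),
    "hbt_bin": (2.0, 6.0),
}


@dataclass
class ProportionSeries:
    """Percent change of O₂Hb/HbT relative to its stimulus-onset value."""

    values: np.ndarray       # percent
    flagged: np.ndarray      # bool, samples with |HbT| below the floor
    onset_proportion: float  # p at the onset sample
    convention: str          # "divisive" or "additive"

    @property
    def n_flagged(self) -> int:
        return int(self.flagged.sum())


def total_hb(o2hb: np.ndarray, hhb: np.ndarray) -> np.ndarray:
    """Pointwise total hemoglobin, the exact sum of the two chromophores."""
    o2hb = np.asarray(o2hb, float)
    hhb = np.asarray(hhb, float)
    if o2hb.shape != hhb.shape:
        raise MetricError("O2Hb and HHb series must have equal shapes")
    return o2hb + hhb


def oxygenation_proportion(o2hb: np.ndarray, hhb: np.ndarray,
                           onset_index: int = 0,
                           hbt_floor: float = 1e-3,
                           convention: str = "divisive") -> ProportionSeries:
    """Percent change of p(t) = O₂Hb/(O₂Hb+HHb) versus the onset sample.

    ``convention`` selects the reading of "percent change": ``"divisive"``
    (default) returns 100·(p(t) − p₀)/p₀, ``"additive"`` returns
    100·(p(t) − p₀) in percentage points.  Samples where |HbT| < ``hbt_floor``
    are flagged (value NaN), never silently dropped; an onset sample below the
    floor is an error because the whole series would be undefined.
    """
    if convention not in ("divisive", "additive"):
        raise ConfigurationError(f"unknown percent-change convention {convention!r}")
    hbt = total_hb(o2hb, hhb)
    o2hb = np.asarray(o2hb, float)
    if np.abs(hbt[onset_index]) < hbt_floor:
        raise MetricError(
            f"|HbT| = {abs(hbt[onset_index]):.3g} at the onset sample is below "
            f"the floor {hbt_floor:.3g}; proportion undefined"
        )
    flagged = np.abs(hbt) < hbt_floor
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(flagged, np.nan, o2hb / hbt)
    p0 = float(o2hb[onset_index] / hbt[onset_index])
    if convention == "divisive":
        if p0 == 0.0:
            raise MetricError("onset proportion is zero; divisive convention undefined")
        values = 100.0 * (p - p0) / p0
    else:
        values = 100.0 * (p - p0)
    return ProportionSeries(values=values, flagged=flagged,
                            onset_proportion=p0, convention=convention)


@dataclass
class NormalizedHbT:
    """Mean-centered total-Hb course divided by its variance (or sd).

    The stored constants reconstruct the raw course exactly:
    ``raw = values * divisor_value + mean``.
    """

    values: np.ndarray
    mean: float
    divisor_value: float
    divisor: str  # "variance" or "sd"

    def reconstruct(self) -> np.ndarray:
        return self.values * self.divisor_value + self.mean


def normalize_hbt(hbt: np.ndarray, divisor: str = "variance") -> NormalizedHbT:
    """Center by the mean, divide by the population variance (or sd).

    Raises ``MetricError`` for a constant series (zero variance).
    """
    if divisor not in ("variance", "sd"):
        raise ConfigurationError(f"unknown divisor {divisor!r}")
    hbt = np.asarray(hbt, float)
    mean = float(hbt.mean())
    var = float(hbt.var())
    # a constant series may leave a rounding-level variance; reject both
    if var == 0.0 or np.ptp(hbt) == 0.0 or var < 1e-28 * max(1.0, mean * mean):
        raise MetricError("total-Hb series is constant; normalization undefined")
    dv = var if divisor == "variance" else float(np.sqrt(var))
    return NormalizedHbT(values=(hbt - mean) / dv, mean=mean,
                         divisor_value=dv, divisor=divisor)


def bin_mean(values: np.ndarray, sampling_rate: float,
             window: tuple[float, float], t0: float = 0.0) -> float:
    """Mean over the half-open time bin ``[start, end)`` (seconds from onset).

    ``t0`` is the time of the first sample.  NaN samples (flagged by upstream
    metrics) propagate so undefined bins surface rather than vanish.
    """
    values = np.asarray(values, float)
    t = t0 + np.arange(values.shape[-1]) / sampling_rate
    mask = (t >= window[0] - 1e-12) & (t < window[1] - 1e-12)
    if not mask.any():
        raise MetricError(f"window {window} contains no samples")
    return float(values[..., mask].mean())


@dataclass
class ShiftedWindow:
    window: tuple[float, float]
    shift: float
    clipped: bool
    flat: bool


def shift_window_to_peak(values: np.ndarray, sampling_rate: float,
                         base_window: tuple[float, float],
                         search_window: tuple[float, float],
                         t0: float = 0.0,
                         epoch_span: tuple[float, float] | None = None
                         ) -> ShiftedWindow:
    """Re-center ``base_window`` on the series argmax inside ``search_window``.

    The returned window keeps the base length; if centering would push it
    outside the epoch span it is clipped back and flagged.  A flat series
    yields no shift, flagged.
    """
    values = np.asarray(values, float)
    t = t0 + np.arange(values.shape[-1]) / sampling_rate
    if epoch_span is None:
        epoch_span = (float(t[0]), float(t[-1] + 1.0 / sampling_rate))
    mask = (t >= search_window[0]) & (t <= search_window[1])
    if not mask.any():
        raise MetricError(f"search window {search_window} contains no samples")
    sub = values[mask]
    length = base_window[1] - base_window[0]
    base_center = 0.5 * (base_window[0] + base_window[1])
    if np.nanmax(sub) == np.nanmin(sub):
        return ShiftedWindow(window=base_window, shift=0.0, clipped=False,
                             flat=True)
    peak_t = float(t[mask][int(np.nanargmax(sub))])
    start = peak_t - length / 2.0
    end = peak_t + length / 2.0
    clipped = False
    if start < epoch_span[0]:
        start, end, clipped = epoch_span[0], epoch_span[0] + length, True
    if end > epoch_span[1]:
        start, end, clipped = epoch_span[1] - length, epoch_span[1], True
    return ShiftedWindow(window=(start, end), shift=peak_t - base_center,
                         clipped=clipped, flat=False)


@dataclass
class SecondPeak:
    found: bool
    time: float        # seconds from onset; NaN when absent
    amplitude: float   # NaN when absent


def find_second_peak(values: np.ndarray, sampling_rate: float,
                     window: tuple[float, float] = (8.0, 16.0),
                     t0: float = 0.0) -> SecondPeak:
    """Locate the late (production-locked) response peak inside ``window``.

    Returns the argmax within the window (ties to the earliest sample).  A
    series that only decays through the window has no late peak and is flagged
    absent.
    """
    values = np.asarray(values, float)
    t = t0 + np.arange(values.shape[-1]) / sampling_rate
    mask = (t >= window[0]) & (t <= window[1])
    if not mask.any():
        raise MetricError(f"window {window} contains no samples")
    sub = values[mask]
    if np.all(np.diff(sub) <= 0):
        return SecondPeak(found=False, time=np.nan, amplitude=np.nan)
    i = int(np.argmax(sub))
    return SecondPeak(found=True, time=float(t[mask][i]),
                      amplitude=float(sub[i]))
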