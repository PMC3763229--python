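"""In-memory containers for optical and chromophore time series.

An :class:`OpticalRecording` holds per-channel optical-density changes at the
two laser wavelengths (763 and 860 nm).  A :class:`ChromophoreSeries` holds the
corresponding ΔO₂Hb / ΔHHb concentration changes in µM; total hemoglobin is
always the exact pointwise sum of the two.  Channels carry their geometry
(hemisphere, transmitter–receiver pair index, separation in cm, differential
pathlength factor) so the Beer–Lambert conversion needs no extra bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import DataError

HEMISPHERES: tuple[str, str] = ("left", "right")

DEFAULT_WAVELENGTHS: tuple[float, float] = (763.0, 860.0)
DEFAULT_SEPARATION_CM: float = 3.5
DEFAULT_DPF: float = 4.0


@dataclass(frozen=True)
class ChannelInfo:
    """Geometry of one transmitter–receiver pair."""

    hemisphere: str
    pair_index: int
    separation_cm: float = DEFAULT_SEPARATION_CM
    dpf: float = DEFAULT_DPF

    def __post_init__(self) -> None:
        if self.hemisphere not in HEMISPHERES:
            raise DataError(f"unknown hemisphere {self.hemisphere!r}")
        if self.separation_cm <= 0 or self.dpf <= 0:
            raise DataError("separation and DPF must be positive")

    @property
    def label(self) -> str:
        return f"{'L' if self.hemisphere == 'left' else 'R'}{self.pair_index}"


def bilateral_channels(pairs_per_hemisphere: int = 2,
                       separation_cm: float = DEFAULT_SEPARATION_CM,
                       dpf: float = DEFAULT_DPF) -> list[ChannelInfo]:
    """Standard 4 × 1 montage: ``pairs_per_hemisphere`` channels over each IFG."""
    return [
        ChannelInfo(h, p, separation_cm, dpf)
        for h in HEMISPHERES
        for p in range(1, pairs_per_hemisphere + 1)
    ]


@dataclass
class OpticalRecording:
    """ΔOD time series, shape (n_channels, 2 wavelengths, n_samples)."""

    sampling_rate: float
    channels: list[ChannelInfo]
    od: np.ndarray
    wavelengths: tuple[float, float] = DEFAULT_WAVELENGTHS

    def __post_init__(self) -> None:
        self.od = np.asarray(self.od, dtype=float)
        if self.sampling_rate <= 0:
            raise DataError("sampling rate must be positive")
        if len(self.wavelengths) != 2:
            raise DataError("exactly two wavelengths are required")
        if self.od.ndim != 3 or self.od.shape[:2] != (len(self.channels), 2):
            raise DataError(
                f"od must have shape (n_channels={len(self.channels)}, 2, n_samples); "
                f"got {self.od.shape}"
            )

    @property
    def n_samples(self) -> int:
        return self.od.shape[2]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate


@dataclass
class ChromophoreSeries:
    """ΔO₂Hb and ΔHHb (µM) per channel; ΔHbT is derived as their exact sum."""

    sampling_rate: float
    channels: list[ChannelInfo]
    o2hb: np.ndarray
    hhb: np.ndarray

    def __post_init__(self) -> None:
        self.o2hb = np.atleast_2d(np.asarray(self.o2hb, dtype=float))
        self.hhb = np.atleast_2d(np.asarray(self.hhb, dtype=float))
        if self.sampling_rate <= 0:
            raise DataError("sampling rate must be positive")
        expected = (len(self.channels), self.o2hb.shape[-1])
        if self.o2hb.shape != expected or self.hhb.shape != expected:
            raise DataError(
                f"chromophore arrays must both have shape {expected}; got "
                f"{self.o2hb.shape} and {self.hhb.shape}"
            )

    @property
    def hbt(self) -> np.ndarray:
        return self.o2hb + self.hhb

    @property
    def n_samples(self) -> int:
        return self.o2hb.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate

    def channel_indices(self, hemisphere: str) -> list[int]:
        return [i for i, c in enumerate(self.channels) if c.hemisphere == hemisphere]

    def measure(self, name: str) -> np.ndarray:
        if name == "o2hb":
            return self.o2hb
        if name == "hhb":
            return self.hhb
        if name == "hbt":
            return self.hbt
        raise DataError(f"unknown measure {name!r}")

    def copy_with(self, **kwargs) -> "ChromophoreSeries":
        data = dict(
            sampling_rate=self.sampling_rate,
            channels=list(self.channels),
            o2hb=self.o2hb.copy(),
            hhb=self.hhb.copy(),
        )
        data.update(kwargs)
        return ChromophoreSeries(**data)


def replicate_channels(series: ChromophoreSeries,
                       pairs_per_hemisphere: int) -> ChromophoreSeries:
    """Expand one series per hemisphere into identical per-pair channel copies.

    Used by the generator: the tissue response under the two ipsilateral
    optode pairs is common; channel-specific instrument noise is added
    afterwards.
    """
    if {c.hemisphere for c in series.channels} != set(HEMISPHERES) or \
            len(series.channels) != 2:
        raise DataError("expected exactly one channel per hemisphere")
    channels = bilateral_channels(
        pairs_per_hemisphere,
        separation_cm=series.channels[0].separation_cm,
        dpf=series.channels[0].dpf,
    )
    idx = [series.channel_indices(c.hemisphere)[0] for c in channels]
    return ChromophoreSeries(
        series.sampling_rate, channels, series.o2hb[idx], series.hhb[idx]
    )
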