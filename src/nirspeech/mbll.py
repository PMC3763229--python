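"""Modified Beer–Lambert law: attenuation ⇄ chromophore concentration changes.

For continuous-wave NIRS the attenuation change at wavelength λ is

    ΔOD(λ) = [ε_O₂Hb(λ)·ΔC_O₂Hb + ε_HHb(λ)·ΔC_HHb] · d · DPF

with ε the specific (decadic) extinction coefficients in 1/(mM·cm), d the
source–detector separation on the scalp (cm) and DPF the differential
pathlength factor converting geometric to effective photon pathlength.  With
two wavelengths this is a 2 × 2 linear system per sample; inversion recovers
ΔO₂Hb and ΔHHb, reported here in µM.

The extinction coefficients are not a property of the instrument geometry and
must come from published absorption spectra; a default table is shipped as a
plain-text config (``data/extinction_default.tsv``) so users can substitute
their instrument's calibration table.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from .exceptions import DataError, FileFormatError, ModelError
from .recording import ChromophoreSeries, OpticalRecording

#: Condition number above which an extinction matrix is refused.
DEFAULT_CONDITION_THRESHOLD = 1e6

_UM_PER_MM = 1e3  # the MBLL system is solved in mM; outputs are µM


@dataclass(frozen=True)
class ExtinctionMatrix:
    """2 × 2 extinction coefficients, rows = wavelengths, cols = (O₂Hb, HHb)."""

    wavelengths: tuple[float, float]
    matrix: np.ndarray  # 1/(mM*cm)
    source: str = "unspecified"
    condition_threshold: float = DEFAULT_CONDITION_THRESHOLD

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        if m.shape != (2, 2):
            raise ModelError("extinction matrix must be 2x2")
        if not np.all(m > 0):
            raise ModelError("extinction coefficients must be positive")
        if not np.isfinite(self.condition_number) or \
                self.condition_number > self.condition_threshold:
            raise ModelError(
                f"extinction matrix {self.source!r} is ill-conditioned "
                f"(condition number {self.condition_number:.3g})"
            )

    @property
    def condition_number(self) -> float:
        return float(np.linalg.cond(self.matrix))

    @classmethod
    def from_table(cls, path: str | Path,
                   condition_threshold: float = DEFAULT_CONDITION_THRESHOLD
                   ) -> "ExtinctionMatrix":
        """Read a headered TSV with columns wavelength_nm, o2hb, hhb."""
        path = Path(path)
        source = "unspecified"
        rows = []
        for lineno, line in enumerate(path.read_text().splitlines(), start=1):
            if line.startswith("#"):
                if line.startswith("# source:"):
                    source = line.split(":", 1)[1].strip()
                continue
            if not line.strip():
                continue
            rows.append((lineno, line.split("\t")))
        if not rows or rows[0][1] != ["wavelength_nm", "o2hb", "hhb"]:
            raise FileFormatError(f"{path}: expected header wavelength_nm/o2hb/hhb")
        body = rows[1:]
        if len(body) != 2:
            raise FileFormatError(f"{path}: expected exactly 2 wavelength rows")
        try:
            values = np.array([[float(v) for v in cols] for _, cols in body])
        except ValueError as exc:
            raise FileFormatError(f"{path}: non-numeric extinction entry: {exc}") from exc
        return cls(
            wavelengths=(values[0, 0], values[1, 0]),
            matrix=values[:, 1:],
            source=source,
            condition_threshold=condition_threshold,
        )

    @classmethod
    def default(cls) -> "ExtinctionMatrix":
        with resources.as_file(
            resources.files("nirspeech.data") / "extinction_default.tsv"
        ) as p:
            return cls.from_table(p)


def optical_density_change(intensity: np.ndarray,
                           reference_intensity: np.ndarray | float) -> np.ndarray:
    """ΔOD = −log₁₀(I / I₀); zero wherever I equals the reference.

    Raises ``DataError`` for nonpositive intensities.
    """
    intensity = np.asarray(intensity, dtype=float)
    reference = np.asarray(reference_intensity, dtype=float)
    if np.any(intensity <= 0) or np.any(reference <= 0):
        raise DataError("intensities must be strictly positive")
    return -np.log10(intensity / reference)


def forward_mbll(o2hb_um: np.ndarray, hhb_um: np.ndarray,
                 extinction: ExtinctionMatrix,
                 separation_cm: float, dpf: float) -> np.ndarray:
    """Forward model: concentration changes (µM) → ΔOD, shape (2, n)."""
    conc_mm = np.vstack([np.asarray(o2hb_um, float),
                         np.asarray(hhb_um, float)]) / _UM_PER_MM
    return extinction.matrix @ conc_mm * (separation_cm * dpf)


def invert_mbll(delta_od: np.ndarray, extinction: ExtinctionMatrix,
                separation_cm: float, dpf: float) -> tuple[np.ndarray, np.ndarray]:
    """Solve the per-sample 2 × 2 system; returns (ΔO₂Hb, ΔHHb) in µM.

    ``delta_od`` has shape (2, n) with rows ordered as the extinction matrix
    wavelengths.
    """
    delta_od = np.atleast_2d(np.asarray(delta_od, dtype=float))
    if delta_od.shape[0] != 2:
        raise DataError("delta_od must have two wavelength rows")
    if separation_cm <= 0 or dpf <= 0:
        raise DataError("separation and DPF must be positive")
    conc_mm = np.linalg.solve(extinction.matrix, delta_od) / (separation_cm * dpf)
    conc_um = conc_mm * _UM_PER_MM
    return conc_um[0], conc_um[1]


def forward_attenuation(series: ChromophoreSeries,
                        extinction: ExtinctionMatrix | None = None
                        ) -> OpticalRecording:
    """Apply the forward MBLL per channel using each channel's own geometry.

    Exact inverse of :func:`convert_recording` up to floating-point error.
    """
    extinction = extinction or ExtinctionMatrix.default()
    od = np.empty((len(series.channels), 2, series.n_samples))
    for i, ch in enumerate(series.channels):
        od[i] = forward_mbll(series.o2hb[i], series.hhb[i], extinction,
                             ch.separation_cm, ch.dpf)
    return OpticalRecording(
        sampling_rate=series.sampling_rate,
        channels=list(series.channels),
        od=od,
        wavelengths=extinction.wavelengths,
    )


def convert_recording(recording: OpticalRecording,
                      extinction: ExtinctionMatrix | None = None
                      ) -> ChromophoreSeries:
    """Invert the MBLL for every channel of an optical recording."""
    extinction = extinction or ExtinctionMatrix.default()
    o2hb = np.empty((len(recording.channels), recording.n_samples))
    hhb = np.empty_like(o2hb)
    for i, ch in enumerate(recording.channels):
        o2hb[i], hhb[i] = invert_mbll(recording.od[i], extinction,
                                      ch.separation_cm, ch.dpf)
    return ChromophoreSeries(
        sampling_rate=recording.sampling_rate,
        channels=list(recording.channels),
        o2hb=o2hb,
        hhb=hhb,
    )
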