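"""Plain-text file formats and run configuration.

Everything the pipeline reads or writes is headered TSV: a block of
``# key: value`` comment lines followed by a tab-separated table.  The study's
8-channel data is desk-scale, so transparent, diff-able text beats a binary
container; every writer's output is accepted by its reader.

Formats
-------
recording
    ``kind: od`` (ΔOD per channel × wavelength) or ``kind: concentration``
    (ΔO₂Hb/ΔHHb per channel, µM).  Channel geometry travels in the header.
events
    onset / duration / trial_type / run columns (events-table convention).
binned table, truth sidecar, epochs
    long-format TSV with a comment header carrying provenance.
config
    YAML mirroring :class:`RunConfig`; unknown keys are rejected and a content
    hash of the resolved configuration is embedded in every artifact.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from .design import CONDITIONS, EventSchedule, ScheduleEntry
from .exceptions import ConfigurationError, FileFormatError
from .metrics import WINDOWS
from .recording import ChannelInfo, ChromophoreSeries, OpticalRecording
from .simulate import NoiseSpec

_FLOAT_FMT = "%.10g"


# ---------------------------------------------------------------------------
# headered TSV plumbing

def _read_header(path: Path) -> tuple[dict[str, str], int]:
    """Parse leading ``# key: value`` lines; returns (header, n_header_lines)."""
    header: dict[str, str] = {}
    n = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n += 1
            body = line[1:].strip()
            if ":" in body:
                key, val = body.split(":", 1)
                header[key.strip()] = val.strip()
    return header, n


def _read_table(path: Path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", comment="#")
    except Exception as exc:  # pandas parser errors carry the line number
        raise FileFormatError(f"{path}: malformed table: {exc}") from exc


def _check_complete(df: pd.DataFrame, path: Path, n_header: int) -> None:
    if df.empty:
        raise FileFormatError(f"{path}: table has no data rows")
    for col in df.columns:
        bad = df.index[df[col].isna()]
        if len(bad):
            line = n_header + 2 + int(bad[0])  # header + column row + 1-based
            raise FileFormatError(
                f"{path}: column {col!r} has {len(bad)} missing value(s), "
                f"first at line {line}"
            )


def _write_tsv(path: Path, df: pd.DataFrame, header: dict[str, Any]) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for key, val in header.items():
            fh.write(f"# {key}: {val}\n")
        df.to_csv(fh, sep="\t", index=False, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# recordings

def _encode_channels(channels: Sequence[ChannelInfo]) -> str:
    return ";".join(f"{c.hemisphere}:{c.pair_index}:{_FLOAT_FMT % c.separation_cm}"
                    f":{_FLOAT_FMT % c.dpf}" for c in channels)


def _decode_channels(spec: str) -> list[ChannelInfo]:
    channels = []
    for part in spec.split(";"):
        try:
            hemi, pair, sep, dpf = part.split(":")
            channels.append(ChannelInfo(hemi, int(pair), float(sep), float(dpf)))
        except Exception as exc:
            raise FileFormatError(f"bad channel spec {part!r}: {exc}") from exc
    return channels


def write_recording(obj: OpticalRecording | ChromophoreSeries,
                    path: str | Path, meta: dict[str, str] | None = None) -> None:
    path = Path(path)
    times = obj.times
    if isinstance(obj, OpticalRecording):
        header = {
            "nirspeech-recording": "v1", "kind": "od",
            "sampling_rate_hz": _FLOAT_FMT % obj.sampling_rate,
            "wavelengths_nm": ",".join(_FLOAT_FMT % w for w in obj.wavelengths),
            "units": "OD",
            "channels": _encode_channels(obj.channels),
        }
        cols = {"time_s": times}
        for i, ch in enumerate(obj.channels):
            for w, wl in enumerate(obj.wavelengths):
                cols[f"{ch.label}_w{int(wl)}"] = obj.od[i, w]
    else:
        header = {
            "nirspeech-recording": "v1", "kind": "concentration",
            "sampling_rate_hz": _FLOAT_FMT % obj.sampling_rate,
            "units": "uM",
            "channels": _encode_channels(obj.channels),
        }
        cols = {"time_s": times}
        for i, ch in enumerate(obj.channels):
            cols[f"{ch.label}_o2hb"] = obj.o2hb[i]
            cols[f"{ch.label}_hhb"] = obj.hhb[i]
    header.update(meta or {})
    _write_tsv(path, pd.DataFrame(cols), header)


def read_recording(path: str | Path) -> OpticalRecording | ChromophoreSeries:
    """Read a recording file; the header's ``kind`` selects the return type."""
    path = Path(path)
    if not path.exists():
        raise FileFormatError(f"{path}: no such file")
    header, n_header = _read_header(path)
    for key in ("kind", "sampling_rate_hz", "units", "channels"):
        if key not in header:
            raise FileFormatError(f"{path}: missing header field {key!r}")
    kind = header["kind"]
    fs = float(header["sampling_rate_hz"])
    channels = _decode_channels(header["channels"])
    df = _read_table(path)
    _check_complete(df, path, n_header)
    if "time_s" not in df.columns:
        raise FileFormatError(f"{path}: missing time_s column")
    t = df["time_s"].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        raise FileFormatError(f"{path}: time_s is not strictly increasing")
    if kind == "od":
        if "wavelengths_nm" not in header:
            raise FileFormatError(f"{path}: od recording missing wavelengths_nm")
        wavelengths = tuple(float(w) for w in header["wavelengths_nm"].split(","))
        if len(wavelengths) != 2:
            raise FileFormatError(f"{path}: exactly 2 wavelengths required")
        od = np.empty((len(channels), 2, len(df)))
        for i, ch in enumerate(channels):
            for w, wl in enumerate(wavelengths):
                col = f"{ch.label}_w{int(wl)}"
                if col not in df.columns:
                    raise FileFormatError(f"{path}: missing column {col!r}")
                od[i, w] = df[col].to_numpy(dtype=float)
        return OpticalRecording(sampling_rate=fs, channels=channels, od=od,
                                wavelengths=wavelengths)
    if kind == "concentration":
        o2hb = np.empty((len(channels), len(df)))
        hhb = np.empty_like(o2hb)
        for i, ch in enumerate(channels):
            for name, dest in (("o2hb", o2hb), ("hhb", hhb)):
                col = f"{ch.label}_{name}"
                if col not in df.columns:
                    raise FileFormatError(f"{path}: missing column {col!r}")
                dest[i] = df[col].to_numpy(dtype=float)
        return ChromophoreSeries(sampling_rate=fs, channels=channels,
                                 o2hb=o2hb, hhb=hhb)
    raise FileFormatError(f"{path}: unknown kind {kind!r}")


# ---------------------------------------------------------------------------
# events

def write_events(schedule: EventSchedule, path: str | Path,
                 meta: dict[str, str] | None = None) -> None:
    header = {
        "nirspeech-events": "v1",
        "trial_duration_s": _FLOAT_FMT % schedule.trial_duration,
        "dummy_duration_s": _FLOAT_FMT % schedule.dummy_duration,
    }
    header.update(meta or {})
    df = pd.DataFrame(
        [dict(onset=e.onset, duration=schedule.trial_duration,
              trial_type=e.condition, run=e.run_index)
         for e in schedule.entries]
    )
    _write_tsv(Path(path), df, header)


def read_events(path: str | Path,
                valid_conditions: Sequence[str] = CONDITIONS) -> EventSchedule:
    """Read an events table and validate it against the schedule invariants.

    Violations (unknown labels, decreasing onsets, wrong spacing) are reported,
    never repaired.
    """
    path = Path(path)
    if not path.exists():
        raise FileFormatError(f"{path}: no such file")
    header, n_header = _read_header(path)
    df = _read_table(path)
    _check_complete(df, path, n_header)
    for col in ("onset", "trial_type", "run"):
        if col not in df.columns:
            raise FileFormatError(f"{path}: missing column {col!r}")
    if not np.issubdtype(df["onset"].dtype, np.number):
        raise FileFormatError(f"{path}: onsets must be numeric")
    unknown = sorted(set(df["trial_type"]) - set(valid_conditions))
    if unknown:
        raise FileFormatError(
            f"{path}: unknown condition label(s) {unknown}; valid labels are "
            f"{list(valid_conditions)}"
        )
    trial_duration = float(header.get("trial_duration_s", 16.0))
    dummy_duration = float(header.get("dummy_duration_s", 16.0))
    entries = tuple(
        ScheduleEntry(float(r.onset), str(r.trial_type), int(r.run))
        for r in df.itertuples()
    )
    try:
        return EventSchedule(entries, trial_duration=trial_duration,
                             dummy_duration=dummy_duration)
    except ConfigurationError as exc:
        raise FileFormatError(f"{path}: invalid schedule: {exc}") from exc


# ---------------------------------------------------------------------------
# long-format tables

def write_table(df: pd.DataFrame, path: str | Path, kind: str,
                meta: dict[str, str] | None = None) -> None:
    header = {f"nirspeech-{kind}": "v1"}
    header.update(meta or {})
    _write_tsv(Path(path), df, header)


def read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileFormatError(f"{path}: no such file")
    _, n_header = _read_header(path)
    df = _read_table(path)
    _check_complete(df, path, n_header)
    return df


# ---------------------------------------------------------------------------
# run configuration

def _strict(cls, data: dict, where: str):
    allowed = {f.name for f in fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ConfigurationError(f"unknown config key(s) in {where}: {sorted(unknown)}")
    return cls(**data)


def _tuple2(x) -> tuple[float, float]:
    a, b = x
    return (float(a), float(b))


@dataclass(frozen=True)
class AcquisitionConfig:
    sampling_rate_hz: float = 250.0
    wavelengths_nm: tuple[float, float] = (763.0, 860.0)
    separation_cm: float = 3.5
    dpf: float = 4.0
    extinction_table: str | None = None  # None -> packaged default table

    def __post_init__(self):
        object.__setattr__(self, "wavelengths_nm", _tuple2(self.wavelengths_nm))


@dataclass(frozen=True)
class PreprocessingConfig:
    cutoff_hz: float = 10.0
    order: int = 5
    epoch_window: tuple[float, float] = (0.0, 16.0)

    def __post_init__(self):
        object.__setattr__(self, "epoch_window", _tuple2(self.epoch_window))


@dataclass(frozen=True)
class MetricsConfig:
    convention: str = "divisive"
    divisor: str = "variance"
    hbt_floor: float = 1e-3
    baseline_o2hb_um: float = 42.0
    baseline_hhb_um: float = 18.0
    shift_nonspeech: bool = True
    shift_search: tuple[float, float] = (2.0, 9.0)
    second_peak_window: tuple[float, float] = (6.0, 16.0)

    def __post_init__(self):
        object.__setattr__(self, "shift_search", _tuple2(self.shift_search))
        object.__setattr__(self, "second_peak_window",
                           _tuple2(self.second_peak_window))


@dataclass(frozen=True)
class StatsConfig:
    strategy: str = "subject_blocked"
    alpha: float = 0.05


@dataclass(frozen=True)
class SimulationConfig:
    n_subjects: int = 15
    n_runs: int = 4
    trials_per_run: int = 25
    trials_per_condition: int = 20
    pairs_per_hemisphere: int = 2
    effects: str = "default"  # "default" | "null"
    pseudoword_excess: float = 0.30
    noise: dict = field(default_factory=dict)  # NoiseSpec field overrides

    def noise_spec(self) -> NoiseSpec:
        allowed = {f.name for f in fields(NoiseSpec)}
        unknown = set(self.noise) - allowed
        if unknown:
            raise ConfigurationError(
                f"unknown noise key(s): {sorted(unknown)}")
        return NoiseSpec(**self.noise)


@dataclass(frozen=True)
class RunConfig:
    acquisition: AcquisitionConfig = field(default_factory=AcquisitionConfig)
    preprocessing: PreprocessingConfig = field(default_factory=PreprocessingConfig)
    metrics: MetricsConfig = field(default_factory=MetricsConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    master_seed: int = 0

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        data.pop("content_hash", None)  # embedded by to_yaml, not a config key
        allowed = {f.name for f in fields(cls)}
        unknown = set(data) - allowed
        if unknown:
            raise ConfigurationError(f"unknown config key(s): {sorted(unknown)}")
        sections = {}
        for name, section_cls in (
            ("acquisition", AcquisitionConfig),
            ("preprocessing", PreprocessingConfig),
            ("metrics", MetricsConfig),
            ("stats", StatsConfig),
            ("simulation", SimulationConfig),
        ):
            sections[name] = _strict(section_cls, dict(data.get(name, {})), name)
        return cls(master_seed=int(data.get("master_seed", 0)), **sections)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ConfigurationError(f"{path}: config must be a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        def clean(obj):
            if isinstance(obj, dict):
                return {k: clean(v) for k, v in obj.items()}
            if isinstance(obj, tuple):
                return [clean(v) for v in obj]
            return obj
        return clean(asdict(self))

    def content_hash(self) -> str:
        canonical = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]

    def to_yaml(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        data = self.to_dict()
        data["content_hash"] = self.content_hash()
        path.write_text(yaml.safe_dump(data, sort_keys=True))
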