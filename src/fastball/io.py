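"""File formats, configuration and run manifests.

Recordings travel as a raw float32 matrix (``.dat``, channels x
samples, C order) with a JSON sidecar carrying the sampling rate,
channel labels and unit; EDF files are read through :mod:`mne` when it
is installed. Event tables are TSV with ``onset_s`` and ``trial_id``
columns.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from fastball.preprocess import Recording

__all__ = [
    "read_recording",
    "write_recording",
    "read_epoch",
    "write_epoch",
    "read_events",
    "write_events",
    "PipelineConfig",
    "RunManifest",
]


def write_recording(rec: Recording, base_path) -> tuple[Path, Path]:
    """Write ``base.dat`` (float32 raw matrix) + ``base.json`` sidecar."""
    base = Path(base_path)
    dat = base.with_suffix(".dat")
    sidecar = base.with_suffix(".json")
    rec.data.astype(np.float32).tofile(dat)
    meta = {
        "fs_hz": rec.fs_hz,
        "channels": list(rec.channel_labels),
        "units": "uV",
        "n_channels": rec.n_channels,
        "n_samples": rec.n_samples,
        "dtype": "float32",
        "order": "C",
        "reference": rec.reference,
    }
    sidecar.write_text(json.dumps(meta, indent=1))
    return dat, sidecar


def _read_matrix_json(path: Path) -> Recording:
    sidecar = path.with_suffix(".json")
    dat = path.with_suffix(".dat")
    if not sidecar.exists():
        raise FileNotFoundError(f"sidecar {sidecar} not found")
    if not dat.exists():
        raise FileNotFoundError(f"data file {dat} not found")
    meta = json.loads(sidecar.read_text())
    if "fs_hz" not in meta:
        raise ValueError("sidecar missing fs_hz")
    units = meta.get("units", "uV")
    scale = {"uV": 1.0, "mV": 1e3, "V": 1e6}.get(units)
    if scale is None:
        raise ValueError(f"unit {units!r} is not convertible to uV")
    raw = np.fromfile(dat, dtype=meta.get("dtype", "float32"))
    if raw.size == 0:
        raise ValueError(f"empty data file {dat}")
    nch = meta.get("n_channels", len(meta.get("channels", [])))
    if nch == 0 or raw.size % nch != 0:
        raise ValueError("data size does not match channel count")
    data = raw.reshape(nch, -1).astype(float) * scale
    if "n_samples" in meta and data.shape[1] != meta["n_samples"]:
        raise ValueError(
            f"sidecar says {meta['n_samples']} samples, file holds {data.shape[1]}"
        )
    return Recording(
        data=data,
        fs_hz=float(meta["fs_hz"]),
        channel_labels=tuple(meta.get("channels", [f"ch{i}" for i in range(nch)])),
        reference=meta.get("reference", "as-recorded"),
    )


def _read_edf(path: Path) -> Recording:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - mne ships with the env
        raise ImportError("reading EDF requires mne") from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # mne returns volts
    return Recording(
        data=data,
        fs_hz=float(raw.info["sfreq"]),
        channel_labels=tuple(raw.ch_names),
    )


def read_recording(path) -> Recording:
    """Read a recording (EDF, or float32 matrix + JSON sidecar), in uV."""
    path = Path(path)
    if path.suffix.lower() == ".edf":
        return _read_edf(path)
    return _read_matrix_json(path)


def write_epoch(ep, base_path) -> tuple[Path, Path]:
    """Write a preprocessed epoch as float32 matrix + JSON sidecar."""
    base = Path(base_path)
    dat = base.with_suffix(".dat")
    sidecar = base.with_suffix(".json")
    ep.data.astype(np.float32).tofile(dat)
    meta = {
        "fs_hz": ep.fs_hz,
        "onset_s": ep.onset_s,
        "n_cycles": ep.n_cycles,
        "oddball_freq_hz": ep.oddball_freq_hz,
        "n_channels": ep.data.shape[0],
        "n_samples": ep.data.shape[1],
        "channels": list(ep.channel_labels),
        "fraction_zeroed": ep.fraction_zeroed,
        "dtype": "float32",
        "units": "uV",
    }
    sidecar.write_text(json.dumps(meta, indent=1))
    return dat, sidecar


def read_epoch(path):
    """Read an epoch written by :func:`write_epoch`."""
    from fastball.preprocess import TrialEpoch

    base = Path(path)
    sidecar = base.with_suffix(".json")
    dat = base.with_suffix(".dat")
    if not sidecar.exists() or not dat.exists():
        raise FileNotFoundError(f"epoch files {dat} / {sidecar} not found")
    meta = json.loads(sidecar.read_text())
    data = np.fromfile(dat, dtype=meta.get("dtype", "float32")).reshape(
        meta["n_channels"], -1
    ).astype(float)
    return TrialEpoch(
        data=data,
        fs_hz=float(meta["fs_hz"]),
        onset_s=float(meta.get("onset_s", 0.0)),
        n_cycles=int(meta["n_cycles"]),
        oddball_freq_hz=float(meta["oddball_freq_hz"]),
        fraction_zeroed=float(meta.get("fraction_zeroed", 0.0)),
        channel_labels=tuple(meta.get("channels", [])),
    )


def write_events(events: pd.DataFrame, path) -> None:
    events[["onset_s", "trial_id"]].to_csv(path, sep="\t", index=False)


def read_events(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"events file {path} not found")
    ev = pd.read_csv(path, sep="\t")
    if "onset_s" not in ev.columns:
        raise ValueError("events file must have an onset_s column")
    return ev


@dataclass
class PipelineConfig:
    """Every tunable analysis parameter, with study defaults.

    Round-trips through YAML; unknown keys are rejected so that typos
    in configuration files fail loudly.
    """

    base_freq_hz: float = 3.0
    oddball_freq_hz: float = 0.6
    n_cycles: int = 104
    target_hz: float = 120.0
    cutoff_hz: float = 40.0
    rolloff_db_per_oct: float = 24.0
    detrend_order: int = 3
    artifact_threshold_uv: float = 250.0
    taper_points: int = 670
    half_width_hz: float = 0.10
    n_adjacent_excluded: int = 1
    z_crit: float = 1.96
    max_candidate_hz: float = 20.0
    harmonic_stop: str = "first_gap"
    use_snr_for_z: bool = False
    bootstrap_B: int = 1000
    seed: int = 0

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "PipelineConfig":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        loaded = yaml.safe_load(text) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(loaded) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**loaded)


@dataclass
class RunManifest:
    """Reproducibility record emitted by every pipeline run."""

    config_hash: str
    package_version: str
    input_hashes: dict[str, str] = field(default_factory=dict)
    stage_counts: dict[str, float] = field(default_factory=dict)

    @staticmethod
    def hash_text(text: str) -> str:
        return hashlib.sha256(text.encode()).hexdigest()

    @staticmethod
    def hash_file(path) -> str:
        return hashlib.sha256(Path(path).read_bytes()).hexdigest()

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1))
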