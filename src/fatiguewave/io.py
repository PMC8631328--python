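"""File formats and configuration.

All text outputs are UTF-8 with ``.`` decimal separators.  Formats:

* signal CSV — header ``time_s,<ch1>,...,<chN>``; one row per sample;
  timestamps in seconds, 0-based at recording start, uniform within 1e-6 s.
* event TSV — columns ``time_s``, ``kind`` (standard/deviant/press),
  ``modality`` (audio/visual).
* session CSV — columns ``subject, session, sss, sleep_min``.
* EDF — read-only path for real-device recordings, via ``mne``.
* config — nested key-value YAML, round-tripping identically.

Every CSV written by the pipeline carries its generating config hash in a
leading ``#`` comment line so outputs are traceable to their parameters.
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

from .behavioral import OddballLog
from .preprocess import EEGRecording

_FLOAT_FMT = "%.9g"


def write_signal_csv(
    recording: EEGRecording, path: str | Path, config_hash: str | None = None
) -> None:
    """Write a recording in the signal CSV dialect."""
    path = Path(path)
    t = np.arange(recording.n_samples) / recording.fs
    df = pd.DataFrame({"time_s": t})
    for label, row in zip(recording.channel_labels, recording.data):
        df[label] = row
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if config_hash:
            fh.write(f"# config={config_hash}\n")
        df.to_csv(fh, index=False, float_format=_FLOAT_FMT)


def read_signal_csv(
    path: str | Path,
    subject: int | str | None = None,
    session: str | None = None,
    jitter_s: float = 1e-6,
) -> EEGRecording:
    """Read a signal CSV; sampling rate is inferred from the time column.

    Raises ``ValueError`` naming the offending line for ragged rows, and
    for timestamp jitter beyond ``jitter_s``.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#", on_bad_lines="error")
    except pd.errors.ParserError as err:
        raise ValueError(f"{path}: ragged row — {err}") from err
    except pd.errors.EmptyDataError as err:
        raise ValueError(f"{path}: empty file") from err
    if "time_s" not in df.columns or df.shape[1] < 2:
        raise ValueError(f"{path}: expected header 'time_s,<ch1>,...'")
    if df.isna().any().any():
        bad = int(df.isna().any(axis=1).idxmax())
        raise ValueError(f"{path}: ragged/short row at data line {bad + 1}")
    if len(df) < 2:
        raise ValueError(f"{path}: need at least 2 samples to infer fs")
    t = df["time_s"].to_numpy(dtype=float)
    dt = np.diff(t)
    dt_med = float(np.median(dt))
    if dt_med <= 0:
        raise ValueError(f"{path}: non-increasing timestamps")
    if np.max(np.abs(dt - dt_med)) > jitter_s:
        raise ValueError(f"{path}: non-uniform timestamps beyond {jitter_s} s jitter")
    labels = tuple(c for c in df.columns if c != "time_s")
    data = df[list(labels)].to_numpy(dtype=float).T
    return EEGRecording(
        data=data, fs=1.0 / dt_med, channel_labels=labels,
        subject=subject, session=session,
    )


def read_edf(
    path: str | Path,
    channels: tuple[str, ...] | None = None,
    subject: int | str | None = None,
    session: str | None = None,
) -> EEGRecording:
    """Read an EDF/EDF+ recording (µV amplitudes) via ``mne``.

    ``channels`` selects and orders a subset; a missing label raises an
    error listing the labels actually present.
    """
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="ERROR")
    available = list(raw.ch_names)
    if channels is not None:
        missing = [c for c in channels if c not in available]
        if missing:
            raise ValueError(
                f"{path}: channel(s) {missing} not found; available: {available}"
            )
        picks = list(channels)
    else:
        picks = available
    data = raw.get_data(picks=picks) * 1e6  # mne loads volts; convert to µV
    return EEGRecording(
        data=data, fs=float(raw.info["sfreq"]), channel_labels=tuple(picks),
        subject=subject, session=session,
    )


def write_events_tsv(
    log: OddballLog, path: str | Path, config_hash: str | None = None
) -> None:
    """Write an oddball event log in the event TSV dialect."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if config_hash:
            fh.write(f"# config={config_hash}\n")
        log.events.to_csv(fh, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_events_tsv(
    path: str | Path, subject: int | str | None = None, session: str | None = None
) -> OddballLog:
    df = pd.read_csv(path, sep="\t", comment="#")
    return OddballLog(events=df, subject=subject, session=session)


def write_table_csv(
    df: pd.DataFrame, path: str | Path, config_hash: str | None = None
) -> None:
    """Write any tidy table with the config-hash comment header."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if config_hash:
            fh.write(f"# config={config_hash}\n")
        df.to_csv(fh, index=False, float_format="%.12g")


def read_table_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


@dataclass
class PipelineConfig:
    """Every tunable parameter of the simulate → extract → stats chain.

    Nested sections mirror the module boundaries; unspecified cohort /
    oddball / effects fields fall back to the generator defaults.
    """

    seed: int = 0
    cohort: dict = field(default_factory=dict)
    oddball: dict = field(default_factory=dict)
    effects: dict = field(default_factory=dict)
    preprocessing: dict = field(
        default_factory=lambda: {
            "band_low_hz": 3.0,
            "band_high_hz": 30.0,
            "decimation": 4,
            "window_s": 8.0,
            "overlap": 0.5,
        }
    )
    entropy: dict = field(
        default_factory=lambda: {
            "wavelet": "db4",
            "levels": 4,
            "q": 2.0,
            "normalized": True,
            "denoise": True,
        }
    )
    behavioral: dict = field(
        default_factory=lambda: {"valid_window_lo_s": 0.1, "valid_window_hi_s": 1.0}
    )
    summary_channel: str = "Fp1h"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        base = cls()
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        merged = {}
        for f in dataclasses.fields(cls):
            default = getattr(base, f.name)
            if f.name in d:
                if isinstance(default, dict):
                    value = dict(default)
                    value.update(d[f.name] or {})
                else:
                    value = d[f.name]
            else:
                value = default
            merged[f.name] = value
        return cls(**merged)

    def hash(self) -> str:
        """Short stable digest identifying this configuration."""
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path: str | Path) -> PipelineConfig:
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig.from_dict(data)


def save_config(config: PipelineConfig, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
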