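"""Core data types and file I/O shared by every pipeline stage.

A :class:`Recording` is the unit of work: one single-channel acoustic
waveform captured at a knee joint during a flexion-extension protocol,
together with the acquisition metadata (subject, diagnostic group, sensor
placement, kinematic chain) that the later classification stages need.

Waveforms are read from WAV (integer or float PCM, via ``scipy.io.wavfile``)
or from two-column CSV files with a ``time_s,value`` header.  Result objects
from the analysis stages are serialised by :func:`write_results`.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
from scipy.io import wavfile


class Group(str, Enum):
    """Diagnostic label: healthy control or osteoarthritis."""

    HC = "HC"
    OA = "OA"


class Sensor(str, Enum):
    """Contact-microphone placement on the patella region."""

    M1 = "M1"
    M2 = "M2"
    M3 = "M3"


class Chain(str, Enum):
    """Kinematic chain of the movement protocol (loaded vs. open)."""

    CKC = "CKC"
    OKC = "OKC"


class FormatError(ValueError):
    """Raised when a waveform file cannot be parsed."""


class InvalidInputError(ValueError):
    """Raised when an input violates a precondition (too short, non-finite ...)."""


@dataclass(frozen=True)
class RecordingMeta:
    """Acquisition metadata attached to one recording."""

    subject_id: str
    group: Group = Group.HC
    sensor: Sensor = Sensor.M1
    chain: Chain = Chain.CKC
    label_known: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "group", Group(self.group))
        object.__setattr__(self, "sensor", Sensor(self.sensor))
        object.__setattr__(self, "chain", Chain(self.chain))

    def to_dict(self) -> dict[str, Any]:
        return {
            "subject_id": self.subject_id,
            "group": self.group.value,
            "sensor": self.sensor.value,
            "chain": self.chain.value,
            "label_known": self.label_known,
        }


@dataclass
class Recording:
    """A sampled single-channel waveform plus its metadata.

    Parameters
    ----------
    samples
        Real-valued signal in arbitrary acoustic units; length >= 2, finite.
    fs
        Sampling rate in Hz, > 0.
    meta
        Acquisition metadata.
    """

    samples: np.ndarray
    fs: float
    meta: RecordingMeta = field(
        default_factory=lambda: RecordingMeta(subject_id="anon")
    )

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise InvalidInputError("samples must be a 1-D sequence of length >= 2")
        if not np.all(np.isfinite(self.samples)):
            raise InvalidInputError("samples contain non-finite values")
        if not self.fs > 0:
            raise InvalidInputError(f"fs must be positive, got {self.fs}")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.fs

    def with_samples(self, samples: np.ndarray) -> "Recording":
        """Copy of this recording with the waveform replaced (same fs/meta)."""
        return Recording(samples=np.asarray(samples, dtype=float), fs=self.fs, meta=self.meta)


def read_recording(path: str | Path, meta: RecordingMeta) -> Recording:
    """Load a waveform from WAV or ``time_s,value`` CSV.

    The sampling rate comes from the WAV header, or for CSV from the median
    spacing of the time column.  Integer PCM is scaled to [-1, 1); float data
    are passed through unchanged.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".wav":
        try:
            fs, data = wavfile.read(path)
        except Exception as exc:  # scipy raises bare ValueError on junk
            raise FormatError(f"cannot read WAV file {path}: {exc}") from exc
        if data.ndim > 1:
            data = data[:, 0]
        if np.issubdtype(data.dtype, np.integer):
            scale = float(np.iinfo(data.dtype).max) + 1.0
            samples = data.astype(float) / scale
        else:
            samples = data.astype(float)
        if samples.size < 2:
            raise InvalidInputError(f"{path}: fewer than 2 samples")
        return Recording(samples=samples, fs=float(fs), meta=meta)
    # CSV branch
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise FormatError(f"cannot parse CSV file {path}: {exc}") from exc
    if not {"time_s", "value"}.issubset(df.columns):
        raise FormatError(f"{path}: CSV must have columns time_s,value")
    t = df["time_s"].to_numpy(dtype=float)
    v = df["value"].to_numpy(dtype=float)
    if t.size < 2:
        raise InvalidInputError(f"{path}: fewer than 2 samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise InvalidInputError(f"{path}: time column is not strictly increasing")
    fs = 1.0 / float(np.median(dt))
    return Recording(samples=v, fs=fs, meta=meta)


def write_recording(recording: Recording, path: str | Path) -> None:
    """Write a recording as float32 WAV or as ``time_s,value`` CSV."""
    path = Path(path)
    if path.suffix.lower() == ".wav":
        wavfile.write(path, int(round(recording.fs)), recording.samples.astype(np.float32))
    else:
        pd.DataFrame(
            {"time_s": recording.times, "value": recording.samples}
        ).to_csv(path, index=False)


def _json_default(obj: Any) -> Any:
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, Enum):
        return obj.value
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return dataclasses.asdict(obj)
    raise TypeError(f"not JSON-serialisable: {type(obj)}")


def write_results(report: Any, path: str | Path) -> None:
    """Serialise an analysis result to disk.

    Dispatch by type: an IMF set becomes a multi-column CSV
    (``imf_1..imf_N, residual``); a scalogram becomes a PNG preview plus a
    CSV of the magnitude matrix; everything else (DFA results, filter
    reports, training results, plain dicts/dataclasses) is written as JSON.
    """
    path = Path(path)
    if not path.parent.exists():
        raise IOError(f"parent directory does not exist: {path.parent}")

    kind = type(report).__name__
    if kind == "IMFSet":
        cols = {f"imf_{j + 1}": imf for j, imf in enumerate(report.imfs)}
        cols["residual"] = report.residual
        pd.DataFrame(cols).to_csv(path, index=False)
    elif kind == "Scalogram":
        np.savetxt(path.with_suffix(".csv"), report.magnitude, delimiter=",")
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 4))
        ax.pcolormesh(report.times_s, report.freqs_hz, report.magnitude, shading="auto")
        ax.set_yscale("log")
        ax.set_xlabel("time [s]")
        ax.set_ylabel("frequency [Hz]")
        fig.savefig(path.with_suffix(".png"), dpi=100)
        plt.close(fig)
    else:
        payload = report if isinstance(report, dict) else dataclasses.asdict(report)
        with open(path, "w") as fh:
            json.dump(payload, fh, default=_json_default, indent=1)


def read_imfset_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read back an IMF-set CSV; returns (imfs [N_imf, T], residual [T])."""
    df = pd.read_csv(path)
    imf_cols = [c for c in df.columns if c.startswith("imf_")]
    imfs = df[imf_cols].to_numpy(dtype=float).T
    residual = df["residual"].to_numpy(dtype=float)
    return imfs, residual
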