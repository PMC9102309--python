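"""Recording containers and file I/O.

A :class:`Recording` is one uniformly sampled channel (EEG in microvolts,
fNIRS in optical-density units) plus its sampling rate.  A
:class:`PairedRecording` holds the motion-corrupted channel together with the
simultaneously acquired artifact-free reference ("ground truth") channel and,
when known, the time intervals during which motion was applied.

Paired recordings are stored as plain comma-separated text with one header
row and ``corrupted`` / ``reference`` columns (an optional ``time`` column is
validated against the declared sampling rate but never authoritative).
Artifact epochs travel in a JSON sidecar next to the CSV.
"""

from __future__ import annotations

import dataclasses
import json
import math
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ParseError, SchemaError

__all__ = [
    "Modality",
    "Recording",
    "PairedRecording",
    "MetricsReport",
    "read_paired_csv",
    "write_paired_csv",
    "write_metrics_json",
    "read_metrics_json",
    "summarize_reports",
]


class Modality(str, Enum):
    EEG = "EEG"
    FNIRS = "fNIRS"


def _as_modality(value: "Modality | str") -> Modality:
    if isinstance(value, Modality):
        return value
    for m in Modality:
        if m.value.lower() == str(value).lower():
            return m
    raise SchemaError(f"unknown modality {value!r}; expected one of "
                      f"{[m.value for m in Modality]}")


@dataclasses.dataclass
class Recording:
    """One uniformly sampled signal channel.

    Parameters
    ----------
    samples:
        Finite-valued sample sequence, length >= 2.
    fs:
        Sampling rate in Hz, > 0.
    modality:
        ``Modality.EEG`` or ``Modality.FNIRS``.
    label:
        Free-text channel description.
    """

    samples: np.ndarray
    fs: float
    modality: Modality = Modality.EEG
    label: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise FormatError("samples must be one-dimensional")
        if self.samples.size < 2:
            raise FormatError("a recording needs at least 2 samples")
        if not np.all(np.isfinite(self.samples)):
            raise FormatError("samples contain NaN or Inf")
        if not (self.fs > 0 and math.isfinite(self.fs)):
            raise FormatError(f"sampling rate must be positive, got {self.fs}")
        self.modality = _as_modality(self.modality)

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def replace(self, **changes) -> "Recording":
        return dataclasses.replace(self, **changes)


@dataclasses.dataclass
class PairedRecording:
    """A motion-corrupted channel aligned sample-for-sample with its reference.

    ``artifact_epochs`` is a sorted list of non-overlapping ``[start_s,
    end_s)`` intervals (seconds from record start) where motion was applied;
    it may be empty when the epochs are unknown.
    """

    corrupted: Recording
    reference: Recording
    artifact_epochs: list[tuple[float, float]] = dataclasses.field(default_factory=list)

    def __post_init__(self) -> None:
        if self.corrupted.n_samples != self.reference.n_samples:
            raise FormatError(
                f"channel lengths differ: corrupted={self.corrupted.n_samples}, "
                f"reference={self.reference.n_samples}")
        if self.corrupted.fs != self.reference.fs:
            raise FormatError("channels must share one sampling rate")
        epochs = [(float(s), float(e)) for s, e in self.artifact_epochs]
        dur = self.corrupted.duration_s
        prev_end = 0.0
        for start, end in epochs:
            if not (0.0 <= start < end <= dur + 1e-9):
                raise FormatError(f"epoch [{start}, {end}) outside [0, {dur:.6g}]")
            if start < prev_end:
                raise FormatError("artifact epochs must be sorted and non-overlapping")
            prev_end = end
        self.artifact_epochs = epochs

    @property
    def fs(self) -> float:
        return self.corrupted.fs

    @property
    def n_samples(self) -> int:
        return self.corrupted.n_samples

    @property
    def duration_s(self) -> float:
        return self.corrupted.duration_s


@dataclasses.dataclass
class MetricsReport:
    """Denoising performance for one record.

    ``delta_snr_db`` is the SNR improvement in dB, ``eta_pct`` the percentage
    reduction in motion artifacts, ``rho_before``/``rho_after`` the Pearson
    correlations of the corrupted/cleaned signal with the reference, and
    ``method`` a free-text descriptor (wavelet, level, stage count,
    selection mode).
    """

    delta_snr_db: float
    eta_pct: float
    rho_before: float
    rho_after: float
    method: str
    rho_clean: float | None = None
    extra: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("rho_before", "rho_after", "rho_clean"):
            v = getattr(self, name)
            if v is not None and math.isfinite(v) and not (-1.0 - 1e-9 <= v <= 1.0 + 1e-9):
                raise FormatError(f"{name}={v} outside [-1, 1]")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "MetricsReport":
        return cls(**d)


def _sidecar_path(path: "str | Path") -> Path:
    path = Path(path)
    return path.with_name(path.stem + ".epochs.json")


def read_paired_csv(path: "str | Path", fs: float,
                    modality: "Modality | str" = Modality.EEG) -> PairedRecording:
    """Read a paired recording from a CSV file written by :func:`write_paired_csv`.

    The file must have a header row and numeric ``corrupted`` and
    ``reference`` columns.  An optional ``time`` column is checked for
    consistency with ``fs`` (0.1 % tolerance) but the metadata rate governs.
    Artifact epochs are picked up from the JSON sidecar when present.
    """
    path = Path(path)
    df = pd.read_csv(path)
    for col in ("corrupted", "reference"):
        if col not in df.columns:
            raise SchemaError(f"missing required column {col!r} in {path}")
    cols = {}
    for col in ("corrupted", "reference"):
        try:
            cols[col] = pd.to_numeric(df[col], errors="raise").to_numpy(dtype=float)
        except (ValueError, TypeError) as exc:
            raise ParseError(f"non-numeric value in column {col!r}: {exc}") from exc
    for col, values in cols.items():
        if np.isnan(values).any():
            raise FormatError(f"column {col!r} has missing values "
                              "(unequal column lengths?)")
    if "time" in df.columns:
        t = pd.to_numeric(df["time"], errors="coerce").to_numpy(dtype=float)
        dt = np.diff(t)
        if dt.size and np.median(dt) > 0:
            implied_fs = 1.0 / float(np.median(dt))
            if abs(implied_fs - fs) / fs > 1e-3:
                raise FormatError(
                    f"time column implies fs={implied_fs:.6g} Hz, declared {fs:.6g} Hz")
    modality = _as_modality(modality)
    epochs: list[tuple[float, float]] = []
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        epochs = [tuple(ep) for ep in meta.get("artifact_epochs", [])]
    return PairedRecording(
        corrupted=Recording(cols["corrupted"], fs=fs, modality=modality, label="corrupted"),
        reference=Recording(cols["reference"], fs=fs, modality=modality, label="reference"),
        artifact_epochs=epochs,
    )


def write_paired_csv(rec: PairedRecording, path: "str | Path") -> None:
    """Write a paired recording as CSV plus a JSON epoch sidecar.

    Samples round-trip through :func:`read_paired_csv` to better than 1e-9.
    """
    path = Path(path)
    df = pd.DataFrame({
        "corrupted": rec.corrupted.samples,
        "reference": rec.reference.samples,
    })
    df.to_csv(path, index=False)
    meta = {
        "artifact_epochs": [list(ep) for ep in rec.artifact_epochs],
        "fs": rec.fs,
        "modality": rec.corrupted.modality.value,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def write_metrics_json(report: MetricsReport, path: "str | Path") -> None:
    """Serialize a metrics report (all fields, losslessly) to JSON."""
    Path(path).write_text(json.dumps(report.to_dict(), indent=1, allow_nan=True))


def read_metrics_json(path: "str | Path") -> MetricsReport:
    return MetricsReport.from_dict(json.loads(Path(path).read_text()))


def summarize_reports(reports: Sequence[MetricsReport]) -> dict:
    """Arithmetic mean and standard deviation of metrics over a batch."""
    if not reports:
        raise FormatError("cannot summarize an empty batch")
    dsnr = np.array([r.delta_snr_db for r in reports], dtype=float)
    eta = np.array([r.eta_pct for r in reports], dtype=float)
    return {
        "n_records": len(reports),
        "mean_delta_snr_db": float(np.mean(dsnr)),
        "sd_delta_snr_db": float(np.std(dsnr)),
        "mean_eta_pct": float(np.mean(eta)),
        "sd_eta_pct": float(np.std(eta)),
    }
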