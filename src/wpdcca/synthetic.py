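"""Seedable generator of paired clean/motion-corrupted recordings.

The generator emulates the structure of the two-channel benchmark protocol
used to validate motion-artifact removal: two simultaneously recorded,
highly correlated channels, one of which is disturbed by motion for 10-25 s
at regular 2-minute intervals over a roughly 9-minute record (EEG acquired
at 2048 Hz, fNIRS at 25 Hz).

The clean EEG channel is a sum of band-limited Gaussian processes in the
canonical delta (1-4 Hz), theta (4-8), alpha (8-13), beta (13-30) and gamma
(30-80 Hz) bands with 1/f-weighted band powers.  The clean fNIRS channel is
a slow hemodynamic oscillation (< 0.1 Hz) plus an ~1 Hz cardiac component
and low-level broadband noise.  The motion artifact is an integrated-noise
walk windowed by a tapered (Tukey) envelope — temporally localized, smooth,
with high local variance and a 1/f^2 spectrum that concentrates its energy
below 2 Hz while leaving weak correlated traces in the higher sub-bands, as
electrode-motion transients do.  Bursts are scaled jointly so that the
whole-record artifact RMS is ``artifact_amplitude`` times the clean RMS.

With ``sensor_noise_level = 0`` (the default) the reference channel equals
the clean signal exactly, so the reference/corrupted correlation over
artifact-free epochs is exactly 1, matching the idealized convention of the
``eta_ideal`` metric; a nonzero level adds independent sensor noise to the
reference so the general metric can be exercised.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import signal as sps

from .errors import ConfigError
from .signal_io import Modality, PairedRecording, Recording, _as_modality

__all__ = ["SynthConfig", "generate_clean", "generate_paired", "EEG_BANDS"]

#: Canonical EEG rhythm bands (Hz).
EEG_BANDS = ((1.0, 4.0), (4.0, 8.0), (8.0, 13.0), (13.0, 30.0), (30.0, 80.0))

_DEFAULT_FS = {Modality.EEG: 2048.0, Modality.FNIRS: 25.0}


@dataclasses.dataclass
class SynthConfig:
    """Configuration of the paired-recording generator.

    Defaults mirror the benchmark protocol: 540 s records, one 10-25 s
    artifact burst per 120 s interval, EEG at 2048 Hz / fNIRS at 25 Hz.
    ``artifact_amplitude`` is the ratio of whole-record artifact RMS to clean
    RMS (bursts are locally much stronger, as electrode-motion artifacts
    are); ``sensor_noise_level`` is the reference-channel noise RMS as a
    fraction of clean RMS.
    """

    modality: Modality = Modality.EEG
    duration_s: float = 540.0
    fs: float | None = None
    artifact_interval_s: float = 120.0
    artifact_duration_range_s: tuple[float, float] = (10.0, 25.0)
    artifact_amplitude: float = 3.0
    sensor_noise_level: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.modality = _as_modality(self.modality)
        if not self.duration_s > self.artifact_interval_s:
            raise ConfigError("duration_s must exceed artifact_interval_s")
        if self.artifact_amplitude < 0:
            raise ConfigError("artifact_amplitude must be >= 0")
        if self.sensor_noise_level < 0:
            raise ConfigError("sensor_noise_level must be >= 0")
        lo, hi = self.artifact_duration_range_s
        if not (0 < lo <= hi):
            raise ConfigError("artifact_duration_range_s must satisfy 0 < lo <= hi")

    @property
    def resolved_fs(self) -> float:
        return float(self.fs) if self.fs is not None else _DEFAULT_FS[self.modality]

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.resolved_fs))


def _streams(cfg: SynthConfig) -> tuple[np.random.Generator, ...]:
    # independent child streams: clean signal, artifact process, sensor noise;
    # the artifact amplitude only rescales, so it never perturbs the draws
    children = np.random.SeedSequence(cfg.seed).spawn(3)
    return tuple(np.random.default_rng(c) for c in children)


def _bandlimited_noise(rng: np.random.Generator, n: int, fs: float,
                       lo: float, hi: float) -> np.ndarray:
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    y = sps.sosfiltfilt(sos, rng.standard_normal(n))
    sd = y.std()
    return y / sd if sd > 0 else y


def _clean_eeg(rng: np.random.Generator, n: int, fs: float) -> np.ndarray:
    x = np.zeros(n)
    nyq = fs / 2.0
    for lo, hi in EEG_BANDS:
        if lo >= 0.9 * nyq:  # band unrepresentable at this rate
            continue
        hi = min(hi, 0.9 * nyq)
        centre = 0.5 * (lo + hi)
        # power ~ 1/f  =>  amplitude ~ 1/sqrt(f)
        x += _bandlimited_noise(rng, n, fs, lo, hi) / np.sqrt(centre)
    return x / x.std()


def _clean_fnirs(rng: np.random.Generator, n: int, fs: float) -> np.ndarray:
    t = np.arange(n) / fs
    sos = sps.butter(4, 0.08, btype="lowpass", fs=fs, output="sos")
    hemo = sps.sosfiltfilt(sos, rng.standard_normal(n))
    hemo /= hemo.std()
    phase = rng.uniform(0, 2 * np.pi)
    cardiac = np.sin(2 * np.pi * 1.1 * t + phase)
    broadband = rng.standard_normal(n)
    x = hemo + 0.3 * cardiac + 0.1 * broadband
    return x / x.std()


def generate_clean(cfg: SynthConfig) -> Recording:
    """Generate the undisturbed channel; deterministic for a given seed."""
    rng_clean, _, _ = _streams(cfg)
    fs, n = cfg.resolved_fs, cfg.n_samples
    if cfg.modality is Modality.EEG:
        x = _clean_eeg(rng_clean, n, fs)
    else:
        x = _clean_fnirs(rng_clean, n, fs)
    return Recording(x, fs=fs, modality=cfg.modality,
                     label=f"synthetic clean {cfg.modality.value} seed={cfg.seed}")


def _artifact_track(cfg: SynthConfig, rng: np.random.Generator,
                    n: int, fs: float) -> tuple[np.ndarray, list[tuple[float, float]]]:
    """Unit-scale artifact waveform and its burst epochs.

    One burst per interval, centred within it, with duration drawn uniformly
    from the configured range: an integrated-noise walk tapered to zero at
    the burst edges.
    """
    track = np.zeros(n)
    epochs: list[tuple[float, float]] = []
    n_bursts = int(np.floor(cfg.duration_s / cfg.artifact_interval_s))
    lo, hi = cfg.artifact_duration_range_s
    for k in range(n_bursts):
        dur = float(rng.uniform(lo, hi))
        start = (k + 0.5) * cfg.artifact_interval_s
        dur = min(dur, cfg.duration_s - start)
        m = int(round(dur * fs))
        if m < 8:
            continue
        walk = np.cumsum(rng.standard_normal(m))
        walk -= walk.mean()
        burst = walk * sps.windows.tukey(m, 0.4)
        i0 = int(round(start * fs))
        track[i0: i0 + m] = burst
        epochs.append((start, start + dur))
    return track, epochs


def generate_paired(cfg: SynthConfig) -> PairedRecording:
    """Generate an aligned corrupted/reference pair with known artifact epochs."""
    clean = generate_clean(cfg)
    _, rng_art, rng_noise = _streams(cfg)
    fs, n = cfg.resolved_fs, cfg.n_samples
    clean_rms = float(clean.samples.std())
    track, epochs = _artifact_track(cfg, rng_art, n, fs)
    artifact = np.zeros(n)
    track_rms = float(track.std())
    if cfg.artifact_amplitude > 0 and track_rms > 0:
        artifact = track * (cfg.artifact_amplitude * clean_rms / track_rms)
    corrupted = clean.samples + artifact
    reference = clean.samples
    if cfg.sensor_noise_level > 0:
        reference = reference + (cfg.sensor_noise_level * clean_rms
                                 ) * rng_noise.standard_normal(n)
    return PairedRecording(
        corrupted=Recording(corrupted, fs=fs, modality=cfg.modality, label="corrupted"),
        reference=Recording(reference, fs=fs, modality=cfg.modality, label="reference"),
        artifact_epochs=epochs,
    )
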