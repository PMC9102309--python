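"""Preprocessing chain: downsampling, power-line notch, baseline-drift removal.

EEG records acquired at 2048 Hz are decimated to 256 Hz (all clinically
relevant EEG rhythms live below the resulting 128 Hz Nyquist), power-line
interference is notched out at 50 Hz and every harmonic below Nyquist, and
slow baseline drift is estimated by least-squares polynomial fitting and
subtracted.  All operations are linear and zero-phase, so the corrupted and
reference channels of a pair can be processed identically without relative
lag.
"""

from __future__ import annotations

import dataclasses
import warnings
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .errors import ConfigError, NumericalError
from .signal_io import PairedRecording, Recording

__all__ = [
    "PreprocessConfig",
    "downsample",
    "notch_filter",
    "baseline_correct",
    "preprocess_recording",
    "preprocess_paired",
]


@dataclasses.dataclass
class PreprocessConfig:
    """Parameters of the preprocessing chain.

    ``target_fs`` of ``None`` (or a rate equal to the record's) skips
    downsampling — the fNIRS benchmark rate of 25 Hz is kept as acquired.
    The notch is a third-order Butterworth band-stop, 2 Hz wide by default
    (narrow enough to spare gamma-band EEG content), repeated at every
    harmonic of the centre frequency below Nyquist.  The baseline is a
    polynomial of order ``baseline_poly_order`` fitted over the whole record.
    """

    target_fs: float | None = None
    notch_center: float = 50.0
    notch_order: int = 3
    notch_bandwidth: float = 2.0
    baseline_poly_order: int = 6
    apply_notch: bool = True
    apply_baseline: bool = True
    apply_downsample: bool = True

    def __post_init__(self) -> None:
        if self.target_fs is not None and not self.target_fs > 0:
            raise ConfigError(f"target_fs must be positive, got {self.target_fs}")
        if self.notch_order < 1:
            raise ConfigError("notch_order must be >= 1")
        if self.notch_bandwidth <= 0:
            raise ConfigError("notch_bandwidth must be positive")
        if self.baseline_poly_order < 0:
            raise ConfigError("baseline_poly_order must be >= 0")


def downsample(rec: Recording, target_fs: float, *, allow_upsample: bool = False) -> Recording:
    """Resample a recording to ``target_fs`` with mandatory anti-aliasing.

    Integer decimation uses a zero-phase FIR low-pass (Kaiser window, cutoff
    at 80 % of the target Nyquist) followed by sample picking; rational
    ratios fall back to polyphase resampling.  Stopband attenuation above the
    target Nyquist exceeds 60 dB in both paths.
    """
    if not target_fs > 0:
        raise ConfigError(f"target_fs must be positive, got {target_fs}")
    if target_fs > rec.fs and not allow_upsample:
        raise ConfigError(
            f"refusing to upsample from {rec.fs} Hz to {target_fs} Hz")
    if target_fs == rec.fs:
        return rec.replace(samples=rec.samples.copy())
    ratio = Fraction(rec.fs / target_fs).limit_denominator(10_000)
    down, up = ratio.numerator, ratio.denominator
    x = rec.samples
    if up == 1 and down > 1:
        # zero-phase FIR anti-alias + decimation
        numtaps = 24 * down + 1
        taps = sps.firwin(numtaps, 0.8 / down, window=("kaiser", 8.0))
        y = sps.filtfilt(taps, [1.0], x, padlen=min(x.size - 1, 3 * numtaps))
        y = y[::down]
    else:
        y = sps.resample_poly(x, up, down, window=("kaiser", 8.0), padtype="line")
    return rec.replace(samples=y, fs=float(target_fs))


def notch_filter(rec: Recording, cfg: PreprocessConfig) -> Recording:
    """Remove the power-line frequency and all harmonics below Nyquist.

    Each harmonic gets its own third-order Butterworth band-stop, applied
    forward-backward (zero phase).  When the notch centre itself is at or
    above Nyquist — the 25 Hz fNIRS case for a 50 Hz mains frequency — no
    filtering is possible and the record is returned unchanged with a
    warning.
    """
    nyq = rec.fs / 2.0
    if cfg.notch_center >= nyq:
        warnings.warn(
            f"notch centre {cfg.notch_center} Hz is at or above Nyquist "
            f"({nyq} Hz); record returned unfiltered", stacklevel=2)
        return rec.replace(samples=rec.samples.copy())
    y = rec.samples.copy()
    k = 1
    while k * cfg.notch_center < nyq:
        f0 = k * cfg.notch_center
        lo = f0 - cfg.notch_bandwidth / 2.0
        hi = min(f0 + cfg.notch_bandwidth / 2.0, nyq * 0.999)
        sos = sps.butter(cfg.notch_order, [lo, hi], btype="bandstop",
                         fs=rec.fs, output="sos")
        y = sps.sosfiltfilt(sos, y)
        k += 1
    return rec.replace(samples=y)


def baseline_correct(rec: Recording, poly_order: int) -> Recording:
    """Subtract a least-squares polynomial baseline fitted over the record.

    The abscissa is rescaled to [-1, 1] before fitting for numerical
    conditioning.  Because the fit always includes the constant term, the
    output has zero mean (up to round-off).
    """
    if poly_order < 0:
        raise ConfigError("poly_order must be >= 0")
    n = rec.n_samples
    if poly_order >= n:
        raise NumericalError(
            f"polynomial order {poly_order} >= record length {n}: fit is degenerate")
    t = np.linspace(-1.0, 1.0, n)
    try:
        coeffs = np.polynomial.polynomial.polyfit(t, rec.samples, poly_order)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise NumericalError(f"baseline fit failed: {exc}") from exc
    baseline = np.polynomial.polynomial.polyval(t, coeffs)
    return rec.replace(samples=rec.samples - baseline)


def preprocess_recording(rec: Recording, cfg: PreprocessConfig) -> Recording:
    """Run the full chain (downsample, notch, baseline) on one channel."""
    out = rec
    if cfg.apply_downsample and cfg.target_fs is not None and cfg.target_fs != rec.fs:
        out = downsample(out, cfg.target_fs)
    if cfg.apply_notch:
        out = notch_filter(out, cfg)
    if cfg.apply_baseline:
        out = baseline_correct(out, cfg.baseline_poly_order)
    return out


def preprocess_paired(pair: PairedRecording, cfg: PreprocessConfig) -> PairedRecording:
    """Preprocess both channels identically so metrics compare like with like."""
    with warnings.catch_warnings():
        # one warning per pair is enough when the notch is skipped
        warnings.simplefilter("once")
        corrupted = preprocess_recording(pair.corrupted, cfg)
        reference = preprocess_recording(pair.reference, cfg)
    return PairedRecording(corrupted=corrupted, reference=reference,
                           artifact_epochs=list(pair.artifact_epochs))
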