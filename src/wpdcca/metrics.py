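"""Denoising performance metrics: SNR improvement and artifact reduction.

``delta_snr`` measures the change in signal-to-noise ratio relative to the
reference channel.  In the default ``error_variance`` mode it is

    dSNR = 10 log10( var(reference - corrupted) / var(reference - cleaned) ),

i.e. the ratio of the error variance before and after cleaning (the variance
of the reference itself cancels).  A ``literal_variance`` mode using the raw
signal variances var(corrupted)/var(cleaned) is available as well.

``eta`` is the percentage reduction in motion artifacts expressed through the
improvement in correlation with the reference:

    eta = 100 (1 - (rho_clean - rho_after) / (rho_clean - rho_before))

with ``rho_clean`` the reference/corrupted correlation over artifact-free
epochs.  The idealized variant fixes ``rho_clean = 1`` (a worst-case,
lower-bound convention: for rho_after between rho_before and rho_clean it
never reports more reduction than the general form).
"""

from __future__ import annotations

import math
import warnings

import numpy as np

from .errors import MetricError
from .signal_io import Recording

__all__ = [
    "pearson",
    "delta_snr",
    "eta_general",
    "eta_ideal",
    "SNR_CAP_DB",
]

#: Sentinel reported when the post-cleaning error variance underflows to zero.
SNR_CAP_DB = 300.0


def _samples(x) -> np.ndarray:
    if isinstance(x, Recording):
        return x.samples
    return np.asarray(x, dtype=float)


def pearson(a, b) -> float:
    """Pearson correlation coefficient of two equal-length sequences."""
    a, b = _samples(a), _samples(b)
    if a.size != b.size:
        raise MetricError(f"length mismatch: {a.size} vs {b.size}")
    if a.size < 2:
        raise MetricError("need at least 2 samples")
    if a.std() == 0 or b.std() == 0:
        raise MetricError("correlation undefined for a zero-variance input")
    r = float(np.corrcoef(a, b)[0, 1])
    return max(-1.0, min(1.0, r))


def delta_snr(reference, corrupted, cleaned, mode: str = "error_variance") -> float:
    """SNR improvement in dB from before to after cleaning.

    Variances are population variances (divide by N); the convention cancels
    in the ratio.  A vanishing denominator (cleaned identical to the
    reference in error mode) is reported as the capped sentinel
    ``SNR_CAP_DB`` with a warning rather than +inf.
    """
    ref, cor, cln = _samples(reference), _samples(corrupted), _samples(cleaned)
    if not (ref.size == cor.size == cln.size):
        raise MetricError(
            f"length mismatch: reference={ref.size}, corrupted={cor.size}, "
            f"cleaned={cln.size}")
    if mode == "error_variance":
        num = float(np.var(ref - cor))
        den = float(np.var(ref - cln))
    elif mode == "literal_variance":
        num = float(np.var(cor))
        den = float(np.var(cln))
    else:
        raise MetricError(f"unknown SNR mode {mode!r}")
    # scale-aware floor: error variances at round-off level count as zero
    floor = 1e-24 * max(float(np.var(ref)), 1e-300)
    num = 0.0 if num < floor else num
    den = 0.0 if den < floor else den
    if num == 0.0 and den == 0.0:
        return 0.0
    if den == 0.0:
        warnings.warn("zero denominator variance in delta_snr; reporting "
                      f"capped sentinel {SNR_CAP_DB} dB", stacklevel=2)
        return SNR_CAP_DB
    value = 10.0 * math.log10(num / den) if num > 0 else -SNR_CAP_DB
    return float(min(max(value, -SNR_CAP_DB), SNR_CAP_DB))


def eta_general(rho_before: float, rho_after: float, rho_clean: float) -> float:
    """Percentage artifact reduction with an epoch-derived clean correlation.

    May exceed 100 when ``rho_after > rho_clean``; reported as computed.
    """
    if not rho_clean > rho_before:
        raise MetricError(
            f"eta undefined: rho_clean ({rho_clean}) must exceed rho_before "
            f"({rho_before})")
    return 100.0 * (1.0 - (rho_clean - rho_after) / (rho_clean - rho_before))


def eta_ideal(rho_before: float, rho_after: float) -> float:
    """Percentage artifact reduction with the idealized ``rho_clean = 1``."""
    if rho_before >= 1.0:
        raise MetricError("eta undefined: rho_before must be < 1")
    return eta_general(rho_before, rho_after, 1.0)
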