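"""Denoising evaluation metrics: SNR, SNR improvement, correlation, RDE."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


@dataclass
class DenoiseReport:
    """Scorecard of one denoising run (dB values, base-10 logs)."""

    method: str
    snr_in: float
    snr_out: float
    snr_ipv: float
    c_r: float
    rde: float

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "snr_in_db": round(self.snr_in, 2),
            "snr_out_db": round(self.snr_out, 2),
            "snr_improvement_db": round(self.snr_ipv, 2),
            "correlation": self.c_r,
            "rde": self.rde,
        }


def snr(clean: np.ndarray, noise: np.ndarray) -> float:
    """Signal-to-noise ratio in dB: ``10 log10(sum s^2 / sum n^2)``.

    Returns +inf when the noise has zero energy.
    """
    clean = np.asarray(clean, dtype=float)
    noise = np.asarray(noise, dtype=float)
    if clean.shape != noise.shape:
        raise ValueError("clean and noise must have equal length")
    p_noise = float(np.sum(noise**2))
    if p_noise == 0.0:
        return math.inf
    return 10.0 * math.log10(float(np.sum(clean**2)) / p_noise)


def snr_improvement(clean: np.ndarray, noisy: np.ndarray, denoised: np.ndarray) -> float:
    """Output SNR minus input SNR, with noise taken as deviation from clean."""
    clean = np.asarray(clean, dtype=float)
    return snr(clean, np.asarray(denoised, float) - clean) - snr(
        clean, np.asarray(noisy, float) - clean
    )


def correlation_coefficient(denoised: np.ndarray, clean: np.ndarray) -> float:
    """Pearson correlation of the mean-centered sequences."""
    a = np.asarray(denoised, dtype=float)
    b = np.asarray(clean, dtype=float)
    if a.shape != b.shape:
        raise ValueError("sequences must have equal length")
    da, db = a - a.mean(), b - b.mean()
    va, vb = float(np.sum(da**2)), float(np.sum(db**2))
    if va == 0.0 or vb == 0.0:
        raise ValueError("zero-variance input")
    return float(np.sum(da * db) / math.sqrt(va * vb))


def rde(denoised: np.ndarray, clean: np.ndarray) -> float:
    """Relative difference of signal energy: (E_denoised - E_clean)/E_clean.

    Positive values flag remaining noise, negative values information loss.
    """
    a = np.asarray(denoised, dtype=float)
    b = np.asarray(clean, dtype=float)
    e_clean = float(np.sum(b**2))
    if e_clean == 0.0:
        raise ValueError("zero clean energy")
    return (float(np.sum(a**2)) - e_clean) / e_clean


def evaluate(
    clean: np.ndarray,
    noisy: np.ndarray,
    denoised: np.ndarray,
    method: str = "",
) -> DenoiseReport:
    """Assemble the full report for one (clean, noisy, denoised) triple."""
    s_in = snr(clean, np.asarray(noisy, float) - np.asarray(clean, float))
    s_out = snr(clean, np.asarray(denoised, float) - np.asarray(clean, float))
    return DenoiseReport(
        method=method,
        snr_in=s_in,
        snr_out=s_out,
        snr_ipv=s_out - s_in,
        c_r=correlation_coefficient(denoised, clean),
        rde=rde(denoised, clean),
    )
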