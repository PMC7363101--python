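"""Threshold determination and denoising operators for noisy IMFs.

Two families:

* the adaptive 3-sigma (Pauta-criterion) threshold paired with peak
  filtering — iterative outlier trimming isolates the sigma of the "pure"
  noise floor in an IMF, and peak filtering zeroes sub-threshold local
  extrema pass after pass so that entire waves whose peaks clear the
  threshold survive unclipped;
* classical per-IMF thresholds from the wavelet tradition — the universal
  threshold ``sigma_hat * sqrt(2 ln N)`` and a custom threshold built on a
  dyadic model of how white-noise energy decays across IMF orders —
  applied through hard or soft threshold functions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .grouping import noise_std_mad

logger = logging.getLogger(__name__)

#: multiplier of sigma in the Pauta criterion
PAUTA_FACTOR = 3.0
#: noise-energy decay model constants across IMF orders (white-noise fit)
ENERGY_DECAY_BETA = 0.719
ENERGY_DECAY_RHO = 2.01


@dataclass
class ThresholdResult:
    """Adaptive threshold with its convergence trace.

    lam == 3 * sigma_trace[-1]; sigma_trace is non-increasing;
    removed_counts[i] is the number of values trimmed on pass i (the final
    entry is 0: the loop stops when a pass removes nothing).
    """

    lam: float
    sigma_trace: list[float]
    removed_counts: list[int]

    @property
    def iterations(self) -> int:
        return len(self.sigma_trace)

    def to_dict(self) -> dict:
        return {
            "lam": self.lam,
            "sigma_trace": self.sigma_trace,
            "removed_counts": self.removed_counts,
            "iterations": self.iterations,
        }


@dataclass
class CustomThresholdParams:
    """Constants of the custom per-order threshold; C is the global gain."""

    C: float = 0.5

    def __post_init__(self) -> None:
        if not self.C > 0:
            raise ValueError("C must be positive")


def adaptive_threshold(imf: np.ndarray, recenter: bool = True) -> ThresholdResult:
    """Iterative 3-sigma threshold of an IMF.

    Center the values about their mean, compute the sample std (N-1
    denominator), trim every value whose centered magnitude exceeds
    3 sigma, and repeat on the survivors until a pass trims nothing.
    Trimmed values never re-enter.  The threshold is 3x the final sigma.

    With ``recenter`` (default) the mean is recomputed over the survivors
    on every pass; ``recenter=False`` freezes the pass-0 mean, exposed for
    sensitivity checks.
    """
    surv = np.asarray(imf, dtype=float).ravel()
    if surv.size < 2:
        raise ValueError("need at least 2 samples")
    sigma_trace: list[float] = []
    removed: list[int] = []
    mu = float(surv.mean())
    while True:
        if recenter:
            mu = float(surv.mean())
        d = surv - mu
        sigma = float(np.std(d, ddof=1)) if surv.size >= 2 else sigma_trace[-1]
        sigma_trace.append(sigma)
        drop = np.abs(d) > PAUTA_FACTOR * sigma
        n_drop = int(drop.sum())
        removed.append(n_drop)
        if n_drop == 0 or surv.size - n_drop < 2:
            break
        surv = surv[~drop]
    return ThresholdResult(
        lam=PAUTA_FACTOR * sigma_trace[-1],
        sigma_trace=sigma_trace,
        removed_counts=removed,
    )


def peak_filter(imf: np.ndarray, lam: float, max_passes: int | None = None) -> np.ndarray:
    """Peak-filtering denoiser: zero sub-threshold local extrema to a fixpoint.

    Each pass finds the current interior local maxima/minima and zeroes
    those with ``0 < |value| < lam`` (ties retained, matching the >=
    convention of hard thresholding); zeroing exposes new, smaller extrema,
    so passes repeat until one zeroes nothing.  Every output sample is
    either 0 or its original value — waves whose peaks clear the threshold
    keep all of their samples, including sub-threshold flanks.
    """
    if not math.isfinite(lam) or lam < 0:
        raise ValueError("threshold must be finite and non-negative")
    y = np.asarray(imf, dtype=float).copy()
    if max_passes is None:
        max_passes = 10 * y.size
    from .emd import find_extrema  # local import avoids a cycle at module load

    for _ in range(max_passes):
        maxima, minima = find_extrema(y)
        ext = np.concatenate([maxima, minima])
        if ext.size == 0:
            return y
        vals = y[ext]
        kill = ext[(np.abs(vals) < lam) & (vals != 0.0)]
        if kill.size == 0:
            return y
        y[kill] = 0.0
    raise RuntimeError("non-terminating peak filter")


def universal_threshold(imf: np.ndarray, n: int | None = None) -> float:
    """Universal threshold ``sigma_hat * sqrt(2 ln N)`` with MAD-based sigma."""
    imf = np.asarray(imf, dtype=float)
    if n is None:
        n = imf.size
    if n < 1:
        raise ValueError("N must be >= 1")
    return noise_std_mad(imf) * math.sqrt(2.0 * math.log(n))


def imf1_noise_energy(imf1: np.ndarray) -> float:
    """Noise-energy estimate of the first IMF: (MAD sigma)^2."""
    return noise_std_mad(imf1) ** 2


def noise_energy(order: int, e1: float) -> float:
    """Modelled noise energy of IMF ``order`` given the IMF1 energy.

    ``E_1`` for order 1; ``(E_1 / 0.719) * 2.01**(-order)`` for order >= 2,
    the standard dyadic decay of white-noise energy across EMD modes.
    """
    if order < 1:
        raise ValueError("order must be >= 1")
    if order == 1:
        return e1
    return (e1 / ENERGY_DECAY_BETA) * ENERGY_DECAY_RHO ** (-order)


def custom_threshold(
    order: int,
    e1: float,
    n: int,
    params: CustomThresholdParams | None = None,
) -> float:
    """Custom per-order threshold ``C * sqrt(E_order * 2 ln N)``."""
    if params is None:
        params = CustomThresholdParams()
    return params.C * math.sqrt(noise_energy(order, e1) * 2.0 * math.log(n))


def hard_threshold(x: np.ndarray, lam: float) -> np.ndarray:
    """Keep values with ``|x| >= lam``, zero the rest."""
    if lam < 0:
        raise ValueError("threshold must be non-negative")
    x = np.asarray(x, dtype=float)
    return np.where(np.abs(x) >= lam, x, 0.0)


def soft_threshold(x: np.ndarray, lam: float) -> np.ndarray:
    """Shrink toward zero: ``sign(x) * (|x| - lam)`` when ``|x| >= lam``.

    sign(0) is taken as +1.
    """
    if lam < 0:
        raise ValueError("threshold must be non-negative")
    x = np.asarray(x, dtype=float)
    sgn = np.where(x >= 0, 1.0, -1.0)
    return np.where(np.abs(x) >= lam, sgn * (np.abs(x) - lam), 0.0)
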