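"""IMF grouping: noisy / clean / low-frequency partition of a decomposition.

High-frequency noise concentrates in the lowest-order IMFs and its energy
decays with order.  The noisy-group boundary K_B is found where the IMF
looks *least* noise-like by two criteria on the per-IMF standard deviation
sigma_k and its MAD-based noise estimate sigma_hat_k: the order maximising
sigma_k / sigma_hat_k and the order maximising sigma_k - sigma_hat_k.
K_B is the ceiling of their mean; IMFs of order <= K_B are the noisy group.

Low-frequency baseline wander lives in IMFs whose average period (samples
per local maximum) exceeds the average R-R period of the ECG; those IMFs
and the residual are discarded from the reconstruction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .emd import Decomposition, Signal, find_extrema

logger = logging.getLogger(__name__)

#: refractory spacing for the fallback R-peak detector (seconds)
R_DETECT_REFRACTORY_S = 0.2


@dataclass
class GroupingResult:
    """Per-IMF statistics and the resulting group labels (orders are 1-based)."""

    K_B: int
    sigma_k: np.ndarray
    sigma_hat_k: np.ndarray
    T_R_bar: float
    T_IMF_bar_k: np.ndarray
    low_freq_indices: frozenset[int]
    N_R: int
    N_max_k: np.ndarray

    def label(self, order: int) -> str:
        """'noisy', 'low-frequency' or 'clean' for a 1-based IMF order."""
        if order <= self.K_B:
            return "noisy"
        if order in self.low_freq_indices:
            return "low-frequency"
        return "clean"

    def to_dict(self) -> dict:
        return {
            "K_B": self.K_B,
            "N_R": self.N_R,
            "T_R_bar": self.T_R_bar,
            "imfs": [
                {
                    "order": k + 1,
                    "sigma": float(self.sigma_k[k]),
                    "sigma_noise": float(self.sigma_hat_k[k]),
                    "average_period": float(self.T_IMF_bar_k[k]),
                    "label": self.label(k + 1),
                }
                for k in range(self.sigma_k.size)
            ],
        }


def imf_std(imf: np.ndarray) -> float:
    """Sample standard deviation (N-1 denominator) about the IMF mean."""
    imf = np.asarray(imf, dtype=float)
    if imf.size < 2:
        raise ValueError("need at least 2 samples for a standard deviation")
    return float(np.std(imf, ddof=1))


def noise_std_mad(imf: np.ndarray) -> float:
    """MAD-based noise sigma estimate: median(|imf - mean|) / 0.6745."""
    imf = np.asarray(imf, dtype=float)
    if imf.size == 0:
        raise ValueError("empty sequence")
    return float(np.median(np.abs(imf - imf.mean())) / 0.6745)


def high_freq_boundary(decomposition: Decomposition) -> int:
    """Boundary order K_B of the high-frequency-noise-predominant IMFs.

    ``K_B = ceil((argmax_k(sigma_k/sigma_hat_k) + argmax_k(sigma_k-sigma_hat_k))/2)``
    with 1-based orders and ties broken toward the smallest order.  IMFs
    whose MAD noise estimate is zero are excluded from the ratio argmax.
    """
    K = decomposition.K
    if K < 1:
        raise ValueError("decomposition has no IMFs")
    sigma = np.array([imf_std(m) for m in decomposition.imfs])
    sigma_hat = np.array([noise_std_mad(m) for m in decomposition.imfs])
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(sigma_hat > 0, sigma / sigma_hat, -np.inf)
    if np.all(np.isneginf(ratio)):
        logger.warning("all MAD noise estimates zero; ratio criterion degenerate")
        k_ratio = 1
    else:
        if np.any(np.isneginf(ratio)):
            logger.info("excluding %d IMFs with zero MAD from ratio argmax",
                        int(np.sum(np.isneginf(ratio))))
        k_ratio = int(np.argmax(ratio)) + 1
    k_diff = int(np.argmax(sigma - sigma_hat)) + 1
    return math.ceil((k_ratio + k_diff) / 2)


def detect_r_peaks(signal: Signal) -> np.ndarray:
    """Crude amplitude-based R detector used when no annotations exist.

    Local maxima above mean + 2 std, with a 0.2 s refractory spacing.
    """
    x = signal.samples
    height = float(x.mean() + 2.0 * x.std())
    distance = max(1, int(round(R_DETECT_REFRACTORY_S * signal.fs)))
    peaks, _ = find_peaks(x, height=height, distance=distance)
    return peaks


def average_r_period(signal: Signal) -> float:
    """Average R-R period in samples: N / N_R.

    Uses the signal's known R peaks when present, else the built-in
    detector.  Raises if no R peak can be found.
    """
    peaks = signal.r_peaks if signal.r_peaks is not None else detect_r_peaks(signal)
    if peaks is None or len(peaks) == 0:
        raise ValueError("cannot establish ECG period: no R peaks")
    return signal.n / len(peaks)


def imf_average_period(imf: np.ndarray) -> float:
    """Average period of an IMF in samples: N / (number of local maxima).

    An IMF with no local maximum (e.g. a near-monotone trend) gets +inf —
    it is trivially low-frequency.
    """
    imf = np.asarray(imf, dtype=float)
    maxima, _ = find_extrema(imf)
    if maxima.size == 0:
        return math.inf
    return imf.size / maxima.size


def low_freq_indices(decomposition: Decomposition, signal: Signal) -> frozenset[int]:
    """1-based orders of IMFs slower than the heartbeat: T_IMF_bar > T_R_bar.

    Strict inequality: an IMF whose average period equals the R-R period is
    kept.  The residual is always discarded alongside (handled by the
    pipeline).
    """
    t_r = average_r_period(signal)
    return frozenset(
        k + 1
        for k, imf in enumerate(decomposition.imfs)
        if imf_average_period(imf) > t_r
    )


def group_imfs(decomposition: Decomposition, signal: Signal) -> GroupingResult:
    """Full grouping of a decomposition against its source signal."""
    K = decomposition.K
    sigma = np.array([imf_std(m) for m in decomposition.imfs])
    sigma_hat = np.array([noise_std_mad(m) for m in decomposition.imfs])
    k_b = high_freq_boundary(decomposition)
    peaks = signal.r_peaks if signal.r_peaks is not None else detect_r_peaks(signal)
    if peaks is None or len(peaks) == 0:
        raise ValueError("cannot establish ECG period: no R peaks")
    n_r = len(peaks)
    t_r = signal.n / n_r
    n_max = np.array([find_extrema(m)[0].size for m in decomposition.imfs])
    periods = np.array(
        [signal.n / c if c > 0 else math.inf for c in n_max]
    )
    low = frozenset(int(k + 1) for k in range(K) if periods[k] > t_r)
    overlap = low & set(range(1, k_b + 1))
    if overlap:
        logger.warning(
            "low-frequency IMF orders %s overlap the noisy group (K_B=%d)",
            sorted(overlap), k_b,
        )
    return GroupingResult(
        K_B=k_b,
        sigma_k=sigma,
        sigma_hat_k=sigma_hat,
        T_R_bar=t_r,
        T_IMF_bar_k=periods,
        low_freq_indices=low,
        N_R=n_r,
        N_max_k=n_max,
    )
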