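"""Empirical mode decomposition and its complementary-noise ensemble variant.

Plain EMD extracts intrinsic mode functions (IMFs) by iteratively
subtracting the mean of cubic-spline envelopes fitted through the local
extrema (sifting).  The integrated ensemble variant (IEMD) wraps the
first-IMF operator ``E_1`` in a CEEMDAN-style staged framework: at stage 1
the input is perturbed by complementary (paired positive/negative) white
Gaussian noise so the ensemble average cancels the perturbation exactly,
and at every later stage the noise *remaining in the ensemble residuals* is
recycled as the assisting noise, instead of decomposing fresh white noise.
This keeps the exact-reconstruction property (the IMFs plus the final
residual sum back to the input to machine precision) while suppressing
residual noise and mode mixing in the individual IMFs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.interpolate import CubicSpline

logger = logging.getLogger(__name__)

#: default sifting-stop tolerance (Cauchy criterion on successive siftings)
DEFAULT_SIFT_TOL = 0.2
#: default cap on sifting iterations per IMF
DEFAULT_MAX_SIFTINGS = 10
#: safety cap on the number of extracted IMFs
MAX_IMFS = 32


class NotSiftableError(ValueError):
    """Raised when a sequence lacks the extrema needed to extract an IMF."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class Signal:
    """A sampled single-channel trace.

    Parameters
    ----------
    samples
        Amplitude values (mV or arbitrary units).
    fs
        Sampling rate in Hz, > 0.
    r_peaks
        Optional strictly increasing sample indices of known R peaks.
    """

    samples: np.ndarray
    fs: float
    r_peaks: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise ValueError("signal must be 1-D with at least 2 samples")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")
        if self.r_peaks is not None:
            self.r_peaks = np.asarray(self.r_peaks, dtype=int)
            if self.r_peaks.size and (
                np.any(np.diff(self.r_peaks) <= 0)
                or self.r_peaks[0] < 0
                or self.r_peaks[-1] >= self.samples.size
            ):
                raise ValueError("r_peaks must be strictly increasing and in range")

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        return self.n / self.fs


@dataclass
class Decomposition:
    """Ordered IMFs plus a residual; sums back to the decomposed input."""

    imfs: np.ndarray        # shape (K, N); K may be 0
    residual: np.ndarray    # shape (N,)

    def __post_init__(self) -> None:
        self.imfs = np.atleast_2d(np.asarray(self.imfs, dtype=float))
        self.residual = np.asarray(self.residual, dtype=float)
        if self.imfs.size == 0:
            self.imfs = self.imfs.reshape(0, self.residual.size)
        if self.imfs.shape[1] != self.residual.size:
            raise ValueError("IMFs and residual must share the sample count")

    @property
    def K(self) -> int:
        return self.imfs.shape[0]

    @property
    def n(self) -> int:
        return self.residual.size

    def reconstruct(self) -> np.ndarray:
        """Sum of all IMFs and the residual."""
        return self.imfs.sum(axis=0) + self.residual


@dataclass
class EnsembleConfig:
    """Knobs of the ensemble decomposition.

    epsilon scales the stage-1 assisting noise as a multiple of the input
    standard deviation.  ensemble_size must be even: noise realisations are
    added in complementary +/- pairs so their ensemble mean is exactly zero.
    """

    ensemble_size: int = 40
    epsilon: float = 0.2
    seed: int | None = None
    max_siftings: int = DEFAULT_MAX_SIFTINGS
    sift_tol: float = DEFAULT_SIFT_TOL

    def __post_init__(self) -> None:
        if self.ensemble_size < 2 or self.ensemble_size % 2 != 0:
            raise ValueError("ensemble_size must be even and >= 2")
        if not self.epsilon > 0:
            raise ValueError("epsilon must be positive")


# ---------------------------------------------------------------------------
# extrema and sifting
# ---------------------------------------------------------------------------

def find_extrema(samples: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    """Interior local maxima and minima of a sequence.

    Strict neighbour comparison; on a flat plateau the first index counts
    as the extremum.  Endpoints are never returned.  Returns
    ``(maxima_indices, minima_indices)`` as int arrays.
    """
    x = np.asarray(samples, dtype=float)
    if x.size == 0:
        raise ValueError("empty signal")
    if x.size < 3:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)

    s = np.sign(np.diff(x))
    # plateau rule: a zero slope takes the sign of the next nonzero slope,
    # so the first sample of a plateau is the turning point
    nz = s != 0
    if not nz.any():
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    idx = np.where(nz, np.arange(s.size), s.size)
    nxt = np.minimum.accumulate(idx[::-1])[::-1]
    filled = np.where(nxt < s.size, s[np.minimum(nxt, s.size - 1)], 0.0)
    turn = filled[:-1] * filled[1:]
    cand = np.where((turn < 0) & (s[:-1] != 0))[0] + 1
    maxima = cand[s[cand - 1] > 0]
    minima = cand[s[cand - 1] < 0]
    return maxima, minima


def _envelope(x: np.ndarray, idx: np.ndarray, val: np.ndarray) -> np.ndarray:
    """Cubic-spline envelope through extrema, mirror-extended at the ends.

    Two extrema are reflected across each signal endpoint to curb spline
    end swings.
    """
    n = x.size
    k = min(2, idx.size)
    left_i = -idx[:k][::-1]
    left_v = val[:k][::-1]
    right_i = 2 * (n - 1) - idx[-k:][::-1]
    right_v = val[-k:][::-1]
    xi = np.concatenate([left_i, idx, right_i])
    vi = np.concatenate([left_v, val, right_v])
    # reflection can duplicate knots when an extremum sits on an endpoint
    xi, keep = np.unique(xi, return_index=True)
    vi = vi[keep]
    if xi.size < 2:
        return np.full(n, vi[0] if vi.size else 0.0)
    if xi.size < 4:
        return np.interp(np.arange(n), xi, vi)
    return CubicSpline(xi, vi)(np.arange(n))


def is_siftable(samples: np.ndarray) -> bool:
    """True when the sequence has at least 2 maxima and 2 minima."""
    try:
        maxima, minima = find_extrema(samples)
    except ValueError:
        return False
    return maxima.size >= 2 and minima.size >= 2


def sift_imf(
    samples: Sequence[float],
    max_siftings: int = DEFAULT_MAX_SIFTINGS,
    sift_tol: float = DEFAULT_SIFT_TOL,
) -> tuple[np.ndarray, np.ndarray]:
    """Extract the first IMF of a sequence (the ``E_1`` operator).

    Iterates envelope-mean subtraction until the Cauchy criterion
    ``sum((h_prev - h)**2) / sum(h_prev**2) < sift_tol`` or the iteration
    cap is hit.  Returns ``(imf, residual_after)`` with
    ``imf + residual_after == samples`` exactly.

    Raises
    ------
    NotSiftableError
        If the input has fewer than 2 maxima or 2 minima.
    """
    x = np.asarray(samples, dtype=float)
    maxima, minima = find_extrema(x)
    if maxima.size < 2 or minima.size < 2:
        raise NotSiftableError("monotone/residual: too few extrema to sift")

    h = x.copy()
    for _ in range(max_siftings):
        upper = _envelope(h, maxima, h[maxima])
        lower = _envelope(h, minima, h[minima])
        mean_env = 0.5 * (upper + lower)
        h_new = h - mean_env
        denom = float(np.sum(h * h))
        sd = float(np.sum((h - h_new) ** 2)) / denom if denom > 0 else 0.0
        h = h_new
        maxima, minima = find_extrema(h)
        if sd < sift_tol or maxima.size < 2 or minima.size < 2:
            break
    return h, x - h


def emd(
    signal: Signal | Sequence[float],
    max_siftings: int = DEFAULT_MAX_SIFTINGS,
    sift_tol: float = DEFAULT_SIFT_TOL,
) -> Decomposition:
    """Plain EMD: repeatedly sift the running residual.

    Stops when the residual has at most one interior extremum (or too few
    extrema to fit envelopes).  A monotone input yields K = 0 with the
    input as residual.
    """
    x = signal.samples if isinstance(signal, Signal) else np.asarray(signal, float)
    imfs: list[np.ndarray] = []
    residual = x.copy()
    while len(imfs) < MAX_IMFS and is_siftable(residual):
        imf, residual = sift_imf(residual, max_siftings, sift_tol)
        imfs.append(imf)
        maxima, minima = find_extrema(residual)
        if maxima.size + minima.size <= 1:
            break
    stack = np.array(imfs) if imfs else np.empty((0, x.size))
    return Decomposition(imfs=stack, residual=residual)


# ---------------------------------------------------------------------------
# ensemble decomposition
# ---------------------------------------------------------------------------

def generate_noise_pairs(
    config: EnsembleConfig, n: int, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Complementary standard-normal assisting noises, shape (I, N).

    Rows come in +/- pairs (w1, -w1, w2, -w2, ...) so they sum to exactly
    zero elementwise.
    """
    if config.ensemble_size % 2 != 0:
        raise ValueError("ensemble size must be even")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    half = rng.standard_normal((config.ensemble_size // 2, n))
    out = np.empty((config.ensemble_size, n))
    out[0::2] = half
    out[1::2] = -half
    return out


def _e1(member: np.ndarray, config: EnsembleConfig) -> np.ndarray:
    """First-IMF extraction for one ensemble member.

    An unsiftable member contributes a zero IMF (its residual is then the
    member itself), preserving the reconstruction identity of the stage.
    """
    try:
        imf, _ = sift_imf(member, config.max_siftings, config.sift_tol)
    except NotSiftableError:
        logger.debug("unsiftable ensemble member; contributing zero IMF")
        return np.zeros_like(member)
    return imf


def iemd(signal: Signal | Sequence[float], config: EnsembleConfig | None = None) -> Decomposition:
    """Integrated ensemble EMD with residual-noise reuse.

    Stage 1 decomposes ``x + epsilon*std(x)*noise_i`` for the I
    complementary noises and averages the first IMFs; the noise left in
    each member's residual (member residual minus the ensemble-mean
    residual) becomes that member's assisting noise for the next stage, at
    unit gain.  Stages repeat until the running residual has at most one
    interior extremum.  Reconstruction is exact by construction.
    """
    if config is None:
        config = EnsembleConfig()
    x = signal.samples if isinstance(signal, Signal) else np.asarray(signal, float)
    n = x.size
    rng = np.random.default_rng(config.seed)
    noises = generate_noise_pairs(config, n, rng)

    scale = config.epsilon * float(np.std(x))
    members = x[None, :] + scale * noises

    imfs: list[np.ndarray] = []
    e1s = np.array([_e1(m, config) for m in members])
    if not np.any(e1s):
        # input itself carries no oscillation to extract
        return Decomposition(imfs=np.empty((0, n)), residual=x.copy())
    imf_k = e1s.mean(axis=0)
    imfs.append(imf_k)
    residual = x - imf_k                       # running residual of the signal
    member_res = members - e1s                 # per-member ensemble residuals
    delta = member_res - member_res.mean(axis=0)  # noise left in each residual

    while len(imfs) < MAX_IMFS:
        maxima, minima = find_extrema(residual)
        if maxima.size + minima.size <= 1 or not is_siftable(residual):
            break
        members = residual[None, :] + delta
        e1s = np.array([_e1(m, config) for m in members])
        imf_k = e1s.mean(axis=0)
        if not np.any(imf_k):
            break
        imfs.append(imf_k)
        residual = residual - imf_k
        member_res = members - e1s
        delta = member_res - member_res.mean(axis=0)

    return Decomposition(imfs=np.array(imfs), residual=residual)
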