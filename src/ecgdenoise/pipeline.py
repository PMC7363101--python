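"""End-to-end ECG denoising pipelines.

The flagship pipeline (``iemd-atd``) decomposes with the complementary-
noise ensemble EMD, groups the IMFs, denoises each high-frequency IMF with
the adaptive 3-sigma threshold plus peak filtering, and reconstructs from
the denoised and clean IMFs while discarding the low-frequency IMFs and
the residual as baseline wander.

Four baselines share the decomposition/grouping/reconstruction structure
but use plain EMD and classical thresholds: universal or custom per-order
thresholds applied through the hard or soft threshold function
(``ut-h``, ``ut-s``, ``cust-h``, ``cust-s``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .emd import Decomposition, EnsembleConfig, Signal, emd, iemd
from .grouping import GroupingResult, group_imfs
from .thresholding import (
    CustomThresholdParams,
    adaptive_threshold,
    custom_threshold,
    hard_threshold,
    imf1_noise_energy,
    peak_filter,
    soft_threshold,
    universal_threshold,
)

logger = logging.getLogger(__name__)

METHODS = ("iemd-atd", "ut-h", "ut-s", "cust-h", "cust-s")


@dataclass
class DenoiseResult:
    """Outcome of one denoising run.

    The accounting identity
    ``input == denoised + baseline_wander + sum_over_noisy_imfs(imf - denoised_imf)``
    holds to machine precision for every method.
    """

    denoised: Signal
    method: str
    decomposition: Decomposition
    grouping: GroupingResult | None
    thresholds: dict[int, float]          # 1-based noisy-IMF order -> lambda
    baseline_wander: Signal

    @property
    def removed_noise(self) -> np.ndarray:
        """Total noise subtracted from the noisy IMFs."""
        total = np.zeros(self.denoised.n)
        for order, den in self._denoised_imfs.items():
            total += self.decomposition.imfs[order - 1] - den
        return total

    # populated by the pipeline; keyed by 1-based order
    _denoised_imfs: dict[int, np.ndarray] = field(default_factory=dict, repr=False)


def _reconstruct(
    decomp: Decomposition,
    grouping: GroupingResult | None,
    denoised_imfs: dict[int, np.ndarray],
    keep_low_freq: bool,
) -> tuple[np.ndarray, np.ndarray]:
    """Sum denoised noisy IMFs + clean IMFs; route slow IMFs + residual to
    the baseline estimate (or keep them when ``keep_low_freq``)."""
    n = decomp.n
    out = np.zeros(n)
    baseline = np.zeros(n)
    low = grouping.low_freq_indices if grouping is not None else frozenset()
    k_b = grouping.K_B if grouping is not None else 0
    for order in range(1, decomp.K + 1):
        if order in denoised_imfs:
            out += denoised_imfs[order]
        elif order > k_b and order in low and not keep_low_freq:
            baseline += decomp.imfs[order - 1]
        else:
            out += decomp.imfs[order - 1]
    if keep_low_freq:
        out += decomp.residual
    else:
        baseline += decomp.residual
    return out, baseline


def _denoise(
    signal: Signal,
    method: str,
    decomposition: Decomposition,
    keep_low_freq: bool,
    custom_params: CustomThresholdParams | None,
) -> DenoiseResult:
    try:
        grouping = group_imfs(decomposition, signal)
        k_b = grouping.K_B
    except ValueError as exc:
        logger.warning("grouping failed (%s); denoising IMF1 only, baseline kept", exc)
        grouping = None
        k_b = 1 if decomposition.K >= 1 else 0
        keep_low_freq = True

    thresholds: dict[int, float] = {}
    denoised_imfs: dict[int, np.ndarray] = {}
    e1 = imf1_noise_energy(decomposition.imfs[0]) if decomposition.K else 0.0
    for order in range(1, k_b + 1):
        imf = decomposition.imfs[order - 1]
        if method == "iemd-atd":
            lam = adaptive_threshold(imf).lam
            denoised_imfs[order] = peak_filter(imf, lam)
        else:
            if method.startswith("ut"):
                lam = universal_threshold(imf, signal.n)
            else:
                lam = custom_threshold(order, e1, signal.n, custom_params)
            fn = hard_threshold if method.endswith("-h") else soft_threshold
            denoised_imfs[order] = fn(imf, lam)
        thresholds[order] = lam

    out, baseline = _reconstruct(decomposition, grouping, denoised_imfs, keep_low_freq)
    result = DenoiseResult(
        denoised=Signal(out, signal.fs, r_peaks=None),
        method=method,
        decomposition=decomposition,
        grouping=grouping,
        thresholds=thresholds,
        baseline_wander=Signal(baseline, signal.fs),
    )
    result._denoised_imfs = denoised_imfs
    return result


def denoise_iemd_atd(
    signal: Signal,
    config: EnsembleConfig | None = None,
    keep_low_freq: bool = False,
    decomposition: Decomposition | None = None,
) -> DenoiseResult:
    """Full adaptive-threshold denoiser on an ensemble decomposition.

    ``keep_low_freq`` skips the baseline-wander discard (high-frequency
    denoising only).  A precomputed ``decomposition`` of the same signal
    may be passed to amortise the ensemble decomposition across variants.
    """
    if decomposition is None:
        decomposition = iemd(signal, config or EnsembleConfig())
    return _denoise(signal, "iemd-atd", decomposition, keep_low_freq, None)


def denoise_baseline(
    signal: Signal,
    method: str,
    keep_low_freq: bool = False,
    custom_params: CustomThresholdParams | None = None,
    decomposition: Decomposition | None = None,
) -> DenoiseResult:
    """Classical-threshold pipelines on a plain EMD decomposition.

    ``method`` is one of ``ut-h``, ``ut-s`` (universal threshold, hard or
    soft) or ``cust-h``, ``cust-s`` (custom per-order threshold).  Grouping
    and baseline-wander elimination are identical to the adaptive pipeline
    so the comparison isolates the thresholding stage.
    """
    if method not in ("ut-h", "ut-s", "cust-h", "cust-s"):
        raise ValueError(f"unknown baseline method {method!r}")
    if decomposition is None:
        decomposition = emd(signal)
    return _denoise(signal, method, decomposition, keep_low_freq, custom_params)


def denoise(signal: Signal, method: str = "iemd-atd", **kwargs) -> DenoiseResult:
    """Dispatch to the adaptive or a baseline pipeline by method label."""
    if method == "iemd-atd":
        return denoise_iemd_atd(signal, **kwargs)
    return denoise_baseline(signal, method, **kwargs)


def extract_baseline(signal: Signal, config: EnsembleConfig | None = None) -> Signal:
    """Estimated baseline wander: slow IMFs plus the decomposition residual."""
    return denoise_iemd_atd(signal, config).baseline_wander
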