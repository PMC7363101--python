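"""IMF statistics, the noisy-group boundary and the slow-IMF discard rule."""

import math

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter1d

from ecgdenoise import (
    Decomposition,
    Signal,
    average_r_period,
    group_imfs,
    high_freq_boundary,
    imf_average_period,
    imf_std,
    low_freq_indices,
    noise_std_mad,
)
from ecgdenoise.grouping import detect_r_peaks

FS = 360.0


def literal_boundary(imfs: np.ndarray) -> int:
    """Independent direct transcription of the boundary formula."""
    sigmas = [np.std(m, ddof=1) for m in imfs]
    mads = [np.median(np.abs(m - np.mean(m))) / 0.6745 for m in imfs]
    ratios = [s / h if h > 0 else -np.inf for s, h in zip(sigmas, mads)]
    k1 = int(np.argmax(ratios)) + 1
    k2 = int(np.argmax([s - h for s, h in zip(sigmas, mads)])) + 1
    return math.ceil((k1 + k2) / 2)


class TestImfStd:
    def test_constant_is_zero(self):
        assert imf_std(np.full(10, 3.5)) == 0.0

    def test_two_point_sample_std(self):
        assert imf_std(np.array([-1.0, 1.0])) == pytest.approx(math.sqrt(2))

    def test_consistent_for_gaussian(self):
        x = np.random.default_rng(0).normal(0, 3, 100_000)
        assert imf_std(x) == pytest.approx(3.0, rel=0.02)

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            imf_std(np.array([1.0]))


class TestNoiseStdMad:
    def test_constant_is_zero(self):
        assert noise_std_mad(np.full(8, 2.0)) == 0.0

    def test_alternating_unit(self):
        x = np.tile([-1.0, 1.0], 50)
        assert noise_std_mad(x) == pytest.approx(1 / 0.6745)

    def test_consistent_for_gaussian(self):
        x = np.random.default_rng(1).normal(0, 2, 10_000)
        assert noise_std_mad(x) == pytest.approx(2.0, rel=0.05)


class TestHighFreqBoundary:
    @staticmethod
    def _spiky(rng, n, n_peaks):
        s = np.zeros(n)
        s[rng.integers(0, n, n_peaks)] = rng.uniform(0.5, 1.5, n_peaks)
        return gaussian_filter1d(s, 15)

    def test_matches_literal_recomputation(self, rng):
        n = 3600
        imfs = np.array(
            [rng.standard_normal(n), 0.5 * rng.standard_normal(n)]
            + [self._spiky(rng, n, 12) for _ in range(3)]
        )
        d = Decomposition(imfs=imfs, residual=np.zeros(n))
        assert high_freq_boundary(d) == literal_boundary(imfs)

    def test_ceiling_rule_on_constructed_stats(self, rng):
        # noise then strongly spiky IMFs put both argmaxes on a known order
        n = 3600
        noise = rng.standard_normal(n)
        spike = self._spiky(rng, n, 10) * 50
        d = Decomposition(imfs=np.array([noise, spike, 0.01 * rng.standard_normal(n)]),
                          residual=np.zeros(n))
        # spike dominates both criteria -> both argmaxes at 2 -> K_B = 2
        assert high_freq_boundary(d) == 2

    def test_lands_at_or_after_last_noise_imf(self):
        n = 3600
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            imfs = np.array(
                [rng.standard_normal(n), 0.5 * rng.standard_normal(n)]
                + [self._spiky(rng, n, k) for k in (12, 8, 5)]
            )
            d = Decomposition(imfs=imfs, residual=np.zeros(n))
            if high_freq_boundary(d) >= 2:
                hits += 1
        assert hits >= 45


class TestPeriods:
    def test_average_r_period_is_ratio(self):
        sig = Signal(np.zeros(3600) + np.sin(np.arange(3600)), FS,
                     r_peaks=np.linspace(0, 3599, 12, dtype=int))
        assert average_r_period(sig) == 3600 / 12

    def test_single_r_peak(self):
        sig = Signal(np.sin(np.arange(3600)), FS, r_peaks=np.array([100]))
        assert average_r_period(sig) == 3600.0

    def test_synthetic_ecg_beat_count(self, ecg):
        assert average_r_period(ecg) == pytest.approx(300, abs=30)

    def test_detector_fallback_on_ecg(self, ecg):
        bare = Signal(ecg.samples, ecg.fs)
        peaks = detect_r_peaks(bare)
        assert abs(len(peaks) - len(ecg.r_peaks)) <= 1

    def test_sinusoid_period(self):
        t = np.arange(0, 10, 1 / FS)
        assert imf_average_period(np.sin(2 * np.pi * 2 * t)) == pytest.approx(180.0)

    def test_monotone_period_is_infinite(self):
        assert imf_average_period(np.linspace(0, 1, 100)) == math.inf


class TestLowFreqIndices:
    def _ecg_decomp(self, ecg, extra=None):
        t = np.arange(ecg.n) / ecg.fs
        imfs = [np.sin(2 * np.pi * f * t) for f in (40.0, 10.0)]
        if extra is not None:
            imfs.append(extra)
        return Decomposition(imfs=np.array(imfs), residual=np.zeros(ecg.n))

    def test_all_fast_imfs_keep_everything(self, ecg):
        d = self._ecg_decomp(ecg)
        assert low_freq_indices(d, ecg) == frozenset()

    def test_slow_drift_is_flagged(self, ecg):
        t = np.arange(ecg.n) / ecg.fs
        drift = np.sin(2 * np.pi * 0.05 * t)  # period 7200 > ~300 samples
        d = self._ecg_decomp(ecg, extra=drift)
        assert 3 in low_freq_indices(d, ecg)

    def test_exact_period_tie_is_kept(self):
        # IMF period exactly equals the R-R period: strict > keeps it
        n = 3600
        sig = Signal(np.sin(np.arange(n)), FS, r_peaks=np.arange(12) * 300 + 10)
        t = np.arange(n)
        imf = np.sin(2 * np.pi * t / 300)  # 12 maxima -> period 300 == T_R
        d = Decomposition(imfs=imf[None, :], residual=np.zeros(n))
        assert low_freq_indices(d, sig) == frozenset()

    def test_amplitude_scaling_invariance(self, ecg, small_ensemble):
        from ecgdenoise import iemd

        d = iemd(ecg, small_ensemble)
        scaled = Decomposition(imfs=7.3 * d.imfs, residual=7.3 * d.residual)
        assert low_freq_indices(d, ecg) == low_freq_indices(scaled, ecg)


class TestGroupImfs:
    def test_equivalence_with_literal_formulas(self, ecg, small_ensemble, rng):
        from ecgdenoise import iemd

        noisy = Signal(ecg.samples + 0.2 * rng.standard_normal(ecg.n),
                       ecg.fs, r_peaks=ecg.r_peaks)
        d = iemd(noisy, small_ensemble)
        g = group_imfs(d, noisy)
        # literal recomputation of every statistic
        assert g.K_B == literal_boundary(d.imfs)
        assert g.T_R_bar == noisy.n / len(noisy.r_peaks)
        for k, imf in enumerate(d.imfs):
            assert g.sigma_k[k] == pytest.approx(np.std(imf, ddof=1))
            assert g.sigma_hat_k[k] == pytest.approx(
                np.median(np.abs(imf - imf.mean())) / 0.6745
            )
            n_max = sum(
                1 for i in range(1, len(imf) - 1)
                if imf[i] > imf[i - 1] and imf[i] > imf[i + 1]
            )
            if n_max:
                assert g.T_IMF_bar_k[k] == pytest.approx(noisy.n / n_max)
        expected_low = frozenset(
            k + 1 for k in range(d.K) if g.T_IMF_bar_k[k] > g.T_R_bar
        )
        assert g.low_freq_indices == expected_low

    def test_no_r_peaks_raises(self):
        flat = Signal(0.01 * np.sin(np.arange(3600) * 0.5), FS)
        with pytest.raises(ValueError, match="period"):
            average_r_period(flat)
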