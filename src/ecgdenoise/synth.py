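"""Synthetic ECGs and noise sources for controlled denoising experiments.

The ECG generator follows the phase-domain Gaussian-sum convention of the
McSharry dynamical model: a cardiac phase advances through 2*pi per beat
(with per-beat R-R jitter) and the waveform is a sum of five Gaussian
bumps — P, Q, R, S, T — placed at fixed phases.  Ground-truth R-peak
sample indices are recorded, which downstream grouping uses directly.

Five noise classes are provided: white noise (WN), baseline wander (BW,
sub-0.5 Hz sinusoids plus a slow random walk), electromyographic noise
(EMG, 20-120 Hz band-passed Gaussian noise), electrode contact noise (ECN,
sparse exponentially decaying step transients) and hybrid noise (HN, the
elementwise sum of the other four at unit variance each).  These emulate
the qualitative character of the MIT-BIH noise-stress records; they are
synthetic stand-ins, not reproductions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, filtfilt

from .emd import Signal

#: default five-wave parameters: phase (rad), amplitude (mV), width (rad)
DEFAULT_WAVES: dict[str, tuple[float, float, float]] = {
    "P": (-math.pi / 3, 0.12, 0.25),
    "Q": (-math.pi / 12, -0.10, 0.10),
    "R": (0.0, 1.20, 0.10),
    "S": (math.pi / 12, -0.25, 0.10),
    "T": (math.pi / 2, 0.35, 0.40),
}

NOISE_KINDS = ("WN", "BW", "EMG", "ECN", "HN")
# stable per-kind spawn keys so HN can regenerate its four parts bit-exactly
_KIND_KEY = {"WN": 0, "BW": 1, "EMG": 2, "ECN": 3}


@dataclass
class SynthConfig:
    """Parameters of one synthetic ECG."""

    fs: float = 360.0
    duration: float = 10.0
    heart_rate: float = 72.0
    rr_jitter: float = 0.05
    wave_params: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_WAVES)
    )
    seed: int | None = None

    def __post_init__(self) -> None:
        n = self.fs * self.duration
        if abs(n - round(n)) > 1e-9 or n < 2:
            raise ValueError("fs * duration must be an integer sample count >= 2")
        if not self.heart_rate > 0:
            raise ValueError("heart rate must be positive")
        if any(w[2] <= 0 for w in self.wave_params.values()):
            raise ValueError("wave widths must be positive")

    @property
    def n(self) -> int:
        return int(round(self.fs * self.duration))


def synth_ecg(config: SynthConfig | None = None) -> Signal:
    """Generate one synthetic ECG with ground-truth R peaks.

    The cardiac phase is piecewise linear across beats whose lengths are
    ``60/HR * (1 + rr_jitter * N(0,1))`` seconds (clipped to 30% of the
    nominal beat at minimum); within each beat the waveform is the Gaussian
    sum over the five waves with phase differences wrapped to (-pi, pi].
    """
    if config is None:
        config = SynthConfig()
    rng = np.random.default_rng(config.seed)
    n = config.n
    rr_nominal = 60.0 / config.heart_rate

    # draw beats until they cover the record (phase starts at -pi so the
    # first R falls mid-way through the first beat)
    rr: list[float] = []
    total = 0.0
    while total < config.duration + rr_nominal:
        beat = rr_nominal * (1.0 + config.rr_jitter * rng.standard_normal())
        beat = max(beat, 0.3 * rr_nominal)
        rr.append(beat)
        total += beat
    rr_arr = np.asarray(rr)
    starts = np.concatenate([[0.0], np.cumsum(rr_arr)])  # beat start times

    t = np.arange(n) / config.fs
    beat_idx = np.clip(np.searchsorted(starts, t, side="right") - 1, 0, len(rr) - 1)
    frac = (t - starts[beat_idx]) / rr_arr[beat_idx]
    theta = 2.0 * math.pi * frac - math.pi  # wrapped phase in [-pi, pi)

    z = np.zeros(n)
    for phase, amp, width in config.wave_params.values():
        d = np.mod(theta - phase + math.pi, 2.0 * math.pi) - math.pi
        z += amp * np.exp(-(d**2) / (2.0 * width**2))

    # AC-couple: recorded ECGs sit on a zero isoelectric line, so the
    # clean reference carries no DC for the baseline-discard stage to eat
    z -= z.mean()

    # R (phase 0) occurs at the midpoint of each beat
    r_times = starts[:-1] + rr_arr / 2.0
    r_idx = np.round(r_times * config.fs).astype(int)
    r_idx = r_idx[(r_idx >= 0) & (r_idx < n)]
    return Signal(samples=z, fs=config.fs, r_peaks=r_idx)


# ---------------------------------------------------------------------------
# noise generators
# ---------------------------------------------------------------------------

def _unit_std(x: np.ndarray) -> np.ndarray:
    s = x.std()
    return x / s if s > 0 else x


def _rng_for(kind: str, seed: int | None) -> np.random.Generator:
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(_KIND_KEY[kind],))
    return np.random.default_rng(ss)


def _gen_wn(n: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    return rng.standard_normal(n)


def _gen_bw(n: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    t = np.arange(n) / fs
    out = np.zeros(n)
    for _ in range(3):
        f = rng.uniform(0.05, 0.45)
        out += rng.uniform(0.5, 1.0) * np.sin(2 * math.pi * f * t + rng.uniform(0, 2 * math.pi))
    walk = np.cumsum(rng.standard_normal(n))
    out += _unit_std(walk - walk.mean())
    return _unit_std(out)


def _gen_emg(n: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    hi = min(120.0, 0.45 * fs)
    b, a = butter(4, [20.0 / (fs / 2), hi / (fs / 2)], btype="band")
    return _unit_std(filtfilt(b, a, rng.standard_normal(n)))


def _gen_ecn(n: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    out = np.zeros(n)
    n_events = max(1, rng.poisson(1.0 * n / fs))  # ~1 transient per second
    for _ in range(n_events):
        i0 = rng.integers(0, n)
        amp = rng.standard_normal()
        tau = rng.uniform(0.04, 0.2) * fs  # decay constant in samples
        k = np.arange(n - i0)
        out[i0:] += amp * np.exp(-k / tau)
    return _unit_std(out)


_GEN = {"WN": _gen_wn, "BW": _gen_bw, "EMG": _gen_emg, "ECN": _gen_ecn}


def gen_noise(kind: str, n: int, fs: float = 360.0, seed: int | None = None) -> np.ndarray:
    """One realisation of a named noise class, length ``n``.

    WN is raw i.i.d. N(0,1); BW/EMG/ECN are normalised to unit sample std.
    HN is the elementwise sum of all four, each generated from a child seed
    derived deterministically from ``seed``, so
    ``gen_noise('HN', ...) == sum(gen_noise(k, ...) for k in WN,BW,EMG,ECN)``
    for the same seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if kind == "HN":
        return sum(gen_noise(k, n, fs, seed) for k in ("WN", "BW", "EMG", "ECN"))
    if kind not in _GEN:
        raise ValueError(f"unknown noise kind {kind!r}; expected one of {NOISE_KINDS}")
    return _GEN[kind](n, fs, _rng_for(kind, seed))


def mix_at_snr(
    clean: np.ndarray, noise: np.ndarray, target_snr_db: float
) -> tuple[np.ndarray, np.ndarray]:
    """Scale ``noise`` so clean+noise sits exactly at the target SNR.

    Returns ``(noisy, scaled_noise)``; the scale is
    ``sqrt(sum s^2 / (sum n^2 * 10**(target/10)))``.
    """
    clean = np.asarray(clean, dtype=float)
    noise = np.asarray(noise, dtype=float)
    p_s = float(np.sum(clean**2))
    p_n = float(np.sum(noise**2))
    if p_s == 0.0 or p_n == 0.0:
        raise ValueError("clean and noise must both have nonzero energy")
    a = math.sqrt(p_s / (p_n * 10.0 ** (target_snr_db / 10.0)))
    scaled = a * noise
    return clean + scaled, scaled


def make_experiment_set(
    n_ecgs: int = 6,
    seed: int | None = None,
    fs: float = 360.0,
    duration: float = 10.0,
) -> list[Signal]:
    """A batch of synthetic ECGs with randomised morphology.

    Heart rate uniform in 55-95 bpm, QRS widths scaled by +-30%, T-wave
    amplitude scaled by +-50% — independent draws per signal, all at the
    given sampling rate and duration.
    """
    master = np.random.SeedSequence(entropy=seed)
    out: list[Signal] = []
    for child in master.spawn(n_ecgs):
        rng = np.random.default_rng(child)
        waves = dict(DEFAULT_WAVES)
        qrs_scale = rng.uniform(0.7, 1.3)
        for w in ("Q", "R", "S"):
            ph, amp, width = waves[w]
            waves[w] = (ph, amp, width * qrs_scale)
        ph, amp, width = waves["T"]
        waves["T"] = (ph, amp * rng.uniform(0.5, 1.5), width)
        cfg = SynthConfig(
            fs=fs,
            duration=duration,
            heart_rate=rng.uniform(55.0, 95.0),
            wave_params=waves,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        out.append(synth_ecg(cfg))
    return out
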