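# ecgdenoise

Denoising of single-channel electrocardiograms by ensemble empirical
mode decomposition with an adaptive 3σ threshold and QRS-preserving peak
filtering — plus the classical EMD threshold denoisers, evaluation
metrics and a synthetic ECG/noise generator, so the whole pipeline can
be exercised and benchmarked without any external data.

Intended for biomedical signal-processing work: cleaning ECG traces
before feature extraction (QRS delineation, interval measurement) where
hard/soft thresholding would clip or fragment the QRS complex.

## Method

A noisy ECG `x(n)` is decomposed into intrinsic mode functions by an
integrated ensemble EMD: stage 1 averages the first IMF of `I`
noise-perturbed copies `x + ε·std(x)·w_i`, where the `w_i` come in
complementary ± pairs (their ensemble mean is exactly zero), and every
later stage reuses the noise left in the ensemble residuals as its
assisting noise. The decomposition is exactly reconstructive:
`x = Σ_k IMF_k + r` to machine precision.

The IMFs are grouped by two boundaries:

* `K_B = ⌈(argmax_k σ_k/σ̂_k + argmax_k (σ_k − σ̂_k)) / 2⌉`, with
  `σ̂_k = median(|IMF_k − mean|)/0.6745` — orders ≤ `K_B` are
  high-frequency-noise predominant;
* IMFs whose average period `N/N_max` exceeds the average R-R period
  `N/N_R` are sub-heart-rate (baseline wander) and are discarded along
  with the residual.

Each noisy IMF gets an adaptive threshold from iterated 3σ (Pauta)
trimming — remove values beyond 3σ of the survivors, recompute, repeat
to a fixpoint; `λ = 3σ_final` — and is denoised by peak filtering:
local extrema below `λ` are zeroed pass after pass until none remain,
so every sample of a wave whose peak clears `λ` survives unaltered.
The output is the sum of denoised and clean IMFs.

Baselines `ut-h`, `ut-s`, `cust-h`, `cust-s` (universal threshold
`σ̂√(2 ln N)` and the per-order custom threshold `C√(E_i·2 ln N)`,
applied hard or soft, on plain EMD) share the grouping and
reconstruction so comparisons isolate the thresholding stage.

See `docs/methods.md` for assumptions, parameter defaults and known
limitations.

## Worked example

```python
import numpy as np
from ecgdenoise import (EnsembleConfig, Signal, SynthConfig, denoise_iemd_atd,
                        evaluate, gen_noise, mix_at_snr, synth_ecg)

ecg = synth_ecg(SynthConfig(seed=42))                   # 10 s @ 360 Hz, 72 bpm
noise = gen_noise("WN", ecg.n, ecg.fs, seed=7)
noisy_samples, _ = mix_at_snr(ecg.samples, noise, 5.0)  # exact 5 dB input SNR
noisy = Signal(noisy_samples, ecg.fs, r_peaks=ecg.r_peaks)

result = denoise_iemd_atd(noisy, EnsembleConfig(ensemble_size=40, seed=7))
report = evaluate(ecg.samples, noisy_samples, result.denoised.samples, "iemd-atd")

print(f"IMFs: {result.decomposition.K}, noisy orders <= K_B = {result.grouping.K_B}, "
      f"discarded slow orders: {sorted(result.grouping.low_freq_indices)}")
print(f"thresholds: {{{', '.join(f'{k}: {v:.3f}' for k, v in result.thresholds.items())}}}")
print(f"SNR {report.snr_in:.2f} -> {report.snr_out:.2f} dB "
      f"(improvement {report.snr_ipv:.2f} dB), C_R = {report.c_r:.4f}, RDE = {report.rde:.3f}")
```

which prints:

```
IMFs: 8, noisy orders <= K_B = 3, discarded slow orders: [7, 8]
thresholds: {1: 0.279, 2: 0.140, 3: 0.088}
SNR 5.00 -> 14.48 dB (improvement 9.48 dB), C_R = 0.9825, RDE = 0.027
```

The decomposition produced 8 IMFs; the first 3 were classified as
noise-predominant and peak-filtered with the per-IMF adaptive thresholds
shown; orders 7–8 (slower than the heartbeat) and the residual were
removed as baseline wander. Denoising raised the SNR by 9.5 dB and the
denoised trace correlates 0.98 with the clean reference; the small
positive RDE means a trace of residual noise rather than signal loss.

The same run from the shell:

```sh
ecgdenoise simulate --ecgs 1 --noise wn --snr 5 --seed 42 --outdir sim/
ecgdenoise denoise --input sim/syn00_noisy.csv --fs 360 --method iemd-atd \
    --seed 7 --out denoised.csv --clean sim/syn00_clean.csv
ecgdenoise evaluate --clean sim/syn00_clean.csv --noisy sim/syn00_noisy.csv \
    --denoised denoised.csv
```

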