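# Methods

## Problem

Recorded electrocardiograms carry broadband instrument and muscle noise,
electrode artefacts and sub-heart-rate baseline wander on top of the
cardiac waveform. `ecgdenoise` removes these while preserving the QRS
complex — the sharp depolarisation spike whose morphology matters for
diagnosis and which classical threshold denoisers clip or fragment.

## Decomposition

Empirical mode decomposition (EMD) expresses a signal `x(n)` as a sum of
intrinsic mode functions (IMFs) plus a residual,
`x = sum_k IMF_k + r`, extracted by sifting: cubic-spline envelopes are
fitted through the local maxima and minima, and the envelope mean is
subtracted until the detail is locally symmetric. Numerical choices (all
configurable):

* **Sifting stop** — Cauchy criterion
  `sum((h_prev - h)^2) / sum(h_prev^2) < 0.2`, capped at 10 iterations
  per IMF; the classical defaults.
* **Envelopes** — cubic splines through the extrema, with the two
  outermost extrema mirror-reflected across each signal endpoint to damp
  end swings.
* **Extrema** — strict neighbour comparison; the first sample of a flat
  plateau counts as the extremum; endpoints are never extrema.
* **Termination** — decomposition stops when the running residual has at
  most one interior extremum (or too few extrema to fit envelopes).

Plain EMD mixes modes when the signal is intermittent. The ensemble
variant (`iemd`) wraps the first-IMF operator `E1` in a staged framework:

1. Stage 1 decomposes `I` perturbed copies `x + eps * std(x) * w_i`,
   where the `w_i` are standard-normal sequences in complementary `+/-`
   pairs (ensemble mean of the perturbations is exactly zero), and
   averages the first IMFs. Defaults `I = 40` (20 pairs), `eps = 0.2`.
2. The noise left in each member's residual (member residual minus the
   ensemble-mean residual) becomes that member's assisting noise for the
   next stage, added at unit gain. No fresh noise is drawn and no noise
   is separately decomposed after stage 1.
3. Stages repeat until the residual is monotone-like.

Because each stage subtracts the averaged IMF from the running residual,
`sum IMF_k + r` equals the input to floating-point round-off for every
seed — asserted at `1e-8 * max(1, |x|_inf)` in the tests. With `I = 2`
and `eps -> 0` the ensemble output converges to plain EMD on inputs with
dense extrema (EMD is discontinuous at smooth signals, so the limit is
checked on rough inputs).

An ensemble member that cannot be sifted contributes a zero IMF and
passes itself through as residual, which keeps the reconstruction
identity intact.

## IMF grouping

IMFs are partitioned into three groups using two boundaries.

**High-frequency boundary `K_B`.** For each IMF, the sample standard
deviation `sigma_k` and a robust noise estimate
`sigma_hat_k = median(|IMF_k - mean|) / 0.6745` are computed.  Orders
maximising `sigma_k / sigma_hat_k` and `sigma_k - sigma_hat_k` mark where
the IMF is least noise-like (ECG content is spiky, so the MAD sits far
below the standard deviation); `K_B` is the ceiling of their mean, with
argmax ties broken toward the smallest order and zero-MAD IMFs excluded
from the ratio. Orders `<= K_B` are treated as noise-predominant and
thresholded. Note the criterion presumes spiky signal IMFs: for a pure
sinusoid `sigma/sigma_hat ~ 0.674`, below the Gaussian-noise value of 1,
so the boundary is only meaningful for ECG-like morphologies.

**Low-frequency discard.** The ECG repeats at the heart rate, so an IMF
whose average period exceeds the average R-R period carries no cardiac
information. With `N_R` R peaks and `N_max` local maxima in an IMF over
`N` samples, the IMF is discarded iff `N / N_max > N / N_R` (strictly —
a period equal to the beat period is kept), together with the residual.
R peaks come from the signal's annotations when present (the synthetic
generator records ground truth), else from a simple amplitude detector
(maxima above mean + 2 std with a 0.2 s refractory period). Both the
set-form rule (discard all IMFs slower than the beat) and a
`keep_low_freq` switch that skips the discard entirely are exposed.

*Known limitation.* On a finite record the count comparison
`N_max < N_R` is biased by edge truncation: a beat-rate component (a
T-wave train) generically shows `N_R - 1` interior maxima, so the discard
can remove genuine T-wave energy for some morphologies. This depresses
the measured SNR improvement mainly at high input SNR, where residual
noise is small relative to the discarded signal energy; the
high-frequency-only variant (`keep_low_freq=True`) is unaffected.
Interval-based period estimators (mean spacing of events) were evaluated
and behave worse — they estimate a stricter beat period — so the
count-ratio form is kept.

## Adaptive threshold and peak filtering

For each noise-predominant IMF a threshold is found by iterative
3-sigma (Pauta-criterion) trimming: center the values about their mean,
compute the sample standard deviation (N-1 denominator), remove values
whose centered magnitude strictly exceeds `3 sigma`, and repeat on the
survivors (mean recomputed each pass; removed values never return) until
a pass removes nothing. The surviving values approximate the pure noise
floor and the threshold is `lambda = 3 sigma_final`. The removal is
two-tailed (`|d| > 3 sigma`): one-tailed trimming would contradict the
symmetric noise model. The trace of sigmas is non-increasing and the
loop terminates because the survivor count strictly decreases.

Denoising then uses **peak filtering** instead of a threshold function:
local extrema whose magnitude is strictly below `lambda` are zeroed;
zeroing exposes new, smaller extrema, and passes repeat until a fixpoint.
Every output sample is either zero or its original value, so a wave whose
peak clears the threshold keeps *all* of its samples — including
sub-threshold flanks — where hard thresholding punches holes and soft
thresholding shrinks amplitudes. The operator is idempotent and its
support shrinks monotonically with `lambda`. Magnitudes exactly equal to
`lambda` are retained, mirroring the `>=` convention of the hard
threshold.

## Baseline methods

Four classical pipelines are provided for comparison, differing only in
the thresholding stage (decomposition is plain EMD; grouping and
baseline-wander elimination are identical, so the comparison isolates
the denoising operator):

* universal threshold `lambda_i = sigma_hat_i * sqrt(2 ln N)` (UT);
* custom per-order threshold `lambda_i = C * sqrt(E_i * 2 ln N)` with
  `E_1 = sigma_hat_1^2`, `E_i = (E_1 / 0.719) * 2.01^(-i)` for `i >= 2`
  (the dyadic decay of white-noise energy across EMD modes), `C = 0.5`;

each applied through the hard (`x` kept iff `|x| >= lambda`) or soft
(`sign(x) * (|x| - lambda)`, with `sign(0) = +1`) threshold function —
methods `ut-h`, `ut-s`, `cust-h`, `cust-s`.

## Metrics

With clean `s`, noisy `x = s + n` and denoised `x_d`:
`SNR = 10 log10(sum s^2 / sum n^2)` dB (output noise is `x_d - s`);
SNR improvement is output minus input SNR; `C_R` is the Pearson
correlation of `x_d` and `s`; `RDE = (sum x_d^2 - sum s^2) / sum s^2`
(positive: residual noise; negative: information loss).

## Synthetic data

The generator stands in for FECGSYN-style simulated records and the
MIT-BIH noise-stress records; it emulates their statistical character,
not their exact waveforms.

**ECG.** A cardiac phase advances 2*pi per beat, with per-beat R-R
intervals `60/HR * (1 + 0.05 * N(0,1))` s (5% jitter, a realistic
resting heart-rate variability), and the waveform is a sum of five
Gaussian bumps at fixed phases — the phase-domain convention of the
McSharry dynamical model:

| wave | phase (rad) | amplitude (mV) | width (rad) |
|------|-------------|----------------|-------------|
| P    | -pi/3       |  0.12          | 0.25        |
| Q    | -pi/12      | -0.10          | 0.10        |
| R    | 0           |  1.20          | 0.10        |
| S    | pi/12       | -0.25          | 0.10        |
| T    | pi/2        |  0.35          | 0.40        |

Defaults: 360 Hz, 10 s, 72 bpm. The output is mean-subtracted
(AC-coupled): recorded ECGs sit on a zero isoelectric line, and a clean
reference with a DC pedestal would charge the baseline-discard stage for
energy no real reference contains. Ground-truth R-peak indices (beat
midpoints) are attached to the signal. The experiment batch randomises
heart rate (uniform 55-95 bpm), QRS width (+-30%) and T amplitude
(+-50%). Not emulated: respiratory RR modulation, ectopic beats,
multi-channel leads, amplitude drift within a record — so passing tests
demonstrate behaviour under idealised quasi-periodic morphology, not
clinical variability.

**Noise.** Five classes at 360 Hz: `WN` i.i.d. standard normal; `BW`
three random sinusoids below 0.5 Hz plus a slow random walk, unit
variance; `EMG` Gaussian noise band-passed to 20-120 Hz (4th-order
Butterworth, forward-backward); `ECN` sparse exponential-decay step
transients (~1 event/s, decay 40-200 ms); `HN` the elementwise sum of
the other four, each at unit variance, generated from deterministic
child seeds so the sum identity is exact. Mixtures are scaled to an
exact target SNR by `a = sqrt(sum s^2 / (sum n^2 * 10^(SNR/10)))`.

## Experiment protocol and problem sizes

The white-noise benchmark (`ecgdenoise.experiments`) draws 6 random-
morphology ECGs, mixes white noise at the requested input SNRs, runs the
selected pipelines and averages SNR improvement / correlation / RDE.
Each replicate re-runs the whole protocol (fresh morphologies and fresh
noise); the evaluation script uses 5 replicates (30 ECG/noise pairs per
SNR level), the test suite 3. The ensemble decomposition of each noisy
record is computed once and shared between the standard and
high-frequency-only variants.

## Degenerate inputs and tie-breaks

* Constant or monotone signals: no IMFs; the signal passes through as
  residual.
* All-equal IMF values: `sigma = 0`, threshold 0, single pass.
* No detectable R peaks: baseline discard is skipped and only the
  high-frequency group is denoised (logged warning).
* `sigma_hat_k = 0`: that order is excluded from the ratio argmax.
* Argmax ties: smallest order (keeps fewer IMFs in the noisy group).
* Peak filtering of a zero-valued extremum is a no-op, so trailing
  zero plateaus cannot prevent termination; an explicit pass cap
  (10 N) guards the loop.
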