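# Methods

`pulsefed` implements cuff-less arterial-blood-pressure (ABP) waveform
estimation from the photoplethysmogram (PPG) as a cycle-consistent
generative adversarial translation between the two signal modalities,
trained with a simulated federated-averaging protocol, and evaluated with
the clinical agreement statistics used for BP devices (Bland–Altman
analysis of mean arterial pressure, the AAMI thresholds) plus waveform
similarity metrics (DTW, RMSE, Pearson correlation).  Everything runs on
synthetic paired waveforms with known ground truth, so the whole pipeline
is testable end to end on a laptop CPU.

## Translation model

Two generators map 1000-sample segments between domains: `P2A` (PPG →
ABP) and `A2P` (ABP → PPG).  Each is a two-layer stacked LSTM with 50
hidden units per layer; a per-timestep fully connected head maps the
50-dimensional hidden state at each step to one output sample, so the
output length structurally equals the input length (a requirement for
the identity and cycle terms to be well defined).  Two discriminators
`D_A`, `D_P` judge whether a segment looks like a real ABP (resp. PPG)
trace: four 1-D convolution layers (package-default widths 16/32/64/64,
kernel 5) each followed by ReLU and width-2 max pooling, then a fully
connected layer with a sigmoid, giving one score in (0, 1) per segment.

Training minimizes, on min-max-normalized segments,

    L = L_adv(P2A, D_A) + L_adv(A2P, D_P) + λ_c · L_cyc + λ_i · L_id

with least-squares adversarial losses (real label 1, fake label 0; the
generators target 1), L1 cycle-consistency loss
`L_cyc = |A2P(P2A(ppg)) − ppg| + |P2A(A2P(abp)) − abp|` and L1 identity
loss `L_id = |P2A(abp) − abp| + |A2P(ppg) − ppg|`, with λ_c = 10 and
λ_i = 5.  Each batch performs one generator update and one discriminator
update; the generator outputs computed for the generator objective are
reused (detached) as the discriminator's fake samples, so both updates
see the batch-start generator weights.

**Optimizer.**  Adam with learning rate 2e-3, β = (0.5, 0.999), applied
per network group (both generators share one optimizer instance, both
discriminators another).  The learning rate is deliberately larger than
typical long-horizon GAN settings: desk-scale runs take only a few
hundred optimizer steps, and Adam's per-step parameter displacement is
approximately the learning rate, so reaching O(1) changes in normalized
output space within that budget requires a step of this size.  Training
was stable at this setting in all smoke runs.

**Numerical backend.**  No GPU framework is used; layers are implemented
in float32 numpy with hand-derived backpropagation (verified against
central finite differences in the test suite).  The LSTM recurrence is
the CPU hot loop: the input projection and all weight-gradient
contractions are batched into single BLAS GEMMs, and the per-timestep
gate arithmetic is a fused numba kernel.  Gate nonlinearities use a
clamped Lambert continued-fraction rational approximation of tanh
(absolute error ≤ ~1.5e-4, far below float32 training noise); forward
and backward use the same approximation consistently.  Runs are
deterministic for a fixed seed on a given machine.  Max-pooling breaks
ties toward the earlier sample.

## Federated protocol

The dataset is shuffled and split into `n_clients` (default 20) equally
sized disjoint subsets; remainder items (at most `n_clients − 1`) are
dropped with a warning.  Each communication round draws
`clients_per_round` (default 6) clients uniformly without replacement;
every selected client copies the current global weights, trains
`local_epochs` (default 5) epochs at batch size 32 on its own subset
only, and the new global weight set is the per-parameter unweighted
arithmetic mean over the selected clients.  The average covers all four
networks' parameters.  Since subsets are equal-sized, unweighted and
example-count-weighted averaging coincide.  Optimizer state is local and
reset at each synchronisation.  Ten rounds is the reference protocol
default.

All randomness derives from one seed through a fixed SeedSequence
layout — `[seed, 0]` model init, `[seed, 1]` partition, `[seed, 2, r]`
round-r client sampling, `[seed, 3, r, c]` client-(r, c) batch
shuffling — so a run is bitwise reproducible, single-client federation
is step-for-step identical to centralized training, and a run can be
resumed from any round checkpoint on an identical trajectory.

## Synthetic paired waveforms

The simulator emulates the statistical structure of paired cuff-less BP
recordings: fixed-length two-channel segments (8 s at 125 Hz or 10 s at
100 Hz, both 1000 samples) with per-segment systolic/diastolic ground
truth.  Each beat is a sum of two Gaussian bumps with channel-specific
morphology — PPG: broad rounded systolic wave (centre 0.22, width 0.13,
of the beat interval) with a weak dicrotic hump (0.45/0.16, amplitude
0.25); ABP: sharp systolic upstroke (0.12/0.07) with a prominent
dicrotic wave (0.35/0.09, amplitude 0.35).  Both channels share one
jittered beat-onset train (i.i.d. Gaussian interval jitter, SD 3% of
the interval, truncated at ±3 SD), and the ABP is delayed by the pulse
transit time (default 0.2 s), so the PPG → ABP coupling is deterministic
and invertible — a learnable target for the translation model.  The ABP
template is affinely rescaled so every noiseless beat peaks at the
target SBP and the segment minimum equals DBP; the PPG carries
multiplicative respiratory amplitude modulation (3% depth at 15
breaths/min), and both channels optionally carry sinusoidal baseline
wander (0.2 Hz) and additive white noise scaled to the pulse amplitude.

Key defaults: HR 60 bpm, SBP/DBP 120/80 mmHg, PTT 0.2 s, noise SD 2% of
pulse amplitude, wander amplitude 1%.  These are engineering choices in
physiological ranges, not estimates of any particular dataset.

Two deliberate idealisations matter for interpreting results:

- **Beat alignment.**  Segments are beat-anchored (a beat onset falls at
  t = 0; jitter accumulates outward, so the anchor never drifts).  With
  free-running phase, no term of the CycleGAN objective constrains the
  output phase — the training optimum degenerates to the identity map
  and the coupling is unidentifiable (a causal LSTM also cannot
  represent the anticausal direction of a pure delay).  Beat alignment
  makes the domain phase a property the discriminators can enforce, and
  all loss terms then share an optimum at the true coupling.
- **Distinct channel morphologies.**  If the two channels shared one
  pulse shape, the domains would differ only by a 0.2-s shift and a
  pass-through generator would be adversarially near-perfect; training
  then collapses into that sink.  The distinct shapes (also the
  physiologically realistic choice) force actual translation.

Consequently, passing end-to-end tests demonstrates that the optimizer,
losses, federation and evaluation machinery are correct and that the
model can learn a deterministic, morphologically distinct, beat-aligned
coupling.  It does not demonstrate clinical-grade BP estimation on real
data, which has free-running phase, beat-to-beat morphological
variability, sensor artifacts, and a BP–waveform relationship that is
neither deterministic nor stationary.

## Blood-pressure evaluation

Generated normalized ABP is mapped to mmHg with the global (min, max) of
the training dataset's ABP — at inference only PPG is observed, so no
per-segment inverse scaling exists; the calibration step then removes
residual scale bias.  Per segment, systolic peaks and diastolic troughs
are detected as local extrema with a minimum separation of
`fs · 60 / 180` samples (assumes HR ≤ 180 bpm) and prominence ≥ 10% of
the segment range; SBP (DBP) is the mean peak (trough) amplitude and
MAP = [SBP + 2·DBP] / 3 computed from those — not the arithmetic mean of
the trace, which differs for asymmetric pulses.  Segments where
detection fails are excluded and counted, not fatal.

Bland–Altman statistics of the per-segment MAP error (estimated − true):
mean μ, SD σ with the sample (n − 1) denominator, 95% limits of
agreement μ ± 1.96σ, and the AAMI verdict |μ| < 5 mmHg and σ < 8 mmHg.
Optional calibration estimates a constant offset (mean error) on the
first `cal_duration` of recording (default one minute, i.e. six 10-s
segments) and subtracts it from all subsequent estimates; calibration
segments are excluded from the reported statistics.  An additive offset
is used because the calibration is meant to remove a per-user bias; an
affine fit is deliberately out of scope.

Waveform similarity is computed per segment on min-max-normalized traces
and averaged: full unconstrained DTW (absolute-difference local cost,
{match, insert, delete} steps, two-row dynamic program), RMSE, and the
sample Pearson correlation.  Normalized units keep the three metrics on
comparable scales across pressure levels.

## Desk-scale problem sizes

Default experiment sizes in the acceptance script and heavy tests —
training sets of 400–1000 segments, 3–4 clients, 3 communication rounds,
2 local epochs — are the package's chosen desk-scale study conditions:
large enough for the learning signal to be unambiguous (held-out PCC of
the translated ABP well above both the untrained model and the
pass-through shortcut), small enough to run on one CPU core in minutes.
The reference protocol values (20 clients, 6 per round, 10 rounds, 5
epochs) remain the config defaults.

## Known limitations

- The simulator's coupling is far simpler than real PPG→ABP physiology
  (fixed PTT independent of pressure, no pathology, no artifacts).
- Discriminator widths/kernel, optimizer settings and peak-detector
  thresholds are package defaults, stated above and in the config dump;
  they are not fitted to any external dataset.
- With sigmoid discriminator heads, a fully confident discriminator
  shrinks the adversarial gradient (sigmoid saturation); the desk-scale
  defaults keep training in a regime where this does not prevent
  learning, but very long runs may need discriminator regularisation.
- Federation is simulated in-process (no transport, encryption, secure
  aggregation, or client asynchrony).
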