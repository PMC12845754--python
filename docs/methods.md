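# Methods

This note records the models implemented in `aesmbe`, the assumptions
behind the synthetic data they are validated on, and the numerical and
design decisions that were genuinely open, with the reasoning for each.

## 1. Signal model and windowing

EEG enters the pipeline as *runs*: continuous multi-channel recordings
(channels × samples) at 160 Hz with one task label per run (rest, motor
execution, motor imagery).  Runs are cut into non-overlapping 1 s
windows (H = 160 samples); trailing samples are dropped.  Each window is
normalized per channel *within the window*: subtract the channel mean,
divide by the channel's population standard deviation (divide by H).
Population rather than sample SD is used because the normalization is a
rescaling of the realized window, not an inference about a parent
distribution; the difference is a factor √(H/(H−1)) ≈ 1.003 and does not
propagate anywhere.  Channels whose within-window SD falls below 1e−12
are returned as all zeros and flagged rather than raising — flat
channels occur in clipped or synthetic data and should not abort a run.
No filtering, artifact rejection or re-referencing is applied.

Consequences of this normalization that shape everything downstream:
every channel of every real window has *exactly* zero mean and *exactly*
unit variance.  Channel identity is therefore carried only by temporal
structure (spectral shape, waveform morphology), never by amplitude or
offset.  Section 4 describes how the architecture has to respect this.

## 2. Run-wise cross-validation

Folds are defined on run indices, never on windows: a fold template
assigns each run to train or test, and windowing happens after the
assignment, so temporally correlated windows cannot straddle a fold.
The shipped templates (14-run subjects, 3 folds each) hold out 5 runs
per fold in the pre-training stage and 4 runs per fold in the
registration stage; both keep rest and task runs represented in the test
sets.  The templates are configuration-overridable; `check_no_leakage`
verifies the run-disjointness of any realized fold, and the pipeline
runs it on every fold it builds.

## 3. Synthetic EEG with planted signatures

The generator emulates a multi-subject motor-imagery protocol: each
subject has `runs_per_subject = 14` runs (runs 1–2 rest, then
alternating execution/imagery).  Background noise on every channel is
pink (1/f power, generated by spectral shaping) plus white noise, mixed
1:1 in power and scaled to unit variance — a minimal EEG-like spectrum
with no claim of physiological fidelity.  Each subject has a secret
*signature*: `n_planted = 4` channels drawn without replacement, each
carrying a sinusoid at a subject-specific alpha-band frequency
(uniform 7–13 Hz) with a random phase per run.  The sinusoid amplitude
encodes the task: modulation factors 0.3 (rest), 1.0 (execution), 0.7
(imagery), scaled so that the sinusoid-to-noise power ratio at
modulation 1 equals the configured `snr`.  The whole dataset is a pure
function of the configuration (every run is seeded from
`(seed, subject, run)`).

What this does and does not emulate: it reproduces the *structure* the
selection method needs — a small subject-specific set of informative
channels against a realistic-looking broadband background, with
task-dependent amplitude — but not volume conduction (signatures are not
mixed across channels; this keeps the planted ground truth unambiguous
for recovery tests), not artifacts, and not evoked-potential morphology.
Passing tests on this data shows that the pipeline can find and exploit
channel-local narrow-band subject differences; it does not show
performance on real EEG, where discriminative information is spatially
mixed and weaker.

The reference oracle for electrode recovery ranks channels by a
subject-vs-rest band-power contrast: mean Welch power in 7–13 Hz per
subject and channel, then `(P_subject − mean_others) / sd_across_subjects`.
On the default test conditions (16 channels, 4 planted, snr ≥ 5) this
recovers at least 3 of 4 planted channels per subject.

## 4. The intent backbone and electrode scoring

Architecture (batch × C × H): input batch normalization (ε = 1e−4) →
channel-attention gate → N multi-scale bidirectional encoder blocks →
global temporal pooling → fully connected C→16→4.  The attention gate
pools a per-channel descriptor `z`, applies a square FC (`W`, initialized
U(−1/√C, 1/√C)) and a sigmoid, and multiplies each channel by its gate
α_c ∈ [0, 1]; dimensionality is never changed.  Each encoder block has
its own channel gate (GAP → FC → sigmoid, multiplied onto the block
input) and two temporal branches — local convolution (k = 3, padding 1),
sigmoid, global convolution (k = 7, padding 3), and a channel-mixing
projection applied in time-major layout; the branch adds the same
projection of its input as a residual.  The backward branch applies its
own weights to the time-reversed signal and reverses the result
(`backward(x) = reverse(forward_pipeline(reverse(x)))` holds exactly
when the weights are tied — this is a tested invariant).  Branch outputs
are combined by summation (configurable: mean, or concatenation with a
1×1 projection).  N defaults to 2; the desk-scale experiments use N = 1.

**Why pooling is rectified.**  Per-window normalization (Section 1)
makes the plain temporal mean of every channel identically zero, and the
sigmoid is odd around its midpoint, so the time-average of any
symmetric, zero-mean signal is amplitude-blind.  Measured on the
synthetic task: with plain temporal means as pooled statistics, the
attention gradient is exactly zero (the descriptor is the same constant
for every window) and training cannot leave the class-prior loss.  The
package therefore uses the *rectified* temporal mean (mean of |x|) for
every pooled statistic — the attention descriptor, the per-block gates,
and the pre-head pooling.  The rectified mean distinguishes
oscillation-dominated from noise-dominated channels even at equal
variance and restores a usable learning signal.

**Why the attention descriptor is standardized.**  The rectified mean
concentrates near √(2/π) for near-Gaussian channels, so its informative
part is a small fluctuation on a large constant; fed raw into the
attention FC, the learned weights are dominated by initialization noise
and the post-training ranking is arbitrary (measured: recovery at
chance).  Standardizing the descriptor per channel across the batch
(running estimates in eval mode) rescales those fluctuations to unit
order.  With this one change the weight-magnitude ranking recovers the
planted channels in every test run.

**Why projections initialize near the identity.**  A square
channel-mixing FC with uniform random init produces outputs whose
per-channel statistics are mixtures of all channels; by the central
limit theorem this gaussianizes away exactly the per-channel structure
the head needs early in training (measured: linear probes of pooled
features at a random init are at chance).  The per-direction projection
matrices therefore initialize as `I + 0.1·U(−1/√C, 1/√C)`, so the
residual path transmits per-channel structure from the start while
remaining fully learnable.

**Electrode scoring.**  After training, channel importance is
`s_c = Σ_j |W[j, c]|` — the aggregated magnitude of the attention-FC
column attached to channel c's descriptor.  The score uses weights only
(never data), so the ranking is frozen and reproducible.  Ranking sorts
by descending score with ties broken by ascending channel index; the
selected top-n subset is re-sorted ascending for input assembly.  An
optional L2 shrinkage on the attention matrix alone
(`aes_weight_decay`) decays the initialization so that surviving
magnitude reflects accumulated task gradient; it is off by default and
sharpens but is not required for recovery at the tested conditions.

**Pre-training task.**  For target subject s: windows of s keep their
task labels; all other subjects' windows become a fourth
`other_subject` class, subsampled (seeded, without replacement) to match
the target's window count so the negative class cannot dominate.
Training is SGD with momentum 0.9 and cross-entropy (the softmax/one-hot
output fixes the loss), batch up to 256, stopping at `max_epochs` or
when the epoch loss has not improved by `min_delta = 1e−4` for
`patience = 20` epochs.  A global-norm gradient clip (default 5.0)
guards against the occasional exploding batch that otherwise derails
momentum SGD at desk-scale learning rates.  Defaults mirror the
full-scale protocol (lr 1e−4, batch 256, up to 1000 epochs); the
desk-scale experiments pass lr 0.02, batch 128, 40 epochs, N = 1
explicitly.

**Rankings and folds.**  Fold models measure held-out intent accuracy.
The frozen ranking is extracted from a refit on *all* of a subject's
enrollment runs (standard refit-after-CV practice; the hold-out exists
for the accuracy estimate, not the ranking).  Measured at the 16-channel
test conditions: rankings from a single 9-run fold model recover planted
channels in only a third of runs, while the all-runs refit recovers
≥ 3 of 4 in every run.

## 5. The identification model

Input assembly: for a sample of subject s, the top-`budget` channels of
s's frozen ranking are gathered and stacked in ascending electrode-index
order — a fixed `budget × 160` input regardless of which physical
electrodes were selected.  The classifier is one unified K-class network
over all enrolled subjects: three 1-D convolutions (64 channels each,
kernels 7/5/3, stride 2, Conv → BN → ReLU) bring 160 samples to
C′ = 64 × H′ = 20; the transposed token sequence passes through L = 2
post-norm Transformer encoder layers (h = 4 heads of d = 16,
`softmax(QKᵀ/√d)V`, FFN width 128, residual + LayerNorm in the order
`LN(x + sublayer(x))`); global average pooling over time and a final FC
give the K softmax posteriors, with hard decisions one-hot at the argmax
(ties to the lowest index).  Conv depth/widths, L, h, d and the FFN
width are not architecture constraints of the method; they are exposed
in the configuration, and the desk-scale experiments use 32-channel
convolutions with a single encoder layer.  No positional encoding is
added (a config flag could add one; the attention over 20 pooled tokens
did not need it on any tested task).

## 6. Verification metrics

For each test sample with true identity y, all K claims are enumerated:
one genuine trial with score P[y] and K−1 impostor trials with scores
P[c], c ≠ y — so |G| + |I| = nK exactly, and no separate verification
model exists.  The accept rule is score ≥ τ (equality accepts): FAR(τ)
is the accepted fraction of impostor trials, FRR(τ) the rejected
fraction of genuine trials.  The threshold sweep covers all unique
scores plus sentinels 0 and max+ε, so FAR starts at 1 and ends at 0 and
FRR the reverse; the EER is read at the crossing by linear interpolation
between the two bracketing thresholds, and when the step curves meet
without a strict sign change, as the midpoint (FAR+FRR)/2 at the
threshold minimizing |FAR − FRR|.  The sweep implementation
(sort + binary search) is tested to 1e−9 against a brute-force oracle
that counts comparisons at every threshold directly.  Identification
reports accuracy and macro-averaged precision/recall (macro chosen so
that small classes are not swamped; classes never present in the truth
are excluded from the average with a warning).

## 7. Study conditions and problem sizes

The package's experiments run on one CPU with the bundled numpy autodiff
engine, so all studies are desk-scale by design:

* *Selection recovery*: 2 subjects, 16 channels, 4 planted, snr 8,
  30 s runs; 3 seeds per subject; backbone N = 1, lr 0.02, 40 epochs.
  Measured: top-4 recovery ≥ 3/4 in 6/6 runs, oracle agreement 92%.
* *Identification*: 8 subjects, 16 channels, budget 4,
  subject-specific selection, run-wise folds; identifier with 32-channel
  convolutions, 10 epochs; held-out accuracy 1.00 versus 0.125 chance.
* *Strategy comparison* (subject-specific vs shared data-driven montage
  vs random fixed montage): same cohort, all 3 registration folds × 5
  seeds.  At convergence every data-driven strategy saturates at
  accuracy 1.000 on this small cohort — 8 subjects × 4 planted channels
  over only 16 channels overlap so heavily that 4 shared channels
  already cover most subjects — so the comparison identifier is trained
  for 4 epochs, below saturation, where input informativeness governs
  learning speed.  There the ordering is subject-specific (0.964) >
  common-global (0.936) > random fixed (0.674).
* The reference-scale setting (64 channels, 109 subjects, 20
  repetitions, 1000-epoch budgets) is out of reach of the C×C
  convolutional backbone on one CPU and is not attempted; the
  `repetitions` default of 20 matches the full protocol while the test
  profile uses 1–5.

## 8. Known limitations

* The planted-sinusoid model makes channel recovery well-posed; real
  inter-subject EEG differences are not characterized by any published
  statistic, and nothing here validates the selection mechanism under
  volume conduction or nonstationarity.
* The rectified-pooling and descriptor-standardization choices are
  consequences of exact per-window normalization; pipelines that
  normalize per run (leaving per-window variance informative) might not
  need them.
* Verification operates strictly closed-set: impostor claims come from
  enrolled identities, so EER here does not measure unknown-user
  rejection.
* EDF reading covers the common single-rate case used by the reference
  dataset layout; files with per-channel sampling rates are rejected.
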