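# Methods

This note records the model as implemented, the choices made where the
design was genuinely open, what the synthetic data generator does and does
not emulate, and the numerical conventions. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Model

Input is one 30-s epoch per sample, one waveform per modality (EEG, EOG,
EMG), default 100 Hz (3000 samples). The network is three per-modality
feature extractors feeding three exit classifiers; exit k consumes exactly
the first k modalities' features, which is what makes skipping the deeper
extractors sound.

### Feature extractor (per modality)

Two parallel branches of `conv → batch-norm → leaky-ReLU (slope 0.01)`
blocks with max pooling:

| | layer 1 | pool | layer 2 | layer 3 | pool |
|---|---|---|---|---|---|
| small | 64 filters, kernel 64, stride 8 | 8/8 | 32, k8, s1 | 56, k8, s1 | 4/4 |
| large | 64 filters, kernel 512, stride 64 | — | 56, k6, s1 | 48, k6, s1 | 8/3 |

All convolutions use valid (no) padding; dropout 0.5 follows the first
block of each branch during training. Both branches end at length d = 8
and are fused by channel concatenation (C = 104). A 1-D CBAM block then
applies channel attention (shared two-layer bottleneck MLP, reduction
r = 8, on the average- and max-pooled channel statistics, summed, sigmoid)
followed by spatial attention (channel-wise mean and max maps, stacked,
one kernel-7 convolution with same padding, sigmoid). Both attention maps
rescale multiplicatively and preserve the C×d shape.

The first small-branch layer (64/64/8 with 8/8 pooling) and the 512 kernel
of the large branch are fixed by the architecture's published figure; the
remaining widths are this package's defaults. They were fixed once by
solving the closed-form cost equations so that the default configuration
reproduces the published cost figures (10.28 GFLOPs at batch 256,
1.29 M parameters); they are overridable field-for-field from the run
config (`model.efem.{eeg,eog,emg}`).

### Exit classifier

The L available C×d maps are stacked to `F ∈ R^{L×C×d}` (L = 1, 2, 3 for
the EEG, EOG and final exit; the three heads are structurally identical up
to L, and all three include the SE block, L = 1 giving a scalar gate).
The squeeze-and-excitation block uses two shape-preserving 1×1
modality-mixing convolutions to form F′, global average pooling to L
scalars, two further 1×1 convolutions and a sigmoid to form the gate, and
the residual output `F″ = F + Mse ⊗ F′` (so zero weights give the exact
identity).

F″ flattens to L·C tokens of length d = 8. One transformer encoder block
follows: H = 8 heads (d/H = 1 per head), scores scaled by `1/√(d/H)` —
the printed normalisation is ambiguous and √d_head is the family
convention; it is configurable — softmax, head concatenation with **no
output projection** (the equations specify concatenation only), residual
layer norm, a two-linear feed-forward (width 16, ReLU), and a second layer
norm whose residual connects back to the **block input** X, exactly as the
equations print it. The conventional variant (second residual from the
feed-forward path only) is available behind `residual_as_printed: false`.
No positional encodings are used (never specified; available nowhere —
token order information enters only through the flatten). Pooling before
the final two linear layers (width 192 → 5 classes) is a flatten, the
simplest shape-sound choice.

### Two-stage training

Stage 1 minimises cross-entropy of the final exit; only extractor and
final-exit parameters are in the optimizer, so the student exits are
bit-identical to initialisation afterwards. Stage 2 loads the stage-1
checkpoint (it refuses to run without one), freezes every stage-1
parameter (batch-norm also runs in inference mode, so running statistics
are frozen too), and minimises `KL(p_s1‖p_t) + KL(p_s2‖p_t)` in nats with
no distillation temperature (none is specified; τ is configurable). The
teacher distribution is a constant — no gradient reaches it. An optional
hard-label cross-entropy term (`ce_weight_stage2`, default 0) is provided
because pure-KL training ignores labels; the default follows the published
loss exactly. Probabilities are clamped at 1e-12 before logarithms.

Optimizer: Adam, lr 1e-3 (unstated in the source; conventional). Inputs
are z-scored per record and channel; this is an explicit normalisation
toggle (`normalize`), on by default, because raw-amplitude training is
unstable while the method itself prescribes no spectral preprocessing —
and none is applied.

### Adaptive inference

Uncertainty is the normalized entropy `Σ p log p / log(1/N)`, base
invariant, 0·log 0 := 0. The halt rule is **strict**: halt iff
`U < Speed`. Speed = 0 therefore never halts, every sample is classified
by the final exit, and the implementation short-circuits the student heads
entirely in that case (they perform no computation). Both student exits
share one Speed by default; per-exit thresholds are available. Routing is
progressive sub-batching: halted samples are physically removed before the
next extractor runs, so the computation saving is real, and the work
counters in `AdaptiveResult.work` reflect it.

## Cost accounting

Default convention: 1 MAC = 2 FLOPs (a `macs` toggle halves multiply-add
terms). Per-layer closed forms: conv `2·k·C_in·C_out·L_out + bias`, linear
`2·n_in·n_out + bias`, attention `6nd² + 4n²d + O(Hn²)`, plus itemised
norm/pool/activation terms; inline activations of the feed-forward and
head layers (< 0.05% of any total) are counted analytically but not by the
instrumented tracer, which is why the dual-route agreement test uses a 1%
band. Two path notions are exposed because a multi-exit network has two:

* **speed0** — three extractors + final head only (the Speed = 0
  behaviour); this is the figure quoted for a batch of 256;
* **cumulative** gated paths — exit k costs all extractors *and heads* up
  to k, which is what a gated sample traverses when Speed > 0. Expected
  cost under exit fractions is their convex combination, and is monotone
  non-increasing in Speed by threshold-set nesting.

Parameter counting is exact (verified against the live model's tensors)
and takes an `active_exits` subset, counting the sub-network any sample
could traverse — this is how a high Speed can report a smaller effective
model.

## Synthetic data generator

The generator produces the statistical structure the method assumes, not
physiological PSG — no spindles, K-complexes, artifacts, or inter-subject
variability. Consequences: passing tests demonstrate that the
architecture, training regimen and router behave as designed when the
assumed structure is present; they do not certify clinical accuracy.

Per stage, EEG is a sum of band-limited oscillations (delta 0.5–4,
theta 4–8, alpha 8–13, beta 13–30 Hz) with fixed relative amplitudes per
stage — delta is the strict maximum for N3, alpha exceeds delta for W,
theta marks N1/REM — each band realised as three sinusoids at uniformly
drawn in-band frequencies with random phases (a single pure tone per band
is memorisable by a classifier; three make band *power* the only stable
cue). EOG is a train of ~0.7 s biphasic deflections at a stage-specific
Poisson rate (frequent in W and REM, nearly absent in N3); EMG is noise
plus short activity bursts whose rate scales with stage muscle tone
(highest in W, atonia in REM). Muscle tone is deliberately encoded as
burst *rate*, not raw amplitude, so the cue survives per-record
normalisation. Gaussian noise (sd 0.1) is added and every waveform is
z-scored. All waveforms are bit-reproducible from (stage, tier, config,
seed).

Difficulty tiers set which modalities are informative: `eeg_separable`
uses the true templates; `eog_required` replaces the EEG template with the
average of the stage and its confusable partner (W↔N1, N2↔N3, REM→N1), so
EOG must disambiguate; `emg_required` uses the all-stage mean EEG template
and the all-stage mean EOG rate, leaving EMG as the only informative
channel. The all-stage blend (rather than a pair blend) in the hardest
tier is required for the tier to be genuinely EEG-inseparable across
pairs — a depth-one stump on delta power tells N3 from W at ≥ 95% on easy
epochs and ≤ 70% on hard ones, which the suite verifies.

Defaults: class proportions follow the 20-subject Sleep-EDF cohort
(19.3 / 6.9 / 41.4 / 14.2 / 18.2%), tiers 50 / 30 / 20%, all modalities at
100 Hz. Class and tier counts are realised by largest-remainder
apportionment (exact to ±1 per class).

## Desk-scale study sizes

The end-to-end study (`somnexit.experiments.scaled_down_study`) uses 1500
training and 500 held-out epochs with a narrow model (16 filters per
branch layer, 4 heads, hidden width 48, dropout 0.3) and batch 64,
18 + 8 epochs, weight decay 1e-3 — sizes chosen so a full run completes in
a few minutes on one CPU while leaving the trade-off measurable. The
weight decay and dropout matter here: a 1500-epoch set is small enough for
an unregularised network to memorise. Accuracy for the sweep is measured
on the held-out set; the sweep derives routing for every Speed from one
ungated forward pass (uncertainties do not depend on Speed), which is
sample-for-sample identical to running the gated path per Speed, and the
suite asserts that equivalence.

## Numerical and degenerate-input conventions

* KL and entropy: natural log; teacher probabilities clamped at 1e-12;
  0·log 0 := 0.
* Macro-F1: a class with no true and no predicted samples contributes
  F1 = 0.
* Cohen's κ with degenerate marginals (p_e = 1) is defined as 0 with a
  warning.
* Batch-norm: eps 1e-5, momentum 0.1, inference uses running statistics.
* Max pooling and the attention argmax break ties toward the first index.
* Epochs are cut at hypnogram annotation boundaries, 0-based, half-open;
  a trailing partial epoch is dropped.
* EMG recorded at 1 Hz (Sleep-EDF convention) is polyphase-upsampled to
  the common grid; no other filtering is ever applied.

## Known limitations

* The numpy training engine is single-threaded BLAS-bound; full-size
  (64/104-channel) training is out of desk scale by design — the full-size
  configuration is exercised analytically (cost counters, shape and
  gradient checks), trained only at reduced width.
* The EDF writer covers the subset of EDF needed to export synthetic
  recordings (16-bit, integer rates, one record per second).
* Tier labels are generator metadata; real recordings carry no tier, and
  the router never uses them — they exist to *evaluate* routing.
* Cross-validation campaign tooling stops at fold assignment; orchestrating
  a 10-fold training campaign is scripting left to the user.
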