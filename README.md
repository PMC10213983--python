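# somnexit

Multi-exit, multimodal sleep-stage classification with adaptive inference
depth, in pure scientific Python.

## The problem

Clinical sleep staging assigns one of five AASM stages — W, N1, N2, N3,
REM — to every 30-second epoch of an overnight polysomnogram (EEG, EOG and
EMG channels). Multimodal deep networks reach the best accuracies, but they
spend the full multimodal computation on *every* epoch, although most
epochs are easy: a clearly alpha-dominated wake epoch or a delta-dominated
N3 epoch is recognisable from the EEG alone. Only the genuinely ambiguous
epochs need the eye-movement and muscle-tone evidence.

`somnexit` implements a network that exploits this. Three per-modality
feature extractors are chained with three classifiers ("exits"):

* **exit 1** sees EEG features only,
* **exit 2** sees EEG + EOG,
* **exit 3** (the final classifier) sees EEG + EOG + EMG.

At inference, each sample stops at the first exit whose predictive
uncertainty — the normalized Shannon entropy

```
U(p) = ( Σᵢ pᵢ log pᵢ ) / log(1/N)  ∈ [0, 1]
```

falls strictly below a single knob called **Speed**. Speed = 0 disables
early exits entirely (every sample is classified by the final exit, and
the student heads do no work); raising Speed trades accuracy for
computation, sample by sample. Halted samples are genuinely removed from
the batch between stages, so the deeper extractors never touch them.

## Architecture

Each **feature extractor** (one per modality) runs two parallel 1-D
convolutional branches — a small-kernel branch (kernel 64: 0.64 s windows
at 100 Hz, resolving alpha/theta activity) and a large-kernel branch
(kernel 512: 5.12 s windows, resolving slow delta waves) — each conv
followed by batch-norm and leaky-ReLU, fused by channel concatenation, and
refined by a 1-D CBAM block: channel attention `Mc = σ(MLP(AvgPool F) +
MLP(MaxPool F))` then spatial attention `Ms = σ(f⁷[AvgPool F′; MaxPool F′])`,
each applied multiplicatively and shape-preserving.

Each **exit** stacks its L available modality feature maps into
`F ∈ R^{L×C×d}`, gates whole modalities with a squeeze-and-excitation
residual block `F″ = F ⊕ Mse ⊗ F′`, flattens to L·C tokens of length d,
runs a transformer encoder block (multi-head self-attention, residual layer
norms, position-wise feed-forward), and classifies with two linear layers.

**Training is two-stage** ("train twice, infer once"): stage 1 trains the
three extractors plus the final exit with cross-entropy; stage 2 freezes
all of that and trains only the two early exits by self-distillation,
minimising `KL(p_s1 ‖ p_t) + KL(p_s2 ‖ p_t)` against the frozen final
exit's predictions.

The whole network, including reverse-mode gradients, lives in
`somnexit.nn` — a compact numpy autodiff core written for this model
family.

## Worked example

No data download is needed: `somnexit.signals` generates labeled synthetic
PSG epochs with the spectral structure the method assumes (delta-dominant
N3, alpha-dominant wake, stage-specific EOG event rates and EMG burst
rates) and three difficulty tiers (EEG-separable / EOG-required /
EMG-required).

```
somnexit synth  --n 1500 --seed 0 --out runs/demo
somnexit train   --data runs/demo/epochs.npz --out runs/demo
somnexit distill --checkpoint runs/demo/stage1.npz --data runs/demo/epochs.npz --out runs/demo
somnexit sweep   --checkpoint runs/demo/stage2.npz --in runs/demo/epochs.npz --out runs/demo/sweep.csv
```

Static cost profile of the full-size configuration (batch 256):

```
$ somnexit flops --set model.preset=default --batch 256 --per-stage
full path (Speed=0), batch 256: 10.27 GFLOPS
  cumulative gated path exit 1: 2.98 G
  cumulative gated path exit 2: 6.74 G
  cumulative gated path exit 3: 11.72 G
  EFEM EEG: 2.646 G
  EFEM EOG: 2.646 G
  EFEM EMG: 2.646 G
  head 1: 0.334 G
  head 2: 1.112 G
  head 3: 2.335 G
params (all exits): 1.29 M
```

The first line is the Speed = 0 cost (three extractors + final head; the
student heads compute nothing). The *cumulative gated* paths are what a
sample actually traverses when Speed > 0; their convex combination under
the observed exit fractions is the expected cost of a gated batch.

On the synthetic study (1500 training / 500 held-out epochs, narrow model,
one CPU, a few minutes), a moderate Speed keeps roughly half of the
samples at the EEG-only exit, cuts expected FLOPs by ~40%, and leaves
accuracy within a point of the Speed = 0 baseline — the package's test
suite (`tests/test_acceptance.py`) re-runs exactly this experiment and
asserts the trade-off.

## Real recordings

`somnexit prepare --manifest manifest.yaml --out store.npz` reads EDF
recordings (via mne) with per-record channel maps and hypnograms, applies
the standard rules — N4 merged into N3, MOVEMENT/UNKNOWN excluded,
leading/trailing wake truncated to 30 min around the sleep period —
resamples all modalities to one grid, and cuts labeled 30-s epochs.
Subject-wise k-fold split assignment is provided (`somnexit.io.assign_folds`).
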