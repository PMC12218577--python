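# Methods

`modgraph` implements a compositional graph of differentiable models for
multimodal AD/CN (Alzheimer's disease vs. cognitively normal)
classification, together with a synthetic cohort generator that makes every
component testable end-to-end on a laptop CPU. This note records the model,
the parameters that matter, the numerical choices, and the limits of what
the synthetic experiments can show.

## The graph of models

A node *n* is a data representation with an associated space Ω_n (an image
volume, a 2D slice, a named feature vector, or an AD/CN probability pair);
an edge is a differentiable map f: Ω_source → Ω_target. A directed path
(n_1 → … → n_k) composes its edge maps into a single predictor
F(x) = f_{k-1,k} ∘ … ∘ f_{1,2}(x), which supports forward evaluation,
gradient flow back to the path input (chain rule), fine-tuning with frozen
edge subsets, and gradient-based attribution.

Interfaces are strict: an edge whose declared spaces do not exactly match
its endpoint nodes is rejected at wiring time. Any adaptation (reshaping,
normalisation) must itself be an edge. Edges are opaque objects exposing
only `(input_space, output_space, apply, parameters)` — the graph never
inspects their internals, so any edge can be retrained or replaced in
isolation.

The default diagnosis graph has **11 nodes and 14 edges** forming **11
declared source-to-sink paths**: raw MRI/PET → skull-stripped MRI/PET →
label (paths 1–2); ROI volume/thickness/surface, APOE4, and cognitive
scores → label (paths 3–7); MRI↔PET translation (paths 8–9); and
label-conditioned diffusion sampling of MRI/PET (paths 10–11). The seven
classifier outputs are additionally wired, as recorded feeder metadata, to
a `scores` node holding the 7×2 probability block that the fusion MLP maps
to the final label. Path enumeration counts these declared source→sink
routes; the generative edges create cycles, so free topological enumeration
is not meaningful.

Because sampling edges (ancestral diffusion) are not deterministic
functions of their input, they support forward evaluation only; gradient
operations (path gradients, saliency) refuse paths that contain them.

## Computational substrate

All edge models run on a small reverse-mode automatic-differentiation
engine written on numpy (`modgraph.autodiff`): a `Tensor` records the
operations applied to it and replays them backwards. The op set is exactly
what the model zoo needs — broadcasting arithmetic, matmul, stride-1
convolution via im2col, average pooling, nearest-neighbour upsampling,
instance normalisation, single-head spatial attention, softmax /
cross-entropy, dropout, and a hard [0,1] clamp. Every backward pass is
validated against central finite differences (the independent oracle) in
the test suite; the gradient-check utility is part of the package
(`modgraph.autodiff.gradcheck`). Float64 throughout; Adam (optionally with
L2 weight decay) is the optimiser for every trainable edge.

## Synthetic cohort

The generator (`modgraph.cohort`) emulates the statistical structure the
experiments need, with no claim to MRI physics:

- **Images.** Each subject gets a stack of 2D "coronal" slices (count
  uniform in `n_slices_range`, default 5–12; side default 32 px). A slice
  contains a bright elliptical skull annulus (thickness 2 px), an interior
  brain region, and background noise. The ground-truth stripped image
  zeroes everything outside the interior; the skull mask is the annulus, so
  skull and brain regions are disjoint by construction.
- **Disease signal.** A per-subject severity latent u ~ N(μ_class, 1) with
  μ_AD = `atrophy_effect` (default 2.0) and μ_CN = 0 sets the radius of a
  dark central region — an atrophy/ventricle proxy. PET expresses a latent
  correlated with MRI's at `mri_pet_correlation` (default 0.7, our choice:
  the redundancy is not quantified anywhere, and 0.7 reproduces the
  qualitative finding that MRI and PET carry largely overlapping signal).
- **Tabular modalities.** ROI volume/thickness/surface (8 regions each) are
  class-conditional Gaussians with standardized effects 0.62/0.45/0.32;
  eight cognitive scores (CDRSB, ADAS11/13/Q4, MMSE, RAVLT
  immediate/learning/forgetting) use effect 1.2 with clinically-signed
  directions (MMSE and RAVLT recall decrease in AD); APOE4 is Bernoulli
  with carrier rates 0.40 (AD) / 0.30 (CN). These defaults were set so
  linear-probe balanced accuracies land near the relative ordering observed
  on real cohorts: cognitive ≈ .95 > images ≈ .82–.86 > volume ≈ .77–.82 >
  thickness > surface > gene ≈ .55–.58. The two weakest modalities sit
  close together; under cohort resampling their probe estimates can swap —
  that is sampling noise, not a generator defect.
- **Labels and missingness.** AD fraction defaults to 0.35 (so balanced and
  raw accuracy genuinely differ); class counts are fixed at round(n·f).
  Modalities go missing completely at random at per-modality rates
  (default: PET 20%, ROI 5%, gene/cognitive 10%); an unavailable modality
  is absent (`None`), never zero-filled.

What passing tests on this cohort do **not** show: robustness to scanner
effects, registration error, intensity non-uniformity, demographic
confounding, or informative missingness. The generator's geometry is
trivially simple; absolute accuracies here say nothing about real data.

## Edge models (desk scale)

- **Skull stripping**: a miniature U-Net (two down/up stages, skip
  connections) regresses the stripped image directly — no binary-mask
  stage — keeping the edge differentiable end-to-end; MSE loss. The final
  activation is a hard clamp to [0,1] (relu(x) − relu(x−1)): the bound is
  architectural, and unlike a sigmoid its gradient only vanishes where the
  output already sits correctly at a bound (a sigmoid saturates globally on
  mostly-zero targets and collapses to the all-zero solution). To score a
  regression output as a mask, the output is thresholded at 5% of its max
  intensity; IoU is computed per volume and averaged over subjects.
- **Image classifiers**: a residual CNN (stem + four residual blocks at
  widths 8/16/32/64 — a faithful miniature of an 18-layer residual
  network) classifies individual 2D slices; slices inherit the subject
  label during training, and the subject score is the arithmetic mean of
  per-slice probability pairs over the normalised slice count. Slice-count
  normalisation is linear interpolation along the slice axis (endpoints
  preserved; exact on constants; idempotent at the target count); the desk
  default is 8 slices, 100 reproduces the reference setting. Normalisation
  happens before a volume enters the graph, since node spaces carry fixed
  shapes.
- **Feature classifiers**: MLPs with two hidden layers of width
  max(16, 4·d). Class imbalance is handled with inverse-frequency loss
  weights in all classifiers and in the fusion MLP.
- **Translation GAN**: a conditional encoder–decoder generator with style
  injection — per-stage adaptive instance normalisation driven by a mapping
  of (noise z, encoded condition) — and a patch-level least-squares
  discriminator. The generator loss is
  λ_L1·L1 + λ_VGG·perceptual-L1 + λ_adv·(D(c,G(c,z))−1)² +
  λ_C·CE(C(G(c,z)), y) with weights (50, 100, 1, 50). The perceptual
  extractor φ is a small frozen random-conv embedder (seeded constants, no
  pretrained weights); a pretrained backbone can be slotted into the same
  handle. The discriminator trains on ½[(D(c,x)−1)² + D(c,G(c,z))²] — the
  generator's (D−1)² term identifies a least-squares GAN, which fixes the
  discriminator objective. C and φ are frozen by construction: they are
  simply never passed to an optimiser (gradients flow through them to G).
- **Label-conditioned diffusion**: a three-stage encoder/decoder of 3×3
  convolutions with residual blocks, bottleneck self-attention, and skip
  connections predicts the injected noise ε from (x_t, t, y); the label
  mask y enters as an all-ones/all-zeros input plane, t as two sinusoidal
  planes. Loss = ‖ε − ε_θ(x_t,t,y)‖² plus the frozen classifier's
  cross-entropy on the one-step denoised estimate
  x̂_0 = (x_t − √(1−ᾱ_t)·ε_θ)/√ᾱ_t — running full ancestral sampling inside
  the training loop is intractable, and the one-step estimate is the
  standard differentiable surrogate. Linear β schedule 1e-4 → 0.02, T = 200
  by default (T = 60 in the desk-scale experiments). Sampling is standard
  ancestral DDPM with the label mask fixed, deterministic per seed, final
  projection to [0,1].

## Fusion and the missing-modality protocols

The fusion MLP (14 inputs = 7 modalities × 2 scores; layers 256/128/64/2;
ReLU after the hidden layers; dropout 0.5 after the second and third
layers; softmax output) is trained with cross-entropy while k ~ U{0..5}
modality groups are masked per sample at every step, each time a fresh
uniformly chosen k-subset. The reference description applies ReLU "after
each layer"; we do not rectify the final 2-unit layer, since clamping
logits at zero halves the usable logit space under cross-entropy — the
softmax output is the probability pair. Masked groups are filled with
(0, 0), which no valid probability pair can equal.

The majority-vote ensemble casts one hard argmax vote per available
modality. Tie-breaking defaults to **conservative**: an even split returns
CN (no majority → no disease call). An alternative
`tie_break="mean_probability"` resolves ties by the mean AD-probability
across available modalities. We measured that the mean-probability rule
turns the two-voter case (5 of 7 modalities missing) into soft score
averaging that is nearly Bayes-optimal on calibrated scores (k=5 BAC ≈
0.81–0.85 vs 0.71–0.74 for literal hard voting on three seeds) — at that
point the baseline is no longer majority voting, and the characteristic
robustness gap between a masked-trained fusion MLP and a vote ensemble
disappears. The conservative rule keeps the ensemble what its name says.

Protocols: `random_k` masks an independent uniformly-drawn k-subset per
subject per repetition (default 100 repetitions) and averages balanced
accuracy; `single` and `subset` remove named groups deterministically. The
synthetic-PET substitution experiment treats every test subject's PET as
missing, translates their MRI through the trained MRI→PET generator, scores
the synthetic volume with the PET classifier, and inserts that pair in
place of the mask fill. Real and synthetic PET are scored by the *same*
split-trained PET classifier: scoring them with differently-calibrated
models puts the substituted slot out of distribution for the fusion MLP and
can spuriously degrade it.

## Attribution

- **Full-gradient saliency** along a path: the map is
  ψ(x ⊙ ∇_x) + Σ_layers ψ(b ⊙ ∇_b), with ψ = absolute value followed by
  per-layer max normalisation, conv-layer bias maps summed over channels
  and linearly upsampled to the input resolution, and the final map
  rescaled to [0,1]. The raw (un-normalised) decomposition is complete for
  rectified-linear networks — f(x) equals the input term plus all bias
  terms — and the test suite checks this to 1e-5. Per-spatial-position bias
  gradients are captured by adding a virtual zero bias plane at each layer
  under a tape context, whose gradient is exactly the pre-activation
  gradient.
- **First-layer weight importance**: mean |weight| of fusion-MLP
  first-layer connections incident to each modality's two input columns.
- **Shapley values** over the 7 modality groups: exact enumeration of all
  2⁷ coalitions (one batched forward), coalition value = fused
  AD-probability with out-of-coalition groups masked to the (0,0) baseline
  — consistent with the fusion layer's missingness semantics. A
  permutation-sampling estimator is provided and agrees with enumeration to
  0.02 at 2000 permutations. On this generator the tabular modalities are
  drawn independently of the imaging latent, so which modality earns the
  largest |Shapley| depends on the configured effects; the package reports
  the values rather than asserting a fixed ranking.

## Desk-scale experiment sizes

The directional experiments (in `modgraph.experiments`) run at sizes a
single CPU finishes in minutes, chosen once: fusion robustness on a
200-subject cohort at 16 px and 4 normalised slices (train/test split
0.6/0.4, 8 training epochs for image classifiers, 250 masked-training
epochs for the fusion MLP, 40 protocol repetitions); guidance ablations and
the skull-strip ablation on 80-subject cohorts (diffusion T = 60, 40
samples per label); three seeds each. The default cohort and graph sizes
(200 subjects, 32 px) remain larger; the experiments state their own sizes
explicitly. Directional effects near the decision boundary (skull-strip
ablation, synthetic-PET substitution) are small relative to the balanced
accuracy resolution at these test-set sizes and can fluctuate across
individual seeds; the claims are made on three-seed means.

## Known limitations

- The autodiff engine is single-threaded numpy; it is a correctness-first
  substrate, not a performance one. Realistic-resolution training is out of
  scope.
- Fréchet distances are embedder-relative; the package uses the trained
  slice classifier's penultimate features (or any caller-provided
  embedder) and the numbers are not comparable to Inception-based values.
- The ensemble/fusion comparison depends on score calibration; with
  strongly miscalibrated upstream classifiers the measured gaps would
  change.
- Saliency maps are not perfectly stable across seeds; high-saliency
  regions largely recur, but individual maps should be read with the usual
  caution attached to gradient attributions.
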