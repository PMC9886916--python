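# Methods

This note records the model implemented by `cslearn`, the numerical and
design choices that were genuinely open, and what the synthetic benchmark
does and does not demonstrate.

## Model

Let E be the embedding network, M ∈ ℝ^{K×d} the learnable prototype matrix
(one row per known class) and μ = (1/K) Σ_k m_k the derived center. μ is
*never* stored: every read recomputes it from the live M, and gradients
taken through μ flow into M. A sample is scored by its unsquared Euclidean
distance to the nearest prototype; distances inside softmax-style losses
are squared (‖·‖₂²), matching the two conventions' different roles —
squared distances make the softmax terms smooth and cheap, while the
decision score and the anchor radius stay in interpretable ℓ₂ units.

### Stage 1 — known-space initialization

Joint minimization over (E, M) of

    L_KSI = mean L_DCE + α₁ · mean L_P + β₁ · L_sep

- L_DCE(z, k) = −log softmax_k(−γ‖z−m_j‖²): cross entropy over a
  distance-based softmax; computed through a max-subtracted log-sum-exp so
  arbitrary distances give finite values. γ (assignment hardness) defaults
  to 1.0; it is exposed in `LossWeights` but no published value exists.
- L_P(z, k) = ‖z−m_k‖²: intra-class contraction.
- L_sep = max_i −log(max(‖m_i−μ‖², ε)): a max-over-prototypes penalty that
  pushes the prototype currently nearest μ radially outward. Successive
  argmax switches inflate the whole hypersphere. ε = 1e-8 keeps the loss
  finite if a prototype ever coincides with μ (the clamp zeroes the direct
  gradient there; the prototype still moves through the other terms).

Weights α₁ = β₁ = 0.1. Batch reduction is the mean for all per-sample
terms (the per-sample definitions leave reduction open; the mean makes
loss values batch-size invariant).

### Stage 2 — unknown anchor generation

With E and M frozen (asserted bit-identical before/after), a generator G
and discriminator D are trained with the original non-saturating GAN
objectives — D minimizes −log σ(D(real)) − log(1−σ(D(fake))), G minimizes
−log σ(D(G(·))) — plus λ · L_cyc with L_cyc = ‖E(G(E(X))) − E(X)‖₂
(unsquared) and λ = 1. G's input is the embedding E(X) of a real training
image, not Gaussian noise, so G learns specifically to invert E on the data
manifold; one D step per G step, Adam on both.

Anchors: a candidate f = E(X_i) + δ perturbs a uniformly drawn training
sample's embedding. δ has direction uniform on the unit sphere and norm
uniform on (0, δ_max]; only the norm bound is prescribed, and this is the
maximum-entropy completion. δ_max = 0.2 by default (an alternative reading
of the published setup suggests 0.1; both are config values). Acceptance
probability P = min(min_k ‖f−m_k‖₂/r, 1) with r the 70th-percentile
("higher" order statistic: the smallest observed value covering ≥ 70% of
the sample — pinned so tests are bit-stable) of training nearest-prototype
ℓ₂ distances. Both P and r use unsquared distances for internal
consistency. Sampling repeats until the accepted count equals the number of
training images; anchors are generated once and held fixed through
refinement. A guard aborts if fewer than 1% of the trailing 10⁴ proposals
are accepted (r mis-scaled against δ_max).

### Stage 3 — centralized-space refinement

    L_CSR = mean L_DCE + α₂ · mean L_P + β₂ · L_sep + θ · mean L_c

with α₂ = 0.1, β₂ = 0.01, θ = 0.1. The cluster penalty on an anchor
embedding z = E(G(f̂)) is, by default, a (K+1)-way distance softmax

    L_c(z) = −log [ exp(−γ d(z,μ)) / (exp(−γ d(z,μ)) + Σ_i exp(−γ d(z,m_i))) ]

which decreases as z approaches μ and moves away from every prototype. An
alternative algebraic form of this penalty reduces to −γ Σ_i d(z, m_i),
which is unbounded below and cannot serve as a clustering objective; it is
retained behind `mode="literal"` for auditability and is exercised by
a test, but never used in training.

Gradient routing: the cluster term sees a *detached* copy of M (hence a
detached μ), so prototypes learn only from the known-sample terms while the
embedder learns from all four. This resolves an ambiguity in which
parameters the cluster term trains; `cluster_grad_to_prototypes=True`
restores full coupling for experimentation. Each refinement step draws one
known batch and one equal-size proxy-image batch (batch composition was
open; equal sizes keep the θ-weighted term's scale stable). Proxy images
are re-embedded by the live E every step.

### Ablation variant modes

- `init_only` — stop after stage 1 (the initialization-only baseline).
- `counter_centralized` — sign-flip the cluster term (push proxies outward
  past the known sphere instead of into the center).
- `random_push` — replace the cluster term with −log(min_k ‖z−m_k‖²),
  a pure push away from the nearest prototype with no target location; the
  −log form gives a force that diverges near a prototype and fades with
  distance, keeping the term bounded on any bounded domain.

## Evaluation

Unknown-as-positive convention throughout. AUROC is computed by the
rank/Mann–Whitney formulation (average ranks implement ties-as-½), exact up
to float rounding and invariant under monotone score transforms. F-measure
is the binary F1 of predicted-unknown vs truly-unknown, defined as 0 in
degenerate cases. Since no threshold policy is published and F-measure
comparisons are threshold-dominated, the rejection threshold defaults to
the 95th percentile ("higher" convention) of training-sample scores; AUROC,
which needs no threshold, is the primary metric. Closed-set accuracy is
nearest-prototype accuracy (ties to the smallest class id) on known
validation samples with no rejection applied.

## Synthetic benchmark

Each class is an anisotropic 2-D Gaussian blob: center (row, col),
orientation, aspect ratio, plus per-sample center/angle jitter and additive
pixel noise, clipped to [0,1]. Known-class centers are drawn in the left
half of the image, unknown-class centers in the right half, so known and
unknown classes are disjoint in parameter space by construction rather than
by accident of sampling.

The desk-scale condition (`SyntheticConfig.desk_scale` +
`TrainingConfig.desk_scale`) is 32×32 images, K=4 known / U=2 unknown
classes, 62 samples per class (an 80% known split gives exactly 200
training images), latent dimension 8, 15 initialization epochs, 2000 GAN
iterations, 10 refinement epochs. Noise σ = 0.2 places the task in a
non-saturated regime: classes remain separable (pixel-space 1-NN exceeds
0.95), but unknown detection is not already solved by an arbitrary
initialization, leaving measurable headroom for the refinement stage to
demonstrate its effect. Desk-scale learning rates are 1e-3 (stage 1) and
5e-4 (stage 3): the published rates belong to a 50/20-epoch schedule over a
pretrained backbone, and a from-scratch small CNN trained for 15 epochs at
those rates stalls far from convergence; the 2:1 stage-1:stage-3 ratio is
preserved. `TrainingConfig.full_scale` restores the published schedule
(50 epochs at 1e-4, 2×10⁴ GAN iterations, 20 epochs at 5e-5, ResNet-18
backbone, nine-layer GAN networks).

What passing tests on this benchmark show: the three-stage mechanism works
end to end — the initialization builds the intended geometry, the GAN's
cycle objective optimizes, rejection sampling is biased away from the class
clusters, refinement contracts proxy embeddings toward μ and improves
unknown-detection AUROC while preserving closed-set accuracy. What they do
not show: performance on real radiographs or dermoscopy images, robustness
to fine-grained class similarity or extreme class imbalance, or behaviour
with a pretrained backbone — blob classes are far more separable than real
medical images.

## Numerical infrastructure

All networks run on the package's own reverse-mode autodiff engine
(`cslearn.autodiff`): float64 tensors over numpy, conv/transposed-conv via
im2col/col2im with BLAS matmuls, iterative topological backward pass. The
small default backbone is conv(3×3)-ReLU-avgpool ×3 + linear head; a
CIFAR-style ResNet-18 (batch norm, eight basic blocks, trained from
scratch) is selectable. Prototypes initialize from N(0, I_d) with a fixed
seed (no published initialization exists). The GAN pair defaults to
4-layer, width-8 networks at desk scale. Optimizer is Adam with standard
moments (0.9, 0.999). Every stochastic component draws from a
`numpy.random.Generator` stream spawned from the single run seed, so a
(config, seed) pair reproduces datasets, training trajectories and reports
byte for byte.

Known degenerate cases: the cycle loss has an undefined gradient exactly at
zero (never reached in practice; its value is still correct); the
separation clamp zeroes the direct gradient of a prototype sitting exactly
on μ; `squared_distance_matrix` clamps tiny negative round-off at zero.
Ties in nearest-prototype classification break toward the smallest class
id.
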