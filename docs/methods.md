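# Methods

## Skeletal model and kinematic conventions

A model is a tree of rigid bodies rooted at the pelvis, each joint carrying
up to three rotational degrees of freedom (axis + angle + range), each
marker a fixed body-frame offset. Matrices act on column vectors and
transforms compose parent-to-child along the tree; all internal units are
meters and radians (millimeters and degrees appear only in files and
reports).

Conventions the formulation leaves open, fixed here:

- **Euler convention** for joint-frame orientations: intrinsic body-fixed
  X-then-Y-then-Z, `F(O) = Rx(o1) Ry(o2) Rz(o3)` — the convention of the
  musculoskeletal modeling software this schema mirrors.
- **Scale application**: the parent-side joint translation scales with the
  parent body's factors, the child-side translation with the child's, and a
  marker offset with its anchor body's. The default model is the all-ones
  baseline, so factors are applied directly.
- **Marker transform**: offsets are scaled (d̂, not the unscaled d⃗) and the
  supplied root transform is prepended, so outputs are root-relative world
  positions; the root transform's translation is zero in every pipeline
  here.
- **Joint position** (for the joint-position loss and metrics): the world
  origin of the joint's child body frame.
- **Out-of-range angles** raise a warning, never an error — the root
  (pelvis) coordinates are legitimately unbounded, and an iterative solver
  or a regressor may transiently leave the declared ranges.
- The axis-angle sequence with pre-rotated axes
  `R₃R₂R₁ = G(A₁,θ₁)G(A₂,θ₂)G(A₃,θ₃)` is implemented literally in
  `motion_transform` and as the equivalent intrinsic product in the batched
  chain; the identity is exact, and tests compare both against independent
  transcriptions.

## Differentiability

Every operation is a composition of smooth primitives. Rather than relying
on an automatic-differentiation framework, the layer exposes exact analytic
Jacobians: for a rotational coordinate the derivative of any downstream
point p is ω × (p − c), with ω the coordinate's current world axis and c
its joint-frame origin; scale derivatives chain linearly through the scaled
translations and marker offsets. `fk_jacobian` is verified against central
finite differences to ≤ 1e-5 relative error (observed ~1e-10) and drives
both the IK solver and gradient training of the direct regressor.

## Inverse kinematics

Per frame, a damped Gauss–Newton (Levenberg–Marquardt) iteration minimizes
the weighted squared marker error over the model coordinates plus three
unbounded root-joint angles (default marker weight 1.0, configurable).
Numerical choices: initial damping 1e-3, ×10 on rejection, ÷3 on
acceptance; at most 100 iterations; convergence when the step norm falls
below 1e-8 rad **or** the relative cost improvement falls below 1e-4 — the
latter matters when large systematic marker bias leaves an irreducible
residual and the solver would otherwise crawl along bound constraints.
Bounded coordinates are clipped into their ranges after each accepted step;
the root is parameterized by three unbounded angles, acceptable for an
iterative solver (the continuity concern that motivates predicting a full
rotation matrix applies to feed-forward regression, not to warm-started
optimization). Frames are warm-started from their predecessor; the first
frame starts at the neutral pose (range midpoints). The accepted-step
objective trace is non-increasing by construction.

**Rejection rule.** "Squared error above 2 cm" is read as a per-segment
marker RMS *distance* above 20 mm (cm is a length unit); all coordinates of
joints touching an offending segment are flagged invalid for that frame.
Segments with no observed marker in a frame yield an undefined residual and
are not flagged. In the comparison harness the pooled metrics are computed
over *all* frames for both paths — under 30–50 mm bias the rule would
disregard nearly every multi-step frame, and dropping them would make the
two paths incomparable; the flags remain available on every result.

**Scaling.** Each configured marker pair maps its mean observed distance /
default-model distance ratio to one body axis; pairs should lie on one body
so the distance is pose-invariant (the default configuration uses the
fixture's three axis-aligned pairs per body). Unconfigured axes inherit the
body's mean configured scale; unconfigured bodies the global mean. Recovery
is exact on noise-free data; under jitter the attainable tolerance is set
by the noise-to-pair-length ratio (σ√2 / (L√n) plus a σ²/L² norm-inflation
bias), which the tests assert per pair.

## Synthetic data

The generator stands in for a motion-capture corpus and defines the study
conditions:

- **Fixture**: a 17-body humanoid (pelvis, 3-segment spine by default —
  configurable up to the 9 segments of a vertebra-group model — head, and
  3-segment arms and legs), 38 bounded coordinates plus 3 unbounded pelvis
  coordinates, and 6 markers per body in axis-aligned pairs; longitudinal
  pairs are the bony-landmark subset. Three non-collinear markers per
  segment is the minimum to observe its orientation; six give the scaling
  stage one pair per axis.
- **Motion**: per-coordinate sinusoid banks (2 harmonics, 0.1–1 Hz,
  amplitudes bounded by 35 % of the half-range) about the range midpoint,
  sampled at 25 Hz; a slow (≤ 0.2 Hz, 0.25 rad) root rotation. An optional
  neutral hold plus smoothstep ramp models the calibration pose at the
  start of a recording without a discontinuity.
- **Corruption**: i.i.d. Gaussian jitter (default σ = 5 mm) plus a constant
  per-marker bias with direction uniform on the sphere and norm uniform in
  30–50 mm, mirroring the error magnitudes reported for image-based
  keypoint detectors; occlusion marks contiguous windows missing (off by
  default). All randomness flows through one seeded generator.

What the generator does **not** emulate: soft-tissue artifact (bias here is
constant in the world frame, not pose-dependent), camera projection and
self-occlusion geometry, heteroscedastic detector confidence, and real
movement repertoires. Passing tests therefore demonstrate correctness of
the computations and the *direction* of the direct-vs-multi-step effect
under systematic input bias — not clinical-grade accuracy on real video.

## The comparison harness

Each synthetic "subject" is one sequence with per-body, per-axis scales
drawn from 0.9–1.1 and its own bias draw; train and test use disjoint seed
streams, and both pipelines consume byte-identical test observations.
Evaluation skips the calibration window.

- **Multi-step**: scale from the (biased) calibration frames, optionally
  low-pass the markers (6 Hz), run sequence IK. Its angle error under bias
  is dominated by the systematic marker displacement it has no way to
  reject.
- **Direct**: a structured linear regressor maps marker features to all 38
  angles, 51 scale factors, and a 3×3 root matrix per frame. Features are
  within-body marker offsets (centroid-centered), body centroids relative
  to the parent body, their elementwise squares, and per-joint products
  between parent-side and child-side offsets — the span of the latter
  contains the entries of the parent-to-child relative rotation that joint
  angles are functions of. Each output row sees the global linear block
  plus its own joint's or body's nonlinear blocks (a locality mask), which
  keeps the estimator sample-efficient; this plays the role of the
  convolutional backbone at desk scale, and the optional input window plus
  6 Hz output smoothing stands in for the sequence network. Weights are
  initialized by masked ridge regression on the kinematic labels and
  fine-tuned with the composite loss (λ = 1.0, 2.0, 0.1, 0.06), whose
  position terms run through the forward-kinematics layer; gradients chain
  through the analytic Jacobian into a small Adam loop (200 steps, batch
  64, rate 3e-5 — chosen so the fine-tune monotonically reduces the
  training loss from the ridge initialization). During training the raw root
  matrix is applied linearly to the identity-root pose (an equivariant
  path, so no gradient flows through the SVD projection); at inference it
  is projected to the nearest rotation. The root is supervised only through
  the marker and joint position terms — the composite loss has no rotation
  term.
- **Problem sizes**: defaults of 30 training / 8 test sequences of 8 s at
  25 Hz on the 3-segment-spine fixture keep a full comparison within a few
  minutes on one CPU while leaving a stable margin between the two paths;
  the acceptance script uses 20/4 per seed for the same reason. Under the
  default bias the direct path reaches roughly 5–6° MAE versus roughly
  10–12° for the multi-step path; in the degenerate no-corruption regime
  the multi-step path is near-exact and the report flags the regime.

Known limitations: the regressor is linear-in-features and data-limited, so
its absolute errors are far from what a deep network achieves on real
datasets; a single composite-loss weighting is used rather than a
hyperparameter search; IK marker weights default to uniform because the
reference procedure does not specify them; and the harness trains one
estimator end-to-end rather than a per-frame stage refined by a separate
sequence model.
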