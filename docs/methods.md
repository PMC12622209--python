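# Methods

## Behavioral similarity from odd-one-out triplets

Each trial shows three items; the chosen odd item implicitly marks the other
two as similar.  The similarity estimate for an unordered pair is the
fraction of trials containing both items in which neither was chosen odd.
The denominator conditions on co-occurrence (not on all trials), so the
estimate is a proper conditional probability in [0, 1] regardless of how
triples were sampled.  Pairs that never co-occur are masked as unobserved and
excluded from every downstream statistic; nothing is imputed.  The diagonal is
always treated as unobserved.  Dissimilarity is d = 1 − S on observed pairs:
the simplest order-reversing map on [0, 1], chosen because only the ranks of
the distances enter any reported statistic.

The split-half reliability ceiling is the average, over random
half-partitions of the judgments, of the squared Spearman correlation between
the two halves' similarity estimates on their commonly observed pairs.  No
Spearman–Brown correction is applied; the plain squared split-half
correlation is the quantity reported.  Splits in which fewer than three
common pairs exist, or in which either half's estimates are constant (no
ordering information), are skipped; if every split is degenerate an error
asks for more data.  The default of 100 splits keeps the Monte-Carlo error of
the ceiling well below the effects measured against it.

## Geometry

All model similarities are cosine; the shared distance operator is
d(i, j) = 1 − ⟨z_i, z_j⟩ on ℓ2-normalized embeddings, which makes every
result invariant to per-item rescaling.  Candidate embeddings of very
different widths can be equalized by sparse random projection sized by the
Johnson–Lindenstrauss bound 4·ln(n)/(ε²/2 − ε³/3) at ε = 0.1, truncated
toward zero (3353 dimensions for 50 samples).  The projection matrix uses the
standard sparse construction: entries in {−1, 0, +1} with density 1/√p and
scale √(1/(density·k)).  Projection is deliberately a no-op when the input
is already at or below the target width.  Correlations between similarity
structures are Spearman (average ranks for ties) over the observed upper
triangle only.

## The adapter and its objective

The trainable object is a rank-r residual linear map on the frozen
embeddings, x ↦ x + s·B(Ax), with A (r×p) small random, B (p×r) zero at
initialization and s = 1/r.  This transfers the principle of low-rank
adaptation — identity at initialization, a small trainable parameter count
(2rp), a frozen backbone — to the embedding interface this package owns; it
is a methodological analog of inserting low-rank matrices into a
transformer's attention layers, not a replica of it, since no backbone is
present here.  Default rank 16.

Training combines:

* **Triplet hinge** max{0, d(anchor, positive) − d(anchor, negative) + γ},
  γ = 0.2.  Each judgment emits two triplets (both surviving items serve as
  anchor); this uses all the information in a trial and keeps the loss
  symmetric in the surviving pair.  Satisfied triplets lie in the flat region
  of the hinge and contribute no gradient.
* **Differentiable RSA**: on a sampled batch of K = 24 items with an M = 6
  gradient-carrying subset, the negative Pearson correlation between z-scored
  model and human distances over the observed pairs touching a carrier
  (C(K,2) − C(K−M,2) = 123 pairs before masking).  Pearson rather than
  Spearman is used inside the loss because it is differentiable; Spearman is
  used only at evaluation.  The z-scoring is mathematically redundant for the
  value (Pearson is affine-invariant) but stabilizes gradient magnitudes, and
  is kept.  By contract, gradients flow only through the M carriers; the
  other batch embeddings enter the distances as constants.  Steps with fewer
  than three observed pairs or zero variance are skipped and counted, not
  errors, so training proceeds on sparse judgment sets.
* **Schedule**: the RSA term activates at the ends of evenly spaced intervals
  (floor(steps_per_epoch / 6) apart), so the first RSA step never precedes
  every triplet step; when an epoch is shorter than six steps every step
  activates.  The combined loss is α·L_triplet + 𝟙·β·L_RSA with α = 0.7 and β
  ramped linearly per epoch from 0.3 to 0.7 (constant within an epoch; the
  ramp granularity was an open choice and per-epoch is the simplest reading).

Optimization is AdamW (decoupled weight decay 0.01 — a common default, logged
in the run manifest) at learning rate 1e-4 for 50 epochs with batches of 4
judgments (8 triplets) per step.  A batch counts judgments, not items.
Because the adapter is a single small linear map, gradients are computed in
closed form (chain rule through the cosine distances and the Pearson
correlation) rather than by automatic differentiation; the test suite checks
every gradient path against central finite differences at 1e-7 tolerance.

After each epoch the adapted RSM is scored against the RSM of a held-out 20%
judgment split (items are shared between the splits; judgments, not items,
are held out for checkpointing) by squared Spearman correlation, and the
best-epoch adapter state is returned, ties to the earliest epoch.  Epochs
where the validation correlation is undefined score 0.

**Ablation modes.** `triplet_only` forces the RSA indicator to 0;
`rsa_only` drops the triplet term and updates only on scheduled steps;
`budget_matched` is triplet-only granted one extra full triplet step per RSA
activation of the matched hybrid run — the control is named but not defined
in the literature this package follows, so "equal optimizer-step budget" is
the recorded assumption.  All randomness (adapter init, validation split,
batch order, RSA batch sampling) derives from a single seed through four
independent streams, so histories are bit-identical under a fixed seed, and
hybrid with β ≡ 0 reproduces triplet-only exactly.

## The synthetic world

The simulator defines the conditions under which every end-to-end claim is
tested.  A world has n items with q-dimensional standard-normal latent
factors; the true similarity is the cosine of the factors.  Choices follow a
Luce-style softmax: for a triple {i, j, k}, item k is odd with probability
∝ exp(S_true(i, j)/τ).  This is the standard forced-choice rule consistent
with the similarity estimator (more similar pairs survive together more
often); τ → 0 gives deterministic argmax choices, τ → ∞ uniform ones.
Candidate embeddings are a random linear observation of the factors
(32 informative dimensions by default) plus per-entry Gaussian noise and 64
pure-noise distractor dimensions — a representation that encodes the latent
structure only partially and noisily, as pretrained model embeddings do.
Attribute ratings (five by default, named after common social-affective
scales) are linear in the factors plus noise, z-scored per attribute.

The standard benchmark world used by the recovery tests has 60 items, q = 4,
τ = 0.1, 6 000 judgments, observation noise σ = 1.0 and 64 distractors, with
an 80/20 judgment split for held-out evaluation; sizes were chosen so the
full suite runs in minutes on one CPU while leaving clear headroom between
the baseline alignment (ρ² ≈ 0.2) and the reliability ceiling (ρ² ≈ 0.5).
What passing on this world shows: the estimator, objective, optimizer and
evaluation stack are mutually consistent and recover plantable structure.
What it does not show: anything about real human judgment data — real
choices are not softmax in a cosine similarity, real embeddings are not
linear observations of the latent structure, and annotator heterogeneity,
session effects and stimulus sampling bias are all absent.

## Evaluation machinery

* **OOO prediction**: the predicted odd item is the one absent from the
  most-similar pair; exact ties resolve to the lexicographically smallest
  candidate — deterministic reproducibility was preferred over unbiasedness
  on a measure-zero event.
* **Layer selection**: k-fold (default 5) cross-validation partitions items,
  not judgments; per fold the candidate RSM is scored on held-out items'
  jointly observed pairs, and the candidate with the best mean rho wins, ties
  to input order.
* **Variance partitioning**: commonality analysis on rank-transformed
  observed distance vectors (consistent with the Spearman-based headline
  metric): OLS fits of the human ranks on {a}, {b}, {a, b} give R²_a, R²_b,
  R²_ab; unique_a = R²_ab − R²_b, unique_b = R²_ab − R²_a,
  shared = R²_a + R²_b − R²_ab.  The components sum to R²_ab by construction
  (asserted to 1e-10).  Negative shared variance (suppression) is reported
  and flagged, never clipped; exact predictor collinearity is flagged via the
  design-matrix rank.
* **Attribute probes**: ridge regression with the penalty chosen by 5-fold
  cross-validation on the training items over a log-spaced grid 1e-3 … 1e3
  (7 values; the grid is a package default, not a literature value), refit on
  all training items, scored by Pearson r on disjoint test items.

## Numerical choices and limitations

Cosine computations guard zero-norm rows with informative errors; RSM values
are clipped to [−1, 1] and symmetrized against floating-point drift.  The
similarity container enforces symmetry to 1e-12.  Matrix text serialization
writes masked cells as `NA`.

Known limitations: the adapter acts on embeddings, not inside the network
that produced them, so it cannot reshape features that were never extracted;
the choice simulator models a single consensus participant; the behavioral
estimator weighs every trial equally (no participant reliability weighting);
and the budget-matched control depends on the step-budget assumption stated
above.
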