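# repalign

Align an embedding space with human similarity judgments from the triplet
odd-one-out (OOO) task.

When people repeatedly pick the "odd one out" of three items, the remaining
pair is implicitly marked as similar, and the aggregate choices induce a
behavioral representational similarity matrix (RSM).  `repalign` is for
researchers in computational cognitive science and representational alignment
who want to (1) estimate that behavioral similarity structure from raw triplet
tables, (2) measure how well a candidate embedding space (a vision model
layer, a sentence-embedding of captions, ...) reproduces it, and (3) nudge a
frozen embedding space toward it with a small trainable adapter.

## The model

**Behavioral similarity.**  For items $i, j$, the similarity estimate is the
probability that they were judged together,

$$S^{\text{human}}_{ij} = \Pr(\text{neither } i \text{ nor } j \text{ chosen odd} \mid i, j \text{ co-occurred}),$$

with never co-occurring pairs masked, never imputed.  Model similarity is
cosine, $S^{\text{model}}_{ij} = \cos(f(v_i), f(v_j))$, with the shared
distance operator $d(i,j) = 1 - \langle z_i, z_j \rangle$ on the
$\ell_2$-normalized embeddings $z$.

**The adapter.**  A rank-$r$ residual linear map over the frozen embeddings,
$x \mapsto x + s\,B(Ax)$ with $B = 0$ at initialization (so it starts as the
identity), trained with a hybrid objective:

- **Triplet loss** (local): for each judgment with surviving pair $(i, j)$ and
  odd item $k$, $\;\mathcal{L}_{\text{triplet}} = \max\{0,\, d(i,j) - d(i,k) + \gamma\}$
  with margin $\gamma = 0.2$;
- **RSA loss** (global), injected 6 times per epoch: on a sampled batch of
  $K = 24$ items with $M = 6$ gradient carriers, the negative Pearson
  correlation between z-scored model and human distances over the observed
  pairs touching a carrier (up to 123 pairs before masking);
- combined as
  $\mathcal{L} = \alpha\,\mathcal{L}_{\text{triplet}} + \mathbb{1}_{\text{RSA}}(t)\,\beta\,\mathcal{L}_{\text{RSA}}$
  with $\alpha = 0.7$ and $\beta$ ramped linearly $0.3 \to 0.7$ over epochs,
  optimized with AdamW (lr $10^{-4}$, 50 epochs, batches of 4 judgments),
  checkpointed by held-out squared Spearman correlation.

**Evaluation** reports Spearman's $\rho$ between model and behavioral RSMs
(and $\rho^2$ as explained variance), OOO prediction accuracy, the split-half
reliability ceiling of the behavioral data, variance partitioning
(commonality analysis) between two candidate representations, cross-validated
layer selection, and ridge linear probes for per-item attribute ratings.

A built-in simulator generates ground-truth latent worlds (factors, softmax
choice model with temperature $\tau$, partially informative noisy embeddings,
attribute ratings) so the whole pipeline is testable end to end without any
data downloads.

## Worked example

```python
import repalign as ra

world = ra.make_world(n_items=60, q=4, tau=0.1, seed=7)
sim = ra.SimulationConfig(n_triplets=6000, seed=7, noise_scale=1.0, distractor_dims=64)
judgments = ra.simulate_judgments(world, sim)
embeddings = ra.make_embeddings(world, sim)          # noisy, partial view of the latent factors
train_js, eval_js = ra.split_judgments(judgments, 0.2, seed=7)

model = ra.AdapterAlignment(embeddings, train_js, ra.TrainConfig(seed=7))
res = model.fit()
print(res.summary(eval_js=eval_js))
print("noise ceiling:", round(res.noise_ceiling(n_splits=20, seed=7), 4))
```

prints

```
Adapter alignment results
============================================================
items: 60    embedding width: 96
judgments: 4800    mode: hybrid
adapter rank: 16    trainable params: 3072 (34.78% of params incl. frozen embeddings)
epochs: 50    batch size: 4 judgments    lr: 0.0001
best epoch: 49    validation rho^2: 0.5096
optimizer steps: 48000    skipped RSA steps: 0
------------------------------------------------------------
held-out rho^2:  base 0.2137  ->  adapted 0.5230
held-out OOO accuracy:  base 0.6125  ->  adapted 0.8692
(on 1540 pairs, 1200 triplets)
noise ceiling: 0.5096
```

The noisy base embeddings explain ρ² ≈ 0.21 of the held-out behavioral
similarity and predict 61% of held-out odd-one-out choices; after hybrid
adapter training the same (frozen) embeddings explain ρ² ≈ 0.52 — at the
split-half reliability ceiling of the simulated judgments (≈ 0.51) — and
predict 87% of choices.  The identity-initialized adapter guarantees the
"before" numbers are exactly the base model's.

The same pipeline is available from the shell:

```bash
repalign simulate --n-items 60 --q 4 --triplets 6000 --tau 0.1 --seed 7 --out world/
repalign train --embeddings world/embeddings.csv --triplets world/triplets.csv --out run/
repalign evaluate --embeddings world/embeddings.csv --adapter run/adapter.npz \
                  --triplets world/triplets.csv --out report.json
```

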