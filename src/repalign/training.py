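"""Training loop for the low-rank adapter under the hybrid triplet-RSA objective.

Gradients are computed in closed form.  For a step's items X (rows gathered
from the frozen base embeddings), the adapter output is Y = X + s X A^T B^T and
every loss term depends on X only through cosine distances of rows of Y.  With
z_i = y_i / ||y_i|| and d(i, j) = 1 - <z_i, z_j>,

    d d(i,j) / d y_i = -(z_j - <z_i, z_j> z_i) / ||y_i||,

and the chain rule to the adapter parameters gives, for per-row gradients G,

    dL/dA = s B^T (G^T X),      dL/dB = s G^T (X A^T).

The RSA term backpropagates only through the designated gradient-carrying
subset of the sampled batch; all other batch embeddings enter the model
distances as constants.  Parameters are updated with decoupled-weight-decay
Adam.  These gradients are verified against finite differences in the test
suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from .adapter import AdamW, LowRankAdapter, init_adapter
from .geometry import EmbeddingSet, rank_correlation, rsm_from_embeddings, joint_observed_upper
from .judgments import (
    DissimilarityMatrix,
    JudgmentSet,
    ValidationError,
    estimate_similarity,
    similarity_to_rdm,
    split_indices,
)
from .losses import (
    LossConfig,
    beta_at,
    build_rsa_batch,
    judgment_to_triplet,
    rsa_loss_grad,
    rsa_step_indices,
)

MODES = ("hybrid", "triplet_only", "rsa_only", "budget_matched")


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings for adapter training.

    batch_size counts judgments per optimizer step (each judgment expands to
    two training triplets).  mode selects the objective ablation: full hybrid,
    triplet-only, RSA-only (updates only on scheduled steps), or the
    budget-matched control (triplet-only granted extra triplet steps equal in
    number to the hybrid run's RSA activations).
    """

    learning_rate: float = 1e-4
    epochs: int = 50
    batch_size: int = 4
    seed: int = 0
    mode: str = "hybrid"
    validation_fraction: float = 0.2
    rank: int = 16
    weight_decay: float = 0.01
    loss: LossConfig = field(default_factory=LossConfig)

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValidationError(f"mode must be one of {MODES}, got {self.mode!r}")
        if not 0.0 < self.validation_fraction < 1.0:
            raise ValidationError("validation_fraction must lie in (0, 1)")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValidationError("epochs and batch_size must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        d = dict(d)
        if "loss" in d and isinstance(d["loss"], dict):
            d["loss"] = LossConfig(**d["loss"])
        return cls(**d)


@dataclass(frozen=True)
class StepRecord:
    step: int
    epoch: int
    triplet_term: Optional[float]
    rsa_term: Optional[float]
    total: float


@dataclass
class TrainingHistory:
    """Per-step loss records and the per-epoch validation trace.

    validation_scores holds one squared Spearman correlation (adapted-model
    RSM vs the held-out-judgment RSM) per epoch; best_epoch maximizes it with
    ties resolved to the earliest epoch.  Epochs whose validation correlation
    is undefined (too few observed pairs, zero variance) score 0.0.
    """

    steps: list[StepRecord] = field(default_factory=list)
    validation_scores: list[float] = field(default_factory=list)
    skipped_rsa_steps: int = 0

    @property
    def best_epoch(self) -> int:
        return select_checkpoint(self)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame([asdict(s) for s in self.steps])


def select_checkpoint(history: TrainingHistory) -> int:
    """Epoch maximizing the validation score; ties go to the earliest epoch."""
    scores = history.validation_scores
    if not scores:
        raise ValidationError("empty training history")
    return int(np.argmax(scores))


def _forward(X: np.ndarray, adapter: LowRankAdapter) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    Y = adapter.transform(X)
    norms = np.linalg.norm(Y, axis=1)
    if np.any(norms == 0.0):
        raise ValidationError("adapter produced a zero-norm embedding")
    return Y, Y / norms[:, None], norms


def triplet_step_loss_and_grads(
    X: np.ndarray, adapter: LowRankAdapter, triplets: np.ndarray, margin: float
) -> tuple[float, np.ndarray, np.ndarray]:
    """Mean triplet hinge loss over rows of ``triplets`` and its row gradients.

    Returns (loss, unique_row_indices, G) where G holds dL/dy for the adapter
    outputs of the unique items touched by the step.
    """
    uniq, inv = np.unique(triplets, return_inverse=True)
    Xu = X[uniq]
    _, Z, norms = _forward(Xu, adapter)
    inv = inv.reshape(triplets.shape)
    ia, ip, ineg = inv[:, 0], inv[:, 1], inv[:, 2]
    za, zp, zn = Z[ia], Z[ip], Z[ineg]
    sp = np.sum(za * zp, axis=1)
    sn = np.sum(za * zn, axis=1)
    viol = (sn - sp) + margin  # = d_pos - d_neg + margin
    active = viol > 0
    T = triplets.shape[0]
    loss = float(np.sum(np.maximum(viol, 0.0)) / T)
    G = np.zeros_like(Xu)
    if np.any(active):
        w = active.astype(float)[:, None] / T
        na = norms[ia][:, None]
        npn = norms[ip][:, None]
        nn = norms[ineg][:, None]
        # d_pos contributes +1, d_neg contributes -1 to the hinge argument
        g_a = w * (-(zp - sp[:, None] * za) / na + (zn - sn[:, None] * za) / na)
        g_p = w * (-(za - sp[:, None] * zp) / npn)
        g_n = w * ((za - sn[:, None] * zn) / nn)
        np.add.at(G, ia, g_a)
        np.add.at(G, ip, g_p)
        np.add.at(G, ineg, g_n)
    return loss, uniq, G


def rsa_step_loss_and_grads(
    X: np.ndarray,
    adapter: LowRankAdapter,
    pairs: list[tuple[int, int]],
    grad_items: np.ndarray,
    human_rdm: DissimilarityMatrix,
) -> Optional[tuple[float, np.ndarray, np.ndarray]]:
    """RSA loss over masked batch pairs and gradients for grad-carrying items.

    Returns None (skip) on degenerate steps: fewer than 3 masked pairs or zero
    variance in either distance vector.
    """
    if len(pairs) < 3:
        return None
    pi = np.array([p[0] for p in pairs])
    pj = np.array([p[1] for p in pairs])
    uniq, inv = np.unique(np.concatenate([pi, pj]), return_inverse=True)
    Xu = X[uniq]
    _, Z, norms = _forward(Xu, adapter)
    li = inv[: len(pairs)]
    lj = inv[len(pairs) :]
    zi, zj = Z[li], Z[lj]
    s_ij = np.sum(zi * zj, axis=1)
    model_d = 1.0 - s_ij
    human_d = human_rdm.values[pi, pj]
    if model_d.std() == 0.0 or human_d.std() == 0.0:
        return None
    loss, dmd = rsa_loss_grad(model_d, human_d)
    grad_set = set(int(g) for g in grad_items)
    in_g_i = np.array([int(g) in grad_set for g in pi])
    in_g_j = np.array([int(g) in grad_set for g in pj])
    G = np.zeros_like(Xu)
    # d model_d_t / d y_i = -(z_j - s z_i)/||y_i||; only grad-carrying items accumulate
    gi = -dmd[:, None] * (zj - s_ij[:, None] * zi) / norms[li][:, None]
    gj = -dmd[:, None] * (zi - s_ij[:, None] * zj) / norms[lj][:, None]
    np.add.at(G, li[in_g_i], gi[in_g_i])
    np.add.at(G, lj[in_g_j], gj[in_g_j])
    return loss, uniq, G


def _param_grads(
    X_rows: np.ndarray, G: np.ndarray, adapter: LowRankAdapter
) -> tuple[np.ndarray, np.ndarray]:
    """Chain per-row output gradients G to (dL/dA, dL/dB)."""
    s = adapter.scale
    gA = s * adapter.up_map.T @ (G.T @ X_rows)
    gB = s * G.T @ (X_rows @ adapter.down_map.T)
    return gA, gB


def train(
    base: EmbeddingSet, js_train: JudgmentSet, cfg: TrainConfig
) -> tuple[LowRankAdapter, TrainingHistory]:
    """Fit a low-rank adapter to odd-one-out judgments over frozen embeddings.

    Splits off a validation fraction of the judgments, builds the training
    human RDM for the RSA term, then runs the scheduled hybrid objective with
    AdamW.  Returns the adapter state from the epoch with the best validation
    squared Spearman correlation, plus the full training history.  Fully
    reproducible under ``cfg.seed``; the base embeddings are never modified.
    """
    known = set(base.items)
    unknown = sorted({it for j in js_train.judgments for it in j.items if it not in known})
    if unknown:
        raise ValidationError(f"judgments reference items without embeddings: {unknown[:5]}")
    if not js_train.judgments:
        raise ValidationError("cannot train on an empty judgment set")

    lc = cfg.loss
    uses_rsa = cfg.mode in ("hybrid", "rsa_only")
    catalogue = list(js_train.catalogue)
    if uses_rsa and len(catalogue) < lc.rsa_batch:
        raise ValidationError(
            f"RSA batch size K={lc.rsa_batch} exceeds the catalogue size {len(catalogue)}"
        )

    master = np.random.default_rng(cfg.seed)
    seed_init, seed_split, seed_batch, seed_rsa = (int(s) for s in master.integers(0, 2**31, size=4))
    rng_batch = np.random.default_rng(seed_batch)
    rng_rsa = np.random.default_rng(seed_rsa)

    fit_indices, val_indices = split_indices(
        len(js_train.judgments), cfg.validation_fraction, seed_split
    )
    if fit_indices.size == 0:
        raise ValidationError("validation split consumed all judgments")
    fit_js = JudgmentSet([js_train.judgments[k] for k in fit_indices], catalogue)
    val_js = JudgmentSet([js_train.judgments[k] for k in val_indices], catalogue)
    human_rdm = similarity_to_rdm(estimate_similarity(fit_js)) if uses_rsa else None
    val_sm = estimate_similarity(val_js) if val_js.judgments else None

    E = base.subset(catalogue)
    X = E.matrix
    base_checksum = X.tobytes()
    index = {it: k for k, it in enumerate(catalogue)}
    tri_per_judgment = [
        [tuple(index[x] for x in t) for t in judgment_to_triplet(j)] for j in js_train.judgments
    ]
    n_fit = len(fit_indices)
    steps_per_epoch = int(np.ceil(n_fit / cfg.batch_size))
    schedule = rsa_step_indices(steps_per_epoch, lc.rsa_steps_per_epoch)
    n_activations = min(lc.rsa_steps_per_epoch, steps_per_epoch)

    adapter = init_adapter(base.width, cfg.rank, seed_init)
    opt = AdamW(
        [adapter.down_map, adapter.up_map],
        lr=cfg.learning_rate,
        weight_decay=cfg.weight_decay,
    )
    history = TrainingHistory()
    best_score = -np.inf
    best_adapter = adapter.copy()
    global_step = 0

    for epoch in range(cfg.epochs):
        beta = beta_at(epoch, cfg.epochs, lc.beta_start, lc.beta_end)
        order = rng_batch.permutation(n_fit)
        if cfg.mode == "budget_matched":
            # one extra full triplet step per RSA activation of the matched hybrid run
            extra = np.resize(order, n_activations * cfg.batch_size)
            order = np.concatenate([order, extra])
        n_steps = int(np.ceil(order.size / cfg.batch_size))
        for step in range(n_steps):
            batch = order[step * cfg.batch_size : (step + 1) * cfg.batch_size]
            tri = np.array(
                [t for k in batch for t in tri_per_judgment[fit_indices[k]]], dtype=int
            )
            rsa_due = (
                uses_rsa
                and step in schedule
                and beta != 0.0
            )

            triplet_term: Optional[float] = None
            rsa_term: Optional[float] = None
            gA = np.zeros_like(adapter.down_map)
            gB = np.zeros_like(adapter.up_map)

            if cfg.mode != "rsa_only":
                t_loss, uniq, G = triplet_step_loss_and_grads(X, adapter, tri, lc.margin)
                triplet_term = t_loss
                ga, gb = _param_grads(X[uniq], G, adapter)
                gA += lc.alpha * ga
                gB += lc.alpha * gb

            if rsa_due:
                rb = build_rsa_batch(catalogue, human_rdm, lc.rsa_batch, lc.grad_subset, rng_rsa)
                out = rsa_step_loss_and_grads(X, adapter, rb.masked_pairs, rb.grad_items, human_rdm)
                if out is None:
                    history.skipped_rsa_steps += 1
                else:
                    r_loss, uniq_r, Gr = out
                    rsa_term = r_loss
                    ga, gb = _param_grads(X[uniq_r], Gr, adapter)
                    gA += beta * ga
                    gB += beta * gb

            if cfg.mode == "rsa_only" and rsa_term is None:
                # off-schedule or degenerate: no optimizer step in this mode
                if rsa_due:
                    global_step += 1
                continue

            total = lc.alpha * (triplet_term or 0.0) if cfg.mode != "rsa_only" else 0.0
            if rsa_term is not None:
                total += beta * rsa_term
            opt.step([gA, gB])
            history.steps.append(
                StepRecord(step=global_step, epoch=epoch, triplet_term=triplet_term,
                           rsa_term=rsa_term, total=float(total))
            )
            global_step += 1

        score = _validation_score(E, adapter, val_sm)
        history.validation_scores.append(score)
        if score > best_score:
            best_score = score
            best_adapter = adapter.copy()

    if X.tobytes() != base_checksum:
        raise RuntimeError("frozen base embeddings were modified during training")
    return best_adapter, history


def _validation_score(E: EmbeddingSet, adapter: LowRankAdapter, val_sm) -> float:
    """Squared Spearman between the adapted RSM and the validation-judgment RSM.

    Scores 0.0 when the correlation is undefined on the validation pairs.
    """
    if val_sm is None:
        return 0.0
    adapted = EmbeddingSet(items=list(E.items), matrix=adapter.transform(E.matrix))
    model_sm = rsm_from_embeddings(adapted)
    try:
        mv, hv = joint_observed_upper(model_sm, val_sm)
        rho = rank_correlation(mv, hv)
    except ValidationError:
        return 0.0
    return float(rho**2)
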