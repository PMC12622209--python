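"""The hybrid training objective.

Two complementary supervision signals derived from odd-one-out judgments:

* a **triplet margin loss** enforcing, per trial, that the surviving pair sits
  closer together (in cosine distance) than either member sits to the odd item,
  by a margin gamma;
* a **differentiable RSA loss**, the negative Pearson correlation between
  z-scored model and human distances over a sampled batch of item pairs,
  injected on a sparse schedule to shape the global geometry.

The hybrid loss is alpha * L_triplet plus, on scheduled steps only,
beta * L_RSA, with beta linearly ramped over epochs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .judgments import DissimilarityMatrix, TripletJudgment, ValidationError


@dataclass(frozen=True)
class LossConfig:
    """Hyperparameters of the hybrid objective.

    margin : hinge margin gamma of the triplet loss (cosine-distance units).
    alpha : weight of the triplet term.
    beta_start, beta_end : endpoints of the linear per-epoch ramp on the RSA weight.
    rsa_batch : K, number of items sampled per RSA step.
    grad_subset : M, number of sampled items whose embeddings carry gradients.
    rsa_steps_per_epoch : number of evenly spaced RSA activations per epoch.
    """

    margin: float = 0.2
    alpha: float = 0.7
    beta_start: float = 0.3
    beta_end: float = 0.7
    rsa_batch: int = 24
    grad_subset: int = 6
    rsa_steps_per_epoch: int = 6

    def __post_init__(self) -> None:
        if self.margin < 0:
            raise ValidationError("margin must be >= 0")
        if not 0 < self.grad_subset <= self.rsa_batch:
            raise ValidationError("need 0 < grad_subset <= rsa_batch")
        if self.rsa_steps_per_epoch < 1:
            raise ValidationError("rsa_steps_per_epoch must be >= 1")


@dataclass(frozen=True)
class RsaBatch:
    """One RSA step's sampled structure.

    ``pair_list`` holds all unordered pairs within the K sampled items that
    touch at least one gradient-carrying item; ``masked_pairs`` restricts to
    pairs with an observed human distance.  Indices refer to the catalogue.
    """

    batch_items: np.ndarray
    grad_items: np.ndarray
    pair_list: list[tuple[int, int]]
    masked_pairs: list[tuple[int, int]]


def pair_count(K: int, M: int) -> int:
    """Number of unordered pairs within K items touching an M-subset: C(K,2) - C(K-M,2)."""
    return K * (K - 1) // 2 - (K - M) * (K - M - 1) // 2


def triplet_loss(d_pos: float, d_neg: float, margin: float = 0.2) -> float:
    """Hinge penalty max(0, d_pos - d_neg + margin)."""
    return max(0.0, d_pos - d_neg + margin)


def judgment_to_triplet(j: TripletJudgment) -> list[tuple[str, str, str]]:
    """Expand a judgment into (anchor, positive, negative) training triplets.

    The odd item is the negative; both orderings of the surviving pair serve
    as (anchor, positive), so each judgment yields two triplets and the loss
    stays symmetric in the surviving pair.
    """
    pos_a, pos_b = j.surviving_pair
    return [(pos_a, pos_b, j.odd), (pos_b, pos_a, j.odd)]


def build_rsa_batch(
    catalogue: list[str],
    human_rdm: DissimilarityMatrix,
    K: int,
    M: int,
    rng: np.random.Generator | int,
) -> RsaBatch:
    """Sample K items, designate M gradient carriers, enumerate touched pairs.

    ``masked_pairs`` keeps only pairs whose human dissimilarity is observed
    (pairs without judgments are masked out).
    """
    if K > len(catalogue):
        raise ValidationError(f"rsa_batch K={K} exceeds catalogue size {len(catalogue)}")
    if human_rdm.items != list(catalogue):
        raise ValidationError("human RDM items must match the catalogue (same order)")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    batch = rng.choice(len(catalogue), size=K, replace=False)
    grad = rng.choice(batch, size=M, replace=False)
    grad_set = set(int(g) for g in grad)
    pairs: list[tuple[int, int]] = []
    for a in range(K):
        for b in range(a + 1, K):
            i, j = int(batch[a]), int(batch[b])
            if i in grad_set or j in grad_set:
                pairs.append((i, j))
    masked = [(i, j) for (i, j) in pairs if human_rdm.observed[i, j]]
    return RsaBatch(batch_items=batch, grad_items=grad, pair_list=pairs, masked_pairs=masked)


def rsa_loss(model_d: np.ndarray, human_d: np.ndarray) -> float:
    """Negative Pearson correlation between z-scored distance vectors.

    Both vectors are standardized to zero mean and unit variance before the
    correlation; this is value-neutral (Pearson is affine-invariant) but keeps
    gradient magnitudes stable during training.
    """
    model_d = np.asarray(model_d, dtype=float)
    human_d = np.asarray(human_d, dtype=float)
    if model_d.size < 3:
        raise ValidationError("rsa_loss needs >= 3 masked pairs")
    sm = model_d.std()
    sh = human_d.std()
    if sm == 0.0 or sh == 0.0:
        raise ValidationError("rsa_loss undefined for zero-variance distances")
    zm = (model_d - model_d.mean()) / sm
    zh = (human_d - human_d.mean()) / sh
    return float(-np.mean(zm * zh))


def rsa_loss_grad(model_d: np.ndarray, human_d: np.ndarray) -> tuple[float, np.ndarray]:
    """rsa_loss and its gradient with respect to the model distance vector.

    With rho = mean(zm * zh) and population std sigma_m,
    d(-rho)/d(model_d_i) = -(zh_i - rho * zm_i) / (N * sigma_m).
    """
    model_d = np.asarray(model_d, dtype=float)
    human_d = np.asarray(human_d, dtype=float)
    n = model_d.size
    sm = model_d.std()
    sh = human_d.std()
    if n < 3 or sm == 0.0 or sh == 0.0:
        raise ValidationError("degenerate RSA step")
    zm = (model_d - model_d.mean()) / sm
    zh = (human_d - human_d.mean()) / sh
    rho = float(np.mean(zm * zh))
    grad = -(zh - rho * zm) / (n * sm)
    return -rho, grad


def rsa_step_indices(steps_per_epoch: int, n_rsa: int) -> set[int]:
    """Evenly spaced 0-based step indices at which the RSA loss activates.

    With interval = floor(steps_per_epoch / n_rsa) >= 1 the activations sit at
    the ends of consecutive intervals, so the first RSA step never precedes
    every triplet step; when the epoch is shorter than n_rsa steps, every step
    activates.  Exactly min(n_rsa, steps_per_epoch) activations result.
    """
    if steps_per_epoch < 1:
        raise ValidationError("steps_per_epoch must be >= 1")
    interval = steps_per_epoch // n_rsa
    if interval >= 1:
        return {k * interval - 1 for k in range(1, n_rsa + 1)}
    return set(range(steps_per_epoch))


def beta_at(epoch: int, total_epochs: int, beta_start: float = 0.3, beta_end: float = 0.7) -> float:
    """Linear per-epoch ramp of the RSA weight from beta_start to beta_end."""
    if total_epochs < 2:
        return beta_end
    if not 0 <= epoch < total_epochs:
        raise ValidationError(f"epoch {epoch} outside [0, {total_epochs})")
    return beta_start + (beta_end - beta_start) * epoch / (total_epochs - 1)


def hybrid_loss(
    step: int,
    triplet_term: float,
    rsa_term: float | None,
    alpha: float,
    beta: float,
    schedule: set[int],
) -> float:
    """alpha * L_triplet + indicator(step in schedule) * beta * L_RSA."""
    on_schedule = step in schedule
    if rsa_term is not None and not on_schedule:
        raise ValidationError(f"rsa_term supplied at off-schedule step {step}")
    total = alpha * triplet_term
    if on_schedule and rsa_term is not None:
        total += beta * rsa_term
    return total
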