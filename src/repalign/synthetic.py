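"""Synthetic ground-truth worlds for end-to-end testing without any downloads.

A world has n items with latent factor vectors (low-dimensional "social
dimensions"); the true similarity structure is the cosine similarity of the
factors.  Simulated participants answer odd-one-out trials with a Luce-style
softmax rule: for a triple {i, j, k}, item k is chosen odd with probability
proportional to exp(S_true(i, j) / tau) — the more similar the surviving pair,
the more likely the third item is called odd.  tau -> 0 gives deterministic
choices, tau -> infinity uniform ones.

Candidate "pretrained" embeddings observe the factors only partially and
noisily: a linear observation map plus Gaussian noise, concatenated with pure
noise distractor dimensions.  Attribute ratings are linear in the factors plus
noise, z-scored per attribute.

Defaults emulate the statistical structure of the behavioral study this
package targets at desk scale: a few dozen to a few hundred items, thousands
of random-triplet trials, choices driven by a latent low-dimensional
similarity structure that the candidate embeddings encode imperfectly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import EmbeddingSet, rsm_from_embeddings
from .judgments import JudgmentSet, SimilarityMatrix, TripletJudgment, ValidationError

DEFAULT_ATTRIBUTES = ("intimacy", "valence", "arousal", "dominance", "communication")


@dataclass
class LatentWorld:
    """Ground truth: latent factors, true similarity, attribute loadings, temperature."""

    n_items: int
    factors: np.ndarray  # (n, q)
    true_rsm: SimilarityMatrix
    attribute_loadings: np.ndarray  # (q, m)
    temperature: float
    items: list[str] = field(default_factory=list)

    @property
    def q(self) -> int:
        return self.factors.shape[1]


@dataclass(frozen=True)
class SimulationConfig:
    """How trials and candidate embeddings are generated from a world.

    observation_map (p_informative x q) determines how embeddings see the
    latent factors; noise_scale is the per-entry Gaussian observation noise;
    distractor_dims appends pure-noise columns carrying no signal.
    """

    n_triplets: int
    seed: int = 0
    observation_map: np.ndarray | None = None
    noise_scale: float = 1.0
    distractor_dims: int = 64

    def __post_init__(self) -> None:
        if self.n_triplets < 1:
            raise ValidationError("n_triplets must be >= 1")
        if self.noise_scale < 0:
            raise ValidationError("noise_scale must be >= 0")


def make_world(
    n_items: int = 60, q: int = 4, m: int = 5, tau: float = 0.1, seed: int = 0
) -> LatentWorld:
    """Sample a seeded latent world: standard-normal factors and loadings."""
    if n_items < 3:
        raise ValidationError("need at least 3 items for odd-one-out trials")
    rng = np.random.default_rng([seed, 0])
    factors = rng.standard_normal((n_items, q))
    loadings = rng.standard_normal((q, m))
    items = [f"item{k:04d}" for k in range(n_items)]
    true_rsm = rsm_from_embeddings(EmbeddingSet(items=items, matrix=factors))
    return LatentWorld(
        n_items=n_items,
        factors=factors,
        true_rsm=true_rsm,
        attribute_loadings=loadings,
        temperature=tau,
        items=items,
    )


def default_observation_map(world: LatentWorld, p_informative: int = 32, seed: int = 0) -> np.ndarray:
    """Random linear map from latent factors to informative embedding dims."""
    rng = np.random.default_rng([seed, 1])
    return rng.standard_normal((p_informative, world.q)) / np.sqrt(world.q)


def triplet_choice_probabilities(world: LatentWorld, triple: tuple[int, int, int]) -> np.ndarray:
    """Closed-form softmax P(odd = each member) for a fixed triple of indices."""
    i, j, k = triple
    S = world.true_rsm.values
    # odd = x is supported by the similarity of the pair excluding x
    logits = np.array([S[j, k], S[i, k], S[i, j]]) / world.temperature
    logits -= logits.max()
    p = np.exp(logits)
    return p / p.sum()


def simulate_judgments(world: LatentWorld, cfg: SimulationConfig) -> JudgmentSet:
    """Simulate odd-one-out trials over uniformly random triples.

    Per trial, three distinct items are drawn uniformly; item k is chosen odd
    with probability proportional to exp(S_true(i, j) / tau) where (i, j) is
    the pair excluding k.
    """
    rng = np.random.default_rng([cfg.seed, 2])
    n = world.n_items
    # uniformly random ordered triples of distinct items
    u = rng.random((cfg.n_triplets, n))
    triples = np.argsort(u, axis=1)[:, :3]
    S = world.true_rsm.values
    i, j, k = triples[:, 0], triples[:, 1], triples[:, 2]
    logits = np.stack([S[j, k], S[i, k], S[i, j]], axis=1) / world.temperature
    logits -= logits.max(axis=1, keepdims=True)
    p = np.exp(logits)
    p /= p.sum(axis=1, keepdims=True)
    draw = rng.random(cfg.n_triplets)
    choice = (draw[:, None] > np.cumsum(p, axis=1)).sum(axis=1)
    choice = np.minimum(choice, 2)
    odd = triples[np.arange(cfg.n_triplets), choice]
    items = world.items
    judgments = [
        TripletJudgment(items[a], items[b], items[c], items[o])
        for a, b, c, o in zip(i, j, k, odd)
    ]
    return JudgmentSet(judgments=judgments, catalogue=list(items))


def make_embeddings(world: LatentWorld, cfg: SimulationConfig) -> EmbeddingSet:
    """Candidate embeddings that encode the latent structure partially and noisily."""
    obs = cfg.observation_map
    if obs is None:
        obs = default_observation_map(world, seed=cfg.seed)
    rng = np.random.default_rng([cfg.seed, 3])
    signal = world.factors @ obs.T
    if cfg.noise_scale > 0:
        signal = signal + cfg.noise_scale * rng.standard_normal(signal.shape)
    if cfg.distractor_dims > 0:
        distract = rng.standard_normal((world.n_items, cfg.distractor_dims))
        signal = np.concatenate([signal, distract], axis=1)
    return EmbeddingSet(items=list(world.items), matrix=signal)


def make_attributes(
    world: LatentWorld,
    noise: float = 0.1,
    seed: int = 0,
    names: tuple[str, ...] = DEFAULT_ATTRIBUTES,
) -> pd.DataFrame:
    """Per-item attribute ratings: linear in the factors plus noise, z-scored.

    Columns are attribute names; each column has mean 0 and unit variance.
    """
    m = world.attribute_loadings.shape[1]
    names = tuple(names)[:m] if len(names) >= m else tuple(
        f"attr{k}" for k in range(m)
    )
    rng = np.random.default_rng([seed, 4])
    raw = world.factors @ world.attribute_loadings
    if noise > 0:
        raw = raw + noise * rng.standard_normal(raw.shape)
    z = (raw - raw.mean(axis=0)) / raw.std(axis=0)
    return pd.DataFrame(z, index=world.items, columns=list(names))
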