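"""Rank-r residual linear adapter over frozen embeddings.

The adapter maps x -> x + s * B (A x) with A (r x p) small random at
initialization and B (p x r) zero, so the map is exactly the identity before
any training step.  This transfers the low-rank / identity-at-init /
small-parameter-count principle of LoRA-style fine-tuning to the embedding
vectors themselves: the backbone that produced the embeddings stays frozen and
only the 2*r*p adapter parameters are trained.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .judgments import ValidationError


@dataclass
class LowRankAdapter:
    """x -> x + scale * up_map @ (down_map @ x); identity when up_map == 0."""

    rank: int
    down_map: np.ndarray  # (r, p)
    up_map: np.ndarray  # (p, r)
    scale: float = 1.0

    def __post_init__(self) -> None:
        r, p = self.down_map.shape
        if r != self.rank or self.up_map.shape != (p, r):
            raise ValidationError(
                f"inconsistent shapes: down {self.down_map.shape}, up {self.up_map.shape}, rank {self.rank}"
            )
        if self.scale <= 0:
            raise ValidationError("scale must be positive")

    @property
    def width(self) -> int:
        return self.down_map.shape[1]

    @property
    def n_trainable(self) -> int:
        return 2 * self.rank * self.width

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Apply the residual map to rows of X (any leading shape)."""
        X = np.asarray(X, dtype=float)
        return X + self.scale * (X @ self.down_map.T) @ self.up_map.T

    def copy(self) -> "LowRankAdapter":
        return LowRankAdapter(
            rank=self.rank,
            down_map=self.down_map.copy(),
            up_map=self.up_map.copy(),
            scale=self.scale,
        )

    def save(self, path: str | Path) -> None:
        np.savez(path, rank=self.rank, down_map=self.down_map, up_map=self.up_map, scale=self.scale)

    @classmethod
    def load(cls, path: str | Path) -> "LowRankAdapter":
        with np.load(path) as data:
            return cls(
                rank=int(data["rank"]),
                down_map=data["down_map"],
                up_map=data["up_map"],
                scale=float(data["scale"]),
            )


def init_adapter(p: int, r: int = 16, seed: int = 0) -> LowRankAdapter:
    """Identity-at-init adapter: A ~ N(0, 1/sqrt(p)), B = 0, scale = 1/r."""
    if not 1 <= r <= p:
        raise ValidationError(f"rank must satisfy 1 <= r <= p, got r={r}, p={p}")
    rng = np.random.default_rng(seed)
    A = rng.standard_normal((r, p)) / np.sqrt(p)
    B = np.zeros((p, r))
    return LowRankAdapter(rank=r, down_map=A, up_map=B, scale=1.0 / r)


def trainable_fraction(adapter: LowRankAdapter, frozen_params: int) -> float:
    """Fraction of all parameters that the adapter trains: 2rp / (2rp + frozen)."""
    t = adapter.n_trainable
    return t / (t + frozen_params)


class AdamW:
    """Decoupled-weight-decay adaptive gradient optimizer (minimal, in-place)."""

    def __init__(
        self,
        params: list[np.ndarray],
        lr: float = 1e-4,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.01,
    ) -> None:
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p -= self.lr * self.weight_decay * p  # decoupled decay
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
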