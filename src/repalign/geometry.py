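"""Embedding containers and the shared geometry: cosine similarity/distance,
representational similarity matrices, sparse random projection with the
Johnson-Lindenstrauss dimension rule, and Spearman rank correlation on masked
pair vectors.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.random_projection import SparseRandomProjection, johnson_lindenstrauss_min_dim

from .judgments import SimilarityMatrix, ValidationError


class DomainError(ValueError):
    """Numerically invalid input (zero-norm vector, eps out of range, ...)."""


@dataclass
class EmbeddingSet:
    """Item x feature real matrix: the representation being aligned or scored."""

    items: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != len(self.items):
            raise ValidationError(
                f"matrix must be (n_items, p); got {self.matrix.shape} for {len(self.items)} items"
            )
        if not np.all(np.isfinite(self.matrix)):
            raise ValidationError("embedding matrix contains non-finite entries")

    @property
    def n_items(self) -> int:
        return len(self.items)

    @property
    def width(self) -> int:
        return self.matrix.shape[1]

    def vector(self, item: str) -> np.ndarray:
        try:
            return self.matrix[self.items.index(item)]
        except ValueError as exc:
            raise KeyError(f"unknown item {item!r}") from exc

    def subset(self, items: list[str]) -> "EmbeddingSet":
        index = {it: k for k, it in enumerate(self.items)}
        missing = [it for it in items if it not in index]
        if missing:
            raise KeyError(f"items not in embedding set: {missing}")
        return EmbeddingSet(items=list(items), matrix=self.matrix[[index[it] for it in items]])

    # --- IO: delimited text (first column = item id) or HDF5 ("items", "matrix")

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.matrix, index=self.items).to_csv(path, header=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "EmbeddingSet":
        df = pd.read_csv(path, header=None, index_col=0)
        return cls(items=[str(i) for i in df.index], matrix=df.to_numpy(dtype=float))

    def to_hdf5(self, path: str | Path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("items", data=np.array(self.items, dtype=h5py.string_dtype()))
            f.create_dataset("matrix", data=self.matrix)

    @classmethod
    def from_hdf5(cls, path: str | Path) -> "EmbeddingSet":
        with h5py.File(path, "r") as f:
            items = [s.decode() if isinstance(s, bytes) else str(s) for s in f["items"][()]]
            matrix = f["matrix"][()]
        return cls(items=items, matrix=matrix)

    @classmethod
    def load(cls, path: str | Path) -> "EmbeddingSet":
        path = Path(path)
        if path.suffix in {".h5", ".hdf5"}:
            return cls.from_hdf5(path)
        return cls.from_csv(path)


@dataclass(frozen=True)
class ProjectionSpec:
    """Sparse random projection target derived from the JL lemma at distortion eps."""

    n_samples: int
    eps: float = 0.1
    seed: int = 0

    @property
    def n_components(self) -> int:
        return jl_min_dim(self.n_samples, self.eps)


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine of the angle between two nonzero vectors, in [-1, 1]."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise DomainError("cosine similarity undefined for zero-norm vectors")
    return float(np.dot(u, v) / (nu * nv))


def cosine_distance(u: np.ndarray, v: np.ndarray) -> float:
    """d(u, v) = 1 - <z_u, z_v> with z the l2-normalized vectors; in [0, 2]."""
    return 1.0 - cosine_similarity(u, v)


def rsm_from_embeddings(E: EmbeddingSet) -> SimilarityMatrix:
    """Fully observed cosine similarity matrix of an embedding set.

    The diagonal equals 1 but is masked so downstream statistics ignore it.
    """
    norms = np.linalg.norm(E.matrix, axis=1)
    if np.any(norms == 0.0):
        bad = [E.items[k] for k in np.flatnonzero(norms == 0.0)]
        raise DomainError(f"zero-norm embedding rows for items: {bad}")
    Z = E.matrix / norms[:, None]
    values = Z @ Z.T
    np.clip(values, -1.0, 1.0, out=values)
    values = (values + values.T) / 2.0
    np.fill_diagonal(values, 1.0)
    observed = np.ones_like(values, dtype=bool)
    np.fill_diagonal(observed, False)
    return SimilarityMatrix(items=list(E.items), values=values, observed=observed)


def jl_min_dim(n_samples: int, eps: float) -> int:
    """Johnson-Lindenstrauss minimum dimension, truncated toward zero.

    Evaluates 4 ln(n) / (eps^2/2 - eps^3/3): the dimension guaranteeing that a
    random projection preserves all pairwise distances among ``n_samples``
    points within a factor 1 +/- eps with high probability.
    """
    if not 0.0 < eps < 1.0:
        raise DomainError(f"eps must lie in (0, 1), got {eps}")
    if n_samples < 2:
        raise DomainError("need at least 2 samples")
    return int(johnson_lindenstrauss_min_dim(n_samples, eps=eps))


def sparse_random_projection(E: EmbeddingSet, spec: ProjectionSpec) -> EmbeddingSet:
    """Project an embedding set to the JL dimension with a sparse random matrix.

    Entries of the projection matrix are in {-1, 0, +1} with density 1/sqrt(p)
    and scale sqrt(1/(density * n_components)) (the standard sparse
    construction).  If the input is already at or below the target dimension it
    is returned unchanged.
    """
    k = spec.n_components
    if E.width <= k:
        return E
    proj = SparseRandomProjection(n_components=k, density="auto", random_state=spec.seed)
    reduced = proj.fit_transform(E.matrix)
    return EmbeddingSet(items=list(E.items), matrix=np.asarray(reduced, dtype=float))


def rank_correlation(x: np.ndarray, y: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Spearman rho between paired vectors, restricted to unmasked entries.

    Ties receive average ranks.  Raises when fewer than 3 paired entries
    survive masking or either side has zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        x = x[mask]
        y = y[mask]
    if x.size < 3:
        raise ValidationError(f"need >= 3 paired entries, got {x.size}")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValidationError("rank correlation undefined: zero variance after masking")
    return float(stats.spearmanr(x, y).statistic)


def joint_observed_upper(
    a: SimilarityMatrix, b: SimilarityMatrix
) -> tuple[np.ndarray, np.ndarray]:
    """Upper-triangle value vectors of two matrices on jointly observed pairs.

    Both matrices must be over the same item list (same order).
    """
    if a.items != b.items:
        only_a = sorted(set(a.items) - set(b.items))
        only_b = sorted(set(b.items) - set(a.items))
        raise ValidationError(
            f"item sets differ (order-sensitive); only in first: {only_a}, only in second: {only_b}"
        )
    common = a.observed & b.observed
    iu, ju = np.triu_indices(a.n_items, k=1)
    keep = common[iu, ju]
    return a.values[iu[keep], ju[keep]], b.values[iu[keep], ju[keep]]
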