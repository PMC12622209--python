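"""Scoring embedding sets against human odd-one-out judgments.

Covers the full evaluation battery: representational similarity analysis
(squared Spearman correlation between model and behavioral similarity
matrices), odd-one-out prediction accuracy, cross-validated layer selection,
variance partitioning (commonality analysis) between two candidate
representations, and ridge-regression attribute probes.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import RidgeCV
from sklearn.model_selection import KFold

from .geometry import EmbeddingSet, joint_observed_upper, rank_correlation, rsm_from_embeddings
from .judgments import (
    DissimilarityMatrix,
    JudgmentSet,
    SimilarityMatrix,
    ValidationError,
    estimate_similarity,
)

_TIE_SENTINEL = "\U0010ffff"  # sorts after any real identifier


@dataclass(frozen=True)
class AlignmentReport:
    """RSA and odd-one-out alignment of one embedding set with behavior."""

    spearman_rho: float
    r_squared: float
    n_pairs: int
    ooo_accuracy: Optional[float] = None
    n_triplets: Optional[int] = None
    noise_ceiling: Optional[float] = None

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class VariancePartition:
    """Commonality decomposition of human-RDM variance across two predictors.

    unique_a + unique_b + shared == total up to numerical tolerance.  A
    negative shared component signals suppression and is reported, not
    clipped.
    """

    unique_a: float
    unique_b: float
    shared: float
    total: float
    n_pairs: int
    collinear: bool = False

    @property
    def suppression(self) -> bool:
        return self.shared < 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["suppression"] = self.suppression
        return d


@dataclass(frozen=True)
class ProbeResult:
    """Ridge-probe decoding of one attribute from an embedding set."""

    attribute: str
    pearson_r: float
    penalty: float
    n_train: int
    n_test: int

    def to_dict(self) -> dict:
        return asdict(self)


def predict_odd_one_out(E: EmbeddingSet, triplet: tuple[str, str, str]) -> str:
    """Predicted odd item: the one absent from the most-similar pair.

    Ties between maximal pairs resolve to the lexicographically smallest
    candidate odd item, so the rule is deterministic.
    """
    a, b, c = triplet
    try:
        va, vb, vc = E.vector(a), E.vector(b), E.vector(c)
    except KeyError as exc:
        raise ValidationError(str(exc)) from exc
    from .geometry import cosine_similarity

    pairs = [(cosine_similarity(va, vb), c), (cosine_similarity(va, vc), b), (cosine_similarity(vb, vc), a)]
    best = max(s for s, _ in pairs)
    return min(odd for s, odd in pairs if s == best)


def ooo_accuracy(E: EmbeddingSet, js: JudgmentSet) -> float:
    """Fraction of judgments whose odd item the embedding geometry predicts."""
    if not js.judgments:
        raise ValidationError("cannot score an empty judgment set")
    missing = sorted(set(js.catalogue) - set(E.items))
    if missing:
        raise ValidationError(f"judgment items lack embeddings: {missing[:5]}")
    sub = E.subset(js.catalogue)
    S = rsm_from_embeddings(sub).values
    index = {it: k for k, it in enumerate(js.catalogue)}
    tri = np.array([[index[j.item_a], index[j.item_b], index[j.item_c]] for j in js.judgments])
    ids = np.array([[j.item_a, j.item_b, j.item_c] for j in js.judgments])
    s_ab = S[tri[:, 0], tri[:, 1]]
    s_ac = S[tri[:, 0], tri[:, 2]]
    s_bc = S[tri[:, 1], tri[:, 2]]
    sims = np.stack([s_ab, s_ac, s_bc], axis=1)
    cand = np.stack([ids[:, 2], ids[:, 1], ids[:, 0]], axis=1)  # odd candidate per pair
    lex = {it: r for r, it in enumerate(sorted(js.catalogue))}
    cand_rank = np.vectorize(lex.__getitem__)(cand)
    best = sims.max(axis=1, keepdims=True)
    masked_rank = np.where(sims == best, cand_rank, len(lex))
    pred = cand[np.arange(len(cand)), masked_rank.argmin(axis=1)]
    truth = np.array([j.odd for j in js.judgments])
    return float(np.mean(pred == truth))


def rsa_alignment(
    model_rsm: SimilarityMatrix, human_rsm: SimilarityMatrix
) -> AlignmentReport:
    """Spearman rho (and its square) over jointly observed upper-triangle pairs."""
    mv, hv = joint_observed_upper(model_rsm, human_rsm)
    if mv.size < 3:
        raise ValidationError(f"need >= 3 jointly observed pairs, got {mv.size}")
    rho = rank_correlation(mv, hv)
    return AlignmentReport(spearman_rho=rho, r_squared=rho**2, n_pairs=int(mv.size))


def evaluate_alignment(
    E: EmbeddingSet, js: JudgmentSet, noise_ceiling: float | None = None
) -> AlignmentReport:
    """Full alignment report of an embedding set against a judgment set."""
    human = estimate_similarity(js)
    model = rsm_from_embeddings(E.subset(js.catalogue))
    base = rsa_alignment(model, human)
    acc = ooo_accuracy(E, js)
    return AlignmentReport(
        spearman_rho=base.spearman_rho,
        r_squared=base.r_squared,
        n_pairs=base.n_pairs,
        ooo_accuracy=acc,
        n_triplets=len(js.judgments),
        noise_ceiling=noise_ceiling,
    )


def select_layer(
    candidates: dict[str, EmbeddingSet],
    js: JudgmentSet,
    k_folds: int = 5,
    seed: int = 0,
) -> str:
    """Cross-validated layer/candidate selection by mean held-out Spearman rho.

    Items (not judgments) are partitioned into k seeded folds; per fold, each
    candidate's RSM is correlated with the behavioral RSM on the held-out
    items' jointly observed pairs.  Returns the candidate with the highest
    mean rho; ties go to the first candidate in input order.
    """
    if len(candidates) < 2:
        raise ValidationError("need at least 2 candidate embedding sets")
    if k_folds < 2:
        raise ValidationError("k_folds must be >= 2 (a single fold leaves no held-out items)")
    human = estimate_similarity(js)
    items = np.array(js.catalogue)
    if len(items) < k_folds * 3:
        raise ValidationError("too few items: each fold needs >= 3 items; reduce k_folds")
    kf = KFold(n_splits=k_folds, shuffle=True, random_state=seed)
    fold_items = [items[test_idx].tolist() for _, test_idx in kf.split(items)]
    means: dict[str, float] = {}
    for name, E in candidates.items():
        rhos = []
        model = rsm_from_embeddings(E.subset(js.catalogue))
        for held in fold_items:
            keep = np.isin(js.catalogue, held)
            sub_idx = np.flatnonzero(keep)
            hm = _restrict(human, sub_idx)
            mm = _restrict(model, sub_idx)
            try:
                mv, hv = joint_observed_upper(mm, hm)
                if mv.size < 3:
                    raise ValidationError("fold too small")
                rhos.append(rank_correlation(mv, hv))
            except ValidationError as exc:
                raise ValidationError(
                    f"fold with items {held[:3]}... yields < 3 usable pairs; use fewer folds"
                ) from exc
        means[name] = float(np.mean(rhos))
    best = max(means.values())
    for name in candidates:
        if means[name] == best:
            return name
    raise AssertionError("unreachable")


def _restrict(sm: SimilarityMatrix, idx: np.ndarray) -> SimilarityMatrix:
    return SimilarityMatrix(
        items=[sm.items[k] for k in idx],
        values=sm.values[np.ix_(idx, idx)],
        observed=sm.observed[np.ix_(idx, idx)],
    )


def variance_partition(
    rdm_a: DissimilarityMatrix, rdm_b: DissimilarityMatrix, human_rdm: DissimilarityMatrix
) -> VariancePartition:
    """Commonality analysis of the human RDM on two predictor RDMs.

    The three observed upper-triangle vectors are rank-transformed (average
    ranks), then ordinary least squares of the human ranks on {a}, {b} and
    {a, b} yields R2_a, R2_b and R2_ab.  unique_a = R2_ab - R2_b,
    unique_b = R2_ab - R2_a, shared = R2_a + R2_b - R2_ab, total = R2_ab.
    """
    if not (rdm_a.items == rdm_b.items == human_rdm.items):
        raise ValidationError("all three RDMs must share the same item list")
    common = rdm_a.observed & rdm_b.observed & human_rdm.observed
    iu, ju = np.triu_indices(len(human_rdm.items), k=1)
    keep = common[iu, ju]
    if keep.sum() < 10:
        raise ValidationError(f"need >= 10 jointly observed pairs, got {int(keep.sum())}")
    xa = stats.rankdata(rdm_a.values[iu[keep], ju[keep]])
    xb = stats.rankdata(rdm_b.values[iu[keep], ju[keep]])
    y = stats.rankdata(human_rdm.values[iu[keep], ju[keep]])

    def r2(*cols: np.ndarray) -> tuple[float, int]:
        Xd = np.column_stack([np.ones_like(y)] + list(cols))
        beta, _, rank, _ = np.linalg.lstsq(Xd, y, rcond=None)
        resid = y - Xd @ beta
        sst = np.sum((y - y.mean()) ** 2)
        return float(1.0 - resid @ resid / sst), rank

    r2_a, _ = r2(xa)
    r2_b, _ = r2(xb)
    r2_ab, rank_ab = r2(xa, xb)
    return VariancePartition(
        unique_a=r2_ab - r2_b,
        unique_b=r2_ab - r2_a,
        shared=r2_a + r2_b - r2_ab,
        total=r2_ab,
        n_pairs=int(keep.sum()),
        collinear=rank_ab < 3,
    )


DEFAULT_PENALTY_GRID = tuple(np.logspace(-3, 3, 7))


def linear_probe(
    E: EmbeddingSet,
    ratings: "pd.Series | dict[str, float]",
    train_items: list[str],
    test_items: list[str],
    penalty_grid: tuple[float, ...] = DEFAULT_PENALTY_GRID,
    attribute: str = "attribute",
) -> ProbeResult:
    """Ridge linear probe: decode a per-item rating from embeddings.

    The penalty is chosen by 5-fold cross-validation on the training items,
    the probe is refit on all training items, and the score is the Pearson
    correlation between predicted and observed ratings on the test items.
    """
    if set(train_items) & set(test_items):
        raise ValidationError("train and test item sets must be disjoint")
    if len(train_items) < 10:
        raise ValidationError(f"need >= 10 training items, got {len(train_items)}")
    ratings = pd.Series(ratings)
    y_train = ratings.loc[train_items].to_numpy(dtype=float)
    y_test = ratings.loc[test_items].to_numpy(dtype=float)
    if np.all(y_train == y_train[0]):
        raise ValidationError("constant ratings cannot be probed")
    X_train = E.subset(list(train_items)).matrix
    X_test = E.subset(list(test_items)).matrix
    model = RidgeCV(alphas=list(penalty_grid), cv=5)
    model.fit(X_train, y_train)
    pred = model.predict(X_test)
    r = float(stats.pearsonr(pred, y_test).statistic)
    return ProbeResult(
        attribute=attribute,
        pearson_r=r,
        penalty=float(model.alpha_),
        n_train=len(train_items),
        n_test=len(test_items),
    )
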