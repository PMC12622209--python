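"""Odd-one-out triplet judgments and the behavioral similarity structure they induce.

A triplet odd-one-out (OOO) trial shows three items; the participant picks the
one that is least like the others, implicitly marking the remaining pair as
similar.  Aggregated over many trials, the probability that a pair "survives
together" (neither member chosen odd, conditioned on co-occurrence) defines a
behavioral similarity matrix.  This module parses trial tables, estimates the
similarity/dissimilarity matrices with an observed-pair mask, produces seeded
judgment splits, and computes the split-half reliability ceiling (squared
Spearman correlation between half-split similarity estimates).
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats


class ParseError(ValueError):
    """A triplet table row could not be parsed."""


class ValidationError(ValueError):
    """Input violates a documented precondition."""


@dataclass(frozen=True)
class TripletJudgment:
    """One odd-one-out trial: three distinct items and the chosen odd item."""

    item_a: str
    item_b: str
    item_c: str
    odd: str

    def __post_init__(self) -> None:
        triple = (self.item_a, self.item_b, self.item_c)
        if len(set(triple)) != 3:
            raise ValidationError(f"triplet items must be pairwise distinct, got {triple}")
        if self.odd not in triple:
            raise ValidationError(f"odd item {self.odd!r} is not one of the triplet {triple}")

    @property
    def items(self) -> tuple[str, str, str]:
        return (self.item_a, self.item_b, self.item_c)

    @property
    def surviving_pair(self) -> tuple[str, str]:
        """The two items not chosen odd, in row order."""
        return tuple(x for x in self.items if x != self.odd)  # type: ignore[return-value]


@dataclass
class JudgmentSet:
    """An ordered collection of triplet judgments over a fixed item catalogue."""

    judgments: list[TripletJudgment]
    catalogue: list[str]

    def __post_init__(self) -> None:
        if len(set(self.catalogue)) != len(self.catalogue):
            raise ValidationError("catalogue contains duplicate identifiers")
        known = set(self.catalogue)
        for j in self.judgments:
            missing = set(j.items) - known
            if missing:
                raise ValidationError(f"judgment references items not in catalogue: {sorted(missing)}")

    def __len__(self) -> int:
        return len(self.judgments)

    @classmethod
    def from_judgments(cls, judgments: list[TripletJudgment]) -> "JudgmentSet":
        """Build a set whose catalogue is the sorted union of referenced items."""
        items: set[str] = set()
        for j in judgments:
            items.update(j.items)
        return cls(judgments=list(judgments), catalogue=sorted(items))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(j.item_a, j.item_b, j.item_c, j.odd) for j in self.judgments],
            columns=["item_a", "item_b", "item_c", "odd"],
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


DEFAULT_COLUMNS = {"item_a": "item_a", "item_b": "item_b", "item_c": "item_c", "odd": "odd"}


def parse_triplets(path: str | Path, dialect: dict[str, str] | None = None) -> JudgmentSet:
    """Read a delimited triplet table (comma or tab, auto-detected).

    Parameters
    ----------
    path
        Text file with a header naming three item columns and one choice column.
    dialect
        Optional mapping from the canonical names ``item_a``, ``item_b``,
        ``item_c``, ``odd`` to the column names used in the file.

    Returns
    -------
    JudgmentSet
        Judgments in row order; catalogue is the sorted union of referenced items.
    """
    colmap = dict(DEFAULT_COLUMNS)
    if dialect:
        colmap.update(dialect)
    path = Path(path)
    text = path.read_text()
    lines = [ln for ln in io.StringIO(text)]
    if not lines:
        raise ParseError(f"{path}: empty file, expected a header row")
    delim = "\t" if lines[0].count("\t") >= lines[0].count(",") and "\t" in lines[0] else ","
    reader = csv.reader(lines, delimiter=delim)
    header = [h.strip() for h in next(reader)]
    try:
        idx = {key: header.index(colmap[key]) for key in ("item_a", "item_b", "item_c", "odd")}
    except ValueError as exc:
        raise ParseError(f"{path}: header {header} is missing a required column ({exc})") from exc

    judgments: list[TripletJudgment] = []
    for lineno, row in enumerate(reader, start=2):
        if not row or all(not f.strip() for f in row):
            continue
        if len(row) < 4:
            raise ParseError(f"{path}:{lineno}: expected at least 4 fields, got {len(row)}")
        fields = {key: row[i].strip() for key, i in idx.items()}
        try:
            judgments.append(TripletJudgment(fields["item_a"], fields["item_b"], fields["item_c"], fields["odd"]))
        except ValidationError as exc:
            raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return JudgmentSet.from_judgments(judgments)


@dataclass
class SimilarityMatrix:
    """Symmetric item x item similarity with an observed-pair mask.

    The diagonal is treated as unobserved by every downstream statistic.
    Behavioral matrices live in [0, 1]; model matrices (cosine) in [-1, 1].
    """

    items: list[str]
    values: np.ndarray
    observed: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.items)
        self.values = np.asarray(self.values, dtype=float)
        self.observed = np.asarray(self.observed, dtype=bool)
        if self.values.shape != (n, n) or self.observed.shape != (n, n):
            raise ValidationError("matrix shapes must be (n_items, n_items)")
        if not np.allclose(self.values[self.observed], self.values.T[self.observed], atol=1e-12):
            raise ValidationError("similarity values must be symmetric on observed pairs")
        if not np.array_equal(self.observed, self.observed.T):
            raise ValidationError("observed mask must be symmetric")

    @property
    def n_items(self) -> int:
        return len(self.items)

    def observed_upper(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Observed upper-triangle entries (diagonal excluded).

        Returns ``(rows, cols, values)`` index/value arrays.
        """
        iu, ju = np.triu_indices(self.n_items, k=1)
        keep = self.observed[iu, ju]
        return iu[keep], ju[keep], self.values[iu[keep], ju[keep]]

    def to_csv(self, path: str | Path, na_rep: str = "NA") -> None:
        out = self.values.copy()
        mask = ~self.observed
        df = pd.DataFrame(out, index=self.items, columns=self.items)
        df = df.mask(pd.DataFrame(mask, index=self.items, columns=self.items))
        df.to_csv(path, na_rep=na_rep)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SimilarityMatrix":
        df = pd.read_csv(path, index_col=0)
        values = df.to_numpy(dtype=float)
        observed = ~np.isnan(values)
        values = np.nan_to_num(values)
        return cls(items=[str(i) for i in df.index], values=values, observed=observed)


@dataclass
class DissimilarityMatrix:
    """Symmetric nonnegative item x item dissimilarity (RDM) with zero diagonal."""

    items: list[str]
    values: np.ndarray
    observed: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.items)
        self.values = np.asarray(self.values, dtype=float)
        self.observed = np.asarray(self.observed, dtype=bool)
        if self.values.shape != (n, n) or self.observed.shape != (n, n):
            raise ValidationError("matrix shapes must be (n_items, n_items)")
        if np.any(self.values[self.observed] < -1e-12):
            raise ValidationError("dissimilarities must be nonnegative")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise ValidationError("dissimilarity diagonal must be zero")

    @property
    def n_items(self) -> int:
        return len(self.items)

    def observed_upper(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        iu, ju = np.triu_indices(self.n_items, k=1)
        keep = self.observed[iu, ju]
        return iu[keep], ju[keep], self.values[iu[keep], ju[keep]]

    def to_csv(self, path: str | Path, na_rep: str = "NA") -> None:
        SimilarityMatrix.to_csv(self, path, na_rep=na_rep)  # type: ignore[arg-type]

    @classmethod
    def from_csv(cls, path: str | Path) -> "DissimilarityMatrix":
        df = pd.read_csv(path, index_col=0)
        values = df.to_numpy(dtype=float)
        observed = ~np.isnan(values)
        values = np.nan_to_num(values)
        np.fill_diagonal(values, 0.0)
        return cls(items=[str(i) for i in df.index], values=values, observed=observed)


def _pair_counts(js: JudgmentSet) -> tuple[np.ndarray, np.ndarray, dict[str, int]]:
    """Co-occurrence and co-survival counts for every unordered pair.

    Vectorized over trials; the conservation identity
    cooccur(i,j) = cosurvive(i,j) + (# trials where {i,j} co-occur and one is odd)
    holds by construction.
    """
    index = {item: k for k, item in enumerate(js.catalogue)}
    n = len(js.catalogue)
    cooc = np.zeros((n, n), dtype=np.int64)
    surv = np.zeros((n, n), dtype=np.int64)
    if js.judgments:
        tri = np.array([[index[j.item_a], index[j.item_b], index[j.item_c]] for j in js.judgments])
        odd = np.array([index[j.odd] for j in js.judgments])
        for a, b in ((0, 1), (0, 2), (1, 2)):
            i, j = tri[:, a], tri[:, b]
            np.add.at(cooc, (i, j), 1)
            alive = (i != odd) & (j != odd)
            np.add.at(surv, (i, j), alive.astype(np.int64))
    cooc = cooc + cooc.T
    surv = surv + surv.T
    return cooc, surv, index


def estimate_similarity(js: JudgmentSet) -> SimilarityMatrix:
    """Behavioral similarity: P(pair judged together | pair co-occurred).

    For each unordered pair, the value is the fraction of trials containing
    both items in which neither was chosen as the odd one out.  Pairs that
    never co-occur are masked as unobserved; the denominator conditions on
    exposure so values stay in [0, 1] regardless of sampling design.
    """
    if not js.judgments:
        raise ValidationError("cannot estimate similarity from an empty judgment set")
    cooc, surv, _ = _pair_counts(js)
    observed = cooc > 0
    np.fill_diagonal(observed, False)
    values = np.zeros_like(cooc, dtype=float)
    values[observed] = surv[observed] / cooc[observed]
    return SimilarityMatrix(items=list(js.catalogue), values=values, observed=observed)


def similarity_to_rdm(S: SimilarityMatrix) -> DissimilarityMatrix:
    """Convert similarity to dissimilarity as d = 1 - S on observed pairs."""
    values = np.zeros_like(S.values)
    values[S.observed] = 1.0 - S.values[S.observed]
    np.fill_diagonal(values, 0.0)
    observed = S.observed.copy()
    np.fill_diagonal(observed, False)
    return DissimilarityMatrix(items=list(S.items), values=values, observed=observed)


def split_indices(n: int, holdout_fraction: float, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Seeded (main, holdout) index partition; holdout gets round(n * fraction)."""
    if not 0.0 < holdout_fraction < 1.0:
        raise ValidationError(f"holdout_fraction must lie in (0, 1), got {holdout_fraction}")
    perm = np.random.default_rng(seed).permutation(n)
    n_hold = int(round(n * holdout_fraction))
    return np.sort(perm[n_hold:]), np.sort(perm[:n_hold])


def split_judgments(
    js: JudgmentSet, holdout_fraction: float, seed: int
) -> tuple[JudgmentSet, JudgmentSet]:
    """Seeded disjoint partition of judgments into (main, holdout).

    The holdout receives ``round(n * holdout_fraction)`` judgments chosen by a
    uniform random permutation; both parts inherit the full catalogue so item
    indexing stays aligned across splits.
    """
    if not js.judgments:
        raise ValidationError("cannot split an empty judgment set")
    main_idx, hold_idx = split_indices(len(js.judgments), holdout_fraction, seed)
    cat = list(js.catalogue)
    main = [js.judgments[k] for k in main_idx]
    hold = [js.judgments[k] for k in hold_idx]
    return (JudgmentSet(main, cat), JudgmentSet(hold, cat))


def _half_similarity_correlation(half_a: JudgmentSet, half_b: JudgmentSet) -> float | None:
    """Spearman rho between two halves' similarity estimates on common pairs.

    Returns None when fewer than 3 commonly observed pairs exist or either
    half's estimates are constant across them.
    """
    sa = estimate_similarity(half_a)
    sb = estimate_similarity(half_b)
    common = sa.observed & sb.observed
    iu, ju = np.triu_indices(sa.n_items, k=1)
    keep = common[iu, ju]
    if keep.sum() < 3:
        return None
    va = sa.values[iu[keep], ju[keep]]
    vb = sb.values[iu[keep], ju[keep]]
    if np.allclose(va, va[0]) and np.allclose(vb, vb[0]):
        # identical constant vectors carry no ordering information either way
        return None
    if np.allclose(va, vb):
        return 1.0
    if np.allclose(va, va[0]) or np.allclose(vb, vb[0]):
        return None
    rho = stats.spearmanr(va, vb).statistic
    if np.isnan(rho):
        return None
    return float(rho)


def split_half_ceiling(js: JudgmentSet, n_splits: int = 100, seed: int = 0) -> float:
    """Split-half reliability ceiling of the behavioral similarity matrix.

    Averages, over ``n_splits`` random half-partitions of the judgments, the
    squared Spearman correlation between the two halves' similarity estimates
    on their commonly observed pairs.  This bounds the variance any model can
    explain given the reliability of the behavioral data.
    """
    if len(js.judgments) < 2:
        raise ValidationError("need at least 2 judgments for a split-half ceiling")
    rng = np.random.default_rng(seed)
    n = len(js.judgments)
    cat = list(js.catalogue)
    vals: list[float] = []
    for _ in range(n_splits):
        perm = rng.permutation(n)
        half = n // 2
        a = JudgmentSet([js.judgments[k] for k in perm[:half]], cat)
        b = JudgmentSet([js.judgments[k] for k in perm[half:]], cat)
        rho = _half_similarity_correlation(a, b)
        if rho is not None:
            vals.append(rho**2)
    if not vals:
        raise ValidationError(
            "no split produced >= 3 commonly observed pairs with usable variance; "
            "collect more judgments or reduce the item set"
        )
    return float(np.mean(vals))
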