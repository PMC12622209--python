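"""Model/Results interface over adapter training.

`AdapterAlignment` pairs a frozen embedding set with a judgment set and a
training configuration; `fit()` runs the hybrid triplet-RSA optimization and
returns an `AdapterAlignmentResults` carrying the trained adapter, the
training history, evaluation helpers, and a text `summary()`.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np

from . import __version__
from .adapter import LowRankAdapter, trainable_fraction
from .evaluation import AlignmentReport, evaluate_alignment
from .geometry import EmbeddingSet
from .judgments import JudgmentSet, parse_triplets, split_half_ceiling
from .training import TrainConfig, TrainingHistory, train


class AdapterAlignment:
    """Aligns a frozen embedding space with human odd-one-out judgments.

    Parameters
    ----------
    embeddings
        Base (frozen) item embeddings; every judged item must be present.
    judgments
        Training odd-one-out judgments.
    config
        Optimization settings; defaults follow the standard recipe
        (AdamW, lr 1e-4, 50 epochs, batch of 4 judgments, hybrid loss with
        margin 0.2, alpha 0.7, beta ramped 0.3 -> 0.7, K=24/M=6 RSA batches
        six times per epoch, rank-16 adapter).

    Examples
    --------
    >>> model = AdapterAlignment(embeddings, judgments)
    >>> res = model.fit()
    >>> print(res.summary())
    """

    def __init__(
        self,
        embeddings: EmbeddingSet,
        judgments: JudgmentSet,
        config: TrainConfig | None = None,
    ) -> None:
        self.embeddings = embeddings
        self.judgments = judgments
        self.config = config or TrainConfig()

    @classmethod
    def from_files(
        cls,
        embeddings_path: str | Path,
        triplets_path: str | Path,
        config: TrainConfig | None = None,
    ) -> "AdapterAlignment":
        return cls(
            embeddings=EmbeddingSet.load(embeddings_path),
            judgments=parse_triplets(triplets_path),
            config=config,
        )

    def fit(self) -> "AdapterAlignmentResults":
        adapter, history = train(self.embeddings, self.judgments, self.config)
        return AdapterAlignmentResults(self, adapter, history)


class AdapterAlignmentResults:
    """Trained adapter, training history, and evaluation helpers."""

    def __init__(
        self, model: AdapterAlignment, adapter: LowRankAdapter, history: TrainingHistory
    ) -> None:
        self.model = model
        self.adapter = adapter
        self.history = history

    @property
    def config(self) -> TrainConfig:
        return self.model.config

    @property
    def best_epoch(self) -> int:
        return self.history.best_epoch

    @property
    def validation_curve(self) -> list[float]:
        return list(self.history.validation_scores)

    def transform(self, E: EmbeddingSet | None = None) -> EmbeddingSet:
        """Adapter-transformed embeddings (defaults to the base set)."""
        E = E if E is not None else self.model.embeddings
        return EmbeddingSet(items=list(E.items), matrix=self.adapter.transform(E.matrix))

    def evaluate(self, js: JudgmentSet, noise_ceiling: float | None = None) -> AlignmentReport:
        """Alignment of the adapted embeddings with a (held-out) judgment set."""
        return evaluate_alignment(self.transform(), js, noise_ceiling=noise_ceiling)

    def evaluate_baseline(self, js: JudgmentSet, noise_ceiling: float | None = None) -> AlignmentReport:
        """Alignment of the unadapted base embeddings, for comparison."""
        return evaluate_alignment(self.model.embeddings, js, noise_ceiling=noise_ceiling)

    def summary(self, eval_js: JudgmentSet | None = None) -> str:
        """Human-readable fit summary; optionally scores a held-out judgment set."""
        cfg = self.config
        E = self.model.embeddings
        frozen = E.n_items * E.width
        lines = [
            "Adapter alignment results",
            "=" * 60,
            f"items: {E.n_items}    embedding width: {E.width}",
            f"judgments: {len(self.model.judgments)}    mode: {cfg.mode}",
            f"adapter rank: {self.adapter.rank}    trainable params: {self.adapter.n_trainable}"
            f" ({100 * trainable_fraction(self.adapter, frozen):.2f}% of params incl. frozen embeddings)",
            f"epochs: {cfg.epochs}    batch size: {cfg.batch_size} judgments    lr: {cfg.learning_rate:g}",
            f"best epoch: {self.best_epoch}    "
            f"validation rho^2: {self.history.validation_scores[self.best_epoch]:.4f}",
            f"optimizer steps: {len(self.history.steps)}    skipped RSA steps: {self.history.skipped_rsa_steps}",
        ]
        if eval_js is not None:
            rep_t = self.evaluate(eval_js)
            rep_b = self.evaluate_baseline(eval_js)
            lines += [
                "-" * 60,
                f"held-out rho^2:  base {rep_b.r_squared:.4f}  ->  adapted {rep_t.r_squared:.4f}",
                f"held-out OOO accuracy:  base {rep_b.ooo_accuracy:.4f}  ->  adapted {rep_t.ooo_accuracy:.4f}",
                f"(on {rep_t.n_pairs} pairs, {rep_t.n_triplets} triplets)",
            ]
        return "\n".join(lines)

    def noise_ceiling(self, js: JudgmentSet | None = None, n_splits: int = 100, seed: int = 0) -> float:
        """Split-half reliability ceiling of a judgment set (default: training set)."""
        return split_half_ceiling(js or self.model.judgments, n_splits=n_splits, seed=seed)

    def plot_history(self, ax=None):
        """Validation-score trajectory over epochs (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.validation_curve, marker="o", ms=3)
        ax.axvline(self.best_epoch, ls="--", c="gray", label=f"best epoch {self.best_epoch}")
        ax.set_xlabel("epoch")
        ax.set_ylabel(r"validation Spearman $\rho^2$")
        ax.legend()
        return ax

    def save(self, out_dir: str | Path) -> None:
        """Write adapter state, per-step history, and a run manifest."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.adapter.save(out / "adapter.npz")
        self.history.to_frame().to_csv(out / "history.csv", index=False)
        manifest = {
            "package_version": __version__,
            "config": self.config.to_dict(),
            "best_epoch": self.best_epoch,
            "validation_scores": self.validation_curve,
            "n_items": self.model.embeddings.n_items,
            "embedding_width": self.model.embeddings.width,
            "n_judgments": len(self.model.judgments),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
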