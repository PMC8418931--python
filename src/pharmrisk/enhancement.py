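"""Feature enhancement: Gini-importance ranking, top-k selection, and
GAN-generated feature columns appended to the signal matrix (FS-GAN).

High-dimensional PRR matrices are sparse, and dropping low-importance ADR
columns would discard rare but serious reactions.  This stage instead keeps
every original column and *adds* information: the k ADR features with the
highest random-forest Gini importance are used to train a GAN
(:mod:`pharmrisk.gan`), and one generated k-vector per drug row is appended
as new columns, giving d + k features in total.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .disproportionality import SignalMatrix
from .errors import RankingError, SelectionError, ShapeError
from .gan import FeatureGan, GanConfig, train_gan

__all__ = [
    "ImportanceRanking",
    "EnhancedMatrix",
    "rank_features",
    "select_top_k",
    "train_feature_gan",
    "generate_features",
    "append_features",
    "enhance",
]


@dataclass
class ImportanceRanking:
    """ADR features sorted by total Gini impurity decrease (descending).

    ``scores[r]`` is the importance of ``feature_ids[r]``: the impurity
    decrease accumulated over every split that uses the feature, summed over
    all trees of the auxiliary forest.  Ties are broken by ascending
    original column index, so the order is fully deterministic given the
    seed.
    """

    feature_ids: list[str]
    scores: np.ndarray
    n_trees: int
    seed: int

    def top(self, k: int) -> list[str]:
        return self.feature_ids[:k]


@dataclass
class EnhancedMatrix:
    """Signal matrix plus generated columns, with per-column provenance."""

    values: pd.DataFrame
    labels: pd.Series
    provenance: pd.Series     # per column: "real" | "generated"

    @property
    def n_real(self) -> int:
        return int((self.provenance == "real").sum())

    @property
    def n_generated(self) -> int:
        return int((self.provenance == "generated").sum())

    def to_csv(self, path) -> None:
        header = pd.DataFrame([self.provenance.to_list()],
                              columns=self.values.columns, index=["provenance"])
        out = pd.concat([header, self.values.astype(object)])
        out["label"] = [""] + self.labels.to_list()
        out.to_csv(path, index_label="drug_name")


def gini_impurity(class_probs) -> float:
    """Node impurity 1 - sum(p_k^2): 0 for a pure node, maximal when the
    classes are equiprobable."""
    p = np.asarray(class_probs, dtype=float)
    return float(1.0 - np.sum(p * p))


def rank_features(
    matrix: SignalMatrix, n_trees: int = 100, seed: int = 0
) -> ImportanceRanking:
    """Rank ADR features by summed Gini impurity decrease over a forest.

    An auxiliary forest (Gini splits, sqrt(d) features per node) is fit on
    the imbalanced signal matrix; each feature's score is the un-normalised
    impurity decrease summed over all trees, which makes the total score
    exactly additive over trees.
    """
    y = matrix.labels.to_numpy()
    if len(np.unique(y)) < 2:
        raise RankingError("feature ranking needs at least two classes")
    X = matrix.values.to_numpy()
    forest = RandomForestClassifier(
        n_estimators=n_trees,
        criterion="gini",
        max_features="sqrt",
        random_state=seed,
        n_jobs=1,
    ).fit(X, y)
    scores = np.zeros(X.shape[1])
    for tree in forest.estimators_:
        scores += tree.tree_.compute_feature_importances(normalize=False)
    # descending score; ties -> ascending column index
    order = np.lexsort((np.arange(len(scores)), -scores))
    cols = list(matrix.values.columns)
    return ImportanceRanking(
        feature_ids=[cols[i] for i in order],
        scores=scores[order],
        n_trees=n_trees,
        seed=seed,
    )


def per_tree_importances(matrix: SignalMatrix, n_trees: int = 100, seed: int = 0) -> np.ndarray:
    """(n_trees, d) un-normalised importance per tree; oracle for additivity."""
    forest = RandomForestClassifier(
        n_estimators=n_trees, criterion="gini", max_features="sqrt",
        random_state=seed, n_jobs=1,
    ).fit(matrix.values.to_numpy(), matrix.labels.to_numpy())
    return np.stack(
        [t.tree_.compute_feature_importances(normalize=False) for t in forest.estimators_]
    )


def select_top_k(ranking: ImportanceRanking, k: int) -> list[str]:
    """First k feature ids of the ranking, order preserved."""
    if k > len(ranking.feature_ids):
        raise SelectionError(
            f"k={k} exceeds the {len(ranking.feature_ids)} available features"
        )
    return ranking.top(k)


def train_feature_gan(
    matrix: SignalMatrix, selected: list[str], config: GanConfig
) -> tuple[FeatureGan, pd.DataFrame]:
    """Train the GAN on the selected top-k submatrix (raw PRR scale)."""
    sub = matrix.values[selected].to_numpy(dtype=float)
    return train_gan(sub, config)


def generate_features(
    generator: FeatureGan, n_rows: int, seed: int | None = None
) -> np.ndarray:
    """One generated k-vector per drug row, inverse-transformed to PRR scale."""
    return generator.sample(n_rows, seed=seed)


def append_features(matrix: SignalMatrix, generated: np.ndarray) -> EnhancedMatrix:
    """Concatenate generated columns after the original ADR columns."""
    generated = np.asarray(generated, dtype=float)
    if generated.ndim == 1:
        generated = generated.reshape(len(matrix.values), 0)
    if generated.shape[0] != len(matrix.values):
        raise ShapeError(
            f"generated block has {generated.shape[0]} rows, matrix has {len(matrix.values)}"
        )
    gen_cols = [f"GEN_{j:04d}" for j in range(generated.shape[1])]
    gen_df = pd.DataFrame(generated, index=matrix.values.index, columns=gen_cols)
    values = pd.concat([matrix.values, gen_df], axis=1)
    values.columns.name = matrix.values.columns.name
    provenance = pd.Series(
        ["real"] * matrix.values.shape[1] + ["generated"] * generated.shape[1],
        index=values.columns,
    )
    return EnhancedMatrix(values=values, labels=matrix.labels.copy(), provenance=provenance)


def nonzero_fraction(block: np.ndarray, threshold: float = 0.01) -> float:
    """Fraction of entries whose magnitude exceeds the PRR-scale epsilon."""
    block = np.asarray(block, dtype=float)
    return float((np.abs(block) > threshold).mean()) if block.size else 0.0


def enhance(
    matrix: SignalMatrix,
    top_k: int = 200,
    gan_config: GanConfig | None = None,
    n_trees: int = 100,
    seed: int = 0,
) -> tuple[EnhancedMatrix, dict]:
    """Full FS-GAN stage: rank, select top k, train GAN, append columns.

    Returns the enhanced matrix plus a diagnostics dict (ranking, trained
    generator, and the sparsity of the selected vs generated blocks).
    """
    gan_config = gan_config or GanConfig(seed=seed)
    ranking = rank_features(matrix, n_trees=n_trees, seed=seed)
    selected = select_top_k(ranking, top_k)
    generator, log = train_feature_gan(matrix, selected, gan_config)
    block = generate_features(generator, n_rows=len(matrix.values))
    enhanced = append_features(matrix, block)
    eps = gan_config.zero_threshold
    info = {
        "ranking": ranking,
        "selected": selected,
        "generator": generator,
        "training_log": log,
        "real_block_nonzero_fraction": nonzero_fraction(
            matrix.values[selected].to_numpy(), eps
        ),
        "generated_block_nonzero_fraction": nonzero_fraction(block, eps),
    }
    return enhanced, info
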