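"""Random-forest risk classifier.

K trees are each fit on a bootstrap sample of the training set (size N,
drawn with replacement), split on the best Gini criterion among m randomly
chosen features per node, and grown to purity without pruning.  Prediction
is by majority vote over trees; vote ties go to the lowest label index, and
per-class scores are the tree-vote fractions.  The tree growing itself is
delegated to scikit-learn's forest, which implements exactly this
procedure; voting and tie-breaking are handled here.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .errors import ConfigurationError, PreconditionError, ShapeError

__all__ = ["ForestConfig", "RiskForest", "train_forest"]


@dataclass(frozen=True)
class ForestConfig:
    n_trees: int = 100
    features_per_split: int | str = "sqrt"
    seed: int = 0

    def validate(self) -> None:
        if self.n_trees < 1:
            raise ConfigurationError("n_trees must be >= 1")
        if isinstance(self.features_per_split, int) and self.features_per_split < 1:
            raise ConfigurationError("features_per_split must be >= 1")


@dataclass
class RiskForest:
    """Trained forest plus the metadata needed for reproducible scoring."""

    model: RandomForestClassifier
    config: ForestConfig
    classes: np.ndarray
    n_features: int

    def predict_scores(self, X) -> np.ndarray:
        """Per-class tree-vote fractions; rows sum to 1."""
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features:
            raise ShapeError(
                f"samples have {X.shape[1]} features, forest expects {self.n_features}"
            )
        votes = np.zeros((X.shape[0], len(self.classes)))
        rows = np.arange(X.shape[0])
        for tree in self.model.estimators_:
            # tree classes match the forest's sorted class order
            vote_idx = np.argmax(tree.predict_proba(X), axis=1)
            np.add.at(votes, (rows, vote_idx), 1)
        return votes / self.config.n_trees

    def predict(self, X) -> np.ndarray:
        """Majority-vote labels; ties resolve to the lowest label index."""
        scores = self.predict_scores(X)
        return self.classes[np.argmax(scores, axis=1)]

    def save(self, path: str | Path) -> None:
        joblib.dump(self, path)

    @classmethod
    def load(cls, path: str | Path) -> "RiskForest":
        return joblib.load(path)


def train_forest(X, y, config: ForestConfig | None = None) -> RiskForest:
    """Fit the forest: bootstrap + Gini + per-node feature subsampling,
    trees grown to purity (no depth limit, no pruning)."""
    config = config or ForestConfig()
    config.validate()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    classes = np.unique(y)
    if len(classes) < 2:
        raise PreconditionError("training data must contain at least two classes")
    model = RandomForestClassifier(
        n_estimators=config.n_trees,
        criterion="gini",
        max_features=config.features_per_split,
        bootstrap=True,
        random_state=config.seed,
        n_jobs=1,
    ).fit(X, y)
    return RiskForest(model=model, config=config, classes=classes, n_features=X.shape[1])


def as_matrix(values: pd.DataFrame | np.ndarray) -> np.ndarray:
    return values.to_numpy(dtype=float) if isinstance(values, pd.DataFrame) else np.asarray(values, dtype=float)
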