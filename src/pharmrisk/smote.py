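"""Synthetic minority over-sampling (SMOTE) for the three risk classes.

The class distribution of the drug catalogue is heavily skewed towards
prescription drugs, which biases any classifier towards the majority class.
SMOTE synthesises new minority samples by interpolating between a minority
sample x and one of its k nearest minority neighbours x̄:

    x_new = x + u * (x̄ - x),   u ~ Uniform(0, 1)

so every synthetic point lies on the segment between a real sample and one
of its neighbours (the ``direction="extrapolate"`` variant instead steps
away from the neighbour, x + u * (x - x̄)).

Two balancing modes are provided:

* ``exact_majority`` (default): every minority class is grown to exactly
  the majority-class count, giving a perfectly balanced dataset.
* ``k_times``: each minority class receives K * N⁻ synthetic samples where
  K = floor(N⁺ / N⁻) is the floored imbalance ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .errors import ConfigurationError, DegenerateClassError, NeighborError

__all__ = [
    "SmoteConfig",
    "BalancedDataset",
    "imbalance_ratio",
    "nearest_minority_neighbors",
    "synthesize",
    "balance_classes",
]


@dataclass(frozen=True)
class SmoteConfig:
    k_neighbors: int = 5
    seed: int = 0
    balance_mode: str = "exact_majority"   # or "k_times"
    direction: str = "interpolate"         # or "extrapolate"

    def validate(self) -> None:
        if self.k_neighbors < 1:
            raise ConfigurationError("k_neighbors must be >= 1")
        if self.balance_mode not in ("exact_majority", "k_times"):
            raise ConfigurationError(f"unknown balance_mode {self.balance_mode!r}")
        if self.direction not in ("interpolate", "extrapolate"):
            raise ConfigurationError(f"unknown direction {self.direction!r}")


@dataclass
class BalancedDataset:
    """Feature rows after balancing, with per-row synthetic provenance."""

    values: pd.DataFrame
    labels: pd.Series
    synthetic: pd.Series                  # bool per row
    provenance: pd.DataFrame              # base/neighbour row names + u per synthetic row

    def class_counts(self) -> dict[int, int]:
        return {int(k): int(v) for k, v in self.labels.value_counts().items()}


def imbalance_ratio(n_major: int, n_minor: int) -> tuple[float, int]:
    """Imbalance ratio IR = N⁺/N⁻ and the floored oversampling rate K."""
    if n_minor <= 0:
        raise DegenerateClassError("minority class has no samples")
    ir = n_major / n_minor
    return float(ir), int(np.floor(ir))


def nearest_minority_neighbors(
    index: int, minority: np.ndarray, k: int
) -> np.ndarray:
    """Indices of the k nearest minority samples to ``minority[index]``.

    The sample itself is excluded; distance ties are broken by ascending
    sample index.
    """
    n = len(minority)
    if n < k + 1:
        raise NeighborError(
            f"minority class of size {n} cannot supply k={k} neighbours"
        )
    d = cdist(minority[index:index + 1], minority).ravel()
    order = np.lexsort((np.arange(n), d))
    order = order[order != index]
    return order[:k]


def synthesize(
    x: np.ndarray, neighbor: np.ndarray, u: float, direction: str = "interpolate"
) -> np.ndarray:
    """One synthetic sample from a base sample and a chosen neighbour."""
    x = np.asarray(x, dtype=float)
    neighbor = np.asarray(neighbor, dtype=float)
    if direction == "interpolate":
        return x + u * (neighbor - x)
    return x + u * (x - neighbor)


def balance_classes(
    values: pd.DataFrame, labels: pd.Series, config: SmoteConfig | None = None
) -> BalancedDataset:
    """Oversample every minority class per the configured balance mode.

    All original rows are retained unchanged; synthetic rows are appended
    after them with names ``SYN_<label>_<i>`` and flagged in ``synthetic``.
    Deterministic given ``config.seed``.
    """
    config = config or SmoteConfig()
    config.validate()
    rng = np.random.default_rng([4, config.seed])

    counts = labels.value_counts()
    majority_count = int(counts.max())
    X = values.to_numpy(dtype=float)

    syn_rows, syn_labels, syn_names, prov = [], [], [], []
    for cls in sorted(counts.index):
        n_cls = int(counts[cls])
        if n_cls == majority_count:
            continue  # only minority classes are expanded
        _, k_rate = imbalance_ratio(majority_count, n_cls)
        if config.balance_mode == "exact_majority":
            n_new = majority_count - n_cls
        else:
            n_new = k_rate * n_cls
        if n_new == 0:
            continue
        mask = (labels == cls).to_numpy()
        minority = X[mask]
        minority_names = values.index[mask]
        if len(minority) < config.k_neighbors + 1:
            raise NeighborError(
                f"class {cls} has {len(minority)} samples; "
                f"needs > k_neighbors={config.k_neighbors}"
            )
        dists = cdist(minority, minority)
        neigh = np.empty((len(minority), config.k_neighbors), dtype=int)
        idx = np.arange(len(minority))
        for i in range(len(minority)):
            order = np.lexsort((idx, dists[i]))
            neigh[i] = order[order != i][: config.k_neighbors]
        for t in range(n_new):
            base = t % len(minority)  # cycle so every minority sample seeds evenly
            nb = int(neigh[base, rng.integers(0, config.k_neighbors)])
            u = float(rng.random())
            syn_rows.append(synthesize(minority[base], minority[nb], u, config.direction))
            syn_labels.append(int(cls))
            syn_names.append(f"SYN_{cls}_{t:05d}")
            prov.append(
                {
                    "row": f"SYN_{cls}_{t:05d}",
                    "base": minority_names[base],
                    "neighbor": minority_names[nb],
                    "u": u,
                }
            )

    if syn_rows:
        syn_df = pd.DataFrame(np.vstack(syn_rows), index=syn_names, columns=values.columns)
        out_values = pd.concat([values, syn_df])
        out_labels = pd.concat(
            [labels, pd.Series(syn_labels, index=syn_names, name=labels.name)]
        )
    else:
        out_values = values.copy()
        out_labels = labels.copy()
    synthetic = pd.Series(
        [False] * len(values) + [True] * len(syn_rows), index=out_values.index
    )
    provenance = pd.DataFrame(prov, columns=["row", "base", "neighbor", "u"])
    return BalancedDataset(
        values=out_values,
        labels=out_labels.astype(int),
        synthetic=synthetic,
        provenance=provenance,
    )
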