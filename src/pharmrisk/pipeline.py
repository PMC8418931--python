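"""End-to-end experiment orchestration.

Three model designs are compared on the same report corpus:

* **Model 1** — PRR signal matrix → random forest (imbalanced baseline).
* **Model 2** — PRR → SMOTE balancing → random forest.
* **Model 3** — PRR → FS-GAN feature enhancement → SMOTE → random forest.

Two evaluation protocols are provided:

* a stratified 70/30 train/test split (test size = ceil(fraction * n)); with
  ``split_mode="resample_first"`` the SMOTE/GAN stages run on the *full* dataset
  before splitting (so synthetic neighbours of test points can enter
  training — the historical protocol this package reproduces), while
  ``split_mode="leak_free"`` splits first and fits GAN/SMOTE on the
  training partition only;
* validation on the source matrix: the trained model scores every original
  (unaugmented, unbalanced) drug row.  A Model-3 forest expects the
  generated columns, so the stored generated block is re-attached to the
  original matrix before scoring.

One master seed fixes every stage, so a full run is reproducible bit for
bit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedShuffleSplit

from .disproportionality import SignalMatrix, build_signal_matrix
from .enhancement import EnhancedMatrix, append_features, enhance
from .errors import ShapeError, SplitError
from .etl import aggregate_counts, attach_labels, clean_reports, standardize_names
from .forest import ForestConfig, RiskForest, train_forest
from .gan import GanConfig
from .metrics import EvaluationReport, evaluate
from .smote import SmoteConfig, balance_classes

logger = logging.getLogger("pharmrisk")

__all__ = [
    "ExperimentConfig",
    "ExperimentResult",
    "split_train_test",
    "reports_to_signal_matrix",
    "run_experiment",
    "validate_on_source",
]


@dataclass(frozen=True)
class ExperimentConfig:
    model: int = 3                       # 1=RF, 2=SMOTE+RF, 3=FS_GAN+SMOTE+RF
    test_fraction: float = 0.30
    split_mode: str = "resample_first"            # or "leak_free"
    seed: int = 0
    top_k: int = 200
    ranking_trees: int = 100
    zero_correction: str = "haldane"
    prr_cap: float = 100.0
    gan: GanConfig = field(default_factory=GanConfig)
    smote: SmoteConfig = field(default_factory=SmoteConfig)
    forest: ForestConfig = field(default_factory=ForestConfig)

    def validate(self) -> None:
        if self.model not in (1, 2, 3):
            raise ValueError("model must be 1, 2, or 3")
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must lie in (0, 1)")
        if self.split_mode not in ("resample_first", "leak_free"):
            raise ValueError(f"unknown split_mode {self.split_mode!r}")

    def with_master_seed(self, seed: int) -> "ExperimentConfig":
        """Rederive every stage seed from one master seed."""
        return replace(
            self,
            seed=seed,
            gan=replace(self.gan, seed=seed + 1),
            smote=replace(self.smote, seed=seed + 2),
            forest=replace(self.forest, seed=seed + 3),
        )


@dataclass
class ExperimentResult:
    config: ExperimentConfig
    forest: RiskForest
    report: EvaluationReport
    signal: SignalMatrix
    enhanced_info: dict | None       # ranking / generator / sparsity (model 3)
    generated_block: np.ndarray | None
    train_index: pd.Index
    test_index: pd.Index


def split_train_test(
    values: pd.DataFrame, labels: pd.Series, fraction: float, seed: int
) -> tuple[pd.Index, pd.Index]:
    """Stratified split with test size = ceil(fraction * n)."""
    if not 0.0 < fraction < 1.0:
        raise SplitError("fraction must lie in (0, 1)")
    if labels.value_counts().min() < 2:
        raise SplitError("every class needs >= 2 samples for a stratified split")
    n_test = int(np.ceil(fraction * len(values)))
    splitter = StratifiedShuffleSplit(n_splits=1, test_size=n_test, random_state=seed)
    train_pos, test_pos = next(splitter.split(values, labels))
    return values.index[np.sort(train_pos)], values.index[np.sort(test_pos)]


def reports_to_signal_matrix(
    reports: pd.DataFrame,
    labels: dict[str, int] | pd.Series,
    synonym_map: dict[str, str] | None = None,
    zero_correction: str = "haldane",
    cap: float = 100.0,
) -> tuple[SignalMatrix, dict[str, int]]:
    """ETL + signal detection: raw report rows to a labeled PRR matrix."""
    std = standardize_names(reports, synonym_map)
    valid, log = clean_reports(std)
    table = aggregate_counts(valid)
    table = attach_labels(table, labels)
    matrix = build_signal_matrix(table, zero_correction=zero_correction, cap=cap)
    logger.info(
        "signal stage: %d cleaned records (%s) -> %d drugs x %d ADR terms",
        len(valid), log, len(matrix.drugs), len(matrix.adr_terms),
    )
    return matrix, log


def _enhanced_dataset(
    matrix: SignalMatrix, config: ExperimentConfig, fit_index: pd.Index | None = None
) -> tuple[pd.DataFrame, pd.Series, dict, np.ndarray]:
    """Model-3 feature stage.  When ``fit_index`` is given, ranking and GAN
    training see only those rows (leak-free); generation still covers every
    row so the feature space is consistent."""
    if fit_index is None:
        enhanced, info = enhance(
            matrix, top_k=config.top_k, gan_config=config.gan,
            n_trees=config.ranking_trees, seed=config.seed,
        )
        block = enhanced.values.loc[:, info_generated_cols(enhanced)].to_numpy()
        return enhanced.values, enhanced.labels, info, block

    fit_matrix = SignalMatrix(
        values=matrix.values.loc[fit_index], labels=matrix.labels.loc[fit_index]
    )
    _, info = enhance(
        fit_matrix, top_k=config.top_k, gan_config=config.gan,
        n_trees=config.ranking_trees, seed=config.seed,
    )
    block = info["generator"].sample(len(matrix.values))
    enhanced = append_features(matrix, block)
    return enhanced.values, enhanced.labels, info, block


def info_generated_cols(enhanced: EnhancedMatrix) -> list[str]:
    return [c for c, p in enhanced.provenance.items() if p == "generated"]


def run_experiment(
    reports: pd.DataFrame,
    labels: dict[str, int] | pd.Series,
    config: ExperimentConfig | None = None,
    signal: SignalMatrix | None = None,
) -> ExperimentResult:
    """Run one model design end to end and evaluate on the held-out split.

    ``signal`` short-circuits the ETL/PRR stages when a prebuilt matrix is
    available (e.g. to run the three models on identical inputs).
    """
    config = config or ExperimentConfig()
    config.validate()
    if signal is None:
        signal, _ = reports_to_signal_matrix(
            reports, labels, zero_correction=config.zero_correction, cap=config.prr_cap
        )

    enhanced_info: dict | None = None
    generated: np.ndarray | None = None

    if config.split_mode == "resample_first":
        values, lab = signal.values, signal.labels
        if config.model == 3:
            values, lab, enhanced_info, generated = _enhanced_dataset(signal, config)
        if config.model in (2, 3):
            balanced = balance_classes(values, lab, config.smote)
            values, lab = balanced.values, balanced.labels
        train_idx, test_idx = split_train_test(
            values, lab, config.test_fraction, config.seed
        )
    else:  # leak_free: split on original drugs, fit stages on train only
        train_idx, test_idx = split_train_test(
            signal.values, signal.labels, config.test_fraction, config.seed
        )
        values, lab = signal.values, signal.labels
        if config.model == 3:
            values, lab, enhanced_info, generated = _enhanced_dataset(
                signal, config, fit_index=train_idx
            )
        if config.model in (2, 3):
            balanced = balance_classes(
                values.loc[train_idx], lab.loc[train_idx], config.smote
            )
            train_values, train_labels = balanced.values, balanced.labels
        else:
            train_values, train_labels = values.loc[train_idx], lab.loc[train_idx]
        test_values, test_labels = values.loc[test_idx], lab.loc[test_idx]
        forest = train_forest(train_values, train_labels, config.forest)
        scores = forest.predict_scores(test_values)
        report = evaluate(test_labels, forest.predict(test_values), scores)
        return ExperimentResult(
            config=config, forest=forest, report=report, signal=signal,
            enhanced_info=enhanced_info, generated_block=generated,
            train_index=balanced.values.index if config.model in (2, 3) else train_idx,
            test_index=test_idx,
        )

    forest = train_forest(values.loc[train_idx], lab.loc[train_idx], config.forest)
    test_values = values.loc[test_idx]
    scores = forest.predict_scores(test_values)
    report = evaluate(lab.loc[test_idx], forest.predict(test_values), scores)
    logger.info(
        "model %d: train %d x %d, test %d, accuracy %.4f",
        config.model, len(train_idx), values.shape[1], len(test_idx), report.accuracy,
    )
    return ExperimentResult(
        config=config, forest=forest, report=report, signal=signal,
        enhanced_info=enhanced_info, generated_block=generated,
        train_index=train_idx, test_index=test_idx,
    )


def validate_on_source(result: ExperimentResult) -> EvaluationReport:
    """Score the trained model on every original drug row.

    Model 3 forests expect the generated columns, so the stored generated
    block (aligned to the original drug order) is appended before scoring.
    """
    values = result.signal.values
    if result.config.model == 3:
        if result.generated_block is None:
            raise ShapeError("model 3 result is missing its generated feature block")
        padded = append_features(result.signal, result.generated_block)
        values = padded.values
    if values.shape[1] != result.forest.n_features:
        raise ShapeError(
            f"{values.shape[1]} features after padding, forest expects "
            f"{result.forest.n_features}"
        )
    scores = result.forest.predict_scores(values)
    return evaluate(result.signal.labels, result.forest.predict(values), scores)
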