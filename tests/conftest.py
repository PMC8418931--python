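"""Shared fixtures.

``fullscale_run`` is the expensive end-to-end fixture: one synthetic
corpus at full catalogue scale (1047 drugs x 751 ADR terms, class split
887/113/47) pushed through all three model designs.  It is session-scoped
so the whole suite pays for GAN training exactly once.
"""

from __future__ import annotations

import dataclasses

import pandas as pd
import pytest

from pharmrisk import (
    ExperimentConfig,
    GanConfig,
    GeneratorConfig,
    aggregate_counts,
    attach_labels,
    build_signal_matrix,
    clean_reports,
    generate_catalog,
    generate_reports,
    run_experiment,
)

FULLSCALE_SEED = 7
# study conditions: generator defaults (desk-scale corpus analogue), GAN at
# 1000 epochs (training diagnostics are converged there; see docs/methods.md)
PIPELINE_GAN_EPOCHS = 1000


@pytest.fixture(scope="session")
def fullscale_config() -> GeneratorConfig:
    return GeneratorConfig(seed=FULLSCALE_SEED)


@pytest.fixture(scope="session")
def fullscale_corpus(fullscale_config):
    catalog = generate_catalog(fullscale_config)
    reports = generate_reports(fullscale_config, catalog)
    return catalog, reports


@pytest.fixture(scope="session")
def fullscale_signal(fullscale_corpus):
    catalog, reports = fullscale_corpus
    valid, _ = clean_reports(reports)
    table = attach_labels(aggregate_counts(valid), catalog.labels)
    return build_signal_matrix(table)


@pytest.fixture(scope="session")
def fullscale_run(fullscale_signal):
    """Models 1-3 trained/evaluated on the same full-scale signal matrix."""
    results = {}
    for model in (1, 2, 3):
        config = ExperimentConfig(
            model=model, gan=GanConfig(epochs=PIPELINE_GAN_EPOCHS)
        ).with_master_seed(FULLSCALE_SEED)
        results[model] = run_experiment(None, None, config, signal=fullscale_signal)
    return results


@pytest.fixture()
def small_config() -> GeneratorConfig:
    """A fast corpus: 60 drugs, 80 ADR terms, dense enough to classify."""
    return GeneratorConfig(
        n_rx=30, n_otc_a=18, n_otc_b=12, n_adr_terms=80,
        reports_per_drug_mean=40.0, class_profile_shift=0.8,
        target_nonzero_fraction=0.15, dup_rate=0.1, invalid_rate=0.1, seed=5,
    )


@pytest.fixture()
def small_signal(small_config):
    catalog = generate_catalog(small_config)
    reports = generate_reports(small_config, catalog)
    valid, _ = clean_reports(reports)
    table = attach_labels(aggregate_counts(valid), catalog.labels)
    return build_signal_matrix(table)


def make_reports(rows: list[tuple]) -> pd.DataFrame:
    """Report frame from (report_id, drug, adr) triples; demographics fixed."""
    return pd.DataFrame(
        [
            {
                "report_id": rid, "region": "Nanjing", "age": 40, "gender": "F",
                "drug_name": drug, "adr_symptom": adr,
            }
            for rid, drug, adr in rows
        ]
    )
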