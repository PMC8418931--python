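"""Seeded generator of synthetic spontaneous ADR report corpora.

Real spontaneous-reporting extracts (drug name + reported adverse-reaction
term per report, with patient demographics) are confidential, so this module
emulates their statistical structure instead: a drug catalogue split into
three risk classes (0 = Rx, 1 = OTC-A, 2 = OTC-B), a fixed ADR-term
vocabulary, per-drug report counts, class-typical symptom profiles, and the
duplicate / incomplete records that a cleaning stage must handle.

Generative model
----------------
Each risk class owns a pool of "class-typical" ADR terms; pools of adjacent
risk classes overlap by 30% so the classes are separable but not trivially
so.  Every drug draws a small personal vocabulary from its class pool.  A
drug receives ``Poisson(reports_per_drug_mean)`` reports; each report's ADR
term comes from the drug's personal class vocabulary with probability
``class_profile_shift`` and otherwise from a *shared* Zipf-shaped background
law over the whole vocabulary.  At ``class_profile_shift = 0`` the mixture
collapses to the shared background, so per-class term distributions are
identical by construction.

The personal-vocabulary size and the Zipf exponent are calibrated
numerically so that the expected nonzero fraction of the downstream
drug x ADR count matrix matches ``target_nonzero_fraction`` (the Poisson
report count makes per-term counts independent Poissons, which gives a
closed-form expected-coverage equation to solve).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq

from .errors import ConfigurationError, PreconditionError

__all__ = [
    "GeneratorConfig",
    "Catalog",
    "generate_catalog",
    "generate_reports",
    "write_reports_csv",
    "write_labels_csv",
    "save_config",
    "load_config",
]

REPORT_COLUMNS = ["report_id", "region", "age", "gender", "drug_name", "adr_symptom"]

_REGIONS = [
    "Nanjing", "Suzhou", "Wuxi", "Changzhou", "Nantong",
    "Yangzhou", "Xuzhou", "Taizhou",
]

# fraction of a class pool shared with each adjacent risk class
_POOL_OVERLAP = 0.30


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic corpus.

    Defaults reproduce the desk-scale analogue of the confidential extract:
    1047 drugs split 887/113/47 over Rx/OTC-A/OTC-B, 751 ADR terms, and a
    drug x ADR matrix with ~1.7% nonzero entries.
    """

    n_rx: int = 887
    n_otc_a: int = 113
    n_otc_b: int = 47
    n_adr_terms: int = 751
    reports_per_drug_mean: float = 50.0
    class_profile_shift: float = 0.8
    target_nonzero_fraction: float = 0.017
    dup_rate: float = 0.05
    invalid_rate: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        counts = (self.n_rx, self.n_otc_a, self.n_otc_b, self.n_adr_terms)
        if any(c <= 0 for c in counts):
            raise ConfigurationError("all catalogue counts must be positive")
        if self.n_rx + self.n_otc_a + self.n_otc_b < 3:
            raise ConfigurationError("need at least one drug per risk class")
        if self.reports_per_drug_mean <= 0:
            raise ConfigurationError("reports_per_drug_mean must be positive")
        if not 0.0 <= self.class_profile_shift <= 1.0:
            raise ConfigurationError("class_profile_shift must lie in [0, 1]")
        if not 0.0 < self.target_nonzero_fraction <= 1.0:
            raise ConfigurationError("target_nonzero_fraction must lie in (0, 1]")
        if not (0.0 <= self.dup_rate < 1.0 and 0.0 <= self.invalid_rate < 1.0):
            raise ConfigurationError("dup_rate and invalid_rate must lie in [0, 1)")
        if self.dup_rate + self.invalid_rate >= 1.0:
            raise ConfigurationError("dup_rate + invalid_rate must be < 1")


@dataclass
class Catalog:
    """Drug list with true risk labels plus the ADR-term vocabulary."""

    drugs: pd.DataFrame          # columns: drug_name, label
    adr_terms: list[str]
    class_pools: dict[int, np.ndarray] = field(repr=False)  # label -> term indices

    @property
    def labels(self) -> pd.Series:
        return self.drugs.set_index("drug_name")["label"]


def generate_catalog(config: GeneratorConfig) -> Catalog:
    """Build the drug catalogue and ADR vocabulary for a configuration.

    Drugs are labelled 0/1/2 (Rx/OTC-A/OTC-B); ADR terms are partitioned
    into three class-typical pools that overlap 30% between adjacent risk
    classes, leaving the remaining terms background-only.
    """
    config.validate()
    n_drugs = config.n_rx + config.n_otc_a + config.n_otc_b
    labels = np.repeat([0, 1, 2], [config.n_rx, config.n_otc_a, config.n_otc_b])
    drugs = pd.DataFrame(
        {
            "drug_name": [f"DRUG_{i:05d}" for i in range(n_drugs)],
            "label": labels.astype(int),
        }
    )
    adr_terms = [f"ADR_{j:04d}" for j in range(config.n_adr_terms)]

    # lay pools on a line: each of size P, adjacent pools share 0.3*P terms
    d = config.n_adr_terms
    pool_size = max(1, int(d / (3 - 2 * _POOL_OVERLAP)))
    step = max(1, int(round(pool_size * (1 - _POOL_OVERLAP))))
    class_pools = {}
    for c in range(3):
        start = c * step
        stop = min(start + pool_size, d)
        class_pools[c] = np.arange(start, stop)
    return Catalog(drugs=drugs, adr_terms=adr_terms, class_pools=class_pools)


def _expected_distinct(rates: np.ndarray) -> float:
    # terms hit by a Poisson(rate) count are present with prob 1 - exp(-rate)
    return float(np.sum(-np.expm1(-rates)))


def _solve_class_vocab_size(lam_class: float, target: float, pool_size: int) -> int:
    """Personal class-vocabulary size v with v*(1-exp(-lam/v)) ≈ target."""
    if target <= 0 or lam_class <= 0:
        return 0
    if target >= 0.99 * lam_class:  # coverage saturates at the report count
        return pool_size
    g = lambda v: v * -np.expm1(-lam_class / v) - target
    v = brentq(g, 1e-9, 1e7)
    return int(min(max(1, round(v)), pool_size))


def _solve_background_exponent(lam_bg: float, target: float, d: int) -> float:
    """Zipf exponent s with sum_t (1 - exp(-lam*q_t(s))) ≈ target."""
    if lam_bg <= 0:
        return 0.0
    ranks = np.arange(1, d + 1, dtype=float)

    def coverage(s: float) -> float:
        w = ranks ** (-s)
        return _expected_distinct(lam_bg * w / w.sum())

    if coverage(0.0) <= target:  # uniform already maximises coverage
        return 0.0
    return float(brentq(lambda s: coverage(s) - target, 0.0, 12.0))


def generate_reports(config: GeneratorConfig, catalog: Catalog) -> pd.DataFrame:
    """Simulate the raw report stream for a catalogue.

    Returns a DataFrame with one row per (report, drug, ADR mention) in the
    columns ``report_id, region, age, gender, drug_name, adr_symptom``.
    Besides the clean base records, ``round(dup_rate * n_base)`` exact
    duplicate rows and ``round(invalid_rate * n_base)`` records with a
    missing drug name or symptom are injected, then the rows are shuffled.
    Fully deterministic given ``config.seed``.
    """
    config.validate()
    if len(catalog.drugs) == 0:
        raise PreconditionError("catalog contains no drugs")
    rng = np.random.default_rng([1, config.seed])
    d = config.n_adr_terms
    lam = config.reports_per_drug_mean
    shift = config.class_profile_shift

    target_distinct = config.target_nonzero_fraction * d
    pool_size = len(catalog.class_pools[0])
    v_class = _solve_class_vocab_size(lam * shift, shift * target_distinct, pool_size)
    s_bg = _solve_background_exponent(
        lam * (1 - shift), (1 - shift) * target_distinct, d
    )
    # background mass assigned to a seeded permutation of the vocabulary so
    # the skew is not aligned with the class-pool layout
    perm = rng.permutation(d)
    w = np.arange(1, d + 1, dtype=float) ** (-s_bg)
    bg_probs = np.empty(d)
    bg_probs[perm] = w / w.sum()

    drug_names = catalog.drugs["drug_name"].to_numpy()
    drug_labels = catalog.drugs["label"].to_numpy()
    n_reports = rng.poisson(lam, size=len(drug_names))

    rows_drug: list[np.ndarray] = []
    rows_term: list[np.ndarray] = []
    for i, (name, label) in enumerate(zip(drug_names, drug_labels)):
        r = int(n_reports[i])
        if r == 0:
            continue
        pool = catalog.class_pools[int(label)]
        vocab = (
            rng.choice(pool, size=min(v_class, len(pool)), replace=False)
            if v_class > 0
            else np.empty(0, dtype=int)
        )
        from_class = (
            rng.random(r) < shift if len(vocab) else np.zeros(r, dtype=bool)
        )
        terms = np.empty(r, dtype=int)
        n_c = int(from_class.sum())
        if n_c:
            terms[from_class] = rng.choice(vocab, size=n_c, replace=True)
        if r - n_c:
            terms[~from_class] = rng.choice(d, size=r - n_c, replace=True, p=bg_probs)
        rows_drug.append(np.repeat(i, r))
        rows_term.append(terms)

    drug_idx = np.concatenate(rows_drug) if rows_drug else np.empty(0, dtype=int)
    term_idx = np.concatenate(rows_term) if rows_term else np.empty(0, dtype=int)

    # the vocabulary is defined from observed reports, so every term must be
    # mentioned at least once: give each unseen term one report from a
    # uniformly drawn drug (a negligible density perturbation)
    unseen = np.setdiff1d(np.arange(d), term_idx)
    if len(unseen) and len(drug_names):
        drug_idx = np.concatenate([drug_idx, rng.integers(0, len(drug_names), len(unseen))])
        term_idx = np.concatenate([term_idx, unseen])

    n_base = len(drug_idx)
    adr_terms = np.asarray(catalog.adr_terms, dtype=object)

    base = pd.DataFrame(
        {
            "report_id": [f"R{k:08d}" for k in range(n_base)],
            "region": rng.choice(_REGIONS, size=n_base),
            "age": _with_missing(rng.integers(1, 91, size=n_base).astype(object), 0.05, rng),
            "gender": _with_missing(rng.choice(["M", "F"], size=n_base).astype(object), 0.05, rng),
            "drug_name": drug_names[drug_idx],
            "adr_symptom": adr_terms[term_idx],
        }
    )

    n_dup = int(round(config.dup_rate * n_base))
    dup = base.iloc[rng.integers(0, n_base, size=n_dup)] if n_dup and n_base else base.iloc[:0]

    n_inv = int(round(config.invalid_rate * n_base))
    if n_inv and n_base:
        inv = base.iloc[rng.integers(0, n_base, size=n_inv)].copy()
        inv["report_id"] = [f"R{k:08d}" for k in range(n_base, n_base + n_inv)]
        drop_drug = rng.random(n_inv) < 0.5
        inv.loc[drop_drug, "drug_name"] = None
        inv.loc[~drop_drug, "adr_symptom"] = None
    else:
        inv = base.iloc[:0]

    out = pd.concat([base, dup, inv], ignore_index=True)
    out = out.iloc[rng.permutation(len(out))].reset_index(drop=True)
    return out


def _with_missing(values: np.ndarray, frac: float, rng: np.random.Generator) -> np.ndarray:
    values = values.copy()
    mask = rng.random(len(values)) < frac
    values[mask] = None
    return values


def write_reports_csv(reports: pd.DataFrame, path: str | Path) -> None:
    reports.to_csv(path, index=False, columns=REPORT_COLUMNS)


def write_labels_csv(catalog: Catalog, path: str | Path) -> None:
    catalog.drugs.to_csv(path, index=False, columns=["drug_name", "label"])


def save_config(config: GeneratorConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(asdict(config), sort_keys=False))


def load_config(path: str | Path) -> GeneratorConfig:
    return GeneratorConfig(**yaml.safe_load(Path(path).read_text()))
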