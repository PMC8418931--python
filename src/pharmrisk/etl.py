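"""Cleaning, standardisation, and aggregation of spontaneous reports.

Raw spontaneous-report streams contain duplicated submissions and records
with no reference value (missing drug name or missing symptom).  This module
removes them, maps drug and ADR terms to canonical names through an explicit
synonym table, and aggregates the surviving records into a drug x ADR-term
count table — one count per (report, drug, ADR) mention.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, LabelingError, LookupError_

__all__ = [
    "DrugAdrCountTable",
    "clean_reports",
    "standardize_names",
    "aggregate_counts",
    "attach_labels",
]

_DEDUP_KEY = ["report_id", "drug_name", "adr_symptom"]


@dataclass
class DrugAdrCountTable:
    """Drug x ADR-term mention counts with marginals.

    ``counts`` is indexed by drug name with one column per ADR term; the
    marginals are derived, never stored, so they cannot drift out of sync.
    An optional ``labels`` vector (0 = Rx, 1 = OTC-A, 2 = OTC-B) is aligned
    to the drug order once :func:`attach_labels` has run.
    """

    counts: pd.DataFrame
    labels: pd.Series | None = None

    @property
    def drugs(self) -> list[str]:
        return list(self.counts.index)

    @property
    def adr_terms(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def row_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    @property
    def grand_total(self) -> int:
        return int(self.counts.to_numpy().sum())

    @property
    def nonzero_fraction(self) -> float:
        values = self.counts.to_numpy()
        return float(np.count_nonzero(values) / values.size) if values.size else 0.0

    def to_csv(self, path: str | Path) -> None:
        self.counts.to_csv(path, index_label="drug_name")

    @classmethod
    def from_csv(cls, path: str | Path) -> "DrugAdrCountTable":
        counts = pd.read_csv(path, index_col="drug_name")
        return cls(counts=counts.astype(int))


def clean_reports(reports: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Drop incomplete and duplicated records.

    A record is incomplete when its drug name or ADR symptom is missing;
    duplicates are exact matches on ``(report_id, drug_name, adr_symptom)``
    and the first occurrence is kept.  Returns the valid records and a
    rejection log keyed by reason.
    """
    if len(reports) == 0:
        return reports.copy(), {"incomplete": 0, "duplicate": 0}
    incomplete = reports["drug_name"].isna() | reports["adr_symptom"].isna()
    complete = reports.loc[~incomplete]
    duplicated = complete.duplicated(subset=_DEDUP_KEY, keep="first")
    valid = complete.loc[~duplicated].reset_index(drop=True)
    log = {"incomplete": int(incomplete.sum()), "duplicate": int(duplicated.sum())}
    return valid, log


def standardize_names(
    reports: pd.DataFrame, synonym_map: dict[str, str] | None = None
) -> pd.DataFrame:
    """Replace drug and ADR terms by their canonical form.

    The synonym map must be idempotent: every canonical value maps to itself
    (or is absent from the keys).  Unmapped terms pass through unchanged.
    """
    if not synonym_map:
        return reports.copy()
    for value in synonym_map.values():
        if value in synonym_map and synonym_map[value] != value:
            raise ConfigurationError(
                f"synonym map is not idempotent: {value!r} is also a non-identity key"
            )
    out = reports.copy()
    for col in ("drug_name", "adr_symptom"):
        out[col] = out[col].map(lambda t: synonym_map.get(t, t))
    return out


def aggregate_counts(reports: pd.DataFrame) -> DrugAdrCountTable:
    """Cross-tabulate cleaned records into mention counts.

    Each record increments the (drug, ADR) cell by one, so the grand total
    equals the number of cleaned records.  Drugs or terms with no records
    simply never appear.  Drug and term orders are sorted, which makes the
    result independent of record order.
    """
    if len(reports) == 0:
        return DrugAdrCountTable(counts=pd.DataFrame())
    counts = pd.crosstab(reports["drug_name"], reports["adr_symptom"])
    counts = counts.sort_index(axis=0).sort_index(axis=1)
    counts.index.name = "drug_name"
    counts.columns.name = "adr_symptom"
    return DrugAdrCountTable(counts=counts.astype(int))


def attach_labels(
    table: DrugAdrCountTable, labels: dict[str, int] | pd.Series
) -> DrugAdrCountTable:
    """Align risk labels (0/1/2) to the table's drug order."""
    if isinstance(labels, pd.Series):
        labels = labels.to_dict()
    missing = [d for d in table.drugs if d not in labels]
    if missing:
        raise LabelingError(f"no label for drug(s): {missing[:5]}")
    aligned = pd.Series([int(labels[d]) for d in table.drugs], index=table.counts.index, name="label")
    return DrugAdrCountTable(counts=table.counts, labels=aligned)


def write_rejection_log(log: dict[str, int], path: str | Path) -> None:
    Path(path).write_text(json.dumps(log, indent=2, sort_keys=True))


def lookup_indices(table: DrugAdrCountTable, drug: str, adr: str) -> tuple[int, int]:
    """Positions of a drug and ADR term in the table, or a lookup error."""
    try:
        i = table.counts.index.get_loc(drug)
        j = table.counts.columns.get_loc(adr)
    except KeyError as exc:
        raise LookupError_(f"unknown drug or ADR term: {exc}") from exc
    return int(i), int(j)
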