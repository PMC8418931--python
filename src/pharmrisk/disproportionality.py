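"""Proportional reporting ratio (PRR) signal detection.

For every drug-ADR pair the mention counts are folded into the classic
2x2 disproportionality table

    =============  ===========  ==========
    .              target ADR   other ADRs
    target drug    A            B
    other drugs    C            D
    =============  ===========  ==========

and the signal strength is PRR = (A / (A + B)) / (C / (C + D)): the rate at
which the target drug's reports mention the target ADR relative to the rate
in all other drugs' reports.  PRR > 1 marks a disproportionately reported
(higher-risk) association.  The drugs x ADR-terms matrix of PRR values,
with the per-drug risk label as the final column, is the feature matrix
every downstream stage consumes.

Zero handling (a choice the classic definition leaves open):

* ``A = 0`` — no mention, no signal: the cell is 0 by definition, which also
  preserves the count matrix's sparsity pattern.
* ``A > 0, C = 0`` — the comparator rate is empty.  Default is the
  Haldane–Anscombe continuity correction (add 0.5 to all four cells);
  alternatively ``zero_correction="cap"`` clamps the value to ``cap``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import PreconditionError, UndefinedPairError
from .etl import DrugAdrCountTable, attach_labels, lookup_indices

__all__ = ["ContingencyCells", "SignalMatrix", "contingency", "prr", "build_signal_matrix"]


@dataclass(frozen=True)
class ContingencyCells:
    """One drug-ADR 2x2 table; cells partition the grand total."""

    A: int
    B: int
    C: int
    D: int

    def __post_init__(self):
        if min(self.A, self.B, self.C, self.D) < 0:
            raise PreconditionError("contingency cells must be non-negative")

    @property
    def total(self) -> int:
        return self.A + self.B + self.C + self.D


@dataclass
class SignalMatrix:
    """Drugs x ADR-terms PRR values plus per-drug risk labels."""

    values: pd.DataFrame     # index: drug names; columns: ADR terms
    labels: pd.Series        # aligned to values.index; 0/1/2

    @property
    def drugs(self) -> list[str]:
        return list(self.values.index)

    @property
    def adr_terms(self) -> list[str]:
        return list(self.values.columns)

    @property
    def nonzero_fraction(self) -> float:
        v = self.values.to_numpy()
        return float(np.count_nonzero(v) / v.size) if v.size else 0.0

    def to_csv(self, path: str | Path) -> None:
        out = self.values.copy()
        out["label"] = self.labels
        out.to_csv(path, index_label="drug_name")

    @classmethod
    def from_csv(cls, path: str | Path) -> "SignalMatrix":
        df = pd.read_csv(path, index_col="drug_name")
        labels = df.pop("label").astype(int)
        return cls(values=df, labels=labels)


def contingency(table: DrugAdrCountTable, drug: str, adr: str) -> ContingencyCells:
    """2x2 disproportionality cells for one drug-ADR pair."""
    i, j = lookup_indices(table, drug, adr)
    counts = table.counts.to_numpy()
    a = int(counts[i, j])
    b = int(counts[i].sum()) - a
    c = int(counts[:, j].sum()) - a
    d = int(counts.sum()) - a - b - c
    return ContingencyCells(A=a, B=b, C=c, D=d)


def prr(
    cells: ContingencyCells,
    zero_correction: str = "haldane",
    cap: float = 100.0,
) -> float:
    """Proportional reporting ratio of one 2x2 table.

    Raises :class:`UndefinedPairError` when the target drug has no reports
    at all (A + B = 0), where the reporting rate is undefined.
    """
    a, b, c, d = cells.A, cells.B, cells.C, cells.D
    if a + b == 0:
        raise UndefinedPairError("PRR undefined: target drug has no reports (A+B=0)")
    if a == 0:
        return 0.0
    if c == 0:
        if zero_correction == "cap":
            return float(cap)
        if zero_correction != "haldane":
            raise ValueError(f"unknown zero_correction: {zero_correction!r}")
        a2, b2, c2, d2 = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        return float((a2 / (a2 + b2)) / (c2 / (c2 + d2)))
    return float((a / (a + b)) / (c / (c + d)))


def build_signal_matrix(
    table: DrugAdrCountTable,
    labels: dict[str, int] | pd.Series | None = None,
    zero_correction: str = "haldane",
    cap: float = 100.0,
) -> SignalMatrix:
    """PRR matrix over all drug-ADR pairs, vectorised over the count table.

    Drugs or ADR terms with an all-zero margin are dropped first (PRR is
    undefined on empty margins).  Structural zeros of the count matrix are
    preserved exactly: values[i, j] = 0 wherever counts[i, j] = 0.
    """
    if labels is not None:
        table = attach_labels(table, labels)
    if table.labels is None:
        raise PreconditionError("signal matrix needs a labeled count table")

    keep_rows = table.counts.sum(axis=1) > 0
    keep_cols = table.counts.sum(axis=0) > 0
    counts_df = table.counts.loc[keep_rows, keep_cols]
    lab = table.labels.loc[keep_rows]

    a = counts_df.to_numpy(dtype=float)
    row = a.sum(axis=1, keepdims=True)
    col = a.sum(axis=0, keepdims=True)
    n = a.sum()
    b = row - a
    c = col - a
    d = n - a - b - c

    with np.errstate(divide="ignore", invalid="ignore"):
        values = (a / (a + b)) / (c / (c + d))
    # A > 0 with C = 0: continuity-correct or cap
    sat = (a > 0) & (c == 0)
    if sat.any():
        if zero_correction == "cap":
            values[sat] = cap
        elif zero_correction == "haldane":
            a2, b2, c2, d2 = a + 0.5, b + 0.5, c + 0.5, d + 0.5
            values[sat] = ((a2 / (a2 + b2)) / (c2 / (c2 + d2)))[sat]
        else:
            raise ValueError(f"unknown zero_correction: {zero_correction!r}")
    values[a == 0] = 0.0
    if not np.isfinite(values).all():
        raise AssertionError("non-finite PRR values after zero handling")

    frame = pd.DataFrame(values, index=counts_df.index, columns=counts_df.columns)
    return SignalMatrix(values=frame, labels=lab.astype(int))
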