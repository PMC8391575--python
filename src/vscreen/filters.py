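"""Deterministic screening-funnel filters and stage accounting.

A virtual-screening funnel narrows a large library in ordered stages
(pharmacophore match, docking-score cutoff, drug-likeness, manual
inspection).  Each stage is a pure per-row predicate; the funnel report
records survivors and the percentage of the original library at each
stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "LIPINSKI_FIELDS",
    "lipinski_pass",
    "lipinski_filter",
    "score_filter",
    "flag_filter",
    "FunnelReport",
    "funnel",
]

LIPINSKI_FIELDS = ("mw", "hbd", "hba", "logp")

_LIPINSKI_LIMITS = {"mw": 500.0, "hbd": 5.0, "hba": 10.0, "logp": 5.0}


def lipinski_pass(compound, canonical: bool = False):
    """Rule-of-five check: MW < 500 Da, HBD < 5, HBA < 10, logP < 5.

    The default uses strict ``<`` bounds; ``canonical=True`` switches to
    the more common ``<=`` convention.  Returns ``(passed, violations)``
    where violations names the offending fields.
    """
    violations = []
    for fld, limit in _LIPINSKI_LIMITS.items():
        if fld not in compound or pd.isna(compound[fld]):
            raise ValueError(f"missing property '{fld}' required for rule-of-five check")
        value = float(compound[fld])
        ok = value <= limit if canonical else value < limit
        if not ok:
            violations.append(fld)
    return len(violations) == 0, violations


def lipinski_filter(table: pd.DataFrame, canonical: bool = False) -> pd.DataFrame:
    """Rows of ``table`` passing the rule of five."""
    mask = table.apply(lambda row: lipinski_pass(row, canonical=canonical)[0], axis=1)
    return table[mask] if len(table) else table


def score_filter(
    table: pd.DataFrame,
    cutoff: float = -6.0,
    column: str = "score",
    lower_is_better: bool = True,
) -> pd.DataFrame:
    """Keep compounds with docking score at least as good as ``cutoff``.

    With ``lower_is_better`` (binding energies), "at least as good" means
    score <= cutoff; boundary values survive.
    """
    if len(table) == 0:
        return table
    if lower_is_better:
        return table[table[column] <= cutoff]
    return table[table[column] >= cutoff]


def flag_filter(table: pd.DataFrame, column: str) -> pd.DataFrame:
    """Keep rows whose boolean column is true (e.g. a visual-inspection flag)."""
    if len(table) == 0:
        return table
    return table[table[column].astype(bool)]


@dataclass
class FunnelReport:
    """Per-stage attrition accounting."""

    stages: pd.DataFrame  # columns: stage, n_in, n_out, percent_of_original
    final: pd.DataFrame  # surviving rows

    def counts(self) -> list:
        return list(self.stages["n_out"])


def funnel(stages, table: pd.DataFrame) -> FunnelReport:
    """Apply ordered ``(name, filter_fn)`` stages and account for attrition.

    Each ``filter_fn`` maps a DataFrame to its surviving subset.
    Percentages are relative to the original (first-stage) input.
    """
    n0 = len(table)
    rows = []
    current = table
    for name, fn in stages:
        n_in = len(current)
        current = fn(current)
        if len(current) > n_in:
            raise ValueError(f"stage '{name}' produced more rows than it received")
        rows.append(
            {
                "stage": name,
                "n_in": n_in,
                "n_out": len(current),
                "percent_of_original": 100.0 * len(current) / n0 if n0 else 0.0,
            }
        )
    return FunnelReport(pd.DataFrame(rows), current)
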