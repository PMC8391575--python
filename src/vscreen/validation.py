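"""Pharmacophore hit-list validation and activity-scale machinery.

Given a screen of a database of D molecules containing A known actives
that returns Ht hits of which Ha are active, the standard Guner-Henry
validation statistics are::

    %Y  = Ha / Ht * 100                    (yield of actives)
    %A  = Ha / A * 100                     (ratio of actives retrieved)
    E   = (Ha * D) / (Ht * A)              (enrichment factor)
    FN  = A - Ha,  FP = Ht - Ha
    GH  = [Ha (3A + Ht) / (4 Ht A)] * [1 - (Ht - Ha) / (D - A)]

GH lies in [0, 1]: 1 for a model retrieving all actives and nothing else,
0 for a null model.  The activity scale buckets IC50 values into
active (+++, IC50 <= 0.3 uM), moderately active (++, 0.3 < IC50 < 2.5 uM),
and inactive (+, IC50 >= 2.5 uM).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "HitListStats",
    "ValidationReport",
    "validate",
    "classify_activity",
    "pic50",
    "pic50_to_ic50_um",
    "scale_confusion",
    "ACTIVITY_SCALES",
]

ACTIVITY_SCALES = ("+++", "++", "+")

#: IC50 boundaries of the activity scale, in uM.
ACTIVE_MAX_UM = 0.3
INACTIVE_MIN_UM = 2.5


@dataclass(frozen=True)
class HitListStats:
    """The validation quadruple: database size D, actives A, hits Ht, active hits Ha."""

    d: int
    a: int
    ht: int
    ha: int

    def __post_init__(self) -> None:
        if not 0 <= self.ha <= min(self.ht, self.a):
            raise ValueError("need 0 <= Ha <= min(Ht, A)")
        if self.ht > self.d or self.a > self.d:
            raise ValueError("Ht and A cannot exceed D")
        # inactive hits cannot outnumber the database's inactives
        if self.ht - self.ha > self.d - self.a:
            raise ValueError("need Ht - Ha <= D - A (false positives exceed inactives)")


@dataclass(frozen=True)
class ValidationReport:
    percent_yield: float
    percent_ratio: float
    enrichment: float
    false_negatives: int
    false_positives: int
    gh: float

    def to_dict(self) -> dict:
        return {
            "percent_yield": self.percent_yield,
            "percent_ratio": self.percent_ratio,
            "enrichment": self.enrichment,
            "false_negatives": self.false_negatives,
            "false_positives": self.false_positives,
            "gh": self.gh,
        }

    def rounded(self, ndigits: int = 2) -> "ValidationReport":
        """Report at printed-table precision."""
        return ValidationReport(
            round(self.percent_yield, ndigits),
            round(self.percent_ratio, ndigits),
            round(self.enrichment, ndigits),
            self.false_negatives,
            self.false_positives,
            round(self.gh, ndigits),
        )


def validate(stats: HitListStats) -> ValidationReport:
    """Compute the full validation report from a hit-list quadruple."""
    d, a, ht, ha = stats.d, stats.a, stats.ht, stats.ha
    if ht == 0 or a == 0:
        raise ValueError("yield/enrichment undefined for Ht = 0 or A = 0")
    if d == a:
        raise ValueError("GH undefined when the database holds only actives (D = A)")
    percent_yield = 100.0 * ha / ht
    percent_ratio = 100.0 * ha / a
    enrichment = ha * d / (ht * a)
    gh = (ha * (3 * a + ht) / (4.0 * ht * a)) * (1.0 - (ht - ha) / float(d - a))
    return ValidationReport(
        percent_yield=percent_yield,
        percent_ratio=percent_ratio,
        enrichment=enrichment,
        false_negatives=a - ha,
        false_positives=ht - ha,
        gh=gh,
    )


def classify_activity(ic50_um: float) -> str:
    """Bucket an IC50 (uM) into the three-level activity scale.

    Boundary semantics: IC50 <= 0.3 uM is active (+++), IC50 >= 2.5 uM is
    inactive (+), strictly between is moderately active (++).
    """
    if not np.isfinite(ic50_um) or ic50_um <= 0:
        raise ValueError(f"IC50 must be a positive concentration, got {ic50_um!r}")
    if ic50_um <= ACTIVE_MAX_UM:
        return "+++"
    if ic50_um >= INACTIVE_MIN_UM:
        return "+"
    return "++"


def pic50(ic50_um: float) -> float:
    """pIC50 = -log10(IC50 in molar) from an IC50 given in uM."""
    if not np.isfinite(ic50_um) or ic50_um <= 0:
        raise ValueError(f"IC50 must be a positive concentration, got {ic50_um!r}")
    return float(-np.log10(ic50_um * 1e-6))


def pic50_to_ic50_um(p: float) -> float:
    """Inverse of :func:`pic50`."""
    return float(10.0 ** (6.0 - p))


def scale_confusion(
    records: pd.DataFrame,
    error_threshold: float = 3.0,
    use_printed_scales: bool = True,
) -> tuple:
    """Cross-tabulate experimental vs estimated activity scales.

    Parameters
    ----------
    records : DataFrame
        Requires ``pic50_experimental`` and ``pic50_estimated``; optionally
        ``error`` (consumed as given; published error columns rarely follow
        a single reproducible convention) and printed ``scale_experimental``
        / ``scale_estimated`` columns.
    error_threshold : float
        Records with ``|error| > threshold`` are counted as exceedances.
    use_printed_scales : bool
        When scale columns are present, tabulate those; otherwise (or when
        False) classify from the pIC50 values.

    Returns
    -------
    (confusion, n_exceed) : (DataFrame, int)
        3x3 confusion matrix (rows experimental, columns estimated, in
        +++/++/+ order) and the error-exceedance count.
    """
    missing = records["pic50_estimated"].isna() if "pic50_estimated" in records else None
    if "pic50_estimated" not in records or missing.any():
        ids = list(records.loc[missing, "compound"]) if missing is not None else "all"
        raise ValueError(f"estimated activity missing for: {ids}")

    if use_printed_scales and {"scale_experimental", "scale_estimated"} <= set(records):
        exp_scale = records["scale_experimental"]
        est_scale = records["scale_estimated"]
    else:
        exp_scale = records["pic50_experimental"].map(lambda p: classify_activity(pic50_to_ic50_um(p)))
        est_scale = records["pic50_estimated"].map(lambda p: classify_activity(pic50_to_ic50_um(p)))

    confusion = pd.DataFrame(0, index=list(ACTIVITY_SCALES), columns=list(ACTIVITY_SCALES))
    for e, s in zip(exp_scale, est_scale):
        confusion.loc[e, s] += 1

    n_exceed = 0
    if "error" in records:
        n_exceed = int((records["error"].abs() > error_threshold).sum())
    return confusion, n_exceed


def estimation_ratio(records: pd.DataFrame) -> pd.Series:
    """Signed estimated/experimental IC50 ratio (Catalyst convention).

    Positive when the estimate is weaker (higher IC50) than experiment,
    negative when stronger; magnitude is the fold-difference.  Provided as
    a clearly separate computed column; it does not reproduce arbitrary
    published error columns.
    """
    ratio = 10.0 ** (records["pic50_experimental"] - records["pic50_estimated"])
    signed = np.where(ratio >= 1.0, ratio, -1.0 / ratio)
    return pd.Series(signed, index=records.index, name="ic50_ratio")
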