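"""Bundled reference tables from a cathepsin B virtual-screening campaign.

Small CSVs shipped with the package so that the validation, energetics and
filter machinery can be exercised against published-style numbers without
re-running pharmacophore, docking or molecular-dynamics engines:

* hit-list validation scenarios for three pharmacophore hypotheses
  (database of 796 molecules, 37 actives);
* experimental vs estimated activities for 61 inhibitors (24 training,
  37 test compounds), with the error values and activity-scale labels as
  printed in the source table;
* MM-PBSA/MM-GBSA component table for three screen hits plus the
  co-crystallized reference ligand CA030;
* re-docking energies for the 18 funnel-surviving screen hits.

Reported-value columns (``*_reported``) are consumed as data for
cross-checking; all derived quantities are recomputed by this package.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "load_hitlist_scenarios",
    "load_activity_table",
    "load_energy_components",
    "load_redock_hits",
    "FUNNEL_STAGE_COUNTS",
]

#: Stage attrition of the screening funnel: full library -> pharmacophore
#: match -> docking-score cutoff (<= -6.0 kcal/mol) -> rule of five plus
#: visual inspection -> five-criteria prioritization.
FUNNEL_STAGE_COUNTS = {
    "library": 60538,
    "pharmacophore": 1728,
    "docking": 176,
    "druglikeness": 18,
    "prioritized": 3,
}


def _read(name: str) -> pd.DataFrame:
    with resources.files("vscreen.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_hitlist_scenarios() -> pd.DataFrame:
    """Per-hypothesis (D, A, Ht, Ha) quadruples with reported statistics."""
    return _read("hitlist_scenarios.csv")


def load_activity_table() -> pd.DataFrame:
    """Experimental/estimated pIC50 table for 61 inhibitors.

    ``training`` marks the 24 model-building compounds; ``error`` and the
    two scale columns are reproduced as printed (the error column does not
    follow a single arithmetic convention and is treated as data).
    """
    df = _read("activity_table.csv")
    df["training"] = df["training"].astype(bool)
    return df


def load_energy_components() -> pd.DataFrame:
    """MM-PB(GB)SA components and reported totals for four complexes."""
    return _read("energy_components.csv")


def load_redock_hits() -> pd.DataFrame:
    """Re-docking energies (kcal/mol) and Ki (uM) for the 18 screen hits."""
    return _read("redock_hits.csv")
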