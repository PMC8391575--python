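"""MM-PBSA / MM-GBSA binding-free-energy component aggregation.

End-state methods decompose the binding free energy as::

    dG_bind = dG_MM + dG_polar_solv + dG_nonpolar_solv - T dS
    dG_MM   = dE_vdw + dE_elec + dE_int
    dG_nonpolar_solv = gamma * SASA + b     (gamma = 0.0072, b = 0 default)

with the polar term from a Poisson-Boltzmann (PB) or generalized-Born (GB)
solver.  This module consumes pre-computed component tables (the solvers
themselves are out of scope) and aggregates them.  Published component
tables frequently report "binding energy" totals that omit the nonpolar
surface term and the entropy (single-trajectory relative ranking); the
default flags reproduce that convention, and both terms can be switched
back on.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "gmm",
    "nonpolar_solvation",
    "binding_energy",
    "binding_energy_from_species",
    "aggregate",
    "GAMMA_DEFAULT",
    "B_DEFAULT",
]

GAMMA_DEFAULT = 0.0072  # kcal/(mol A^2)
B_DEFAULT = 0.0  # kcal/mol

#: tolerance (kcal/mol) when checking a reported total against its components
CONSISTENCY_TOL = 0.005


def gmm(components) -> float | pd.Series:
    """Molecular-mechanics term dG_MM = dE_vdw + dE_elec + dE_int.

    ``dE_int`` defaults to 0 (single-trajectory convention, where internal
    energies cancel).  Accepts a mapping/Series for one compound or a
    DataFrame for many.
    """
    if isinstance(components, pd.DataFrame):
        _require(components, ["dE_vdw", "dE_elec"])
        internal = components.get("dE_int", 0.0)
        return components["dE_vdw"] + components["dE_elec"] + internal
    for fld in ("dE_vdw", "dE_elec"):
        if fld not in components or pd.isna(components[fld]):
            raise ValueError(f"missing component '{fld}'")
    return float(components["dE_vdw"] + components["dE_elec"] + components.get("dE_int", 0.0))


def _require(df: pd.DataFrame, cols) -> None:
    missing = [c for c in cols if c not in df]
    if missing:
        raise ValueError(f"missing component columns: {missing}")


def nonpolar_solvation(sasa: float, gamma: float = GAMMA_DEFAULT, b: float = B_DEFAULT) -> float:
    """Surface-area nonpolar solvation term gamma * SASA + b (kcal/mol)."""
    if sasa < 0:
        raise ValueError("SASA must be >= 0")
    return gamma * sasa + b


def binding_energy(
    components,
    model: str = "pb",
    include_nonpolar: bool = False,
    include_entropy: bool = False,
):
    """Total binding energy for the chosen solvation model.

    dG_MM + dG_polar, plus the nonpolar surface term and minus T dS when
    the corresponding flags are set.  Defaults (both off) match the common
    reporting convention for relative rankings.
    """
    model = model.lower()
    if model not in ("pb", "gb"):
        raise ValueError("model must be 'pb' or 'gb'")
    polar_col = f"dG_polar_{model}"
    nonpolar_col = f"dG_nonpolar_{model}"

    if isinstance(components, pd.DataFrame):
        _require(components, [polar_col])
        total = gmm(components) + components[polar_col]
        if include_nonpolar:
            _require(components, [nonpolar_col])
            total = total + components[nonpolar_col]
        if include_entropy:
            if "minus_TdS" not in components:
                raise ValueError("entropy requested but 'minus_TdS' column absent")
            total = total + components["minus_TdS"]
        return total

    if polar_col not in components or pd.isna(components[polar_col]):
        raise ValueError(f"missing component '{polar_col}'")
    total = gmm(components) + float(components[polar_col])
    if include_nonpolar:
        if nonpolar_col not in components:
            raise ValueError(f"missing component '{nonpolar_col}'")
        total += float(components[nonpolar_col])
    if include_entropy:
        if "minus_TdS" not in components:
            raise ValueError("entropy requested but 'minus_TdS' term absent")
        total += float(components["minus_TdS"])
    return float(total)


def binding_energy_from_species(g_complex: float, g_protein: float, g_ligand: float) -> float:
    """dG_bind = G(complex) - [G(protein) + G(ligand)] from per-species totals."""
    return float(g_complex - (g_protein + g_ligand))


def aggregate(
    table: pd.DataFrame,
    include_nonpolar: bool = False,
    include_entropy: bool = False,
) -> pd.DataFrame:
    """Totals for a component table, with reported-value consistency checks.

    Adds ``dG_MM``, ``dG_bind_pb`` and/or ``dG_bind_gb`` (whichever polar
    columns are present).  When the input carries reported columns
    (``dG_MM_reported`` etc.), each is compared against the recomputed
    value; mismatches beyond 0.005 kcal/mol are flagged in a boolean
    ``*_consistent`` column and warned about - published tables do contain
    internal typos.
    """
    out = table.copy()
    out["dG_MM"] = gmm(table)
    for model in ("pb", "gb"):
        if f"dG_polar_{model}" in table:
            out[f"dG_bind_{model}"] = binding_energy(
                table, model=model, include_nonpolar=include_nonpolar, include_entropy=include_entropy
            )
    for col in ("dG_MM", "dG_bind_pb", "dG_bind_gb"):
        rep = f"{col}_reported"
        if rep in out and col in out:
            consistent = (out[rep] - out[col]).abs() <= CONSISTENCY_TOL
            out[f"{col}_consistent"] = consistent
            if not consistent.all():
                bad = out.loc[~consistent, "compound"].tolist() if "compound" in out else "<rows>"
                warnings.warn(
                    f"reported {col} disagrees with its own components for {bad}",
                    UserWarning,
                    stacklevel=2,
                )
    return out
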