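"""Synthetic inputs with known ground truth for the screening pipeline.

Real campaigns obtain these inputs from docking engines, pharmacophore
software, molecular-dynamics codes, and plate readers.  This module
replaces them with controlled generators:

* toy protein-ligand complexes (PDB text) whose per-residue interaction
  bit patterns are planted by construction;
* ranked screening libraries with a planted active fraction and a
  controllable active/decoy score separation;
* fluorometric kinetic plates with planted fractional inhibition;
* binding-free-energy component tables whose totals are left to the
  energetics module.

The toy complex geometry is deliberately unphysical: panel residues are
laid out on a widely spaced grid (atoms ~9 A apart within a residue,
residues 60 A apart) so that each planted interaction can be realized by a
single ligand atom without perturbing any other bit.  What is faithful is
the *detection* side: the emitted PDB text realizes every planted bit
under the geometric criteria documented in :mod:`vscreen.sift`, which is
exactly what the round-trip tests exercise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from vscreen.enrichment import RankedLibrary
from vscreen.sift import (
    BIT_NAMES,
    PROTEIN_ACCEPTOR_ATOMS,
    PROTEIN_DONOR_ATOMS,
    ResidueInteractionRecord,
    ResidueKey,
    sort_panel,
)

__all__ = [
    "ComplexSpec",
    "LibrarySpec",
    "AssaySpec",
    "UnrealizablePatternError",
    "generate_complex",
    "generate_library",
    "generate_assay",
    "generate_energy_table",
    "default_panel",
    "random_realizable_pattern",
]

# Minimal side-chain topology per residue name: (atom name, element).
# One nonpolar carbon plus, where the residue has one, a polar atom typed by
# the donor/acceptor tables in vscreen.sift.
SIDE_CHAIN_ATOMS = {
    "GLY": [],
    "ALA": [("CB", "C")],
    "VAL": [("CB", "C")],
    "LEU": [("CB", "C")],
    "ILE": [("CB", "C")],
    "PRO": [("CB", "C")],
    "PHE": [("CB", "C")],
    "SER": [("CB", "C"), ("OG", "O")],
    "THR": [("CB", "C"), ("OG1", "O")],
    "TYR": [("CB", "C"), ("OH", "O")],
    "CYS": [("CB", "C"), ("SG", "S")],
    "MET": [("CB", "C"), ("SD", "S")],
    "ASP": [("CB", "C"), ("OD1", "O")],
    "GLU": [("CB", "C"), ("OE1", "O")],
    "ASN": [("CB", "C"), ("ND2", "N")],
    "GLN": [("CB", "C"), ("OE1", "O")],
    "HIS": [("CB", "C"), ("ND1", "N")],
    "TRP": [("CB", "C"), ("NE1", "N")],
    "LYS": [("CB", "C"), ("NZ", "N")],
    "ARG": [("CB", "C"), ("NH1", "N")],
}

BACKBONE_ATOMS = [("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O")]

# Layout constants (A).  Margins: H-bond contacts are placed at 3.0 A
# (cutoff 3.5), plain contacts at 4.0 A (H-bond floor 3.5, contact ceiling
# 4.5), so coordinate jitter up to MAX_JITTER cannot flip any bit.
RESIDUE_SPACING = 60.0
ATOM_SPACING = 9.0
HBOND_PLACEMENT = 3.0
CONTACT_PLACEMENT = 4.0
MAX_JITTER = 0.4


class UnrealizablePatternError(ValueError):
    """A planted bit pattern cannot be realized on the toy topology."""


def default_panel() -> tuple:
    """The cathepsin B binding-site panel used throughout the package.

    Thirteen residues lining the substrate cleft and catalytic machinery
    (catalytic Cys29/His199 dyad plus the His110/His111 pair of the
    occluding loop).
    """
    names = [
        (23, "GLN"),
        (24, "GLY"),
        (27, "GLY"),
        (29, "CYS"),
        (72, "ASN"),
        (74, "GLY"),
        (110, "HIS"),
        (111, "HIS"),
        (122, "GLU"),
        (196, "MET"),
        (198, "GLY"),
        (199, "HIS"),
        (221, "TRP"),
    ]
    return tuple(ResidueKey("A", num, name) for num, name in names)


@dataclass
class ComplexSpec:
    """Recipe for a toy complex with planted per-residue interaction bits.

    ``planted_pattern`` maps ResidueKey -> 7-character bit string in the
    order contact, MC, SC, HBA, HBD, polar, nonpolar; panel residues absent
    from the map default to all-zero (no interaction).
    """

    residue_panel: tuple = field(default_factory=default_panel)
    planted_pattern: dict = field(default_factory=dict)
    ligand_atom_count: int | None = None
    jitter_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.residue_panel = sort_panel(self.residue_panel)
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")
        if self.ligand_atom_count is not None and self.ligand_atom_count < 1:
            raise ValueError("ligand_atom_count must be >= 1")
        seen = {}
        for key in self.residue_panel:
            prev = seen.setdefault(key.chain, 0)
            if key.number <= prev and prev != 0:
                raise ValueError("residue numbers must be strictly ascending per chain")
            seen[key.chain] = key.number
        for key in self.planted_pattern:
            if key not in self.residue_panel:
                raise ValueError(f"planted pattern for {key} outside the residue panel")


def _flags_of(bits: str) -> dict:
    return dict(zip(BIT_NAMES, (b == "1" for b in bits)))


def _side_atom(resname: str, want: str) -> str | None:
    """Side-chain atom of a given capability: 'C', 'donor', 'acceptor', 'polar'."""
    for name, elem in SIDE_CHAIN_ATOMS.get(resname.upper(), []):
        if want == "C" and elem == "C":
            return name
        if want == "polar" and elem in ("N", "O", "S"):
            return name
        if want == "donor" and name in PROTEIN_DONOR_ATOMS and elem != "C":
            return name
        if want == "acceptor" and name in PROTEIN_ACCEPTOR_ATOMS and elem != "C":
            return name
    return None


def _plan_tasks(key: ResidueKey, bits: str) -> list:
    """Choose (residue atom, ligand element, distance) placements realizing ``bits``.

    Raises UnrealizablePatternError when the pattern violates the bit
    implications or the residue's toy topology cannot support it (e.g. a
    side-chain H-bond on glycine).
    """
    rec = ResidueInteractionRecord.from_bits(key, bits)  # checks implications
    f = _flags_of(bits)
    if not f["contact"]:
        return []
    if not (f["polar"] or f["nonpolar"]):
        raise UnrealizablePatternError(
            f"{key}: any contacting atom is polar or nonpolar; pattern {bits} plants neither"
        )
    del rec

    resname = key.name.upper()

    def task_flags(atom, elem, dist, lig_elem):
        flags = {"contact", "main_chain" if atom in ("N", "CA", "C", "O") else "side_chain"}
        flags.add("polar" if elem in ("N", "O", "S") else "nonpolar")
        if dist <= 3.5:
            if atom in PROTEIN_ACCEPTOR_ATOMS and elem != "C" and lig_elem == "N":
                flags.add("hba")
            if atom in PROTEIN_DONOR_ATOMS and elem != "C" and lig_elem == "O":
                flags.add("hbd")
        return flags

    # candidate placements for the two H-bond roles, by region
    hba_opts, hbd_opts = [], []
    if f["hba"]:
        if f["main_chain"]:
            hba_opts.append(("O", "O", "N", HBOND_PLACEMENT))
        if f["side_chain"]:
            acc = _side_atom(resname, "acceptor")
            if acc is not None:
                elem = dict(SIDE_CHAIN_ATOMS[resname])[acc]
                hba_opts.append((acc, elem, "N", HBOND_PLACEMENT))
        if not hba_opts:
            raise UnrealizablePatternError(
                f"{key}: no hydrogen-bond acceptor atom available for pattern {bits}"
            )
    if f["hbd"]:
        if f["main_chain"]:
            hbd_opts.append(("N", "N", "O", HBOND_PLACEMENT))
        if f["side_chain"]:
            don = _side_atom(resname, "donor")
            if don is not None:
                elem = dict(SIDE_CHAIN_ATOMS[resname])[don]
                hbd_opts.append((don, elem, "O", HBOND_PLACEMENT))
        if not hbd_opts:
            raise UnrealizablePatternError(
                f"{key}: no hydrogen-bond donor atom available for pattern {bits}"
            )

    planted = {b for b, v in f.items() if v}

    # filler contacts that each add only {contact, region, polarity} bits
    fillers = []
    fillers.append(("CA", "C", "C", CONTACT_PLACEMENT))  # MC + nonpolar
    fillers.append(("O", "O", "C", CONTACT_PLACEMENT))  # MC + polar
    side_c = _side_atom(resname, "C")
    if side_c is not None:
        fillers.append((side_c, "C", "C", CONTACT_PLACEMENT))  # SC + nonpolar
    side_p = _side_atom(resname, "polar")
    if side_p is not None:
        elem = dict(SIDE_CHAIN_ATOMS[resname])[side_p]
        fillers.append((side_p, elem, "C", CONTACT_PLACEMENT))  # SC + polar

    for hba_choice in hba_opts or [None]:
        for hbd_choice in hbd_opts or [None]:
            tasks = [c for c in (hba_choice, hbd_choice) if c is not None]
            achieved = set()
            for atom, elem, lig_elem, dist in tasks:
                achieved |= task_flags(atom, elem, dist, lig_elem)
            if not achieved <= planted:
                continue
            ok = True
            while planted - achieved:
                progressed = False
                for atom, elem, lig_elem, dist in fillers:
                    fl = task_flags(atom, elem, dist, lig_elem)
                    if fl <= planted and fl - achieved:
                        tasks.append((atom, elem, lig_elem, dist))
                        achieved |= fl
                        progressed = True
                        break
                if not progressed:
                    ok = False
                    break
            if ok and achieved == planted:
                return tasks
    raise UnrealizablePatternError(f"{key}: pattern {bits} not realizable on {resname}")


def _residue_coords(index: int) -> dict:
    """Atom name -> coordinate for panel residue ``index`` on the toy grid."""
    x = index * RESIDUE_SPACING
    coords = {}
    for j, (name, _elem) in enumerate(BACKBONE_ATOMS):
        coords[name] = np.array([x, j * ATOM_SPACING, 0.0])
    return coords


def _side_coords(index: int, resname: str) -> dict:
    x = index * RESIDUE_SPACING
    coords = {}
    for j, (name, _elem) in enumerate(SIDE_CHAIN_ATOMS.get(resname.upper(), [])):
        coords[name] = np.array([x, (len(BACKBONE_ATOMS) + j) * ATOM_SPACING, 0.0])
    return coords


def _pdb_atom_line(serial, name, resname, chain, resnum, xyz, element, het=False) -> str:
    record = "HETATM" if het else "ATOM  "
    aname = name if len(name) == 4 else f" {name:<3s}"
    return (
        f"{record}{serial:>5d} {aname}{'':1s}{resname:<3s} {chain:1s}"
        f"{resnum:>4d}    {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
        f"{1.00:6.2f}{0.00:6.2f}          {element:>2s}"
    )


def generate_complex(spec: ComplexSpec):
    """Emit a toy complex realizing the planted bit patterns.

    Returns
    -------
    (pdb_text, records) : (str, list of ResidueInteractionRecord)
        PDB text of the complex (ligand as HETATM residue ``LIG`` on chain
        ``L``) and the ground-truth records the encoder should recover.
        Output is byte-identical for identical specs (seed included).
    """
    rng = np.random.default_rng(spec.seed)
    panel = spec.residue_panel
    patterns = {key: spec.planted_pattern.get(key, "0000000") for key in panel}

    lines = []
    serial = 1
    ligand_positions = []
    records = []
    for i, key in enumerate(panel):
        tasks = _plan_tasks(key, patterns[key])  # may raise UnrealizablePatternError
        records.append(ResidueInteractionRecord.from_bits(key, patterns[key]))
        coords = _residue_coords(i)
        coords.update(_side_coords(i, key.name))
        for name, elem in BACKBONE_ATOMS + SIDE_CHAIN_ATOMS.get(key.name.upper(), []):
            lines.append(
                _pdb_atom_line(serial, name, key.name.upper(), key.chain, key.number, coords[name], elem)
            )
            serial += 1
        directions = [(1, 0, 0), (0, 0, 1), (-1, 0, 0), (0, 0, -1)]
        for t_idx, (atom, _elem, lig_elem, dist) in enumerate(tasks):
            # cycle placement directions so tasks sharing a target atom
            # (e.g. Ser OG as both donor and acceptor) do not overlap
            direction = np.array(directions[t_idx % 4], dtype=float)
            pos = coords[atom] + dist * direction
            ligand_positions.append((pos, lig_elem))

    # pad the ligand with far-away spectator atoms if more were requested
    n_needed = max(len(ligand_positions), 1)
    n_atoms = spec.ligand_atom_count if spec.ligand_atom_count is not None else n_needed
    if n_atoms < len(ligand_positions):
        raise ValueError(
            f"ligand_atom_count={n_atoms} but {len(ligand_positions)} atoms are "
            "needed to realize the planted patterns"
        )
    for j in range(n_atoms - len(ligand_positions)):
        ligand_positions.append((np.array([-100.0 - 6.0 * j, -100.0, 0.0]), "C"))

    if spec.jitter_sd > 0:
        for k, (pos, elem) in enumerate(ligand_positions):
            delta = rng.normal(0.0, spec.jitter_sd, size=3)
            norm = float(np.linalg.norm(delta))
            if norm > MAX_JITTER:  # clip so no planted bit can flip
                delta *= MAX_JITTER / norm
            ligand_positions[k] = (pos + delta, elem)

    for j, (pos, elem) in enumerate(ligand_positions, start=1):
        lines.append(_pdb_atom_line(serial, f"L{j}", "LIG", "L", 1, pos, elem, het=True))
        serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n", records


def random_realizable_pattern(key: ResidueKey, rng: np.random.Generator) -> str:
    """Draw a random bit pattern that is realizable for this residue."""
    for _ in range(200):
        bits = "".join(rng.choice(["0", "1"], size=7))
        try:
            _plan_tasks(key, bits)
        except (ValueError, UnrealizablePatternError):
            continue
        return bits
    return "0000000"


# ---------------------------------------------------------------------------
# Ranked libraries
# ---------------------------------------------------------------------------


@dataclass
class LibrarySpec:
    """Gaussian score model for a labeled screening library.

    Scores mimic docking binding energies in kcal/mol (lower is better);
    enrichment strength is set by the active/decoy mean separation relative
    to the common standard deviation.
    """

    n_total: int = 1000
    n_active: int = 50
    active_score_mean: float = -9.0
    decoy_score_mean: float = -6.0
    score_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.n_active <= self.n_total:
            raise ValueError("need 0 <= n_active <= n_total")
        if self.score_sd <= 0:
            raise ValueError("score_sd must be > 0")


def generate_library(spec: LibrarySpec) -> RankedLibrary:
    """Draw a labeled library from the two-Gaussian score model."""
    rng = np.random.default_rng(spec.seed)
    n_decoy = spec.n_total - spec.n_active
    scores = np.concatenate(
        [
            rng.normal(spec.active_score_mean, spec.score_sd, spec.n_active),
            rng.normal(spec.decoy_score_mean, spec.score_sd, n_decoy),
        ]
    )
    active = np.concatenate([np.ones(spec.n_active, bool), np.zeros(n_decoy, bool)])
    ids = [f"ACT{i+1:05d}" for i in range(spec.n_active)] + [
        f"DEC{i+1:05d}" for i in range(n_decoy)
    ]
    order = rng.permutation(spec.n_total)
    return RankedLibrary(
        ids=[ids[i] for i in order],
        scores=scores[order],
        active=active[order],
        lower_is_better=True,
    )


# ---------------------------------------------------------------------------
# Kinetic assay plates
# ---------------------------------------------------------------------------


@dataclass
class AssaySpec:
    """Linear-regime fluorometric plate with planted fractional inhibition.

    Each test condition's expected slope is ``control_slope * (1 - f)`` for
    planted inhibition fraction ``f``; readings get additive i.i.d. Gaussian
    noise.  ``concentrations_um`` (one per inhibition fraction) are carried
    through to the output table for dose-response summaries.
    """

    baseline_rfu: float = 100.0
    control_slope: float = 6.0  # RFU/min
    inhibition_fractions: tuple = (0.25, 0.5, 0.75)
    concentrations_um: tuple | None = None
    timepoints: tuple = (0.0, 15.0)  # min
    noise_sd: float = 0.0
    replicates: int = 3
    compound: str = "CMP1"
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.timepoints) < 2:
            raise ValueError("need at least two timepoints")
        if any(t2 <= t1 for t1, t2 in zip(self.timepoints, self.timepoints[1:])):
            raise ValueError("timepoints must be strictly increasing")
        if any(not 0.0 <= f <= 1.0 for f in self.inhibition_fractions):
            raise ValueError("inhibition fractions must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.concentrations_um is None:
            self.concentrations_um = tuple(float(i + 1) for i in range(len(self.inhibition_fractions)))
        if len(self.concentrations_um) != len(self.inhibition_fractions):
            raise ValueError("one concentration per inhibition fraction required")


def generate_assay(spec: AssaySpec) -> pd.DataFrame:
    """Long-format plate table: well, role, compound, concentration_uM, time_min, rfu."""
    rng = np.random.default_rng(spec.seed)
    rows = []

    def emit(well, role, compound, conc, slope):
        for t in spec.timepoints:
            noise = rng.normal(0.0, spec.noise_sd) if spec.noise_sd > 0 else 0.0
            rows.append(
                {
                    "well": well,
                    "role": role,
                    "compound": compound,
                    "concentration_uM": conc,
                    "time_min": float(t),
                    "rfu": spec.baseline_rfu + slope * t + noise,
                }
            )

    for r in range(spec.replicates):
        emit(f"EC{r+1}", "enzyme-control", "", np.nan, spec.control_slope)
    well = 1
    for frac, conc in zip(spec.inhibition_fractions, spec.concentrations_um):
        for r in range(spec.replicates):
            emit(f"T{well}", "test", spec.compound, float(conc), spec.control_slope * (1.0 - frac))
            well += 1
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Compound property tables
# ---------------------------------------------------------------------------


def generate_property_table(
    n: int,
    n_pass: int,
    seed: int = 0,
    score_cutoff: float = -6.0,
) -> pd.DataFrame:
    """Property table spanning the funnel's filter boundaries.

    Exactly ``n_pass`` compounds satisfy the docking-score cutoff, the rule
    of five, and the visual-inspection flag; each of the remaining rows
    violates at least one stage (drawn at random), so a correctly ordered
    funnel must end with exactly ``n_pass`` survivors.
    """
    if not 0 <= n_pass <= n:
        raise ValueError("need 0 <= n_pass <= n")
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        passes = i < n_pass
        row = {
            "id": f"CMP{i+1:04d}",
            "mw": rng.uniform(200.0, 480.0),
            "hbd": int(rng.integers(0, 5)),
            "hba": int(rng.integers(0, 10)),
            "logp": rng.uniform(0.0, 4.5),
            "score": rng.uniform(score_cutoff - 4.0, score_cutoff - 0.1),
            "visual_ok": True,
        }
        if not passes:
            breakage = rng.choice(["mw", "hbd", "hba", "logp", "score", "visual"])
            if breakage == "mw":
                row["mw"] = rng.uniform(500.0, 700.0)
            elif breakage == "hbd":
                row["hbd"] = int(rng.integers(5, 9))
            elif breakage == "hba":
                row["hba"] = int(rng.integers(10, 15))
            elif breakage == "logp":
                row["logp"] = rng.uniform(5.0, 8.0)
            elif breakage == "score":
                row["score"] = rng.uniform(score_cutoff + 0.1, score_cutoff + 3.0)
            else:
                row["visual_ok"] = False
        rows.append(row)
    df = pd.DataFrame(rows)
    return df.sample(frac=1.0, random_state=int(rng.integers(2**31))).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Energy component tables
# ---------------------------------------------------------------------------


def generate_energy_table(n: int, seed: int = 0) -> pd.DataFrame:
    """Random MM-PB(GB)SA component table; totals are left to the energetics module.

    Component magnitudes are drawn on the scale typical of end-state
    binding-energy decompositions (tens of kcal/mol, polar solvation
    opposing the MM terms, small negative nonpolar terms).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "compound": [f"CMP{i+1:03d}" for i in range(n)],
            "dE_vdw": np.round(rng.normal(-25.0, 5.0, n), 2),
            "dE_elec": np.round(rng.normal(-45.0, 8.0, n), 2),
            "dG_polar_pb": np.round(rng.normal(42.0, 4.0, n), 2),
            "dG_nonpolar_pb": np.round(rng.normal(-6.0, 0.5, n), 2),
            "dG_polar_gb": np.round(rng.normal(36.0, 3.0, n), 2),
            "dG_nonpolar_gb": np.round(rng.normal(-6.0, 0.5, n), 2),
        }
    )
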