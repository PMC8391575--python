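"""Structural interaction fingerprints (SIFt) and pose clustering.

A SIFt encodes how a docked ligand touches each residue of a fixed
binding-site panel as seven bits per residue::

    contact | main chain | side chain | HBA | HBD | polar | nonpolar

where HBA means a residue atom accepts a hydrogen bond from the ligand and
HBD means a residue atom donates one to the ligand.  Residue blocks are
concatenated in ascending residue order (chain id first, lexicographic) so
that fingerprints over the same panel are directly comparable.  Similarity
between fingerprints is the Jaccard-Tanimoto coefficient over ON bits, and
poses are grouped by agglomerative hierarchical clustering on 1 - JT.

Geometric criteria (the defaults reflect common SIFt practice):

* contact  -- any ligand heavy atom within 4.5 A of a residue heavy atom;
* H-bond   -- donor/acceptor heavy atoms within 3.5 A; when the donor
  carries an explicit hydrogen the donor-H...acceptor angle must also be
  >= 120 deg, otherwise the check is distance-only;
* polar    -- the contacting residue atom is N, O, or S; nonpolar -- C.
  Both flags may be set when atoms of both classes contact.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.PDB import PDBParser
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "BIT_NAMES",
    "GeometricCriteria",
    "ResidueKey",
    "ResidueInteractionRecord",
    "InteractionFingerprint",
    "SimilarityMatrix",
    "ClusterResult",
    "detect_interactions",
    "encode",
    "tanimoto",
    "similarity_matrix",
    "cluster",
]

#: Bit order within each per-residue block.
BIT_NAMES = ("contact", "main_chain", "side_chain", "hba", "hbd", "polar", "nonpolar")

BITS_PER_RESIDUE = 7

#: Backbone atom names; everything else on a residue counts as side chain.
MAIN_CHAIN_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})

# Hydrogen-bond capability by protein atom name.  Backbone N donates, the
# carbonyl O accepts; side-chain entries cover the standard amino acids
# (His ND1/NE2 and hydroxyl oxygens can act in either role).
PROTEIN_DONOR_ATOMS = frozenset(
    {"N", "OG", "OG1", "OH", "SG", "ND1", "NE2", "ND2", "NE", "NE1", "NH1", "NH2", "NZ"}
)
PROTEIN_ACCEPTOR_ATOMS = frozenset(
    {"O", "OXT", "OG", "OG1", "OH", "OD1", "OD2", "OE1", "OE2", "SD", "SG", "ND1", "NE2"}
)

# Without explicit hydrogens or bond orders, ligand H-bond roles are assigned
# by element: N donates, O and S accept, C does neither.
LIGAND_DONOR_ELEMENTS = frozenset({"N"})
LIGAND_ACCEPTOR_ELEMENTS = frozenset({"O", "S"})

POLAR_ELEMENTS = frozenset({"N", "O", "S"})

WATER_NAMES = frozenset({"HOH", "WAT", "H2O", "DOD"})


@dataclass(frozen=True)
class GeometricCriteria:
    """Distance/angle thresholds used to call contacts and hydrogen bonds."""

    contact_cutoff: float = 4.5  # A, heavy-atom contact
    hbond_distance: float = 3.5  # A, donor-acceptor heavy atoms
    hbond_angle: float = 120.0  # deg, donor-H...acceptor, when H present


@dataclass(frozen=True, order=True)
class ResidueKey:
    """Identity of a panel residue: (chain, number, name)."""

    chain: str
    number: int
    name: str

    def __str__(self) -> str:  # e.g. "A:His199"
        return f"{self.chain}:{self.name.capitalize()}{self.number}"


@dataclass
class ResidueInteractionRecord:
    """Seven interaction flags for one panel residue, with supporting atom pairs.

    ``atom_pairs`` lists (residue atom, ligand atom, distance in A) for every
    heavy-atom pair within the contact cutoff, so that each set flag can be
    traced back to geometry.
    """

    residue: ResidueKey
    contact: bool = False
    main_chain: bool = False
    side_chain: bool = False
    hba: bool = False
    hbd: bool = False
    polar: bool = False
    nonpolar: bool = False
    atom_pairs: list = field(default_factory=list)

    def flags(self) -> tuple:
        return tuple(bool(getattr(self, b)) for b in BIT_NAMES)

    def bits(self) -> str:
        return "".join("1" if f else "0" for f in self.flags())

    def validate(self) -> None:
        """Enforce the bit-consistency implications of the encoding."""
        c, mc, sc, hba, hbd, pol, npol = self.flags()
        if (mc or sc or hba or hbd or pol or npol) and not c:
            raise ValueError(f"{self.residue}: interaction bit set without contact bit")
        if (hba or hbd) and not pol:
            raise ValueError(f"{self.residue}: H-bond bit set without polar bit")
        if c and not (mc or sc):
            raise ValueError(f"{self.residue}: contact set but neither main nor side chain")

    @classmethod
    def from_bits(cls, residue: ResidueKey, bits: str) -> "ResidueInteractionRecord":
        if len(bits) != BITS_PER_RESIDUE or set(bits) - {"0", "1"}:
            raise ValueError(f"bit string must be 7 binary characters, got {bits!r}")
        rec = cls(residue, *(b == "1" for b in bits))
        rec.validate()
        return rec


@dataclass
class InteractionFingerprint:
    """Concatenated 7-bit residue blocks over an ordered binding-site panel."""

    panel: tuple  # tuple[ResidueKey, ...] in ascending order
    bits: str
    label: str | None = None

    def __post_init__(self) -> None:
        self.panel = tuple(self.panel)
        if len(self.bits) != BITS_PER_RESIDUE * len(self.panel):
            raise ValueError(
                f"fingerprint length {len(self.bits)} != 7 x panel size {len(self.panel)}"
            )
        if set(self.bits) - {"0", "1"}:
            raise ValueError("fingerprint must be a binary string")

    def __len__(self) -> int:
        return len(self.bits)

    def on_bits(self) -> frozenset:
        return frozenset(i for i, b in enumerate(self.bits) if b == "1")

    def block(self, residue: ResidueKey) -> str:
        i = self.panel.index(residue)
        return self.bits[i * BITS_PER_RESIDUE : (i + 1) * BITS_PER_RESIDUE]

    def records(self) -> list:
        return [
            ResidueInteractionRecord.from_bits(res, self.block(res)) for res in self.panel
        ]


def sort_panel(panel) -> tuple:
    """Canonical panel order: chain id (lexicographic), then residue number."""
    return tuple(sorted(panel, key=lambda r: (r.chain, r.number)))


# ---------------------------------------------------------------------------
# Interaction detection
# ---------------------------------------------------------------------------


def _load_structure(pdb_text: str):
    parser = PDBParser(QUIET=True)
    return parser.get_structure("complex", io.StringIO(pdb_text))


def _is_ligand(residue) -> bool:
    hetflag = residue.id[0]
    return hetflag not in (" ",) and residue.get_resname() not in WATER_NAMES


def _heavy_atoms(residue):
    return [a for a in residue.get_atoms() if (a.element or "X").upper() != "H"]


def _hydrogens_bonded_to(residue, atom, max_dist: float = 1.3):
    out = []
    for a in residue.get_atoms():
        if (a.element or "").upper() == "H" and a - atom <= max_dist:
            out.append(a)
    return out


def _angle_deg(a, b, c) -> float:
    """Angle a-b-c in degrees from coordinates."""
    v1 = a - b
    v2 = c - b
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def _hbond_geometry_ok(donor_res, donor_atom, acceptor_atom, criteria: GeometricCriteria) -> bool:
    dist = donor_atom - acceptor_atom
    if dist > criteria.hbond_distance:
        return False
    hydrogens = _hydrogens_bonded_to(donor_res, donor_atom)
    if not hydrogens:  # no explicit H: distance-only
        return True
    return any(
        _angle_deg(donor_atom.coord, h.coord, acceptor_atom.coord) >= criteria.hbond_angle
        for h in hydrogens
    )


def detect_interactions(
    pdb_text: str,
    panel,
    criteria: GeometricCriteria | None = None,
) -> list:
    """Annotate each panel residue with its interaction flags for one complex.

    Parameters
    ----------
    pdb_text : str
        A PDB-format complex with exactly one ligand residue (HETATM).
    panel : iterable of ResidueKey
        Binding-site residues to annotate; each must exist in the structure.
    criteria : GeometricCriteria, optional
        Distance/angle thresholds; defaults as documented in the module.

    Returns
    -------
    list of ResidueInteractionRecord, one per panel residue in canonical
    panel order; residues with no atom pair within the contact cutoff get an
    all-zero record.
    """
    criteria = criteria or GeometricCriteria()
    structure = _load_structure(pdb_text)
    model = next(structure.get_models())

    ligands = [r for chain in model for r in chain if _is_ligand(r)]
    if len(ligands) != 1:
        raise ValueError(f"expected exactly one ligand residue, found {len(ligands)}")
    ligand = ligands[0]
    ligand_atoms = _heavy_atoms(ligand)

    residue_index = {}
    for chain in model:
        for res in chain:
            if res.id[0] == " ":
                residue_index[(chain.id, res.id[1])] = res

    records = []
    for key in sort_panel(panel):
        try:
            res = residue_index[(key.chain, key.number)]
        except KeyError:
            raise ValueError(f"panel residue {key} not found in structure") from None
        rec = ResidueInteractionRecord(key)
        for ratom in _heavy_atoms(res):
            relem = (ratom.element or "C").upper()
            for latom in ligand_atoms:
                dist = ratom - latom
                if dist > criteria.contact_cutoff:
                    continue
                rec.contact = True
                rec.atom_pairs.append((ratom.get_name(), latom.get_name(), round(float(dist), 3)))
                if ratom.get_name() in MAIN_CHAIN_ATOMS:
                    rec.main_chain = True
                else:
                    rec.side_chain = True
                if relem in POLAR_ELEMENTS:
                    rec.polar = True
                elif relem == "C":
                    rec.nonpolar = True
                lelem = (latom.element or "C").upper()
                # residue accepts from a ligand donor
                if (
                    ratom.get_name() in PROTEIN_ACCEPTOR_ATOMS
                    and lelem in LIGAND_DONOR_ELEMENTS
                    and _hbond_geometry_ok(ligand, latom, ratom, criteria)
                ):
                    rec.hba = True
                    rec.polar = True
                # residue donates to a ligand acceptor
                if (
                    ratom.get_name() in PROTEIN_DONOR_ATOMS
                    and lelem in LIGAND_ACCEPTOR_ELEMENTS
                    and _hbond_geometry_ok(res, ratom, latom, criteria)
                ):
                    rec.hbd = True
                    rec.polar = True
        rec.validate()
        records.append(rec)
    return records


def encode(records, panel, label: str | None = None) -> InteractionFingerprint:
    """Concatenate per-residue records into one fingerprint in panel order.

    The input record order is irrelevant; blocks are laid out by ascending
    (chain, residue number).  Every panel residue must be covered exactly
    once, and records for residues outside the panel are an error.
    """
    ordered = sort_panel(panel)
    panel_set = set(ordered)
    by_res = {}
    for rec in records:
        if rec.residue not in panel_set:
            raise ValueError(f"record for residue {rec.residue} not in panel")
        if rec.residue in by_res:
            raise ValueError(f"duplicate record for residue {rec.residue}")
        rec.validate()
        by_res[rec.residue] = rec
    missing = [str(r) for r in ordered if r not in by_res]
    if missing:
        raise ValueError(f"records missing for panel residues: {', '.join(missing)}")
    bits = "".join(by_res[res].bits() for res in ordered)
    return InteractionFingerprint(ordered, bits, label=label)


# ---------------------------------------------------------------------------
# Similarity and clustering
# ---------------------------------------------------------------------------


def tanimoto(a: InteractionFingerprint, b: InteractionFingerprint) -> float:
    """Jaccard-Tanimoto coefficient |A & B| / |A | B| over ON bits.

    Two all-zero fingerprints share no interactions; their similarity is
    defined as 0.0 (with a warning) rather than the indeterminate 0/0.
    """
    if a.panel != b.panel:
        raise ValueError("fingerprints are over different residue panels")
    on_a, on_b = a.on_bits(), b.on_bits()
    union = len(on_a | on_b)
    if union == 0:
        warnings.warn(
            "Tanimoto of two all-zero fingerprints is undefined; returning 0.0",
            UserWarning,
            stacklevel=2,
        )
        return 0.0
    return len(on_a & on_b) / union


@dataclass
class SimilarityMatrix:
    """Symmetric Jaccard-Tanimoto matrix with item identifiers."""

    values: np.ndarray
    ids: list

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match number of ids")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def distances(self) -> np.ndarray:
        """1 - JT, zero diagonal, suitable for condensed-form clustering."""
        d = 1.0 - self.values
        np.fill_diagonal(d, 0.0)
        return d


def similarity_matrix(fps, ids=None) -> SimilarityMatrix:
    """All-pairs Jaccard-Tanimoto similarity for fingerprints on one panel."""
    fps = list(fps)
    if len(fps) < 2:
        raise ValueError("need at least two fingerprints")
    if ids is None:
        ids = [fp.label if fp.label is not None else f"fp{i}" for i, fp in enumerate(fps)]
    ids = list(ids)
    if len(ids) != len(fps):
        raise ValueError("ids length does not match fingerprints")

    on = [fp.on_bits() for fp in fps]
    panel0 = fps[0].panel
    for fp in fps[1:]:
        if fp.panel != panel0:
            raise ValueError("fingerprints are over different residue panels")
    n = len(fps)
    m = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            union = len(on[i] | on[j])
            m[i, j] = m[j, i] = (len(on[i] & on[j]) / union) if union else 0.0
        if not on[i]:
            m[i, i] = 1.0  # degenerate all-zero item kept at unit self-similarity
    return SimilarityMatrix(m, ids)


@dataclass
class ClusterResult:
    """Agglomerative clustering of poses by interaction-pattern distance."""

    linkage: np.ndarray  # scipy linkage matrix
    labels: np.ndarray  # flat cluster label per item (1-based)
    ids: list
    method: str
    composition: pd.DataFrame | None = None  # per-cluster class percentages

    def n_clusters(self) -> int:
        return int(len(np.unique(self.labels)))

    def members(self, cluster_label: int) -> list:
        return [i for i, lab in zip(self.ids, self.labels) if lab == cluster_label]

    def to_newick(self) -> str:
        """Dendrogram as a Newick string with merge-height branch lengths."""
        tree = hierarchy.to_tree(self.linkage)

        def walk(node, parent_height):
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.ids[node.id]}:{length:.6g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return walk(tree, tree.dist) + ";"


def _composition(ids, labels, class_labels) -> pd.DataFrame:
    df = pd.DataFrame({"id": ids, "cluster": labels, "class": class_labels})
    rows = []
    for clab, grp in df.groupby("cluster"):
        counts = grp["class"].value_counts()
        for cls, cnt in counts.items():
            rows.append(
                {
                    "cluster": clab,
                    "class": cls,
                    "count": int(cnt),
                    "percent_of_cluster": 100.0 * cnt / len(grp),
                    "percent_of_class": 100.0 * cnt / (df["class"] == cls).sum(),
                }
            )
    return pd.DataFrame(rows)


def cluster(
    matrix: SimilarityMatrix,
    method: str = "average",
    k: int | None = None,
    height: float | None = None,
    class_labels=None,
) -> ClusterResult:
    """Agglomerative hierarchical clustering on 1 - JT distances.

    Parameters
    ----------
    matrix : SimilarityMatrix
    method : str
        scipy linkage method; UPGMA ("average") by default.
    k : int, optional
        Number of flat clusters to cut the dendrogram into.
    height : float, optional
        Alternative distance-threshold cut; used when ``k`` is None.
        With neither given, all items fall in one cluster.
    class_labels : sequence, optional
        One class per item (e.g. "inhibitor" vs "virtual hit"); when given,
        a per-cluster composition summary is attached.
    """
    n = len(matrix.ids)
    if k is not None and (k < 1 or k > n):
        raise ValueError(f"k={k} out of range for {n} items")
    condensed = squareform(matrix.distances(), checks=False)
    Z = hierarchy.linkage(condensed, method=method)
    if k is not None:
        labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    elif height is not None:
        labels = hierarchy.fcluster(Z, t=height, criterion="distance")
    else:
        labels = np.ones(n, dtype=int)
    comp = None
    if class_labels is not None:
        comp = _composition(matrix.ids, labels, list(class_labels))
    return ClusterResult(Z, np.asarray(labels), list(matrix.ids), method, comp)
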