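"""Interaction-fingerprint construction, similarity, and clustering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vscreen import synthetic
from vscreen.sift import (
    BIT_NAMES,
    InteractionFingerprint,
    ResidueInteractionRecord,
    ResidueKey,
    cluster,
    detect_interactions,
    encode,
    similarity_matrix,
    tanimoto,
)

# --- record / fingerprint invariants ---------------------------------------


@pytest.mark.parametrize(
    "bits",
    ["0100000", "0010000", "1001000", "1101000", "0000010", "1000010"],
    ids=["mc-no-contact", "sc-no-contact", "hba-no-mc-sc", "hba-no-polar",
         "polar-no-contact", "contact-no-region"],
)
def test_inconsistent_bit_patterns_rejected(bits):
    with pytest.raises(ValueError):
        ResidueInteractionRecord.from_bits(ResidueKey("A", 1, "SER"), bits)


def test_all_zero_record_permitted():
    rec = ResidueInteractionRecord.from_bits(ResidueKey("A", 1, "GLY"), "0000000")
    assert rec.bits() == "0000000"


def test_fingerprint_length_must_match_panel(toy_panel):
    with pytest.raises(ValueError):
        InteractionFingerprint(toy_panel, "101")


# --- detection on generated complexes --------------------------------------


def test_distant_ligand_gives_all_zero_records(panel):
    pdb, _ = synthetic.generate_complex(synthetic.ComplexSpec(residue_panel=panel))
    records = detect_interactions(pdb, panel)
    assert len(records) == len(panel)
    assert all(r.bits() == "0000000" for r in records)


def test_planted_single_residue_pattern_detected(panel):
    key = ResidueKey("A", 199, "HIS")
    pdb, _ = synthetic.generate_complex(
        synthetic.ComplexSpec(residue_panel=panel, planted_pattern={key: "1010110"})
    )
    records = detect_interactions(pdb, panel)
    by_res = {r.residue: r for r in records}
    assert by_res[key].bits() == "1010110"
    assert by_res[key].atom_pairs  # every flag backed by a recorded pair
    assert all(r.bits() == "0000000" for r in records if r.residue != key)


def test_backbone_carbonyl_accepting_from_ligand_amine(toy_panel):
    # contact + MC + HBA + polar and nothing else
    key = toy_panel[0]  # glycine: backbone only
    pdb, _ = synthetic.generate_complex(
        synthetic.ComplexSpec(residue_panel=toy_panel, planted_pattern={key: "1101010"})
    )
    rec = {r.residue: r for r in detect_interactions(pdb, toy_panel)}[key]
    assert rec.bits() == "1101010"
    # manual geometric check: the supporting pair is O...N within 3.5 A
    (ratom, _latom, dist) = rec.atom_pairs[0]
    assert ratom == "O" and dist <= 3.5


def test_missing_panel_residue_is_named(panel):
    pdb, _ = synthetic.generate_complex(synthetic.ComplexSpec(residue_panel=panel))
    ghost = ResidueKey("A", 999, "ALA")
    with pytest.raises(ValueError, match="999"):
        detect_interactions(pdb, panel + (ghost,))


def test_multiple_ligands_rejected(panel):
    pdb, _ = synthetic.generate_complex(synthetic.ComplexSpec(residue_panel=panel))
    extra = "HETATM 9999  X1  LIG L   2     -50.000 -50.000   0.000  1.00  0.00           C\n"
    with pytest.raises(ValueError, match="ligand"):
        detect_interactions(pdb.replace("END", extra + "END"), panel)


# --- encoding ---------------------------------------------------------------


def test_encode_concatenates_in_ascending_residue_order(toy_panel):
    p10, p20, p30 = "1100001", "1011010", "1010110"
    records = [
        ResidueInteractionRecord.from_bits(toy_panel[i], bits)
        for i, bits in ((2, p30), (0, p10), (1, p20))  # deliberately shuffled
    ]
    fp = encode(records, toy_panel)
    assert fp.bits == p10 + p20 + p30


def test_encode_rejects_record_outside_panel(toy_panel):
    records = [ResidueInteractionRecord.from_bits(r, "0000000") for r in toy_panel]
    records.append(ResidueInteractionRecord.from_bits(ResidueKey("B", 5, "ALA"), "0000000"))
    with pytest.raises(ValueError, match="not in panel"):
        encode(records, toy_panel)


def test_encode_requires_full_panel_coverage(toy_panel):
    records = [ResidueInteractionRecord.from_bits(toy_panel[0], "0000000")]
    with pytest.raises(ValueError, match="missing"):
        encode(records, toy_panel)


def test_single_residue_identity(toy_panel):
    key = toy_panel[1]
    fp = encode([ResidueInteractionRecord.from_bits(key, "1100001")], (key,))
    assert fp.bits == "1100001"


# --- round trip: generator -> detector -> encoder ---------------------------


def test_roundtrip_random_realizable_patterns(panel):
    rng = np.random.default_rng(2024)
    for trial in range(25):
        patterns = {k: synthetic.random_realizable_pattern(k, rng) for k in panel}
        spec = synthetic.ComplexSpec(
            residue_panel=panel, planted_pattern=patterns, seed=trial, jitter_sd=0.15
        )
        pdb, truth = synthetic.generate_complex(spec)
        fp = encode(detect_interactions(pdb, panel), panel)
        expected = "".join(patterns[k] for k in panel)
        assert fp.bits == expected
        assert [r.bits() for r in truth] == [patterns[k] for k in panel]


def test_encoder_output_satisfies_bit_implications(panel):
    rng = np.random.default_rng(7)
    patterns = {k: synthetic.random_realizable_pattern(k, rng) for k in panel}
    pdb, _ = synthetic.generate_complex(
        synthetic.ComplexSpec(residue_panel=panel, planted_pattern=patterns, seed=1)
    )
    for rec in detect_interactions(pdb, panel):
        rec.validate()  # raises on any violated implication


# --- Tanimoto ----------------------------------------------------------------


def _fp(bits, panel):
    return InteractionFingerprint(panel, bits)


def test_tanimoto_hand_computed(toy_panel):
    one = toy_panel[:1]
    assert tanimoto(_fp("1100001", one), _fp("1100001", one)) == 1.0
    assert tanimoto(_fp("1100000", one), _fp("0000001", one)) == 0.0
    # |A&B| = 1 (bit 0), |A|B| = 3
    assert tanimoto(_fp("1100000", one), _fp("1010000", one)) == pytest.approx(1 / 3)


def test_tanimoto_both_empty_defined_as_zero_with_warning(toy_panel):
    one = toy_panel[:1]
    with pytest.warns(UserWarning, match="all-zero"):
        assert tanimoto(_fp("0000000", one), _fp("0000000", one)) == 0.0


def test_tanimoto_panel_mismatch(toy_panel):
    with pytest.raises(ValueError, match="panel"):
        tanimoto(_fp("1100001", toy_panel[:1]), _fp("1100001", toy_panel[1:2]))


@settings(deadline=None, derandomize=True, max_examples=200)
@given(st.integers(0, 2**21 - 1), st.integers(0, 2**21 - 1))
def test_tanimoto_symmetry_range_and_self_similarity(a_int, b_int):
    panel = (ResidueKey("A", 1, "SER"), ResidueKey("A", 2, "HIS"), ResidueKey("A", 3, "GLY"))
    a = _fp(format(a_int, "021b"), panel)
    b = _fp(format(b_int, "021b"), panel)
    if a_int == 0 and b_int == 0:
        return  # degenerate case covered separately
    jt = tanimoto(a, b)
    assert jt == tanimoto(b, a)
    assert 0.0 <= jt <= 1.0
    if a_int:
        assert tanimoto(a, a) == 1.0


# --- similarity matrix -------------------------------------------------------


def test_matrix_matches_naive_double_loop(toy_panel, rng):
    n_bits = 7 * len(toy_panel)
    fps = []
    while len(fps) < 12:
        bits = "".join(rng.choice(["0", "1"], size=n_bits))
        try:
            fps.append(InteractionFingerprint(toy_panel, bits))
        except ValueError:
            continue
    mat = similarity_matrix(fps)
    for i in range(len(fps)):
        for j in range(len(fps)):
            if i == j:
                continue
            on_i, on_j = fps[i].on_bits(), fps[j].on_bits()
            union = len(on_i | on_j)
            naive = len(on_i & on_j) / union if union else 0.0
            assert mat.values[i, j] == pytest.approx(naive)
    assert np.allclose(mat.values, mat.values.T)
    assert np.allclose(np.diag(mat.values), 1.0)


def test_matrix_of_duplicates_is_all_ones(toy_panel):
    fp = _fp("1100001" * 3, toy_panel)
    mat = similarity_matrix([fp] * 4)
    assert np.allclose(mat.values, 1.0)


def test_matrix_requires_at_least_two(toy_panel):
    with pytest.raises(ValueError):
        similarity_matrix([])


# --- clustering --------------------------------------------------------------


def _block_fps(toy_panel):
    block_a = _fp("1100001" + "0000000" + "1011010", toy_panel)
    block_b = _fp("0000000" + "1010110" + "0000000", toy_panel)
    return [block_a] * 4 + [block_b] * 3


def test_planted_two_block_partition_recovered(toy_panel):
    fps = _block_fps(toy_panel)
    mat = similarity_matrix(fps, ids=[f"p{i}" for i in range(7)])
    result = cluster(mat, k=2)
    labels = result.labels
    assert len(set(labels[:4])) == 1
    assert len(set(labels[4:])) == 1
    assert labels[0] != labels[4]


def test_identical_items_merge_at_height_zero(toy_panel):
    fp = _fp("1100110" * 3, toy_panel)
    mat = similarity_matrix([fp] * 5)
    result = cluster(mat, k=1)
    assert result.n_clusters() == 1
    assert np.allclose(result.linkage[:, 2], 0.0)


def test_merge_heights_monotone_and_leaves_conserved(toy_panel, rng):
    n_bits = 7 * len(toy_panel)
    fps = []
    while len(fps) < 15:
        bits = "".join(rng.choice(["0", "1"], size=n_bits))
        try:
            fps.append(InteractionFingerprint(toy_panel, bits))
        except ValueError:
            continue
    result = cluster(similarity_matrix(fps), method="average", k=3)
    heights = result.linkage[:, 2]
    assert np.all(np.diff(heights) >= -1e-12)
    assert len(result.labels) == 15
    assert result.n_clusters() == 3


def test_composition_percentages(toy_panel):
    fps = _block_fps(toy_panel)
    classes = ["X", "X", "X", "Y", "X", "Y", "Y"]
    mat = similarity_matrix(fps, ids=[f"p{i}" for i in range(7)])
    result = cluster(mat, k=2, class_labels=classes)
    comp = result.composition
    first_cluster = result.labels[0]
    row = comp[(comp["cluster"] == first_cluster) & (comp["class"] == "X")].iloc[0]
    assert row["count"] == 3
    assert row["percent_of_cluster"] == pytest.approx(75.0)
    assert row["percent_of_class"] == pytest.approx(75.0)


def test_k_larger_than_n_rejected(toy_panel):
    mat = similarity_matrix(_block_fps(toy_panel))
    with pytest.raises(ValueError):
        cluster(mat, k=50)


def test_newick_export_contains_all_leaves(toy_panel):
    mat = similarity_matrix(_block_fps(toy_panel), ids=[f"p{i}" for i in range(7)])
    nwk = cluster(mat, k=2).to_newick()
    assert nwk.endswith(";")
    for i in range(7):
        assert f"p{i}" in nwk
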