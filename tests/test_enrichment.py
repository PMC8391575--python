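"""Early-enrichment metrics: AUC, BEDROC, bootstrap, retrieval curves."""

import numpy as np
import pytest

from vscreen.enrichment import RankedLibrary, bedroc, bootstrap_p, retrieval_curve, roc_auc
from vscreen.synthetic import LibrarySpec, generate_library


def make_lib(scores, active, lower_is_better=True):
    return RankedLibrary(
        ids=[f"c{i}" for i in range(len(scores))],
        scores=np.asarray(scores, float),
        active=np.asarray(active, bool),
        lower_is_better=lower_is_better,
    )


def brute_force_auc(lib):
    """Pair-counting oracle: P(active outranks decoy), ties count 1/2."""
    goodness = -lib.scores if lib.lower_is_better else lib.scores
    act = goodness[lib.active]
    dec = goodness[~lib.active]
    wins = sum((a > d) + 0.5 * (a == d) for a in act for d in dec)
    return wins / (len(act) * len(dec))


def literal_bedroc(ranks, n_total, n_active, alpha):
    """Independent transcription of the published BEDROC formula."""
    ra = n_active / n_total
    rie = sum(np.exp(-alpha * r / n_total) for r in ranks) / (
        (n_active / n_total) * (1 - np.exp(-alpha)) / (np.exp(alpha / n_total) - 1)
    )
    return rie * ra * np.sinh(alpha / 2) / (
        np.cosh(alpha / 2) - np.cosh(alpha / 2 - alpha * ra)
    ) + 1 / (1 - np.exp(alpha * (1 - ra)))


# --- AUC ---------------------------------------------------------------------


def test_auc_trivial_orderings():
    assert roc_auc(make_lib([-9, -8, -5, -4], [1, 1, 0, 0])) == 1.0
    assert roc_auc(make_lib([-9, -8, -5, -4], [0, 0, 1, 1])) == 0.0
    # interleaved A,D,A,D: 3 of 4 pairs concordant
    assert roc_auc(make_lib([-9, -8, -7, -6], [1, 0, 1, 0])) == pytest.approx(0.75)


def test_auc_matches_brute_force_pair_counting():
    rng = np.random.default_rng(17)
    for _ in range(20):
        n = int(rng.integers(10, 200))
        scores = np.round(rng.normal(size=n), 1)  # rounding forces ties
        active = rng.random(n) < 0.25
        if active.sum() in (0, n):
            continue
        lib = make_lib(scores, active)
        assert roc_auc(lib) == pytest.approx(brute_force_auc(lib))


def test_auc_direction_flag():
    lib = make_lib([9, 8, 5, 4], [1, 1, 0, 0], lower_is_better=False)
    assert roc_auc(lib) == 1.0


def test_single_class_rejected():
    with pytest.raises(ValueError):
        roc_auc(make_lib([1, 2, 3], [1, 1, 1]))


def test_roc_curve_endpoints():
    auc, points = roc_auc(make_lib([-9, -8, -5, -4], [1, 0, 1, 0]), return_curve=True)
    assert (points.iloc[0]["fpr"], points.iloc[0]["tpr"]) == (0.0, 0.0)
    assert (points.iloc[-1]["fpr"], points.iloc[-1]["tpr"]) == (1.0, 1.0)


# --- BEDROC ------------------------------------------------------------------


def test_bedroc_extremes():
    n, n_act = 100, 8
    top = make_lib(np.arange(n), np.arange(n) < n_act)
    bottom = make_lib(np.arange(n), np.arange(n) >= n - n_act)
    assert bedroc(top) == pytest.approx(1.0, abs=1e-9)
    assert bedroc(bottom) == pytest.approx(0.0, abs=1e-3)


def test_bedroc_matches_literal_formula():
    # 10 compounds, actives at positional ranks 1 and 6
    scores = np.arange(10, dtype=float)
    active = np.zeros(10, bool)
    active[[0, 5]] = True
    lib = make_lib(scores, active)
    assert bedroc(lib, alpha=20.0) == pytest.approx(literal_bedroc([1, 6], 10, 2, 20.0))


def test_bedroc_matches_rdkit_reference():
    rdkit_scoring = pytest.importorskip("rdkit.ML.Scoring.Scoring")
    rng = np.random.default_rng(23)
    for _ in range(10):
        scores = rng.normal(size=80)
        active = rng.random(80) < 0.15
        if active.sum() in (0, 80):
            continue
        lib = make_lib(scores, active)
        order = np.argsort(scores, kind="stable")
        ranked = [[0, int(active[i])] for i in order]
        assert bedroc(lib, 20.0) == pytest.approx(
            rdkit_scoring.CalcBEDROC(ranked, 1, 20), abs=1e-9
        )
        assert roc_auc(lib) == pytest.approx(rdkit_scoring.CalcAUC(ranked, 1), abs=1e-9)


def test_bedroc_invariant_to_decoy_permutation():
    rng = np.random.default_rng(5)
    scores = np.arange(50, dtype=float)
    active = np.zeros(50, bool)
    active[[2, 10, 30]] = True
    lib = make_lib(scores, active)
    base = bedroc(lib)
    # permuting decoy scores among decoy positions leaves active ranks fixed
    decoy_idx = np.flatnonzero(~active)
    for _ in range(5):
        s = scores.copy()
        perm = rng.permutation(decoy_idx)
        s[decoy_idx] = scores[perm]
        assert bedroc(make_lib(s, active)) == pytest.approx(base)


def test_metrics_increase_when_active_swaps_upward():
    rng = np.random.default_rng(31)
    scores = np.sort(rng.normal(size=60))
    active = np.zeros(60, bool)
    active[[20, 40]] = True
    lib = make_lib(scores, active)
    # swap the active at position 20 with the decoy at 19 (better score)
    swapped = active.copy()
    swapped[[19, 20]] = [True, False]
    lib_up = make_lib(scores, swapped)
    assert roc_auc(lib_up) > roc_auc(lib)
    assert bedroc(lib_up) > bedroc(lib)


def test_tied_active_decoy_scores_warn_for_bedroc():
    lib = make_lib([-8, -8, -5, -4], [1, 0, 1, 0])
    with pytest.warns(UserWarning, match="tied"):
        bedroc(lib)


def test_invalid_alpha_rejected():
    lib = make_lib([-9, -5], [1, 0])
    with pytest.raises(ValueError):
        bedroc(lib, alpha=0.0)


# --- bootstrap ---------------------------------------------------------------


def test_bootstrap_perfect_ranking_significant():
    lib = make_lib(np.arange(100, dtype=float), np.arange(100) < 10)
    assert bootstrap_p(lib, "auc", n_rand=10_000, seed=1) <= 0.001


def test_bootstrap_single_draw_bounds():
    lib = make_lib([-9, -8, -5, -4], [1, 1, 0, 0])
    p = bootstrap_p(lib, "auc", n_rand=1, seed=0)
    assert p in (0.5, 1.0)


def test_bootstrap_chance_metric_gives_uniform_like_p():
    rng = np.random.default_rng(99)
    ps = []
    for i in range(40):
        scores = rng.normal(size=60)
        active = np.zeros(60, bool)
        active[rng.choice(60, 8, replace=False)] = True
        lib = make_lib(scores, active)
        ps.append(bootstrap_p(lib, "auc", n_rand=500, seed=int(rng.integers(2**31))))
    assert 0.3 <= float(np.median(ps)) <= 0.7


def test_bootstrap_bedroc_path_runs():
    lib = make_lib(np.arange(50, dtype=float), np.arange(50) < 5)
    p = bootstrap_p(lib, "bedroc", n_rand=200, seed=2)
    assert 0 < p <= 1


def test_random_library_auc_centered_at_half():
    aucs = [
        roc_auc(
            generate_library(
                LibrarySpec(n_total=100, n_active=10, active_score_mean=-6.0,
                            decoy_score_mean=-6.0, score_sd=1.0, seed=s)
            )
        )
        for s in range(300)
    ]
    assert float(np.mean(aucs)) == pytest.approx(0.5, abs=0.02)


def test_separated_library_enriches():
    lib = generate_library(
        LibrarySpec(n_total=100, n_active=10, active_score_mean=-9.0,
                    decoy_score_mean=-5.0, score_sd=0.5, seed=4)
    )
    assert roc_auc(lib) > 0.95


# --- retrieval curve ---------------------------------------------------------


def test_retrieval_curve_shape_and_endpoints():
    lib = make_lib(np.arange(20, dtype=float), np.arange(20) < 4)
    curve = retrieval_curve(lib)
    assert curve["actives_retrieved"].iloc[0] == 0
    assert curve["actives_retrieved"].iloc[4] == 4  # perfect ranking: all by selection A
    assert curve["actives_retrieved"].iloc[-1] == 4
    assert curve["random_expectation"].iloc[-1] == pytest.approx(4.0)
    assert (np.diff(curve["actives_retrieved"]) >= 0).all()


def test_strong_library_dominates_random_line():
    lib = generate_library(
        LibrarySpec(n_total=200, n_active=20, active_score_mean=-10.0,
                    decoy_score_mean=-5.0, score_sd=0.4, seed=8)
    )
    curve = retrieval_curve(lib)
    inner = curve.iloc[1:-1]
    assert (inner["actives_retrieved"] >= inner["random_expectation"] - 1e-9).all()
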