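# vscreen

Post-docking analysis for ligand-based virtual screening, built around the
triage workflow of a cathepsin B inhibitor-discovery campaign.  Cathepsin B
is a papain-family cysteine protease (catalytic Cys29/His199 dyad, with the
His110/His111 pair on its occluding loop) whose inhibition is a candidate
anti-Alzheimer's strategy; the package, however, is target-agnostic: it
analyzes the *outputs* of pharmacophore screens, docking runs, MD energy
decompositions, and fluorometric assays, for anyone who needs to turn a
large scored library into a short, defensible hit list.

The docking, pharmacophore, and molecular-dynamics engines themselves are
out of scope.  In their place a synthetic-data generator produces every
input with known ground truth, so the entire analysis chain is testable
end-to-end.

## What it computes

**Structural interaction fingerprints (SIFt).** Each binding-site residue
is encoded in seven bits — contact, main chain, side chain, H-bond
acceptor, H-bond donor, polar, nonpolar — and residue blocks are
concatenated in ascending residue order.  Pose similarity is the
Jaccard–Tanimoto coefficient JT(A, B) = |A∩B| / |A∪B| over ON bits;
poses are grouped by agglomerative (UPGMA) clustering on 1 − JT.

**Pharmacophore hit-list validation.** From a database of D molecules with
A actives, a hit list of Ht hits containing Ha actives gives

    %Y = Ha/Ht · 100          %A = Ha/A · 100
    E  = Ha·D / (Ht·A)        FN = A − Ha,  FP = Ht − Ha
    GH = [Ha(3A + Ht) / (4 Ht A)] · [1 − (Ht − Ha)/(D − A)]

with the Güner–Henry score GH ∈ [0, 1] separating null from ideal models.

**Early enrichment.** ROC AUC (Mann–Whitney, ties ½) and the
Truchon–Bailey BEDROC(α = 20) early-recognition metric, with permutation
bootstrap p-values against random rankings of the actives.

**Funnel filters.** Docking-score cutoff (score ≤ −6.0 kcal/mol by
default), Lipinski rule of five (MW < 500 Da, HBD < 5, HBA < 10,
logP < 5), and manual-flag stages, with per-stage attrition accounting.

**Hit prioritization.** Five conjunctive criteria: active-like cluster
membership, binding-site occupancy, His199 π-stacking proximity, H-bonds
to both His110 and His111, and an acceptable overall conformation.

**Energetics.** MM-PBSA/MM-GBSA aggregation
ΔG_bind = ΔG_MM + ΔG_polar (+ ΔG_nonpolar − TΔS when enabled), with
ΔG_MM = ΔE_vdw + ΔE_elec + ΔE_int and ΔG_nonpolar = γ·SASA + b.

**Kinetics.** Linear-regime slopes from plate fluorescence and
% relative inhibition = (slope_EC − slope_sample)/slope_EC · 100.

## Worked example

Validate three pharmacophore hypotheses screened against a 796-compound
database with 37 known actives:

```sh
$ vscreen validate --stats src/vscreen/data/hitlist_scenarios.csv
   label  percent_yield  percent_ratio  enrichment  false_negatives  false_positives   gh
  Hypo I          23.14          75.68        4.98                9               93 0.32
 Hypo II          50.00          81.08       10.76                7               30 0.55
Hypo III          77.78          94.59       16.73                2               10 0.81
```

Hypo III retrieves 35 of 37 actives (2 false negatives) at a 16.7-fold
enrichment over random selection and a GH score of 0.81 — a model good
enough to screen with.  The full synthetic pipeline (pose generation, SIFt
clustering, enrichment, funnel, prioritization, energetics, assay) runs
with one seed:

```sh
$ vscreen run --seed 7 --out report/
```

which writes per-stage CSVs plus a consolidated `report.json`; with the
default configuration the 18-pose cohort splits into 2 interaction
clusters and exactly 3 poses survive all five prioritization criteria,
mirroring the 18 → 3 narrowing of the original campaign.

From Python:

```python
>>> from vscreen import validate, HitListStats, pic50
>>> round(validate(HitListStats(796, 37, 45, 35)).gh, 2)
0.81
>>> round(pic50(0.00224), 2)   # IC50 of 2.24 nM in uM units
8.65
```

## Layout

- `vscreen.sift` — fingerprints, Tanimoto similarity, clustering
- `vscreen.validation` — Güner–Henry statistics, activity scales
- `vscreen.enrichment` — AUC, BEDROC, bootstrap, retrieval curves
- `vscreen.filters` / `vscreen.prioritization` — funnel and hit triage
- `vscreen.energetics` / `vscreen.kinetics` — energy aggregation, assays
- `vscreen.synthetic` — ground-truth generators for every input
- `vscreen.datasets` — bundled reference tables
- `vscreen.pipeline` / `vscreen.cli` — orchestration and the `vscreen` CLI

See `docs/methods.md` for the models, conventions, and their limits.
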