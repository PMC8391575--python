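# Methods

This note documents the models and conventions behind `vscreen`: what each
component assumes, which parameters matter, what the synthetic generators
do and do not emulate, and where genuinely open design choices were
resolved.

## Interaction fingerprints

A pose's interaction with a fixed binding-site panel is encoded as seven
bits per residue, in the order **contact, main chain, side chain, HBA,
HBD, polar, nonpolar** (HBA/HBD from the residue's perspective: HBA means
a residue atom accepts a hydrogen bond from the ligand).  Residue blocks
are concatenated by chain id (lexicographic) and then ascending residue
number, so fingerprints over one panel are positionally comparable.  The
encoding obeys implications that the detector enforces and the tests
check: any set bit implies contact; HBA/HBD imply polar; contact implies
main or side chain; and — because every heavy atom is either carbon or a
N/O/S heteroatom — contact implies polar or nonpolar.

Geometric criteria (tunable via `GeometricCriteria`):

| criterion | default | notes |
|---|---|---|
| contact | 4.5 Å | any ligand heavy atom vs residue heavy atom |
| H-bond distance | 3.5 Å | donor–acceptor heavy atoms |
| H-bond angle | ≥ 120° | donor–H⋯acceptor, only when explicit H present |

These values are common fingerprinting practice; tools that identify
H-bonds from full chemistry (explicit hydrogens, bond orders,
protonation) will disagree on edge cases, which is why the thresholds are
part of the public API rather than constants.  H-bond *capability* is
assigned from PDB atom names for the protein (backbone N donates, carbonyl
O accepts, standard side-chain roles, His ND1/NE2 and hydroxyl O in both
roles) and from the element for the ligand (N donates, O/S accept) — a
deliberate simplification for ligands supplied without hydrogens.

Main-chain atoms are N, CA, C, O, OXT; everything else is side chain.
Polar/nonpolar follows the *residue* atom's element (N/O/S vs C); both
flags may be set when both atom classes contact.

The default panel is the 13-residue cathepsin B site (Gln23, Gly24,
Gly27, Cys29, Asn72, Gly74, His110, His111, Glu122, Met196, Gly198,
His199, Trp221).  His111 is included because the prioritization criteria
require it; the panel is a plain argument everywhere.

## Similarity and clustering

Pose similarity is the Jaccard–Tanimoto coefficient over ON bits.  The
0/0 case (two all-zero fingerprints) is defined as 0 with a warning:
"no shared interactions" is the semantics a screening analyst wants, and
it keeps the coefficient total.  Self-similarity of a non-empty
fingerprint is 1.

Clustering is agglomerative on distance 1 − JT, average linkage (UPGMA)
by default and configurable; scipy's deterministic merge ordering provides
reproducible tie-breaking.  Flat clusters come from a cluster-count or
height cut, and per-cluster class composition (e.g. known inhibitors vs
virtual hits) is reported as percentages of the cluster and of the class.
Dendrograms export to Newick with merge-height branch lengths.

## Hit-list validation

`HitListStats(d, a, ht, ha)` enforces 0 ≤ Ha ≤ min(Ht, A), Ht ≤ D, A ≤ D,
and additionally Ht − Ha ≤ D − A (a hit list cannot contain more inactive
hits than the database holds inactives).  Under these constraints the
Güner–Henry score

GH = [Ha(3A + Ht)/(4·Ht·A)] · [1 − (Ht − Ha)/(D − A)]

is provably within [0, 1], which the property tests exercise; without the
last constraint the second factor can go negative on impossible inputs.
The GH parenthesization follows the standard form, which reproduces the
bundled reference GH values to two decimals.  Metrics are computed in
full precision; `ValidationReport.rounded()` gives printed-table parity,
and comparisons against published tables tolerate ±0.01–0.03 because such
tables round intermediate values (the bundled scenarios include one
enrichment factor printed 16.74 where the quadruple gives 16.73).

Activity scale: +++ for IC50 ≤ 0.3 µM, ++ strictly between 0.3 and
2.5 µM, + for IC50 ≥ 2.5 µM; boundaries are inclusive on the outer
classes.  pIC50 = −log10(IC50 in molar).  The bundled activity table's
printed error column follows no single reproducible convention and is
consumed as data; a clearly separate signed estimated/experimental IC50
ratio is available as a computed alternative.  Its printed scale labels
are likewise not always consistent with the printed estimated pIC50s, so
the confusion machinery tabulates the printed labels by default
(`use_printed_scales`), with classification-from-pIC50 as the other path.

## Enrichment metrics

AUC is the normalized Mann–Whitney statistic on midranks, so tied scores
contribute ½; it equals brute-force concordant-pair counting (tested).
BEDROC follows Truchon–Bailey: the exponentially weighted sum of active
ranks, normalized by its uniform expectation (RIE) and mapped onto [0, 1]
between worst- and best-case placements.  α = 20 by default
(≈ 80% of the weight in the top 8% of the list).  BEDROC is
rank-positional, so active/decoy score ties are broken by stable input
order with a warning.  Docking scores rank lower-is-better by default,
with a flag to invert.

The bootstrap p-value redistributes active labels uniformly over rank
positions (`n_rand` draws, vectorized), recomputes the metric, and
reports (1 + #{null ≥ observed})/(n_rand + 1); the add-one smoothing keeps
p > 0 and makes a single-draw p lie in {0.5, 1.0}.  The tail uses ≥ with
a 10⁻¹² slack so exact re-achievement of the observed value counts
against significance.

## Funnel and prioritization

The rule of five uses strict `<` bounds by default (MW < 500 Da, HBD < 5,
HBA < 10, logP < 5), matching the screening protocol this package mirrors;
`canonical=True` restores the usual ≤ convention.  The docking-score stage
keeps score ≤ cutoff (−6.0 kcal/mol default) — i.e. "score magnitude at
least 6" for negative binding energies — with the direction exposed as a
flag.  Properties are consumed as columns (any property calculator can
produce them); external predictions such as blood–brain-barrier
permeation and human visual inspection enter as boolean columns so funnel
accounting can include them.

Prioritization is a pure conjunction of five booleans: designated active
cluster; occupancy ≥ 0.5 (fraction of panel residues contacted); aromatic
centroid within 5.5 Å of the His199 side chain (a π-stacking proximity
heuristic — an optional ring-normal angle check exists but is off, since
no angle threshold is established); H-bonds to *both* His110 and His111;
and a manual conformation-quality flag.  The occupancy and distance
defaults are package heuristics surfaced in every report; relaxing any
threshold can only grow the pass set (tested).

## Energetics

ΔG_MM = ΔE_vdw + ΔE_elec + ΔE_int with ΔE_int defaulting to 0
(single-trajectory convention).  ΔG_bind = ΔG_MM + ΔG_polar by default;
the γ·SASA + b nonpolar term (γ = 0.0072 kcal·mol⁻¹·Å⁻², b = 0) and −TΔS
join only when flagged, because published "binding energy" columns of
end-state decompositions routinely omit both — the bundled reference
table's eight PB/GB totals are reproduced exactly by the default flags,
while literal inclusion of its printed nonpolar column would not
reproduce any of them.  When a table carries reported totals, each is
checked against its own components at 0.005 kcal/mol and inconsistencies
are flagged (the bundled table contains one genuine ΔG_MM typo, −81.66
printed vs −81.16 summed, plus one 0.01 rounding artifact in a GB total).
Species-total input (G_complex, G_protein, G_ligand) is supported and
agrees with the component path.

## Kinetics

Slopes default to the two-point estimate (first and last reading), the
convention of 0/15-minute fluorometric protocols; least-squares regression
is available for multi-read noisy traces and coincides with two-point on
noiseless linear data.  % relative inhibition is anchored to the mean
enzyme-control slope and is not clipped (negative values mean
activation).  Replicates aggregate as mean ± SEM with SEM = SD/√n.

## Synthetic data

The generators define the study conditions for every test:

* **Complexes** — panel residues on a widely spaced grid (backbone
  N/CA/C/O plus up to two typed side-chain atoms, 9 Å apart within a
  residue, residues 60 Å apart) with ligand atoms placed at 3.0 Å for
  planted H-bonds and 4.0 Å for plain contacts.  The margins (0.5 Å to
  each criterion boundary) guarantee that coordinate jitter — Gaussian
  with `jitter_sd`, clipped at 0.4 Å displacement — cannot flip a planted
  bit, so encode∘generate round-trips exactly.  Patterns that the toy
  topology cannot realize (side-chain bits on glycine, H-bond roles the
  residue lacks, contact with neither polarity) are rejected naming the
  residue.  The geometry is deliberately unphysical: it validates the
  detector's criteria, not protein structure.
* **Libraries** — active and decoy docking scores are Gaussian with
  common SD; defaults (−9.0 vs −6.0 kcal/mol, SD 1.0) give the strong
  separation of a well-behaved screen, and equal means give the
  exchangeable null.
* **Assay plates** — RFU = baseline + slope·t + N(0, noise_sd), with test
  slopes control_slope·(1 − f) for planted fraction f; defaults mirror a
  triplicate 0/15-min protocol at control slope 6 RFU/min.
* **Energy tables** — component columns on the typical tens-of-kcal/mol
  scale with totals deliberately absent.
* **Property tables** — exactly `n_pass` rows satisfy every funnel stage;
  each other row violates one randomly chosen stage, spanning all filter
  boundaries.

What passing tests on these inputs shows: the analysis arithmetic,
orderings, and boundary semantics are correct under known ground truth.
What it does not show: robustness to real docking noise, correlated
errors, non-Gaussian score tails, nonlinear kinetic regimes, or genuine
protein geometry — none of which the generators emulate.

## Problem sizes and determinism

Default analysis sizes (synthetic pose cohorts of ~18, libraries of
100–2000, bootstrap draws of 10³–10⁴) are chosen so the full suite and the
acceptance script run comfortably on a laptop; all are plain parameters.
Every stochastic component takes a seed; the pipeline fans one global seed
into per-stage substreams, records it (with a config hash and package
version) in `report.json`, and produces byte-identical outputs on re-run.

## Known limitations

* SIFt subtyping stops at the seven defined bits: no π–π stacking bit, no
  water-mediated bridges, no protonation-state assignment.
* Ligand H-bond roles are element-based unless hydrogens are supplied.
* No IC50 curve fitting; assays report % inhibition per concentration.
* The energetics module aggregates components; it contains no PB/GB
  solver, SASA algorithm, or entropy estimator.
* Conformation quality (prioritization criterion 5) is a manual flag by
  design — it encodes expert judgement, not geometry.
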