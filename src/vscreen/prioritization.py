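"""Five-criteria hit prioritization over clustering and interaction output.

After funnel filtering, surviving hits are triaged with five conjunctive
criteria modeled on expert pose inspection of a cathepsin B screen:

1. membership in the designated "active-like" SIFt cluster;
2. binding-site occupancy (fraction of panel residues contacted) at or
   above a threshold;
3. an aromatic/hydrophobic group close enough to the His199 side chain
   for pi-stacking;
4. hydrogen bonds to *both* His110 and His111 (occluding-loop anchor);
5. an acceptable overall binding conformation (a manual flag - this
   judgement is inherently human).

A hit passes overall iff all five criteria hold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = ["HitAnnotation", "PrioritizationParams", "evaluate_criteria", "prioritize"]

CRITERION_NAMES = (
    "in_active_cluster",
    "occupancy",
    "his199_stacking",
    "his110_his111_hbonds",
    "conformation_quality",
)


@dataclass
class HitAnnotation:
    """Everything the five criteria need for one hit."""

    compound: str
    cluster: int
    residues_contacted: frozenset = frozenset()
    hbond_partners: frozenset = frozenset()
    his199_distance: float = float("inf")  # A, aromatic centroid to His199 side chain
    occupancy: float = 0.0  # fraction of panel residues contacted, [0, 1]
    quality_ok: bool = False

    def __post_init__(self) -> None:
        self.residues_contacted = frozenset(self.residues_contacted)
        self.hbond_partners = frozenset(self.hbond_partners)
        if self.his199_distance < 0:
            raise ValueError("distance must be >= 0")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError("occupancy must lie in [0, 1]")


@dataclass
class PrioritizationParams:
    """Thresholds surfaced in every report; defaults are package heuristics.

    ``max_his199_distance`` is a centroid-to-ring proximity heuristic for
    pi-stacking; ``required_hbond_partners`` demands H-bonds to every
    listed residue.
    """

    active_cluster: int = 2
    min_occupancy: float = 0.5
    max_his199_distance: float = 5.5  # A
    required_hbond_partners: tuple = ("His110", "His111")
    # optional ring-normal angle check, off by default (no stated threshold)
    max_ring_angle: float | None = None


def evaluate_criteria(h: HitAnnotation, params: PrioritizationParams | None = None) -> dict:
    """Per-criterion booleans plus the overall conjunction."""
    params = params or PrioritizationParams()
    result = {
        "in_active_cluster": h.cluster == params.active_cluster,
        "occupancy": h.occupancy >= params.min_occupancy,
        "his199_stacking": h.his199_distance <= params.max_his199_distance,
        "his110_his111_hbonds": set(params.required_hbond_partners) <= set(h.hbond_partners),
        "conformation_quality": bool(h.quality_ok),
    }
    result["overall"] = all(result[name] for name in CRITERION_NAMES)
    return result


def prioritize(annotations, params: PrioritizationParams | None = None) -> pd.DataFrame:
    """Evaluate a cohort; one row per hit with criterion booleans and overall pass."""
    params = params or PrioritizationParams()
    rows = []
    for h in annotations:
        res = evaluate_criteria(h, params)
        rows.append({"compound": h.compound, **res})
    return pd.DataFrame(rows)
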