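"""State-unique inter-helical interaction maps.

The central statistic is the minimum Euclidean distance between the heavy
atoms of two residues on different helices.  A pair is *active-state-unique*
when this closest-atom distance is below ``contact_max`` (default 4.6 Å) in
the active-state structure and above ``separated_min`` (default 6.0 Å) in
the inactive-state structure of the same receptor; *inactive-state-unique*
is the mirrored condition.  Both inequalities are strict, so boundary values
classify as neither.  Pairs found state-unique in reference receptors can
then be checked for plain contact (< ``contact_max``) in a query receptor
whose residues are located through generic-number correspondence, including
any per-helix numbering slide.

Residues missing from a model (e.g. a disordered helix end) yield
unresolved records rather than being silently dropped — the absence itself
is biologically meaningful.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from statemap.generic_numbering import GenericNumber, GenericNumberMap
from statemap.structure_io import ResidueRecord, StructureModel

__all__ = [
    "DistanceThresholds",
    "ResiduePairDistance",
    "StateUniqueInteraction",
    "ConservationCheck",
    "closest_heavy_atom_distance",
    "pairwise_interhelix_distances",
    "classify_state_unique",
    "build_state_unique_map",
    "check_conservation",
]

ACTIVE_UNIQUE = "active_unique"
INACTIVE_UNIQUE = "inactive_unique"
NONE = "none"


@dataclass(frozen=True)
class DistanceThresholds:
    """Contact / separation cutoffs in Å.

    ``contact_max``: closest-atom distance below which two residues are in
    contact.  ``separated_min``: distance above which they count as well
    separated.  The gap between the two makes the state-unique call robust
    to coordinate error.
    """

    contact_max: float = 4.6
    separated_min: float = 6.0

    def __post_init__(self) -> None:
        if not 0 < self.contact_max < self.separated_min:
            raise ValueError(
                f"require 0 < contact_max < separated_min, got "
                f"({self.contact_max}, {self.separated_min})")


@dataclass(frozen=True)
class ResiduePairDistance:
    gn_a: GenericNumber
    gn_b: GenericNumber
    distance: float  # Å; NaN when unresolved
    resolved: bool


@dataclass(frozen=True)
class StateUniqueInteraction:
    gn_a: GenericNumber
    gn_b: GenericNumber
    classification: str  # active_unique | inactive_unique
    d_active: float
    d_inactive: float
    receptor: str


@dataclass(frozen=True)
class ConservationCheck:
    gn_a: GenericNumber
    gn_b: GenericNumber
    query_receptor: str
    distance: float  # Å; NaN when unresolved
    interacting: bool
    status: str  # checked | unresolved


def closest_heavy_atom_distance(res_a: ResidueRecord, res_b: ResidueRecord) -> float:
    """Minimum distance (Å) over all heavy-atom pairs, backbone included.

    Returns NaN for a residue with no heavy atoms (unresolved — distinct
    from a genuine zero).
    """
    if not res_a.atoms or not res_b.atoms:
        return float("nan")
    return float(cdist(res_a.coords(), res_b.coords()).min())


def classify_state_unique(d_active: float, d_inactive: float,
                          thr: DistanceThresholds = DistanceThresholds()) -> str:
    """Classify one residue pair from its two-state closest-atom distances.

    Strict inequalities on both thresholds; an unresolved (NaN) distance
    classifies as "none".
    """
    if np.isnan(d_active) or np.isnan(d_inactive):
        return NONE
    if d_active < thr.contact_max and d_inactive > thr.separated_min:
        return ACTIVE_UNIQUE
    if d_inactive < thr.contact_max and d_active > thr.separated_min:
        return INACTIVE_UNIQUE
    return NONE


def _mapped_residues(model: StructureModel, gmap: GenericNumberMap
                     ) -> dict[GenericNumber, ResidueRecord]:
    out: dict[GenericNumber, ResidueRecord] = {}
    for res in model.residues:
        gn = gmap.generic(res.key)
        if gn is not None:
            out[gn] = res
    return out


def _gn_pairs(gmap: GenericNumberMap, include_h8: bool = True
              ) -> list[tuple[GenericNumber, GenericNumber]]:
    """All unordered cross-helix generic-number pairs in a map, sorted."""
    gns = sorted(gn for _, gn in gmap.entries()
                 if include_h8 or gn.helix != 8)
    return [(a, b) for a, b in itertools.combinations(gns, 2) if a.helix != b.helix]


def pairwise_interhelix_distances(model: StructureModel, gmap: GenericNumberMap,
                                  *, include_h8: bool = True) -> list[ResiduePairDistance]:
    """Closest-atom distances for every cross-helix pair of mapped residues.

    One record per unordered pair with different helix indices, ordered by
    (helix_a, pos_a, helix_b, pos_b).  Pairs whose residues are missing from
    the model come back with ``resolved=False`` and NaN distance; same-helix
    pairs and residues absent from the numbering map are excluded.
    """
    if model.receptor != gmap.receptor:
        raise ValueError(
            f"model receptor {model.receptor!r} != map receptor {gmap.receptor!r}")
    present = _mapped_residues(model, gmap)
    records: list[ResiduePairDistance] = []
    for gn_a, gn_b in _gn_pairs(gmap, include_h8):
        ra, rb = present.get(gn_a), present.get(gn_b)
        if ra is None or rb is None:
            records.append(ResiduePairDistance(gn_a, gn_b, float("nan"), False))
        else:
            records.append(ResiduePairDistance(
                gn_a, gn_b, closest_heavy_atom_distance(ra, rb), True))
    return records


def build_state_unique_map(active: StructureModel, inactive: StructureModel,
                           gmap_active: GenericNumberMap, gmap_inactive: GenericNumberMap,
                           thr: DistanceThresholds = DistanceThresholds(),
                           *, include_h8: bool = True) -> list[StateUniqueInteraction]:
    """State-unique interactions between the two activation states of one receptor.

    Distances are computed per state on that state's own numbering map (the
    two maps may differ in resolved residues); pairs resolvable in both
    states are classified, and only classified pairs are returned, sorted by
    (helix_a, pos_a, helix_b, pos_b).
    """
    if active.receptor != inactive.receptor:
        raise ValueError(
            f"receptor mismatch: {active.receptor!r} vs {inactive.receptor!r}")
    d_act = {(r.gn_a, r.gn_b): r for r in
             pairwise_interhelix_distances(active, gmap_active, include_h8=include_h8)}
    d_ina = {(r.gn_a, r.gn_b): r for r in
             pairwise_interhelix_distances(inactive, gmap_inactive, include_h8=include_h8)}

    out: list[StateUniqueInteraction] = []
    for key in sorted(set(d_act) & set(d_ina)):
        ra, ri = d_act[key], d_ina[key]
        if not (ra.resolved and ri.resolved):
            continue
        cls = classify_state_unique(ra.distance, ri.distance, thr)
        if cls != NONE:
            out.append(StateUniqueInteraction(
                gn_a=key[0], gn_b=key[1], classification=cls,
                d_active=ra.distance, d_inactive=ri.distance,
                receptor=active.receptor))
    return out


def check_conservation(reference: list[StateUniqueInteraction],
                       query: StructureModel, query_map: GenericNumberMap,
                       thr: DistanceThresholds = DistanceThresholds()
                       ) -> list[ConservationCheck]:
    """Check whether reference state-unique pairs are in contact in a query receptor.

    Each reference pair's generic numbers are translated into the query's
    numbering via the query map's helix offsets (reference generic numbers
    are taken as canonical).  ``interacting`` is True iff both residues are
    resolved and their closest-atom distance is strictly below
    ``thr.contact_max``; pairs with a missing residue get status
    "unresolved".
    """
    present = _mapped_residues(query, query_map)
    out: list[ConservationCheck] = []
    for ref in reference:
        located: list[ResidueRecord | None] = []
        for gn in (ref.gn_a, ref.gn_b):
            pos = gn.position + query_map.helix_offsets.get(gn.helix, 0)
            res = None
            if 1 <= pos <= 99:
                res = present.get(GenericNumber(gn.helix, pos))
            located.append(res)
        ra, rb = located
        if ra is None or rb is None:
            out.append(ConservationCheck(ref.gn_a, ref.gn_b, query.receptor,
                                         float("nan"), False, "unresolved"))
        else:
            d = closest_heavy_atom_distance(ra, rb)
            out.append(ConservationCheck(ref.gn_a, ref.gn_b, query.receptor,
                                         d, bool(d < thr.contact_max), "checked"))
    return out
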