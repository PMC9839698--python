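"""Closest-atom distances and state-unique interaction classification."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from statemap.generic_numbering import GenericNumber, GenericNumberMap
from statemap.interaction_map import (
    ACTIVE_UNIQUE,
    INACTIVE_UNIQUE,
    NONE,
    DistanceThresholds,
    StateUniqueInteraction,
    build_state_unique_map,
    check_conservation,
    classify_state_unique,
    closest_heavy_atom_distance,
    pairwise_interhelix_distances,
)
from statemap.structure_io import AtomRecord, ResidueRecord, StructureModel
from statemap.synthetic_data import BundleSpec, make_two_state_bundle


def _res(chain, seqnum, *positions):
    atoms = tuple(AtomRecord(name=f"C{i}", element="C", position=np.array(p, float))
                  for i, p in enumerate(positions))
    return ResidueRecord(chain, seqnum, "", "ALA", atoms)


class TestClosestDistance:
    def test_single_atom_pair(self):
        assert closest_heavy_atom_distance(
            _res("A", 1, (0, 0, 0)), _res("A", 2, (3, 0, 0))) == pytest.approx(3.0)

    def test_minimum_over_all_pairs(self):
        # min(dist((0,0,0),(4,3,0)), dist((10,0,0),(4,3,0))) = min(5.0, 6.708) = 5.0
        d = closest_heavy_atom_distance(
            _res("A", 1, (0, 0, 0), (10, 0, 0)), _res("A", 2, (4, 3, 0)))
        assert d == pytest.approx(5.0)

    def test_self_distance_zero(self):
        r = _res("A", 1, (1, 2, 3), (4, 5, 6))
        assert closest_heavy_atom_distance(r, r) == 0.0


class TestClassify:
    @pytest.mark.parametrize("d_act,d_ina,expected", [
        (4.0, 7.0, ACTIVE_UNIQUE),
        (7.0, 4.0, INACTIVE_UNIQUE),
        (4.6, 6.0, NONE),       # boundary values: strict inequalities
        (4.5999, 6.0, NONE),
        (4.6, 6.0001, NONE),
        (5.0, 5.5, NONE),
        (float("nan"), 7.0, NONE),
    ])
    def test_rule(self, d_act, d_ina, expected):
        assert classify_state_unique(d_act, d_ina) == expected

    @settings(max_examples=200, deadline=None)
    @given(st.floats(0.1, 12.0), st.floats(0.1, 12.0))
    def test_mirror_symmetry(self, a, b):
        swap = {ACTIVE_UNIQUE: INACTIVE_UNIQUE, INACTIVE_UNIQUE: ACTIVE_UNIQUE, NONE: NONE}
        assert classify_state_unique(a, b) == swap[classify_state_unique(b, a)]

    @settings(max_examples=200, deadline=None)
    @given(st.floats(0.1, 12.0), st.floats(0.1, 12.0))
    def test_never_both_unique(self, a, b):
        # contact_max < separated_min forbids a pair satisfying both rules
        assert classify_state_unique(a, b) in (ACTIVE_UNIQUE, INACTIVE_UNIQUE, NONE)
        if classify_state_unique(a, b) == ACTIVE_UNIQUE:
            assert classify_state_unique(a, b, DistanceThresholds()) != INACTIVE_UNIQUE

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError):
            DistanceThresholds(contact_max=6.0, separated_min=4.6)


def _toy_model_and_map(n_helices=2, per_helix=3, delete=None):
    gmap = GenericNumberMap("TOY")
    residues = []
    seq = 1
    for h in range(n_helices):
        for i in range(per_helix):
            key = ("A", seq, "")
            gmap.add(key, GenericNumber(h + 1, 49 + i))
            if delete is None or key != delete:
                residues.append(_res("A", seq, (h * 8.0, i * 1.5, 0.0)))
            seq += 1
    return StructureModel("toy", "TOY", "unspecified", residues), gmap


class TestPairwiseDistances:
    def test_cross_helix_pair_count(self):
        model, gmap = _toy_model_and_map(2, 3)
        recs = pairwise_interhelix_distances(model, gmap)
        assert len(recs) == 9
        assert all(r.gn_a.helix != r.gn_b.helix for r in recs)

    def test_deleted_residue_yields_unresolved(self):
        model, gmap = _toy_model_and_map(2, 3, delete=("A", 1, ""))
        recs = pairwise_interhelix_distances(model, gmap)
        unresolved = [r for r in recs if not r.resolved]
        assert len(unresolved) == 3
        assert all(math.isnan(r.distance) for r in unresolved)

    def test_receptor_mismatch_raises(self):
        model, _ = _toy_model_and_map()
        other = GenericNumberMap("OTHER")
        with pytest.raises(ValueError, match="receptor"):
            pairwise_interhelix_distances(model, other)

    def test_matches_bruteforce_on_random_bundle(self, rng):
        """O(n²) oracle: every record's distance equals the naive all-atom minimum."""
        spec = BundleSpec(n_helices=4, residues_per_helix=5, seed=3)
        active, _, gmap, _ = make_two_state_bundle(spec)
        recs = pairwise_interhelix_distances(active, gmap)
        by_key = {r.key: r for r in active.residues}
        gn_to_key = {gn: key for key, gn in gmap.entries()}
        for rec in recs:
            ra, rb = by_key[gn_to_key[rec.gn_a]], by_key[gn_to_key[rec.gn_b]]
            naive = min(float(np.linalg.norm(pa.position - pb.position))
                        for pa in ra.atoms for pb in rb.atoms)
            assert rec.distance == pytest.approx(naive, abs=1e-12)


class TestBuildStateUniqueMap:
    def test_recovers_planted_pairs(self, two_helix_bundle):
        active, inactive, gmap, truth = two_helix_bundle
        found = build_state_unique_map(active, inactive, gmap, gmap)
        got = [(r.gn_a, r.gn_b, r.classification) for r in found]
        assert got == truth.state_unique_pairs
        assert len(got) > 0

    def test_identical_states_give_empty_map(self):
        spec = BundleSpec(n_helices=2, residues_per_helix=6,
                          axis_positions=[(0, 0), (7.5, 0)])
        active, inactive, gmap, truth = make_two_state_bundle(spec)
        assert truth.state_unique_pairs == []
        assert build_state_unique_map(active, inactive, gmap, gmap) == []

    def test_unattainable_thresholds_give_empty_map(self, two_helix_bundle):
        active, inactive, gmap, _ = two_helix_bundle
        thr = DistanceThresholds(contact_max=2.0, separated_min=50.0)
        assert build_state_unique_map(active, inactive, gmap, gmap, thr) == []

    def test_receptor_label_mismatch(self, two_helix_bundle):
        active, inactive, gmap, _ = two_helix_bundle
        inactive.receptor = "OTHER"
        with pytest.raises(ValueError, match="mismatch"):
            build_state_unique_map(active, inactive, gmap, gmap)

    def test_monotonic_in_thresholds(self, two_helix_bundle):
        """Enlarging contact_max / shrinking separated_min never removes a pair."""
        active, inactive, gmap, _ = two_helix_bundle
        base = {(r.gn_a, r.gn_b) for r in
                build_state_unique_map(active, inactive, gmap, gmap)}
        wider = {(r.gn_a, r.gn_b) for r in build_state_unique_map(
            active, inactive, gmap, gmap, DistanceThresholds(5.2, 5.8))}
        assert base <= wider


def _conservation_query(distance):
    gmap = GenericNumberMap("Q")
    gmap.add(("A", 10, ""), GenericNumber(3, 50))
    gmap.add(("A", 20, ""), GenericNumber(6, 30))
    model = StructureModel("q", "Q", "unspecified", [
        _res("A", 10, (0, 0, 0)), _res("A", 20, (distance, 0, 0))])
    ref = [StateUniqueInteraction(GenericNumber(3, 50), GenericNumber(6, 30),
                                  ACTIVE_UNIQUE, 4.0, 7.0, "B2AR")]
    return ref, model, gmap


class TestConservation:
    def test_contact_below_threshold_interacting(self):
        ref, model, gmap = _conservation_query(3.2)
        (chk,) = check_conservation(ref, model, gmap)
        assert chk.interacting and chk.status == "checked"
        assert chk.distance == pytest.approx(3.2)

    def test_exact_threshold_not_interacting(self):
        ref, model, gmap = _conservation_query(4.6)
        (chk,) = check_conservation(ref, model, gmap)
        assert not chk.interacting and chk.status == "checked"

    def test_missing_residue_unresolved(self):
        ref, model, gmap = _conservation_query(3.2)
        model.residues = model.residues[:1]  # delete the 6.30 residue
        (chk,) = check_conservation(ref, model, gmap)
        assert chk.status == "unresolved" and not chk.interacting

    def test_helix_offset_applied_to_query(self):
        """A query numbered with a +1 slide on helix 6 still resolves 6.30."""
        gmap = GenericNumberMap("Q", helix_offsets={6: 1})
        gmap.add(("A", 10, ""), GenericNumber(3, 50))
        gmap.add(("A", 20, ""), GenericNumber(6, 31))  # table label, slid by +1
        model = StructureModel("q", "Q", "unspecified", [
            _res("A", 10, (0, 0, 0)), _res("A", 20, (3.0, 0, 0))])
        ref = [StateUniqueInteraction(GenericNumber(3, 50), GenericNumber(6, 30),
                                      ACTIVE_UNIQUE, 4.0, 7.0, "B2AR")]
        (chk,) = check_conservation(ref, model, gmap)
        assert chk.status == "checked" and chk.interacting
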