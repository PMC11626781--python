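"""Overlap-junction metrics: twist angle, bend, overlap, width, distance maps."""

import numpy as np
import pytest

from conftest import random_rigid_transform
from coilgeom import (JunctionModel, StructureModel, distance_change_map,
                      distance_map, junction_bend_omega, junction_twist_angle,
                      junctions_from_cable, overlap_length, terminal_width)
from coilgeom.junction import JunctionError
from coilgeom.model import AtomRecord, Chain, Residue


def _point_residue(seqid, pos, name="ALA"):
    return Residue(seqid, name, [AtomRecord("CA", "C", np.asarray(pos, float))])


def _plane_dimer(p_left, p_right, p_apex, edge_residues, apex_residue, chain_ids):
    """Two single-atom chains whose plane anchors sit exactly at the given points."""
    lo, hi = edge_residues
    chain1 = Chain(chain_ids[0], [_point_residue(s, p_left) for s in range(lo, hi + 1)])
    chain2 = Chain(chain_ids[1], [_point_residue(s, p_right) for s in range(lo, hi + 1)])
    # apex residue present in both chains, at the same point -> joint centroid = p_apex
    for ch in (chain1, chain2):
        ch.residues.append(_point_residue(apex_residue, p_apex))
        ch.residues.sort(key=lambda r: r.seqid)
    return StructureModel([chain1, chain2])


def analytic_junction(angle_deg):
    """Junction whose two twist planes have normals exactly ``angle_deg`` apart."""
    # C-plane triangle: vertices symmetric about z, apex below -> normal along y
    c_dimer = _plane_dimer([1.0, 0.0, 0.0], [-1.0, 0.0, 0.0], [0.0, 0.0, -2.0],
                           (157, 159), 147, ("A", "B"))
    a = np.deg2rad(angle_deg)
    Rz = np.array([[np.cos(a), -np.sin(a), 0.0],
                   [np.sin(a), np.cos(a), 0.0],
                   [0.0, 0.0, 1.0]])
    pts = [Rz @ np.array(p) + np.array([0.0, 0.0, 5.0])
           for p in ([1.0, 0.0, 0.0], [-1.0, 0.0, 0.0], [0.0, 0.0, -2.0])]
    n_dimer = _plane_dimer(pts[0], pts[1], pts[2], (4, 6), 14, ("C", "D"))
    return JunctionModel(c_dimer, n_dimer)


class TestTwistAngle:
    @pytest.mark.parametrize("angle", [10.0, 60.0, 98.26, 179.0])
    def test_analytic_plane_construction(self, angle):
        got = junction_twist_angle(analytic_junction(angle))
        assert got == pytest.approx(angle, abs=0.01)

    def test_rigid_transform_invariance(self, rng):
        jm = analytic_junction(60.0)
        R, t = random_rigid_transform(rng)
        moved = JunctionModel(jm.c_dimer.transformed(R, t), jm.n_dimer.transformed(R, t))
        assert junction_twist_angle(moved) == pytest.approx(
            junction_twist_angle(jm), abs=1e-4)

    def test_swapping_chains_in_both_dimers_preserves_theta(self, cable):
        jm = junctions_from_cable(cable)[0]
        theta = junction_twist_angle(jm)
        swapped = JunctionModel(
            StructureModel(jm.c_dimer.chains[::-1]),
            StructureModel(jm.n_dimer.chains[::-1]))
        assert junction_twist_angle(swapped) == pytest.approx(theta, abs=1e-6)

    def test_missing_anchor_residue_is_named(self, cable):
        jm = junctions_from_cable(cable)[0]
        stripped = StructureModel([
            Chain(c.chain_id, [r for r in c.residues if r.seqid != 147])
            for c in jm.c_dimer.chains])
        with pytest.raises(JunctionError, match="147"):
            junction_twist_angle(JunctionModel(stripped, jm.n_dimer))


class TestBendOmega:
    def test_collinear_cable_is_straight(self, cable):
        jm = junctions_from_cable(cable)[0]
        assert junction_bend_omega(jm) == pytest.approx(0.0, abs=1.0)

    def test_constructed_hinge(self, cable):
        from scipy.spatial.transform import Rotation
        jm = junctions_from_cable(cable)[0]
        hinge = np.array([0.0, 0.0, 160 * 1.49 - 4.0])
        R = Rotation.from_euler("x", 20, degrees=True).as_matrix()
        bent = jm.n_dimer.transformed(R, hinge - R @ hinge)
        assert junction_bend_omega(JunctionModel(jm.c_dimer, bent)) == pytest.approx(20.0, abs=1.0)


class TestOverlapAndWidth:
    def test_generator_round_trip(self, params):
        from coilgeom import JunctionSpec, build_cable
        spec = JunctionSpec(75.0, 7.0, 17.5, 2)
        jm = junctions_from_cable(build_cable(params, spec))[0]
        assert overlap_length(jm) == pytest.approx(7.0, abs=0.3)
        assert terminal_width(jm) == pytest.approx(17.5, abs=0.3)

    def test_width_is_direct_distance(self):
        dummy_c = StructureModel([
            Chain("A", [_point_residue(150, [0.0, 0.0, -30.0])]),
            Chain("B", [_point_residue(150, [0.0, 0.0, -30.0])])])
        n_dimer = StructureModel([
            Chain("C", [_point_residue(1, [0.0, 0.0, 0.0])]),
            Chain("D", [_point_residue(1, [10.0, 0.0, 0.0])])])
        assert terminal_width(JunctionModel(dummy_c, n_dimer)) == pytest.approx(10.0)

    def test_missing_terminal_residue_is_an_error(self, cable):
        jm = junctions_from_cable(cable)[0]
        with pytest.raises(JunctionError, match="999"):
            terminal_width(jm, residue=999)


def _random_window_junction(rng, n_res=4, atoms_per_res=5, spread=8.0):
    chains = []
    for cid, (lo, hi) in (("A", (150, 161)), ("B", (150, 161))):
        residues = [Residue(s, "ALA",
                            [AtomRecord("CA", "C", rng.uniform(0, spread, 3))
                             for _ in range(atoms_per_res)])
                    for s in range(lo, lo + n_res)]
        chains.append(Chain(cid, residues))
    c_dimer = StructureModel(chains)
    chains = []
    for cid in ("C", "D"):
        residues = [Residue(s, "ALA",
                            [AtomRecord("CA", "C", rng.uniform(0, spread, 3))
                             for _ in range(atoms_per_res)])
                    for s in range(1, 1 + n_res)]
        chains.append(Chain(cid, residues))
    return JunctionModel(c_dimer, StructureModel(chains))


class TestDistanceMap:
    def test_direct_entry(self):
        c_dimer = StructureModel([
            Chain("A", [_point_residue(150, [0.0, 0.0, 0.0])]),
            Chain("B", [_point_residue(150, [50.0, 0.0, 0.0])])])
        n_dimer = StructureModel([
            Chain("C", [_point_residue(1, [3.0, 0.0, 0.0])]),
            Chain("D", [_point_residue(1, [60.0, 0.0, 0.0])])])
        dm = distance_map(JunctionModel(c_dimer, n_dimer))
        df = dm.to_dataframe()
        assert df.loc["C:1", "A:150"] == pytest.approx(3.0)

    def test_cutoff_masks_far_pairs(self):
        c_dimer = StructureModel([
            Chain("A", [_point_residue(150, [0.0, 0.0, 0.0])]),
            Chain("B", [_point_residue(150, [0.0, 0.0, 0.0])])])
        n_dimer = StructureModel([
            Chain("C", [_point_residue(1, [7.5, 0.0, 0.0])]),
            Chain("D", [_point_residue(1, [7.5, 0.0, 0.0])])])
        dm = distance_map(JunctionModel(c_dimer, n_dimer), cutoff=6.0)
        assert dm.mask.all()
        assert np.isnan(dm.to_dataframe().to_numpy()).all()

    def test_matches_bruteforce_all_pairs(self, rng):
        jm = _random_window_junction(rng)
        dm = distance_map(jm, cutoff=np.inf)
        for i, (_, rn) in enumerate(
                [(f"{c.chain_id}:{r.seqid}", r) for c in jm.n_dimer.chains for r in c.residues]):
            for k, (_, rc) in enumerate(
                    [(f"{c.chain_id}:{r.seqid}", r) for c in jm.c_dimer.chains for r in c.residues]):
                brute = min(np.linalg.norm(a.position - b.position)
                            for a in rn.atoms for b in rc.atoms)
                assert dm.values[i, k] == pytest.approx(brute, abs=1e-9)

    def test_raising_cutoff_only_unmasks(self, rng):
        jm = _random_window_junction(rng)
        lo = distance_map(jm, cutoff=4.0)
        hi = distance_map(jm, cutoff=8.0)
        assert (hi.mask <= lo.mask).all()  # unmasking only
        both = ~lo.mask & ~hi.mask
        np.testing.assert_array_equal(lo.values[both], hi.values[both])


class TestDistanceChange:
    def test_identical_maps_give_zero(self, rng):
        jm = _random_window_junction(rng)
        dm = distance_map(jm, cutoff=np.inf)
        change = distance_change_map(dm, dm)
        np.testing.assert_allclose(change.mean_change, 0.0, atol=1e-12)

    def test_uniform_shift(self, rng):
        jm = _random_window_junction(rng)
        a = distance_map(jm, cutoff=np.inf)
        import copy
        b = copy.deepcopy(a)
        b.values = b.values + 1.0
        change = distance_change_map(a, b)
        np.testing.assert_allclose(change.mean_change, 1.0, atol=1e-12)

    def test_matches_bruteforce_on_random_maps(self, rng):
        jm = _random_window_junction(rng)
        a = distance_map(jm, cutoff=8.0)
        jm2 = _random_window_junction(rng)
        b = distance_map(jm2, cutoff=8.0)
        b.row_labels, b.col_labels = a.row_labels, a.col_labels
        change = distance_change_map(a, b)
        for i in range(len(a.row_labels)):
            shared = ~a.mask[i] & ~b.mask[i]
            if shared.any():
                expected = (b.values[i, shared] - a.values[i, shared]).mean()
                assert change.mean_change[i] == pytest.approx(expected, abs=1e-12)
            else:
                assert np.isnan(change.mean_change[i])

    def test_mismatched_windows_rejected(self, rng):
        a = distance_map(_random_window_junction(rng))
        b = distance_map(_random_window_junction(rng, n_res=3))
        with pytest.raises(JunctionError, match="window"):
            distance_change_map(a, b)
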