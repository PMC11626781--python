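"""Local axes, coiled-coil profile, register, superposition, kink angle."""

import numpy as np
import pytest

from conftest import random_rigid_transform
from coilgeom import (CrickParams, assign_heptad, build_ideal_dimer, chirality,
                      coiled_coil_profile, kabsch_superpose, kink_angle,
                      local_axes, pitch_summary, rmsd_matrix, symmetry_rmsd)
from coilgeom.crick import dimer_traces
from coilgeom.geometry import GeometryError
from coilgeom.model import ChainTrace


def horn_quaternion_rmsd(A, B):
    """Independent superposition oracle: Horn's closed-form quaternion method."""
    A = A - A.mean(axis=0)
    B = B - B.mean(axis=0)
    S = B.T @ A
    K = np.array([
        [S[0, 0] + S[1, 1] + S[2, 2], S[1, 2] - S[2, 1], S[2, 0] - S[0, 2], S[0, 1] - S[1, 0]],
        [S[1, 2] - S[2, 1], S[0, 0] - S[1, 1] - S[2, 2], S[0, 1] + S[1, 0], S[0, 2] + S[2, 0]],
        [S[2, 0] - S[0, 2], S[0, 1] + S[1, 0], -S[0, 0] + S[1, 1] - S[2, 2], S[1, 2] + S[2, 1]],
        [S[0, 1] - S[1, 0], S[0, 2] + S[2, 0], S[1, 2] + S[2, 1], -S[0, 0] - S[1, 1] + S[2, 2]],
    ])
    lam = np.linalg.eigvalsh(K)[-1]
    msd = (np.sum(A ** 2) + np.sum(B ** 2) - 2.0 * lam) / len(A)
    return np.sqrt(max(msd, 0.0))


class TestLocalAxes:
    def test_straight_helix_axis_collinear(self):
        p = CrickParams(superhelical_radius=0.0)
        trace, _ = dimer_traces(build_ideal_dimer(p, 80))
        ax = local_axes(trace)
        pts = ax.points[ax.defined]
        centered = pts - pts.mean(axis=0)
        _, _, vt = np.linalg.svd(centered)
        off_axis = np.linalg.norm(centered - np.outer(centered @ vt[0], vt[0]), axis=1)
        assert off_axis.max() < 1e-3

    def test_axis_points_on_supercoil_radius(self, params, ideal_traces):
        ax = local_axes(ideal_traces[0])
        radial = np.linalg.norm(ax.points[ax.defined][:, :2], axis=1)
        assert np.allclose(radial, params.superhelical_radius, rtol=0.01)

    def test_reversal_negates_directions_keeps_points(self, ideal_traces):
        fwd = local_axes(ideal_traces[0])
        rev = local_axes(ideal_traces[0].reversed())
        np.testing.assert_allclose(rev.points[rev.defined][::-1],
                                   fwd.points[fwd.defined], atol=1e-9)
        np.testing.assert_allclose(rev.directions[rev.defined][::-1],
                                   -fwd.directions[fwd.defined], atol=1e-9)

    def test_too_short_trace_is_an_error(self, ideal_traces):
        short = ChainTrace("A", ideal_traces[0].residue_numbers[:6],
                           ideal_traces[0].ca_positions[:6])
        with pytest.raises(GeometryError, match="window"):
            local_axes(short)


class TestProfile:
    def test_recovers_specified_pitch(self):
        p = CrickParams(superhelical_pitch=-140.0)
        prof = coiled_coil_profile(*dimer_traces(build_ideal_dimer(p, 161)))
        assert pitch_summary(prof)["pitch_A"] == pytest.approx(140.0, abs=1.4)

    def test_rigid_transform_invariance(self, ideal_dimer, ideal_profile, rng):
        R, t = random_rigid_transform(rng)
        moved = coiled_coil_profile(*dimer_traces(ideal_dimer.transformed(R, t)))
        for field in ("local_pitch", "residues_per_pitch", "interhelical_radius",
                      "crick_phase_a"):
            a = getattr(ideal_profile, field)
            b = getattr(moved, field)
            ok = np.isfinite(a) & np.isfinite(b)
            np.testing.assert_allclose(a[ok], b[ok], rtol=1e-6, atol=1e-6)

    def test_terminal_positions_marked_undefined(self, ideal_profile):
        assert not ideal_profile.defined[0] and not ideal_profile.defined[-1]
        assert np.isnan(ideal_profile.local_pitch[0])

    def test_unpaired_traces_error(self, ideal_traces):
        other = ChainTrace("B", ideal_traces[1].residue_numbers + 500,
                           ideal_traces[1].ca_positions)
        with pytest.raises(GeometryError, match="pair"):
            coiled_coil_profile(ideal_traces[0], other)


class TestChirality:
    def test_negative_pitch_is_left_handed(self, ideal_profile):
        assert chirality(ideal_profile) == "left"

    def test_positive_pitch_is_right_handed(self):
        p = CrickParams(superhelical_pitch=130.0)
        prof = coiled_coil_profile(*dimer_traces(build_ideal_dimer(p, 120)))
        assert chirality(prof) == "right"

    def test_no_supercoil_for_straight_helix(self):
        p = CrickParams(superhelical_radius=0.0)
        prof = coiled_coil_profile(*dimer_traces(build_ideal_dimer(p, 120)))
        assert chirality(prof) == "no_supercoil"


class TestHeptad:
    def test_period_seven_register(self, ideal_profile):
        letters, disc = assign_heptad(ideal_profile)
        assert disc == []
        defined = [c for c in letters if c != "-"]
        assert len(set(defined)) == 7
        # strict heptad periodicity
        for i in range(len(letters) - 7):
            if letters[i] != "-" and letters[i + 7] != "-":
                assert letters[i] == letters[i + 7]

    def test_anchor_maps_phase_a_to_letter_a(self, ideal_profile):
        # generator default phase puts residue 1 (index 0) at the 'a' position;
        # first defined positions continue the abcdefg cycle
        letters, _ = assign_heptad(ideal_profile)
        first = next(i for i, c in enumerate(letters) if c != "-")
        assert letters[first] == "abcdefg"[first % 7]


class TestSuperposition:
    def test_identity(self, ideal_traces):
        res = kabsch_superpose(ideal_traces[0].ca_positions, ideal_traces[0].ca_positions)
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0)

    def test_translation_invariance(self, ideal_traces):
        moved = ideal_traces[0].ca_positions + np.array([10.0, 0.0, 0.0])
        res = kabsch_superpose(ideal_traces[0].ca_positions, moved)
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)

    def test_matches_quaternion_oracle_on_random_sets(self, rng):
        for _ in range(20):
            A = rng.normal(size=(10, 3)) * 5.0
            B = rng.normal(size=(10, 3)) * 5.0
            got = kabsch_superpose(A, B).rmsd
            assert got == pytest.approx(horn_quaternion_rmsd(A, B), abs=1e-6)

    def test_collinear_points_rejected(self):
        line = np.outer(np.arange(5, dtype=float), [1.0, 0.0, 0.0])
        with pytest.raises(GeometryError, match="degenerate"):
            kabsch_superpose(line, line)

    def test_rotation_is_proper(self, rng):
        A = rng.normal(size=(30, 3))
        R, t = random_rigid_transform(rng)
        res = kabsch_superpose(A @ R.T + t, A)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0)
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)


class TestRmsdMatrix:
    def test_symmetric_zero_diagonal(self, ideal_traces, rng):
        a, b = ideal_traces
        noisy = ChainTrace("C", a.residue_numbers, a.ca_positions + rng.normal(0, 1, a.ca_positions.shape))
        M = rmsd_matrix([a, b, noisy]).to_numpy()
        assert np.allclose(M, M.T)
        assert np.allclose(np.diag(M), 0.0)

    def test_entries_match_quaternion_oracle(self, ideal_traces, rng):
        a, b = ideal_traces
        noisy = ChainTrace("C", a.residue_numbers,
                           a.ca_positions + rng.normal(0, 1, a.ca_positions.shape))
        traces = [a, b, noisy]
        M = rmsd_matrix(traces).to_numpy()
        for i in range(3):
            for j in range(i + 1, 3):
                oracle = horn_quaternion_rmsd(traces[i].ca_positions, traces[j].ca_positions)
                assert M[i, j] == pytest.approx(oracle, abs=1e-6)

    def test_symmetry_rmsd_matches_matrix(self, ideal_traces):
        assert symmetry_rmsd(*ideal_traces) == pytest.approx(
            rmsd_matrix(list(ideal_traces)).iloc[0, 1], abs=1e-12)


class TestKinkAngle:
    def test_straight_dimer_is_zero(self, ideal_traces):
        assert kink_angle(*ideal_traces) == pytest.approx(0.0, abs=1.0)

    def test_constructed_hinge_recovered(self, ideal_traces):
        from scipy.spatial.transform import Rotation
        hinge_z = 81 * 1.49
        R = Rotation.from_euler("y", 30, degrees=True).as_matrix()
        pivot = np.array([0.0, 0.0, hinge_z])

        def bend(trace):
            pos = trace.ca_positions.copy()
            sel = pos[:, 2] > hinge_z
            pos[sel] = (pos[sel] - pivot) @ R.T + pivot
            return ChainTrace(trace.chain_id, trace.residue_numbers, pos)

        assert kink_angle(bend(ideal_traces[0]), bend(ideal_traces[1])) == pytest.approx(30.0, abs=1.0)

    def test_overlapping_windows_rejected(self, ideal_traces):
        with pytest.raises(GeometryError, match="disjoint"):
            kink_angle(*ideal_traces, window_n=(20, 100), window_c=(95, 145))
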