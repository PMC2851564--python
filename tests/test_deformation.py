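import numpy as np
import pytest
from conftest import model_from_coords
from scipy.spatial.transform import Rotation

from aakdyn import (
    AlignmentMap,
    ToySpec,
    build_hessian,
    cumulative_overlap,
    decompose,
    deformation_vector,
    generate_conformers,
    make_toy,
    overlap,
    superpose,
)
from aakdyn.deformation import DeformationVector, apply_transform
from aakdyn.synthetic_data import deform_toy


@pytest.fixture(scope="module")
def dumbbell_modes(dumbbell):
    return decompose(build_hessian(dumbbell))


class TestSuperpose:
    def test_recovers_applied_rotation(self, dumbbell):
        rot_true = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        moved = dumbbell.coords @ rot_true.T + np.array([1.0, -2.0, 3.0])
        rot, trans, rmsd = superpose(moved, dumbbell.coords)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(rot, rot_true, atol=1e-9)

    def test_identity_case(self, dumbbell):
        rot, trans, rmsd = superpose(dumbbell.coords, dumbbell.coords)
        assert np.allclose(rot, np.eye(3), atol=1e-9)
        assert rmsd == pytest.approx(0.0, abs=1e-12)

    def test_matches_scipy_align_vectors(self, dumbbell):
        """Independent oracle: scipy's Kabsch implementation."""
        rng = np.random.default_rng(11)
        rot_true = Rotation.random(rng=rng).as_matrix()
        noisy = dumbbell.coords @ rot_true.T + rng.normal(0, 0.3, (40, 3))
        rot, _, _ = superpose(dumbbell.coords, noisy)
        a_c = dumbbell.coords - dumbbell.coords.mean(axis=0)
        b_c = noisy - noisy.mean(axis=0)
        oracle, _ = Rotation.align_vectors(a_c, b_c)
        assert np.allclose(rot, oracle.as_matrix(), atol=1e-8)

    def test_noise_rmsd_scaling(self):
        rng = np.random.default_rng(42)
        coords = rng.uniform(0, 50, size=(500, 3))
        sigma = 0.5
        noisy = coords + rng.normal(0, sigma, size=coords.shape)
        _, _, rmsd = superpose(coords, noisy)
        assert abs(rmsd - sigma * np.sqrt(3)) < 0.2 * sigma * np.sqrt(3)

    def test_proper_rotation_only(self):
        rng = np.random.default_rng(5)
        a = rng.normal(size=(10, 3))
        b = a * np.array([-1.0, 1.0, 1.0])     # mirror image
        rot, _, _ = superpose(a, b)
        assert np.linalg.det(rot) == pytest.approx(1.0)

    def test_too_few_pairs(self):
        with pytest.raises(ValueError, match="at least 3"):
            superpose(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_collinear_pairs(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(ValueError, match="collinear"):
            superpose(line, line)

    def test_idempotent(self, dumbbell):
        rng = np.random.default_rng(3)
        other = dumbbell.coords + rng.normal(0, 0.4, (40, 3))
        rot, trans, rmsd1 = superpose(dumbbell.coords, other)
        moved = apply_transform(other, rot, trans)
        _, _, rmsd2 = superpose(dumbbell.coords, moved)
        assert abs(rmsd1 - rmsd2) < 1e-12


class TestDeformationVector:
    def test_identical_structures_zero_vector(self, dumbbell):
        d = deformation_vector(dumbbell, dumbbell)
        assert np.abs(d.delta).max() < 1e-9
        assert d.rmsd == pytest.approx(0.0, abs=1e-12)

    def test_rigid_shift_removed(self, dumbbell):
        shifted = dumbbell.coords + np.array([1.0, 0.0, 0.0])
        d = deformation_vector(dumbbell, shifted)
        assert np.abs(d.delta).max() < 1e-9

    def test_rmsd_consistent_with_delta(self, dumbbell):
        closed = deform_toy(dumbbell, mode=1, amplitude=1.0)
        d = deformation_vector(dumbbell, closed)
        assert np.linalg.norm(d.delta) / np.sqrt(d.n_mapped) == pytest.approx(
            d.rmsd, abs=1e-9
        )

    def test_bend_localizes_on_moving_lobe(self, dumbbell):
        """Rotating one lobe about the bridge then superposing on the other
        lobe leaves the deformation concentrated on the rotated lobe."""
        lobe_a = dumbbell.meta["lobe_a"]
        lobe_b = dumbbell.meta["lobe_b"]
        bridge = dumbbell.coords[dumbbell.meta["bridge_index"]]
        rot = Rotation.from_euler("y", 10, degrees=True).as_matrix()
        coords = dumbbell.coords.copy()
        sel = np.array(lobe_b)
        coords[sel] = (coords[sel] - bridge) @ rot.T + bridge
        mapping = AlignmentMap(tuple((i, i) for i in lobe_a))
        d = deformation_vector(dumbbell.coords, coords, mapping)
        assert d.rmsd < 0.2     # superposed lobe barely moves
        full = deformation_vector(
            dumbbell.coords, coords, AlignmentMap.identity(40)
        )
        assert np.linalg.norm(full.delta) > 1.0


class TestOverlap:
    def test_parallel_gives_unity(self, dumbbell, dumbbell_modes):
        u1 = dumbbell_modes.mode(1)
        d = DeformationVector(2.0 * u1, AlignmentMap.identity(40), 1.0)
        assert overlap(u1, d) == pytest.approx(1.0)
        d_neg = DeformationVector(-2.0 * u1, AlignmentMap.identity(40), 1.0)
        assert overlap(u1, d_neg) == pytest.approx(-1.0)

    def test_orthogonal_gives_zero(self, dumbbell_modes):
        u1, u2 = dumbbell_modes.mode(1), dumbbell_modes.mode(2)
        d = DeformationVector(u2, AlignmentMap.identity(40), 1.0)
        assert overlap(u1, d) == pytest.approx(0.0, abs=1e-10)

    def test_zero_deformation_rejected(self, dumbbell_modes):
        d = DeformationVector(np.zeros(120), AlignmentMap.identity(40), 0.0)
        with pytest.raises(ValueError, match="no conformational change"):
            overlap(dumbbell_modes.mode(1), d)

    def test_single_random_deformation_mean_cos2(self, dumbbell,
                                                 dumbbell_modes):
        """For any internal deformation the squared cosines over the full
        mode set sum to 1, so their mean is exactly 1/(3M-6)."""
        rng = np.random.default_rng(0)
        d = deformation_vector(
            dumbbell, dumbbell.coords + rng.normal(size=(40, 3))
        )
        cos2 = [
            overlap(dumbbell_modes.mode(k), d) ** 2
            for k in range(1, dumbbell_modes.n_modes + 1)
        ]
        assert np.mean(cos2) == pytest.approx(1 / (3 * 40 - 6), abs=1e-12)

    def test_mode1_mean_cos2_over_trials(self, dumbbell, dumbbell_modes):
        """Across random deformations, one mode's expected squared cosine
        is 1/(3M-6); checked within 3 standard errors over 200 trials."""
        rng = np.random.default_rng(7)
        u1 = dumbbell_modes.mode(1)
        cos2 = []
        for _ in range(200):
            d = deformation_vector(
                dumbbell, dumbbell.coords + rng.normal(size=(40, 3))
            )
            cos2.append(overlap(u1, d) ** 2)
        cos2 = np.asarray(cos2)
        se = cos2.std(ddof=1) / np.sqrt(cos2.size)
        assert abs(cos2.mean() - 1 / (3 * 40 - 6)) < 3 * se


class TestCumulativeOverlap:
    def test_complete_basis_reaches_unity(self, dumbbell, dumbbell_modes):
        rng = np.random.default_rng(1)
        d = deformation_vector(
            dumbbell, dumbbell.coords + rng.normal(size=(40, 3))
        )
        co = cumulative_overlap(dumbbell_modes, d)
        assert co[-1] == pytest.approx(1.0, abs=1e-8)
        assert np.all(np.diff(co) >= -1e-12)

    def test_pure_mode_deformation(self, dumbbell_modes):
        u1 = dumbbell_modes.mode(1)
        d = DeformationVector(u1.copy(), AlignmentMap.identity(40), 1.0)
        assert cumulative_overlap(dumbbell_modes, d, 1)[0] == pytest.approx(1.0)

    def test_two_mode_pythagoras(self, dumbbell_modes):
        u = (dumbbell_modes.mode(1) + dumbbell_modes.mode(2)) / np.sqrt(2)
        d = DeformationVector(u, AlignmentMap.identity(40), 1.0)
        co = cumulative_overlap(dumbbell_modes, d, 2)
        assert co[0] == pytest.approx(1 / np.sqrt(2))
        assert co[1] == pytest.approx(1.0)

    def test_mode_recovery_after_deformation(self, dumbbell, dumbbell_modes):
        """Deforming along mode 1 and recomputing the deformation vector
        recovers that mode: CO(1) >= 0.99, also under 5% noise."""
        closed = deform_toy(dumbbell, mode=1, amplitude=1.0)
        d = deformation_vector(dumbbell, closed)
        assert cumulative_overlap(dumbbell_modes, d, 1)[0] >= 0.99
        noisy = deform_toy(dumbbell, mode=1, amplitude=1.0,
                           noise=0.05, seed=2)
        d_noisy = deformation_vector(dumbbell, noisy)
        assert cumulative_overlap(dumbbell_modes, d_noisy, 1)[0] >= 0.99

    def test_partial_mapping_valid_cosines(self, dumbbell, dumbbell_modes):
        """Modes sliced to a partial mapping and renormalized still give
        true cosines (|cos| <= 1) and a monotone CO profile; the sliced
        basis is no longer orthonormal, so CO is not capped at 1."""
        closed = deform_toy(dumbbell, mode=2, amplitude=0.5)
        mapping = AlignmentMap(tuple((i, i) for i in range(0, 40, 2)))
        d = deformation_vector(dumbbell, closed, mapping)
        cos = [
            overlap(dumbbell_modes.mode(k), d) for k in range(1, 21)
        ]
        assert np.abs(cos).max() <= 1 + 1e-12
        co = cumulative_overlap(dumbbell_modes, d, 20)
        assert np.all(np.diff(co) >= -1e-12)

    def test_m_out_of_range(self, dumbbell_modes):
        d = DeformationVector(
            dumbbell_modes.mode(1), AlignmentMap.identity(40), 1.0
        )
        with pytest.raises(ValueError):
            cumulative_overlap(dumbbell_modes, d, dumbbell_modes.n_modes + 1)


class TestConformers:
    def test_zero_amplitude_reproduces_reference(self, dumbbell,
                                                 dumbbell_modes):
        plus, minus = generate_conformers(dumbbell, dumbbell_modes, 1,
                                          amplitude=0.0)
        assert np.array_equal(plus, dumbbell.coords)
        assert np.array_equal(minus, dumbbell.coords)

    def test_plus_minus_rmsd_identity(self, dumbbell, dumbbell_modes):
        s = 2.0
        k = 4
        plus, minus = generate_conformers(dumbbell, dumbbell_modes, k,
                                          amplitude=s)
        rmsd = np.sqrt(((plus - minus) ** 2).sum() / 40)
        expected = 2 * s / np.sqrt(dumbbell_modes.eigenvalue(k)) / np.sqrt(40)
        assert rmsd == pytest.approx(expected, rel=1e-9)

    def test_target_rmsd_honoured(self, dumbbell, dumbbell_modes):
        plus, _ = generate_conformers(dumbbell, dumbbell_modes, 3,
                                      target_rmsd=1.0)
        rmsd = np.sqrt(((plus - dumbbell.coords) ** 2).sum() / 40)
        assert rmsd == pytest.approx(1.0, rel=1e-9)

    def test_self_consistent_overlap(self, dumbbell, dumbbell_modes):
        k = 5
        plus, _ = generate_conformers(dumbbell, dumbbell_modes, k,
                                      target_rmsd=0.3)
        d = deformation_vector(dumbbell.coords, plus)
        assert abs(overlap(dumbbell_modes.mode(k), d)) == pytest.approx(
            1.0, abs=1e-6
        )

    def test_all_atom_rigid_residue_shift(self, dumbbell, dumbbell_modes):
        plus, _ = generate_conformers(
            dumbbell, dumbbell_modes, 1, target_rmsd=0.5,
            all_atom_source=dumbbell,
        )
        node = plus.nodes[0]
        ref = dumbbell.nodes[0]
        shift = np.asarray(node.coord) - np.asarray(ref.coord)
        for h_new, h_old in zip(node.heavy_coords, ref.heavy_coords):
            assert np.allclose(
                np.asarray(h_new) - np.asarray(h_old), shift, atol=1e-9
            )

    def test_gnm_modes_rejected(self, dumbbell):
        from aakdyn import build_kirchhoff

        gnm = decompose(build_kirchhoff(dumbbell))
        with pytest.raises(ValueError, match="ANM"):
            generate_conformers(dumbbell, gnm, 1)
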