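"""
Superimposition, RMSD/RMSF, SASA and secondary-structure assignment,
each checked against an independent oracle.
"""

import numpy as np
import pytest

from atomseq import (
    AtomArray,
    SasaParameters,
    annotate_sse,
    rmsd,
    rmsf,
    sasa,
    sphere_points,
    superimpose,
)
from atomseq.analyze import atom_radii
from atomseq.fixtures import ideal_helix, ideal_strand, random_coil
from conftest import random_rotation


def quaternion_min_rmsd(fixed: np.ndarray, mobile: np.ndarray) -> float:
    """
    Independent oracle: minimal RMSD over proper rigid motions via the
    quaternion characteristic-polynomial method (largest eigenvalue of
    the 4x4 key matrix), no rotation matrix ever constructed.
    """
    a = fixed - fixed.mean(axis=0)
    b = mobile - mobile.mean(axis=0)
    inner = (a * a).sum() + (b * b).sum()
    r = b.T @ a
    f = np.array(
        [
            [r[0, 0] + r[1, 1] + r[2, 2], r[1, 2] - r[2, 1],
             r[2, 0] - r[0, 2], r[0, 1] - r[1, 0]],
            [r[1, 2] - r[2, 1], r[0, 0] - r[1, 1] - r[2, 2],
             r[0, 1] + r[1, 0], r[0, 2] + r[2, 0]],
            [r[2, 0] - r[0, 2], r[0, 1] + r[1, 0],
             -r[0, 0] + r[1, 1] - r[2, 2], r[1, 2] + r[2, 1]],
            [r[0, 1] - r[1, 0], r[0, 2] + r[2, 0],
             r[1, 2] + r[2, 1], -r[0, 0] - r[1, 1] + r[2, 2]],
        ]
    )
    lam = np.linalg.eigvalsh(f)[-1]
    return float(np.sqrt(max(inner - 2.0 * lam, 0.0) / len(fixed)))


def sphere_pair_exposed_area(r1, r2, d, resolution=2000):
    """
    Numerical integration oracle: lat-long quadrature of the part of a
    sphere of radius r1 lying outside a sphere of radius r2 centered at
    distance d along the z axis.
    """
    theta = (np.arange(resolution) + 0.5) * np.pi / resolution
    z = r1 * np.cos(theta)
    # all points at polar angle theta have the same distance to the
    # second center
    dist = np.sqrt(r1**2 + d**2 - 2 * d * z)
    outside = dist >= r2
    ring_area = 2 * np.pi * r1**2 * np.sin(theta) * (np.pi / resolution)
    return float((ring_area * outside).sum())


class TestSuperimpose:
    def test_identity(self):
        coords = np.random.default_rng(1).normal(size=(10, 3))
        sup, transform = superimpose(coords, coords.copy())
        assert np.allclose(transform.rotation, np.eye(3), atol=1e-9)
        assert rmsd(coords, sup) < 1e-12

    def test_exact_recovery_of_known_motion(self, rng):
        for _ in range(10):
            fixed = rng.normal(size=(12, 3)) * 4
            rotation = random_rotation(rng)
            shift = rng.normal(size=3) * 7
            mobile = fixed @ rotation.T + shift
            sup, transform = superimpose(fixed, mobile)
            assert rmsd(fixed, sup) < 1e-9
            # recovered rotation is the inverse of the applied one
            assert np.allclose(transform.rotation, rotation.T, atol=1e-9)

    def test_noisy_pairs_match_quaternion_oracle(self, rng):
        for _ in range(20):
            fixed = rng.normal(size=(20, 3)) * 3
            mobile = fixed @ random_rotation(rng).T + rng.normal(size=(20, 3)) * 0.3
            sup, _ = superimpose(fixed, mobile)
            assert rmsd(fixed, sup) == pytest.approx(
                quaternion_min_rmsd(fixed, mobile), abs=1e-9
            )

    def test_optimality_against_random_transforms(self, rng):
        fixed = rng.normal(size=(15, 3)) * 3
        mobile = fixed + rng.normal(size=(15, 3)) * 0.5
        sup, _ = superimpose(fixed, mobile)
        best = rmsd(fixed, sup)
        for _ in range(100):
            trial = mobile @ random_rotation(rng).T + rng.normal(size=3)
            assert best <= rmsd(fixed, trial) + 1e-12

    def test_no_reflection_even_for_mirrored_input(self, rng):
        fixed = rng.normal(size=(10, 3))
        mirrored = fixed * np.array([1.0, 1.0, -1.0])
        _, transform = superimpose(fixed, mirrored)
        assert np.linalg.det(transform.rotation) == pytest.approx(1.0)
        assert np.allclose(
            transform.rotation @ transform.rotation.T, np.eye(3), atol=1e-9
        )

    def test_errors(self):
        with pytest.raises(ValueError):
            superimpose(np.zeros((4, 3)), np.zeros((5, 3)))
        with pytest.raises(ValueError):
            superimpose(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_pretransformed_mobile_same_final_rmsd(self, rng):
        fixed = rng.normal(size=(10, 3))
        mobile = fixed + rng.normal(size=(10, 3)) * 0.2
        sup1, _ = superimpose(fixed, mobile)
        moved = mobile @ random_rotation(rng).T + rng.normal(size=3)
        sup2, _ = superimpose(fixed, moved)
        assert rmsd(fixed, sup1) == pytest.approx(rmsd(fixed, sup2), abs=1e-9)


class TestRmsdRmsf:
    def test_identical_zero(self, rng):
        coords = rng.normal(size=(8, 3))
        assert rmsd(coords, coords) == 0

    def test_single_displacement_closed_form(self):
        coords = np.zeros((16, 3))
        displaced = coords.copy()
        displaced[3, 0] = 2.0
        assert rmsd(coords, displaced) == pytest.approx(2.0 / np.sqrt(16))

    def test_stack_rmsd_matches_per_model_loop(self, rng):
        ref = rng.normal(size=(6, 3))
        stack = rng.normal(size=(4, 6, 3))
        values = rmsd(ref, stack)
        for k in range(4):
            assert values[k] == pytest.approx(rmsd(ref, stack[k]))

    def test_rmsf_all_identical_zero(self):
        stack = np.tile(np.arange(9, dtype=float).reshape(3, 3), (4, 1, 1))
        assert np.allclose(rmsf(stack), 0)

    def test_rmsf_symmetric_displacement(self):
        base = np.zeros((2, 3))
        up = base.copy(); up[1, 2] = 1.5
        down = base.copy(); down[1, 2] = -1.5
        values = rmsf(np.stack([up, down]))
        assert values[0] == 0
        assert values[1] == pytest.approx(1.5)

    def test_rmsf_matches_double_loop_oracle(self, rng):
        stack = rng.normal(size=(5, 7, 3))
        mean = stack.mean(axis=0)
        expected = np.array(
            [
                np.sqrt(
                    np.mean(
                        [np.sum((stack[m, i] - mean[i]) ** 2) for m in range(5)]
                    )
                )
                for i in range(7)
            ]
        )
        assert np.allclose(rmsf(stack), expected)

    def test_rmsf_needs_two_models(self):
        with pytest.raises(ValueError):
            rmsf(np.zeros((1, 4, 3)))


def single_atom(element="O", res_name="HOH"):
    array = AtomArray(1)
    array.element = np.asarray([element], dtype="U2")
    array.res_name = np.asarray([res_name], dtype="U5")
    array.atom_name = np.asarray([element], dtype="U6")
    return array


class TestSasa:
    def test_isolated_atom_analytic(self):
        # r = 1.52 (O vdW), probe 1.4 => sphere of 2.92 A, all exposed
        array = single_atom()
        area = sasa(array, SasaParameters(point_count=1000, radius_set="element"))
        assert area[0] == pytest.approx(4 * np.pi * 2.92**2, rel=0.01)

    def test_fully_buried_atom(self):
        # central atom enclosed by a tight octahedral + cubic shell
        offsets = [
            (2, 0, 0), (-2, 0, 0), (0, 2, 0), (0, -2, 0), (0, 0, 2),
            (0, 0, -2),
            (1.4, 1.4, 1.4), (-1.4, 1.4, 1.4), (1.4, -1.4, 1.4),
            (1.4, 1.4, -1.4), (-1.4, -1.4, 1.4), (-1.4, 1.4, -1.4),
            (1.4, -1.4, -1.4), (-1.4, -1.4, -1.4),
        ]
        n = 1 + len(offsets)
        array = AtomArray(n)
        array.coord = np.vstack([np.zeros(3), np.asarray(offsets)])
        array.element = np.full(n, "O", dtype="U2")
        array.res_name = np.full(n, "HOH", dtype="U5")
        area = sasa(array, SasaParameters(point_count=500, radius_set="element"))
        assert area[0] == 0

    def test_two_sphere_numeric_integration_oracle(self):
        probe = 1.4
        r_o, r_c = 1.52 + probe, 1.70 + probe
        for d in (1.0, 2.0, 3.0, 4.5, 6.0):
            array = AtomArray(2)
            array.coord = np.array([[0, 0, 0], [0, 0, d]], dtype=float)
            array.element = np.asarray(["O", "C"], dtype="U2")
            array.res_name = np.asarray(["HOH", "UNK"], dtype="U5")
            area = sasa(
                array, SasaParameters(point_count=5000, radius_set="element")
            )
            expected_o = sphere_pair_exposed_area(r_o, r_c, d)
            expected_c = sphere_pair_exposed_area(r_c, r_o, d)
            if expected_o > 1:
                assert area[0] == pytest.approx(expected_o, rel=0.02)
            if expected_c > 1:
                assert area[1] == pytest.approx(expected_c, rel=0.02)

    def test_convergence_with_point_count(self):
        array = single_atom()
        exact = 4 * np.pi * 2.92**2
        errors = []
        for count in (100, 1000, 10000):
            area = sasa(
                array, SasaParameters(point_count=count, radius_set="element")
            )
            errors.append(abs(area[0] - exact) / exact)
        assert errors[0] >= errors[1] >= errors[2]

    def test_total_sasa_non_increasing_when_atoms_added(self, rng):
        coords = rng.uniform(0, 8, size=(12, 3))
        areas = []
        for n in (6, 12):
            array = AtomArray(n)
            array.coord = coords[:n]
            array.element = np.full(n, "C", dtype="U2")
            array.res_name = np.full(n, "UNK", dtype="U5")
            result = sasa(
                array, SasaParameters(point_count=300, radius_set="element")
            )
            areas.append(result[:6].sum())
        assert areas[1] <= areas[0] + 1e-9

    def test_mask_excludes_occluders(self):
        array = AtomArray(2)
        array.coord = np.array([[0, 0, 0], [0, 0, 1.0]])
        array.element = np.asarray(["O", "O"], dtype="U2")
        array.res_name = np.asarray(["HOH", "HOH"], dtype="U5")
        mask = np.array([True, False])
        area = sasa(
            array, SasaParameters(point_count=1000, radius_set="element"), mask
        )
        assert area[0] == pytest.approx(4 * np.pi * 2.92**2, rel=0.01)
        assert np.isnan(area[1])

    def test_unknown_radius_raises_with_atom_name(self):
        array = single_atom(element="ZZ")
        with pytest.raises(ValueError, match="ZZ"):
            sasa(array, SasaParameters(radius_set="element"))

    def test_protor_radii_for_protein_atoms(self):
        array = AtomArray(4)
        array.res_name = np.asarray(["ALA", "ALA", "PHE", "SER"], dtype="U5")
        array.atom_name = np.asarray(["C", "CB", "CD1", "OG"], dtype="U6")
        array.element = np.asarray(["C", "C", "C", "O"], dtype="U2")
        radii = atom_radii(array, "protor")
        assert radii.tolist() == [1.61, 1.88, 1.76, 1.46]

    def test_sphere_points_on_unit_sphere(self):
        points = sphere_points(777)
        assert np.allclose(np.linalg.norm(points, axis=1), 1.0)
        # quasi-uniform: centroid near origin
        assert np.linalg.norm(points.mean(axis=0)) < 0.01


class TestSecondaryStructure:
    def test_ideal_helix_interior_is_helix(self):
        labels = annotate_sse(ideal_helix(20))
        interior = labels[2:-2]
        assert (interior == "a").mean() >= 0.9

    def test_ideal_strand_interior_is_strand(self):
        labels = annotate_sse(ideal_strand(12))
        interior = labels[2:-2]
        assert (interior == "b").all()

    def test_short_chain_all_coil(self):
        labels = annotate_sse(ideal_helix(4))
        assert "".join(labels) == "cccc"

    def test_depends_only_on_ca(self):
        helix = ideal_helix(15)
        labels_before = annotate_sse(helix)
        # add side-chain atoms at silly positions: assignment unchanged
        extra = helix.copy()
        extra.atom_name = np.full(15, "CB", dtype="U6")
        extra.coord = extra.coord + 40.0
        from atomseq import concatenate

        combined = concatenate([helix, extra])
        assert np.array_equal(annotate_sse(combined), labels_before)

    def test_random_coil_mostly_coil(self):
        labels = annotate_sse(random_coil(30, seed=3))
        assert (labels == "c").mean() > 0.5

    def test_biotite_oracle_on_fixtures(self):
        # independent published-criteria implementation as cross-check
        import biotite.structure as struc

        for fixture in (ideal_helix(20), ideal_strand(12)):
            bio = struc.AtomArray(fixture.array_length)
            bio.coord = fixture.coord.astype(np.float32)
            bio.chain_id = fixture.chain_id
            bio.res_id = fixture.res_id
            bio.res_name = fixture.res_name
            bio.atom_name = fixture.atom_name
            bio.element = fixture.element
            bio.hetero = fixture.hetero
            theirs = struc.annotate_sse(bio)
            ours = annotate_sse(fixture)
            interior = slice(2, -2)
            assert (ours[interior] == theirs[interior]).mean() >= 0.9
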