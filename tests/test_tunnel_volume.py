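"""Grid volume calculation against brute-force and analytic oracles."""

import numpy as np
import pytest

from tunnelfold.structure_io import BeadModel
from tunnelfold.tunnel_volume import (
    InclusionRegion,
    SECM_ANCHORS_10,
    SECM_ANCHORS_8,
    compute_volume,
    inclusion_region_from_residues,
    keep_largest_component,
    volume_difference,
)

from conftest import make_peptide


def brute_force_points(region, occupant_coords, spacing, cutoff):
    """Triple-loop grid oracle without spatial indexing."""
    lo = (region.centers - region.radii[:, None]).min(axis=0)
    hi = (region.centers + region.radii[:, None]).max(axis=0)
    i0 = np.floor(lo / spacing).astype(int)
    i1 = np.ceil(hi / spacing).astype(int)
    count = 0
    for ix in range(i0[0], i1[0] + 1):
        for iy in range(i0[1], i1[1] + 1):
            for iz in range(i0[2], i1[2] + 1):
                p = np.array([ix, iy, iz]) * spacing
                inside = any(np.linalg.norm(p - c) <= r
                             for c, r in zip(region.centers, region.radii))
                if not inside:
                    continue
                if len(occupant_coords) and np.min(
                        np.linalg.norm(occupant_coords - p, axis=1)) <= cutoff:
                    continue
                count += 1
    return count


def bead_model(coords):
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    n = len(coords)
    return BeadModel(np.full(n, "CA"), np.full(n, "A"), np.arange(1, n + 1),
                     coords, np.full(n, 2.0))


class TestComputeVolume:
    def test_empty_sphere_matches_brute_force_and_analytic(self):
        region = InclusionRegion(np.array([[1.0, 2.0, 3.0]]), np.array([10.0]))
        res = compute_volume(None, region, spacing=2.0)
        assert res.n_points == brute_force_points(region, [], 2.0, 1.09)
        analytic = 4.0 / 3.0 * np.pi * 10.0 ** 3
        assert abs(res.volume - analytic) / analytic < 0.05

    def test_halving_spacing_converges_to_analytic(self):
        region = InclusionRegion(np.array([[0.0, 0.0, 0.0]]), np.array([10.0]))
        analytic = 4.0 / 3.0 * np.pi * 10.0 ** 3
        err2 = abs(compute_volume(None, region, spacing=2.0).volume - analytic)
        err1 = abs(compute_volume(None, region, spacing=1.0).volume - analytic)
        assert err1 < err2

    def test_occupant_atom_on_grid_point_removes_exactly_one(self):
        region = InclusionRegion(np.array([[0.0, 0.0, 0.0]]), np.array([8.0]))
        empty = compute_volume(None, region, spacing=2.0, cutoff=1.09)
        occ = bead_model([[2.0, 0.0, 2.0]])  # on the lattice; next point 2 A away
        res = compute_volume(occ, region, spacing=2.0, cutoff=1.09)
        assert empty.n_points - res.n_points == 1

    def test_occupied_region_matches_brute_force(self):
        rng = np.random.default_rng(4)
        region = InclusionRegion(np.array([[0.0, 0.0, 0.0], [8.0, 0.0, 4.0]]),
                                 np.array([9.0, 6.0]))
        coords = rng.uniform(-8, 12, size=(40, 3))
        res = compute_volume(bead_model(coords), region, spacing=2.0)
        assert res.n_points == brute_force_points(region, coords, 2.0, 1.09)

    def test_deterministic(self):
        region = InclusionRegion(np.array([[0.0, 0.0, 0.0]]), np.array([10.0]))
        occ = bead_model(np.random.default_rng(0).uniform(-9, 9, (20, 3)))
        a = compute_volume(occ, region)
        b = compute_volume(occ, region)
        assert a.n_points == b.n_points and a.volume == b.volume

    def test_excluded_chain_ignored(self):
        region = InclusionRegion(np.array([[0.0, 0.0, 0.0]]), np.array([6.0]))
        occ = bead_model([[0.0, 0.0, 0.0]])
        full = compute_volume(occ, region, exclusions=["A"])
        empty = compute_volume(None, region)
        assert full.n_points == empty.n_points

    def test_monotone_in_occupant_and_radius(self):
        rng = np.random.default_rng(7)
        coords = rng.uniform(-6, 6, (30, 3))
        region_small = InclusionRegion(np.zeros((1, 3)), np.array([7.0]))
        region_big = InclusionRegion(np.zeros((1, 3)), np.array([9.0]))
        v_few = compute_volume(bead_model(coords[:10]), region_small).volume
        v_many = compute_volume(bead_model(coords), region_small).volume
        assert v_many <= v_few
        assert (compute_volume(bead_model(coords), region_big).volume
                >= compute_volume(bead_model(coords), region_small).volume)

    def test_bad_inputs(self):
        region = InclusionRegion(np.zeros((1, 3)), np.array([5.0]))
        with pytest.raises(ValueError):
            compute_volume(None, region, spacing=0.0)
        with pytest.raises(ValueError):
            compute_volume(None, region, cutoff=-1.0)
        with pytest.raises(ValueError):
            InclusionRegion(np.zeros((0, 3)), np.zeros(0))


class TestVolumeDifference:
    def test_identical_is_zero(self):
        region = InclusionRegion(np.zeros((1, 3)), np.array([8.0]))
        occ = bead_model([[1.0, 1.0, 1.0]])
        a = compute_volume(occ, region)
        assert volume_difference(a, a) == 0.0

    def test_removing_beads_increases_volume(self):
        rng = np.random.default_rng(11)
        coords = rng.uniform(-7, 7, (60, 3))
        region = InclusionRegion(np.zeros((1, 3)), np.array([9.0]))
        full = compute_volume(bead_model(coords), region)
        reduced = compute_volume(bead_model(coords[:-10]), region)
        diff = volume_difference(full, reduced)
        assert diff >= 0
        # cross-check against the brute-force recount
        expected = (brute_force_points(region, coords[:-10], 2.0, 1.09)
                    - brute_force_points(region, coords, 2.0, 1.09)) * 8.0
        assert diff == pytest.approx(expected)

    def test_mismatched_grids_rejected(self):
        region = InclusionRegion(np.zeros((1, 3)), np.array([8.0]))
        a = compute_volume(None, region, spacing=2.0)
        b = compute_volume(None, region, spacing=1.0)
        with pytest.raises(ValueError):
            volume_difference(a, b)
        other = InclusionRegion(np.ones((1, 3)), np.array([8.0]))
        c = compute_volume(None, other, spacing=2.0)
        with pytest.raises(ValueError):
            volume_difference(a, c)


class TestLargestComponent:
    def test_single_blob_identity(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 1]])
        np.testing.assert_array_equal(keep_largest_component(pts), pts)

    def test_small_blob_removed(self):
        big = np.array([[i, j, 0] for i in range(10) for j in range(10)])
        small = np.array([[50, 50, 50], [51, 50, 50], [50, 51, 50],
                          [51, 51, 50], [50, 50, 51]])
        pts = np.concatenate([big, small])
        out = keep_largest_component(pts)
        assert len(out) == len(big)
        assert out.max() < 20

    def test_equal_blobs_tie_break_lexicographic(self):
        blob_a = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0]])
        blob_b = np.array([[10, 10, 10], [11, 10, 10], [10, 11, 10]])
        out = keep_largest_component(np.concatenate([blob_b, blob_a]))
        np.testing.assert_array_equal(np.sort(out, axis=0), np.sort(blob_a, axis=0))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            keep_largest_component(np.zeros((0, 3)))


class TestInclusionFromResidues:
    def test_anchor_preset_sizes(self):
        assert len(SECM_ANCHORS_10) == 11  # ten 20-A spheres plus one 40-A
        assert len(SECM_ANCHORS_8) == 9

    def test_spheres_centred_on_ca(self):
        s = make_peptide(30)
        anchors = [("A", r, 20.0) for r in (11, 13, 15)] + [("A", 3, 40.0)]
        region = inclusion_region_from_residues(s, anchors)
        assert region.n_spheres == 4
        np.testing.assert_array_equal(region.centers[0],
                                      s.atom_coord("A", 11, "CA"))
        assert region.radii[-1] == 40.0

    def test_missing_anchor_residue_raises(self):
        s = make_peptide(5)
        with pytest.raises(ValueError, match="99"):
            inclusion_region_from_residues(s, [("A", 99, 20.0)])


def test_grid_point_export(tmp_path):
    region = InclusionRegion(np.zeros((1, 3)), np.array([6.0]))
    res = compute_volume(None, region, keep_grid=True)
    xyz = tmp_path / "points.xyz"
    pdb = tmp_path / "points.pdb"
    from tunnelfold.tunnel_volume import write_grid_points_pdb, write_grid_points_xyz

    write_grid_points_xyz(res, xyz)
    back = np.loadtxt(xyz)
    np.testing.assert_allclose(back, res.grid_points, atol=1e-3)
    write_grid_points_pdb(res, pdb)
    assert pdb.read_text().count("HETATM") == res.n_points
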