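"""Structure-based potential: construction, energies, gradients, Q."""

import numpy as np
import pytest

from tunnelfold.go_model import (
    GoParams,
    NativeTopology,
    build_native_contacts,
    build_topology,
    fraction_native_contacts,
    potential_energy,
    potential_energy_terms,
    potential_gradient,
)

from conftest import make_peptide


def brute_force_contacts(structure, cutoff, min_sep):
    """Independent all-pairs enumeration over residues and heavy atoms."""
    res = sorted(set(structure.res_id.tolist()))
    out = []
    for a in range(len(res)):
        for b in range(a + min_sep, len(res)):
            ia = structure.coord[(structure.res_id == res[a])
                                 & (structure.element != "H")]
            ib = structure.coord[(structure.res_id == res[b])
                                 & (structure.element != "H")]
            dmin = min(np.linalg.norm(p - q) for p in ia for q in ib)
            if dmin <= cutoff:
                out.append((a, b))
    return out


class TestContacts:
    def test_far_apart_residues_make_no_contact(self):
        s = make_peptide(6)  # 3.8 A spacing: residues 1 and 6 are 19 A apart
        contacts = build_native_contacts(s, cutoff=4.5, min_separation=4)
        assert contacts == []

    def test_hairpin_matches_brute_force_enumeration(self, hairpin):
        structure, topology = hairpin
        cutoff = topology.params.contact_cutoff
        expected = brute_force_contacts(structure, cutoff, 4)
        got = [(i, j) for i, j, _ in build_native_contacts(structure, cutoff, 4)]
        assert got == expected
        assert len(got) > 0

    def test_min_separation_excludes_near_pairs(self, hairpin):
        structure, _ = hairpin
        for i, j, _ in build_native_contacts(structure, 8.0, 4):
            assert j - i >= 4

    def test_empty_structure_rejected(self, hairpin):
        structure, _ = hairpin
        with pytest.raises(ValueError):
            build_native_contacts(structure.subset(
                np.zeros(structure.n_atoms, dtype=bool)), 4.5, 4)


class TestTopology:
    @pytest.mark.parametrize("n", [5, 12, 29])
    def test_bonded_term_counts(self, n):
        s = make_peptide(n)
        top = build_topology(s, GoParams(contact_cutoff=4.5))
        assert len(top.bonds) == n - 1
        assert len(top.angles) == n - 2
        assert len(top.dihedrals) == n - 3

    def test_native_conformation_has_zero_bonded_energy(self, hairpin):
        _, top = hairpin
        terms = potential_energy_terms(top, top.native_coord)
        assert terms["bond"] == pytest.approx(0.0, abs=1e-12)
        assert terms["angle"] == pytest.approx(0.0, abs=1e-12)
        assert terms["dihedral"] == pytest.approx(0.0, abs=1e-10)

    def test_chain_break_reported_with_position(self):
        s = make_peptide(10)
        keep = s.res_id != 5
        with pytest.raises(ValueError, match="chain breaks"):
            build_topology(s.subset(keep))

    def test_json_roundtrip_exact(self, hairpin, tmp_path):
        _, top = hairpin
        path = tmp_path / "topology.json"
        top.to_json(path)
        back = NativeTopology.from_json(path)
        np.testing.assert_array_equal(back.contacts, top.contacts)
        np.testing.assert_array_equal(back.contact_sigma, top.contact_sigma)
        np.testing.assert_array_equal(back.bond_r0, top.bond_r0)
        np.testing.assert_array_equal(back.native_coord, top.native_coord)
        assert back.params == top.params


class TestEnergy:
    def test_native_energy_is_minus_eps_times_contacts(self, hairpin, three_helix):
        for _, top in (hairpin, three_helix):
            e = potential_energy(top, top.native_coord)
            assert e == pytest.approx(-top.params.epsilon * top.n_contacts,
                                      abs=1e-9)

    def test_extended_conformation_limits(self, hairpin):
        _, top = hairpin
        n = top.n_beads
        ext = np.zeros((n, 3))
        ext[:, 2] = np.arange(n) * 50.0
        terms = potential_energy_terms(top, ext)
        assert abs(terms["contact"]) < 1e-9
        assert terms["bond"] >= 0.0

    def test_gradient_matches_finite_differences(self, hairpin):
        _, top = hairpin
        rng = np.random.default_rng(0)
        for _ in range(3):
            conf = top.native_coord + rng.normal(0, 0.3, (top.n_beads, 3))
            g = potential_gradient(top, conf)
            fd = np.zeros_like(g)
            h = 1e-6
            for i in range(top.n_beads):
                for d in range(3):
                    up, dn = conf.copy(), conf.copy()
                    up[i, d] += h
                    dn[i, d] -= h
                    fd[i, d] = (potential_energy(top, up)
                                - potential_energy(top, dn)) / (2 * h)
            assert np.abs(g - fd).max() / np.abs(fd).max() < 1e-4

    def test_energy_invariant_under_rigid_motion(self, hairpin):
        _, top = hairpin
        rng = np.random.default_rng(1)
        conf = top.native_coord + rng.normal(0, 0.2, (top.n_beads, 3))
        e0 = potential_energy(top, conf)
        theta = 1.1
        R = np.array([[np.cos(theta), -np.sin(theta), 0],
                      [np.sin(theta), np.cos(theta), 0], [0, 0, 1]])
        moved = conf @ R.T + np.array([7.0, -2.0, 3.0])
        assert potential_energy(top, moved) == pytest.approx(
            e0, rel=1e-9, abs=1e-9)

    def test_contact_term_bounded_below(self, hairpin):
        _, top = hairpin
        rng = np.random.default_rng(2)
        for _ in range(20):
            conf = top.native_coord + rng.normal(0, 0.5, (top.n_beads, 3))
            terms = potential_energy_terms(top, conf)
            assert terms["contact"] >= -top.params.epsilon * top.n_contacts - 1e-12

    def test_mismatched_dimensions_rejected(self, hairpin):
        _, top = hairpin
        with pytest.raises(ValueError):
            potential_energy(top, np.zeros((top.n_beads + 1, 3)))


class TestFractionNativeContacts:
    def test_native_is_one(self, hairpin):
        _, top = hairpin
        assert fraction_native_contacts(top, top.native_coord) == 1.0

    def test_collinear_stretched_is_zero(self, hairpin):
        _, top = hairpin
        n = top.n_beads
        conf = np.zeros((n, 3))
        conf[:, 2] = np.arange(n) * 50.0
        assert fraction_native_contacts(top, conf) == 0.0

    def test_half_formed_counts_half(self):
        # a constructed topology where exactly half the contact pairs sit
        # at sigma and the other half at 10x sigma
        nc = 4
        contacts = np.array([[4 * k, 4 * k + 4] for k in range(nc)])
        top2 = NativeTopology(
            n_beads=4 * nc + 5,
            bonds=np.stack([np.arange(4 * nc + 4), np.arange(1, 4 * nc + 5)], axis=1),
            bond_r0=np.full(4 * nc + 4, 3.8),
            angles=np.zeros((0, 3)), angle_theta0=np.zeros(0),
            dihedrals=np.zeros((0, 4)), dihedral_phi0=np.zeros(0),
            contacts=contacts, contact_sigma=np.full(nc, 5.0),
        )
        conf2 = np.zeros((top2.n_beads, 3))
        conf2[:, 2] = np.arange(top2.n_beads) * 3.8
        for k in range(nc):
            i, j = contacts[k]
            if k < nc // 2:
                conf2[j] = conf2[i] + [5.0, 0, 0]      # exactly at sigma
            else:
                conf2[j] = conf2[i] + [50.0, 0, 0]     # 10x sigma
        assert fraction_native_contacts(top2, conf2) == pytest.approx(0.5)

    def test_q_monotone_when_contact_stretched(self, hairpin):
        _, top = hairpin
        i, j = top.contacts[0]
        conf = top.native_coord.copy()
        q_prev = fraction_native_contacts(top, conf)
        direction = conf[j] - conf[i]
        direction /= np.linalg.norm(direction)
        for scale in [2.0, 5.0, 20.0]:
            stretched = conf.copy()
            stretched[j] = conf[i] + direction * scale * top.contact_sigma[0]
            q = fraction_native_contacts(top, stretched)
            assert q <= q_prev + 1e-12
            q_prev = q

    def test_zero_contacts_rejected(self):
        top = NativeTopology(
            n_beads=2, bonds=np.array([[0, 1]]), bond_r0=np.array([3.8]),
            angles=np.zeros((0, 3)), angle_theta0=np.zeros(0),
            dihedrals=np.zeros((0, 4)), dihedral_phi0=np.zeros(0),
            contacts=np.zeros((0, 2)), contact_sigma=np.zeros(0))
        with pytest.raises(ValueError):
            fraction_native_contacts(top, np.zeros((2, 3)))
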