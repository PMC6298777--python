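"""Generators: toy tunnels, toy domains, synthetic profiles and gels."""

import numpy as np
import pytest

from tunnelfold.go_model import fraction_native_contacts, potential_gradient
from tunnelfold.profile_analysis import (NoPeakError, aggregate_replicates,
                                         extract_features,
                                         f_fl_from_intensities)
from tunnelfold.synthetic_data import (
    SyntheticProfileSpec,
    ToyDomainSpec,
    ToyTunnelSpec,
    make_synthetic_gel,
    make_synthetic_profile,
    make_toy_domain,
    make_toy_tunnel,
    remove_tunnel_loop,
)
from tunnelfold.go_model import build_native_contacts


class TestToyTunnel:
    def test_cylinder_wall_beads_sit_at_given_radius(self):
        spec = ToyTunnelSpec(length=100.0,
                             radius_profile=((0.0, 12.0), (100.0, 12.0)),
                             constriction=None, obstruction_start=200.0)
        scaffold = make_toy_tunnel(spec, seed=0)
        wall = scaffold.beads.subset(scaffold.beads.chain_id == "WALL")
        r = np.linalg.norm(wall.coord[:, :2], axis=1)
        assert np.all(np.abs(r - 12.0) <= 0.5)

    def test_constriction_limits_free_radius(self):
        spec = ToyTunnelSpec()
        scaffold = make_toy_tunnel(spec, seed=0)
        cz, cr = spec.constriction
        # brute-force free-radius scan at the constriction position
        sel = np.abs(scaffold.beads.coord[:, 2] - cz) < 2.0
        r = np.linalg.norm(scaffold.beads.coord[sel, :2], axis=1)
        assert r.min() == pytest.approx(cr, abs=spec.wall_spacing / 2)

    def test_same_seed_identical(self):
        a = make_toy_tunnel(seed=3)
        b = make_toy_tunnel(seed=3)
        np.testing.assert_array_equal(a.beads.coord, b.beads.coord)
        assert list(a.beads.chain_id) == list(b.beads.chain_id)

    def test_loop_removal_is_chainwise_and_deterministic(self):
        scaffold = make_toy_tunnel(seed=0)
        for which, chain in (("mid", "MID"), ("exit", "EXIT")):
            reduced = remove_tunnel_loop(scaffold, which)
            n_loop = int((scaffold.beads.chain_id == chain).sum())
            assert n_loop > 0
            assert scaffold.beads.n_beads - reduced.beads.n_beads == n_loop
            assert chain not in set(reduced.beads.chain_id.tolist())

    def test_anchor_at_closed_end_with_clearance(self):
        scaffold = make_toy_tunnel(seed=0)
        d = np.linalg.norm(scaffold.beads.coord - scaffold.anchor, axis=1)
        assert d.min() > 4.4  # no overlap with the anchored chain bead


class TestToyDomain:
    @pytest.mark.parametrize("fold_class,n", [("hairpin", 12),
                                              ("hairpin", 16),
                                              ("three-helix", 28)])
    def test_native_is_exact_local_minimum(self, fold_class, n):
        _, top = make_toy_domain(ToyDomainSpec(fold_class, n), seed=0)
        g = potential_gradient(top, top.native_coord)
        assert np.abs(g).max() < 1e-6

    def test_native_q_is_one(self, hairpin):
        _, top = hairpin
        assert fraction_native_contacts(top, top.native_coord) == 1.0

    def test_hairpin_contact_count_near_enumerated_target(self):
        # enumerate the generated geometry independently, then require the
        # generator to reproduce that count as its target
        spec = ToyDomainSpec("hairpin", 16)
        structure, top = make_toy_domain(spec, seed=2)
        enumerated = len(build_native_contacts(
            structure, spec.effective_cutoff, spec.effective_min_separation))
        assert top.n_contacts == enumerated
        _, top2 = make_toy_domain(
            ToyDomainSpec("hairpin", 16, target_contacts=enumerated), seed=5)
        assert abs(top2.n_contacts - enumerated) <= 2

    def test_unreachable_contact_target_rejected(self):
        with pytest.raises(ValueError, match="target"):
            make_toy_domain(ToyDomainSpec("hairpin", 12, target_contacts=500),
                            seed=0)

    def test_two_seeds_distinct_coordinates_same_topology(self):
        _, t1 = make_toy_domain(ToyDomainSpec("hairpin", 12), seed=1)
        _, t2 = make_toy_domain(ToyDomainSpec("hairpin", 12), seed=2)
        assert not np.allclose(t1.native_coord, t2.native_coord)
        assert t1.n_contacts == t2.n_contacts
        np.testing.assert_array_equal(t1.contacts, t2.contacts)

    def test_too_small_domain_rejected(self):
        with pytest.raises(ValueError):
            ToyDomainSpec("hairpin", 4)


class TestSyntheticProfile:
    def test_noiseless_features_recovered_exactly(self):
        spec = SyntheticProfileSpec(onset=20, peak=25, end=30, sigma=0.0,
                                    n_replicates=1)
        (p,) = make_synthetic_profile(spec, seed=0)
        f = extract_features(p)
        assert (f.L_onset, f.L_max, f.L_end) == (20, 25, 30)

    @pytest.mark.parametrize("onset,peak,end", [(18, 22, 28), (21, 25, 27)])
    def test_noiseless_other_shapes(self, onset, peak, end):
        spec = SyntheticProfileSpec(onset=onset, peak=peak, end=end,
                                    sigma=0.0, n_replicates=1)
        (p,) = make_synthetic_profile(spec, seed=0)
        f = extract_features(p)
        assert (f.L_onset, f.L_max, f.L_end) == (onset, peak, end)

    def test_zero_amplitude_has_no_peak_downstream(self):
        spec = SyntheticProfileSpec(amplitude=0.0, sigma=0.0, n_replicates=1)
        (p,) = make_synthetic_profile(spec, seed=0)
        with pytest.raises(NoPeakError):
            extract_features(p)

    def test_replicates_independent_but_seeded(self):
        spec = SyntheticProfileSpec(sigma=0.05, n_replicates=3)
        a = make_synthetic_profile(spec, seed=7)
        b = make_synthetic_profile(spec, seed=7)
        for pa, pb in zip(a, b):
            np.testing.assert_array_equal(pa.f_fl, pb.f_fl)
        assert not np.allclose(a[0].f_fl, a[1].f_fl)

    def test_feature_validation(self):
        with pytest.raises(ValueError):
            SyntheticProfileSpec(onset=25, peak=25, end=30)


class TestSyntheticGel:
    def test_exact_intensities_at_zero_noise(self):
        spec = SyntheticProfileSpec(onset=20, peak=25, end=30, sigma=0.0,
                                    n_replicates=1)
        (p,) = make_synthetic_profile(spec, seed=0)
        lanes = make_synthetic_gel(p, total_intensity=1000.0)
        k = int(np.flatnonzero(p.L == 25)[0])
        assert lanes[k].I_FL == pytest.approx(p.f_fl[k] * 1000.0)
        assert lanes[k].I_A == pytest.approx((1 - p.f_fl[k]) * 1000.0)
        recovered = [f_fl_from_intensities(l) for l in lanes]
        np.testing.assert_allclose(recovered, p.f_fl, atol=1e-12)

    def test_quarter_split(self):
        from tunnelfold.profile_analysis import FflProfile

        p = FflProfile(np.array([20]), np.array([0.25]))
        (lane,) = make_synthetic_gel(p, total_intensity=1000.0)
        assert lane.I_FL == pytest.approx(250.0)
        assert lane.I_A == pytest.approx(750.0)

    def test_noisy_roundtrip_unbiased(self):
        from tunnelfold.profile_analysis import FflProfile

        truth = 0.4
        p = FflProfile(np.array([20]), np.array([truth]))
        recovered = []
        for seed in range(200):
            (lane,) = make_synthetic_gel(p, total_intensity=1000.0,
                                         sigma=0.03, seed=seed)
            recovered.append(f_fl_from_intensities(lane))
        recovered = np.array(recovered)
        se = recovered.std(ddof=1) / np.sqrt(len(recovered))
        assert abs(recovered.mean() - truth) < 2 * se + 1e-3

    def test_invalid_total_rejected(self):
        from tunnelfold.profile_analysis import FflProfile

        p = FflProfile(np.array([20]), np.array([0.5]))
        with pytest.raises(ValueError):
            make_synthetic_gel(p, total_intensity=0.0)
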