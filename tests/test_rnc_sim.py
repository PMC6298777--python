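"""Langevin integrator statistics, RNC assembly, force measurement."""

import numpy as np
import pytest
from scipy.integrate import quad

from tunnelfold.rnc_sim import (
    RNCConstruct,
    SimulationParams,
    TrajectorySummary,
    assemble_rnc,
    domain_system,
    measure_force_statistics,
    run_langevin,
    scan_linker_lengths,
    single_bead_system,
)
from tunnelfold.synthetic_data import make_toy_tunnel


def blocked_se(x, n_blocks=10):
    blocks = np.array_split(np.asarray(x), n_blocks)
    means = np.array([b.mean() for b in blocks])
    return means.std(ddof=1) / np.sqrt(n_blocks)


class TestIntegratorStatistics:
    def test_harmonic_well_equipartition(self):
        """Positional variance of a restrained bead matches kT/k within 5%."""
        k = 50.0
        params = SimulationParams(temperature=0.8, dt=0.005,
                                  production_steps=600_000,
                                  equilibration_steps=20_000, stride=20,
                                  seed=3)
        summary = run_langevin(single_bead_system(k_anchor=k), params,
                               k_anchor=k)
        var = summary.bead0_positions.var(axis=0).mean()  # average over x,y,z
        assert var == pytest.approx(params.temperature / k, rel=0.05)

    def test_free_diffusion_msd_slope(self):
        """Free-bead MSD grows as 2 D t per dimension with D = kT/gamma."""
        params = SimulationParams(temperature=1.0, friction=1.0, dt=0.005,
                                  production_steps=400_000,
                                  equilibration_steps=0, stride=10, seed=9)
        summary = run_langevin(single_bead_system(), params)
        pos = summary.bead0_positions
        dt_frame = summary.frame_dt
        lags = np.array([20, 40, 80, 160])
        msd = np.array([
            np.mean(np.sum((pos[lag:] - pos[:-lag]) ** 2, axis=1))
            for lag in lags])
        slope = np.polyfit(lags * dt_frame, msd, 1)[0] / 3.0  # per dimension
        D = params.temperature / params.friction
        assert slope == pytest.approx(2.0 * D, rel=0.10)

    def test_double_well_populations_match_boltzmann(self):
        """Two-state bead in an asymmetric double well: simulated K = Pf/Pu
        agrees with the quadrature partition-function ratio within 3 SE."""
        a, b, c, kxy = 0.15, 2.0, 0.2, 5.0
        T = 1.0
        params = SimulationParams(temperature=T, dt=0.005,
                                  production_steps=1_500_000,
                                  equilibration_steps=50_000, stride=50,
                                  seed=17)
        system = single_bead_system(double_well=(a, b, c, kxy))
        summary = run_langevin(system, params)
        V = lambda z: a * (z * z - b * b) ** 2 + c * z
        Zp, _ = quad(lambda z: np.exp(-V(z) / T), 0, 12)
        Zm, _ = quad(lambda z: np.exp(-V(z) / T), -12, 0)
        p_true = Zp / (Zp + Zm)
        folded = summary.q  # indicator z > 0 for contact-free systems
        se = blocked_se(folded)
        assert abs(folded.mean() - p_true) < 3 * se

    def test_fixed_seed_reproducible(self):
        params = SimulationParams(temperature=0.9, production_steps=20_000,
                                  equilibration_steps=1_000, stride=50, seed=5)
        s1 = run_langevin(single_bead_system(k_anchor=10.0), params,
                          k_anchor=10.0)
        s2 = run_langevin(single_bead_system(k_anchor=10.0), params,
                          k_anchor=10.0)
        np.testing.assert_array_equal(s1.bead0_positions, s2.bead0_positions)

    def test_blow_up_aborts_with_diagnostic(self, hairpin):
        _, top = hairpin
        params = SimulationParams(temperature=1.0, dt=0.5,  # absurd time step
                                  production_steps=10_000,
                                  equilibration_steps=0, stride=10, seed=1)
        with pytest.raises(RuntimeError, match="displacement"):
            run_langevin(domain_system(top, "native"), params)


class TestTwoStateDomain:
    def test_cold_domain_stays_folded(self, hairpin):
        _, top = hairpin
        params = SimulationParams(temperature=0.5, production_steps=150_000,
                                  equilibration_steps=10_000, stride=100,
                                  seed=2)
        summary = run_langevin(domain_system(top, "native"), params)
        assert summary.q.mean() > params.q_folded

    def test_hot_domain_unfolds(self, hairpin):
        _, top = hairpin
        params = SimulationParams(temperature=3.0, production_steps=150_000,
                                  equilibration_steps=10_000, stride=100,
                                  seed=2)
        summary = run_langevin(domain_system(top, "native"), params)
        assert summary.q.mean() < params.q_unfolded


class TestAssembly:
    def test_bead_count_and_anchor(self, three_helix):
        _, top = three_helix
        # a 28-residue domain with L = 17 gives a 45-bead chain
        tunnel = make_toy_tunnel(seed=0)
        params = SimulationParams()
        system = assemble_rnc(tunnel, RNCConstruct(top, 17), params, seed=0)
        assert system.n_beads == top.n_beads + 17
        np.testing.assert_allclose(system.positions[-1], tunnel.anchor,
                                   atol=1e-9)

    def test_initial_state_has_no_scaffold_overlap(self, hairpin):
        _, top = hairpin
        tunnel = make_toy_tunnel(seed=0)
        system = assemble_rnc(tunnel, RNCConstruct(top, 25),
                              SimulationParams(), seed=4)
        from scipy.spatial import cKDTree

        tree = cKDTree(system.scaffold_pos)
        d, j = tree.query(system.positions, k=1)
        min_allowed = system.radii + system.scaffold_rad[j]
        assert np.all(d > min_allowed - 1e-9)

    def test_same_seed_bitwise_identical(self, hairpin):
        _, top = hairpin
        tunnel = make_toy_tunnel(seed=0)
        a = assemble_rnc(tunnel, RNCConstruct(top, 20), SimulationParams(), seed=8)
        b = assemble_rnc(tunnel, RNCConstruct(top, 20), SimulationParams(), seed=8)
        np.testing.assert_array_equal(a.positions, b.positions)

    def test_arrest_peptide_minimum_length(self, hairpin):
        _, top = hairpin
        with pytest.raises(ValueError, match="arrest"):
            RNCConstruct(top, 10)

    def test_overlong_chain_rejected(self, hairpin):
        _, top = hairpin
        tunnel = make_toy_tunnel(seed=0)
        with pytest.raises(ValueError, match="threadable"):
            assemble_rnc(tunnel, RNCConstruct(top, 120), SimulationParams(),
                         seed=0)


class TestForceStatistics:
    def _summary(self, q, ext, L=20):
        q = np.asarray(q, dtype=float)
        ext = np.asarray(ext, dtype=float)
        return TrajectorySummary(q=q, tether_extension=ext,
                                 bead0_positions=np.zeros((len(q), 3)),
                                 final_positions=np.zeros((1, 3)),
                                 frame_dt=1.0, L=L)

    def test_all_frames_folded(self):
        params = SimulationParams(epsilon_kcal_per_mol=1.0)
        stats = measure_force_statistics(
            self._summary([0.9] * 10, [0.1] * 10), params)
        assert stats.Pf == 1.0 and stats.Pu == 0.0
        assert stats.n_folded == 10

    def test_hookes_law_exact(self):
        """A tether held at constant elongation d reports F = k d."""
        d = 0.25
        params = SimulationParams(k_tether=100.0, epsilon_kcal_per_mol=1.0)
        stats = measure_force_statistics(
            self._summary([0.9] * 5, [d] * 5), params)
        from tunnelfold.constants import KCAL_PER_MOL_PER_ANGSTROM_IN_PN

        assert stats.Ff == pytest.approx(
            100.0 * d * KCAL_PER_MOL_PER_ANGSTROM_IN_PN)

    def test_intermediate_frames_discarded_and_tracked(self):
        params = SimulationParams()
        stats = measure_force_statistics(
            self._summary([0.9, 0.5, 0.1, 0.5], [0.1] * 4), params)
        assert stats.p_intermediate == pytest.approx(0.5)
        assert stats.Pu == pytest.approx(0.5) and stats.Pf == pytest.approx(0.5)

    def test_no_classified_frames_is_an_error(self):
        params = SimulationParams()
        with pytest.raises(ValueError, match="classified"):
            measure_force_statistics(self._summary([0.5] * 4, [0.0] * 4), params)


class TestScan:
    def test_duplicate_l_values_identical(self, hairpin):
        _, top = hairpin
        tunnel = make_toy_tunnel(seed=0)
        params = SimulationParams(temperature=0.85, dt=0.01,
                                  production_steps=30_000,
                                  equilibration_steps=5_000, stride=100,
                                  seed=21)
        stats = scan_linker_lengths(tunnel, top, [19, 19], params)
        assert stats[0].Pf == stats[1].Pf
        assert stats[0].Fu == stats[1].Fu

    def test_empty_l_list_rejected(self, hairpin):
        _, top = hairpin
        with pytest.raises(ValueError):
            scan_linker_lengths(make_toy_tunnel(seed=0), top, [],
                                SimulationParams())
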