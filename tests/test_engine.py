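"""Metropolis sampling, GCMC acceptance machinery, schedule plumbing."""

import math

import numpy as np
import pytest

from cf1water.analysis import block_stats
from cf1water.engine import (
    GCMCParameters,
    MCState,
    ParticleConfiguration,
    b_parameter,
    displacement_step,
    factorial_ratio,
    run_cmc,
    run_gcmc,
)
from cf1water.testkit import ideal_gas_gcmc_reference


class TestFactorialRatio:
    def test_empty_system(self):
        assert factorial_ratio(0, 0) == 0.5

    def test_small_counts_match_direct_factorials(self):
        # 2! 4! / (3! 6!) = 48/4320 = 1/90
        assert factorial_ratio(2, 4) == pytest.approx(
            math.factorial(2) * math.factorial(4)
            / (math.factorial(3) * math.factorial(6)), rel=1e-14)
        assert factorial_ratio(2, 4) == pytest.approx(1 / 90)

    def test_large_counts_closed_form(self):
        assert factorial_ratio(200, 400) == pytest.approx(
            1.0 / (201 * 401 * 402), rel=1e-14)

    def test_validation(self):
        with pytest.raises(ValueError):
            factorial_ratio(-1, -2)
        with pytest.raises(ValueError):
            factorial_ratio(3, 5)


class TestBParameter:
    def test_zero_when_volume_equals_wavelength_product(self):
        # choose L so that L^3 = Lambda_H^2 Lambda_O at mu = 0
        from cf1water.model import thermal_wavelength

        T = 300.0
        lam = thermal_wavelength(1.008, T) ** 2 * thermal_wavelength(15.999, T)
        L = lam ** (1.0 / 3.0)
        assert b_parameter(0.0, T, L) == pytest.approx(0.0, abs=1e-12)

    def test_against_independent_constants_evaluation(self):
        # CODATA h, k_B; m_H = 1.008 u, m_O = 15.999 u; L for 200 waters
        # at 1 g/mL; mu from the linear mu(T) model at 300 K.
        # Independent evaluation gives B = -215.555098.
        mu = -589.0 - 0.08 * 300.0
        L = 18.15394
        assert b_parameter(mu, 300.0, L) == pytest.approx(-215.5551, abs=2e-3)

    def test_strictly_increasing_in_mu(self):
        Bs = [b_parameter(mu, 300.0, 12.0) for mu in (-650, -600, -550, -500)]
        assert all(b < a for b, a in zip(Bs, Bs[1:]))

    def test_validation(self):
        with pytest.raises(ValueError):
            b_parameter(0.0, -1.0, 10.0)


class TestParticleConfiguration:
    def test_stoichiometry_enforced(self):
        with pytest.raises(ValueError):
            ParticleConfiguration(10.0, np.zeros((4, 3)),
                                  np.array([0, 0, 1, 1], dtype=np.int8))

    def test_random_molecular_is_wrapped_and_neutral(self):
        rng = np.random.default_rng(0)
        c = ParticleConfiguration.random_molecular(20, 11.0, rng)
        assert c.n_O == 20 and c.n_H == 40
        assert np.all(c.positions >= 0) and np.all(c.positions < 11.0)
        assert abs(c.charges.sum()) < 1e-12

    def test_density_roundtrip(self):
        from cf1water.experiments import box_length_from_density

        L = box_length_from_density(1.0, 64)
        rng = np.random.default_rng(1)
        c = ParticleConfiguration.random_molecular(64, L, rng)
        assert c.density == pytest.approx(1.0, rel=1e-12)


class _HarmonicEnergy:
    """Independent external potential: U = k/2 |r - center|^2 per site."""

    def __init__(self, k, center):
        self.k = k
        self.center = np.asarray(center, dtype=float)

    def total_energy(self, state):
        d = state.positions[: state.n_sites] - self.center
        return 0.5 * self.k * float((d**2).sum())

    def delta_displacement(self, state, i, new):
        d_old = state.positions[i] - self.center
        d_new = new - self.center
        return 0.5 * self.k * float(d_new @ d_new - d_old @ d_old)


class TestDisplacementStep:
    def test_zero_energy_change_always_accepted(self):
        cfg = ParticleConfiguration(20.0, np.full((3, 3), 10.0),
                                    np.array([0, 1, 1], dtype=np.int8))
        state = MCState.create(cfg, 300.0, 0, energy="ideal")
        for _ in range(50):
            assert displacement_step(state, max_disp=0.3)

    def test_infinite_temperature_accepts_everything(self):
        rng = np.random.default_rng(2)
        cfg = ParticleConfiguration.random_molecular(8, 10.0, rng)
        state = MCState.create(cfg, 300.0, 3, beta_override=0.0)
        n = 10_000
        for _ in range(n):
            displacement_step(state, max_disp=0.5)
        assert state.counters["disp_accepted"] == n

    def test_harmonic_toy_samples_boltzmann_gaussian(self):
        from scipy import stats

        from cf1water.model import R_GAS_KJ

        T = 300.0
        k = 30.0  # kJ/mol/A^2 -> sigma = sqrt(RT/k) ~ 0.288 A
        L = 20.0
        center = np.full(3, 10.0)
        cfg = ParticleConfiguration(L, np.tile(center, (3, 1)),
                                    np.array([0, 1, 1], dtype=np.int8))
        state = MCState.create(cfg, T, 11, energy=_HarmonicEnergy(k, center))
        samples = []
        for step in range(100_000):
            displacement_step(state, max_disp=0.5)
            if step % 10 == 9:
                samples.append(state.positions[0, 0])
        sigma = math.sqrt(R_GAS_KJ * T / k)
        ks = stats.kstest(np.array(samples), "norm",
                          args=(center[0], sigma))
        assert ks.statistic < 0.02, ks


class TestRunCmc:
    def test_fixed_seed_reproduces_trajectory(self):
        def one():
            rng = np.random.default_rng(5)
            cfg = ParticleConfiguration.random_molecular(8, 10.0, rng)
            state = MCState.create(cfg, 500.0, 123)
            stream = run_cmc(state, 2000, 8000, sample_interval=1000)
            return stream

        s1, s2 = one(), one()
        assert s1.series.equals(s2.series)
        np.testing.assert_array_equal(np.asarray(s1.frames),
                                      np.asarray(s2.frames))

    def test_energy_series_is_stationary_after_equilibration(self):
        from scipy import stats

        rng = np.random.default_rng(6)
        cfg = ParticleConfiguration.random_molecular(16, 10.0, rng)
        state = MCState.create(cfg, 1000.0, 7)
        stream = run_cmc(state, 400_000, 600_000, sample_interval=5_000)
        e = stream.series["energy"].to_numpy()
        blocks = e[: (len(e) // 12) * 12].reshape(12, -1).mean(axis=1)
        res = stats.linregress(np.arange(len(blocks)), blocks)
        assert res.pvalue > 0.05  # no trend at 95% confidence


class TestGCMC:
    def test_insertion_geometry_always_inside_printed_windows(self,
                                                              kernels_warm):
        xs = np.empty(3)
        ys = np.empty(3)
        zs = np.empty(3)
        kernels_warm.seed_rng(99)
        L = 12.0
        for _ in range(20_000):
            ok = kernels_warm.sample_insertion_triplet(
                L, 0.875, 1.075, 1.3, 1.7, 100, xs, ys, zs)
            assert ok
            def mi(a, b):
                d = a - b
                d -= L * np.round(d / L)
                return math.sqrt(float(d @ d))
            o = np.array([xs[0], ys[0], zs[0]])
            h1 = np.array([xs[1], ys[1], zs[1]])
            h2 = np.array([xs[2], ys[2], zs[2]])
            assert 0.875 <= mi(o, h1) <= 1.075
            assert 0.875 <= mi(o, h2) <= 1.075
            assert 1.3 <= mi(h1, h2) <= 1.7

    def test_stoichiometry_preserved_through_gcmc(self):
        rng = np.random.default_rng(8)
        cfg = ParticleConfiguration.random_molecular(6, 10.0, rng)
        state = MCState.create(cfg, 800.0, 31)
        params = GCMCParameters(mu=-620.0, T=800.0, L=10.0)
        for _ in range(60):
            run_gcmc(state, params, 0, 200, sample_interval=200)
            assert state.n_H == 2 * state.n_O
            assert state.n_sites == 3 * state.n_O

    def test_nearest_hydrogens_selected_for_deletion(self, kernels_warm):
        # 2-molecule fixture with hand-placed coordinates: the two H
        # nearest to each O are its own, across the periodic boundary too.
        L = 10.0
        pos = np.array([
            [0.5, 5.0, 5.0],   # O1 near the boundary
            [9.7, 5.0, 5.0],   # its H across the wrap (min image 0.8)
            [1.45, 5.0, 5.0],  # its second H
            [5.0, 1.0, 1.0],   # O2
            [5.95, 1.0, 1.0],
            [5.0, 1.97, 1.0],
        ])
        sp = np.array([0, 1, 1, 0, 1, 1], dtype=np.int8)
        i1, i2 = kernels_warm._nearest_two_h(pos, sp, 6, L, 0)
        assert {i1, i2} == {1, 2}
        i1, i2 = kernels_warm._nearest_two_h(pos, sp, 6, L, 3)
        assert {i1, i2} == {4, 5}

    def test_ideal_gas_matches_analytic_distribution(self):
        B = 12.0
        mean_ref, var_ref, _ = ideal_gas_gcmc_reference(B)
        cfg = ParticleConfiguration(10.0, np.zeros((0, 3)),
                                    np.zeros(0, dtype=np.int8))
        state = MCState.create(cfg, 300.0, 42, energy="ideal")
        params = GCMCParameters(mu=0.0, T=300.0, L=10.0, B_override=B)
        stream = run_gcmc(state, params, 100_000, 1_200_000,
                          sample_interval=200)
        Ns = stream.series["n_molecules"].to_numpy()
        mean, err = block_stats(Ns, 20)
        assert mean == pytest.approx(mean_ref, abs=3 * max(err, 1e-3))
        assert np.var(Ns) == pytest.approx(var_ref, rel=0.2)

    def test_gcmc_density_increases_with_mu_in_gas_phase(self):
        # dilute-vapour branch at high T: three well-separated mu values
        T, L = 800.0, 12.417
        rhos = []
        for i, mu in enumerate((-680.0, -640.0, -600.0)):
            cfg = ParticleConfiguration(L, np.zeros((0, 3)),
                                        np.zeros(0, dtype=np.int8))
            state = MCState.create(cfg, T, 100 + i)
            params = GCMCParameters(mu=mu, T=T, L=L)
            stream = run_gcmc(state, params, 100_000, 400_000,
                              sample_interval=1000)
            rhos.append(stream.series["density"].mean())
        assert rhos[0] < rhos[1] < rhos[2]


class TestDetailedBalance:
    def test_two_state_toy_reaches_analytic_stationary_distribution(self):
        # same acceptance rule, discretized: states {0,1} with E1-E0 = eps
        rng = np.random.default_rng(17)
        beta_eps = 1.3
        state = 0
        visits = np.zeros(2)
        n = 200_000
        for _ in range(n):
            if state == 0:
                state = 1 if rng.random() < math.exp(-beta_eps) else 0
            else:
                state = 0
            visits[state] += 1
        p1 = visits[1] / n
        p1_ref = math.exp(-beta_eps) / (1 + math.exp(-beta_eps))
        se = math.sqrt(p1_ref * (1 - p1_ref) / n) * 3
        # correlated samples: allow a few times the iid standard error
        assert p1 == pytest.approx(p1_ref, abs=10 * se)
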