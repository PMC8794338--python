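"""Molecule assignment, RDFs, geometry, H-bond counts, order parameters."""

import itertools
import math

import numpy as np
import pytest

from cf1water.analysis import (
    Histogram1D,
    assign_molecules,
    block_stats,
    compute_rdf,
    geometry_stats,
    hbond_count_distance,
    hbond_count_energy,
    pair_energy_distribution,
    running_coordination,
    second_minimum,
    structure_summary,
    tetrahedral_q,
    translational_tau,
)
from cf1water.testkit import perfect_tetrahedron
from tests.conftest import make_molecule, oracle_pair_kj


class TestHistogram1D:
    def test_density_normalization_integrates_to_one(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 100, size=50).astype(float)
        h = Histogram1D(np.linspace(0, 5, 51), counts).density()
        assert h.values.sum() * h.bin_width == pytest.approx(1.0, abs=1e-12)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            Histogram1D(np.linspace(0, 1, 3), np.array([1.0, -1.0]))


class TestAssignment:
    def test_well_separated_molecules_get_their_own_hydrogens(self):
        L = 20.0
        a = make_molecule([2, 2, 2], [1, 0, 0], [0, 1, 0])
        b = make_molecule([12, 12, 12], [0, 0, 1], [0, 1, 0])
        pos = np.vstack([a, b])
        sp = np.array([0, 1, 1, 0, 1, 1], dtype=np.int8)
        asg = assign_molecules(pos, sp, L)
        got = {int(o): set(map(int, h)) for o, h in zip(asg.o_sites, asg.h_sites)}
        assert got == {0: {1, 2}, 3: {4, 5}}

    def test_conflict_fixture_matches_exhaustive_minimum(self):
        # one H nearly equidistant to both oxygens
        L = 30.0
        pos = np.array([
            [5.0, 5.0, 5.0],    # O1
            [8.0, 5.0, 5.0],    # O2
            [5.9, 5.0, 5.0],    # H near O1
            [6.55, 5.0, 5.0],   # H between (slightly closer to O2)
            [8.9, 5.0, 5.0],    # H near O2
            [5.0, 5.9, 5.0],    # H near O1
        ])
        sp = np.array([0, 0, 1, 1, 1, 1], dtype=np.int8)
        asg = assign_molecules(pos, sp, L)

        def total(pairing):
            return sum(np.linalg.norm(pos[o] - pos[h])
                       for o, hs in pairing.items() for h in hs)

        best, best_val = None, np.inf
        for hs1 in itertools.combinations([2, 3, 4, 5], 2):
            hs2 = tuple(sorted(set([2, 3, 4, 5]) - set(hs1)))
            val = total({0: hs1, 1: hs2})
            if val < best_val:
                best, best_val = {0: set(hs1), 1: set(hs2)}, val
        got = {int(o): set(map(int, h)) for o, h in zip(asg.o_sites, asg.h_sites)}
        assert got == best

    def test_invariant_to_site_ordering(self):
        rng = np.random.default_rng(1)
        from cf1water.engine import ParticleConfiguration

        c = ParticleConfiguration.random_molecular(10, 10.0, rng)
        asg = assign_molecules(c.positions, c.species, 10.0)
        ref = {tuple(sorted([int(o), *map(int, h)]))
               for o, h in zip(asg.o_sites, asg.h_sites)}
        perm = rng.permutation(c.n_sites)
        asg2 = assign_molecules(c.positions[perm], c.species[perm], 10.0)
        inv = np.argsort(perm)  # map permuted index -> original
        got = {tuple(sorted([int(perm[o]), *(int(perm[h]) for h in hs)]))
               for o, hs in zip(asg2.o_sites, asg2.h_sites)}
        assert got == ref

    def test_count_mismatch_rejected(self):
        with pytest.raises(ValueError):
            assign_molecules(np.zeros((3, 3)),
                             np.array([0, 1, 0], dtype=np.int8), 10.0)


class TestRDF:
    def test_ideal_gas_rdf_is_unity(self):
        rng = np.random.default_rng(2)
        L, n, nf = 10.0, 60, 60
        frames = rng.random((nf, n, 3)) * L
        sp = np.zeros(n, dtype=np.int8)
        g = compute_rdf((frames, sp, L), "OO", bin_width=0.25)
        # chi^2 over bins with decent expected counts
        from scipy.stats import chi2

        shell = 4 / 3 * math.pi * (g.edges[1:] ** 3 - g.edges[:-1] ** 3)
        expected = nf * (n * (n - 1) / 2) * shell / L**3
        sel = expected > 20
        stat = float(np.sum((g.counts[sel] - expected[sel]) ** 2
                            / expected[sel]))
        dof = int(sel.sum())
        assert chi2.ppf(0.001, dof) < stat < chi2.ppf(0.999, dof)

    def test_simple_cubic_lattice_peaks_match_direct_counting(self):
        a, m = 3.0, 3
        L = a * m
        grid = np.array([[i, j, k] for i in range(m) for j in range(m)
                         for k in range(m)], dtype=float) * a
        sp = np.zeros(len(grid), dtype=np.int8)
        g = compute_rdf((grid[None], sp, L), "OO", bin_width=0.05)
        # direct pair counting oracle under minimum image
        dists = []
        for i in range(len(grid)):
            for j in range(i + 1, len(grid)):
                d = grid[i] - grid[j]
                d -= L * np.round(d / L)
                dists.append(np.linalg.norm(d))
        dists = np.asarray(dists)
        for r_shell in (a, a * math.sqrt(2)):
            b = int(r_shell / 0.05)
            n_oracle = np.sum((dists >= g.edges[b]) & (dists < g.edges[b + 1]))
            assert g.counts[b] == n_oracle and n_oracle > 0
        # no pairs off the lattice shells
        assert g.counts[int(0.5 * a / 0.05)] == 0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            compute_rdf((np.zeros((0, 4, 3)), np.zeros(4, dtype=np.int8), 5.0))


class TestRunningCoordination:
    def test_uniform_gas_gives_ideal_volume_law(self):
        edges = np.arange(0, 5.0 + 0.05, 0.05)
        g = Histogram1D(edges, np.zeros(len(edges) - 1),
                        np.ones(len(edges) - 1), "rdf")
        rho = 0.03
        r, n = running_coordination(g, rho)
        ref = 4 / 3 * math.pi * rho * r**3
        # trapezoid on bin centers: small offset at the origin only
        np.testing.assert_allclose(n[5:], ref[5:] - ref[5] + n[5], rtol=5e-3)

    def test_non_decreasing(self):
        rng = np.random.default_rng(3)
        edges = np.arange(0, 3.0, 0.05)
        vals = rng.random(len(edges) - 1)
        g = Histogram1D(edges, np.zeros(len(edges) - 1), vals, "rdf")
        _, n = running_coordination(g, 0.1)
        assert np.all(np.diff(n) >= -1e-12)


class TestGeometry:
    def test_right_angle_fixture(self):
        L = 20.0
        mol = make_molecule([5, 5, 5], [1, 0, 0], [0, 1, 0], 1.0, 1.0)
        sp = np.array([0, 1, 1], dtype=np.int8)
        geo = geometry_stats((mol[None], sp, L))
        assert geo.l_OH == pytest.approx(1.0, abs=1e-12)
        assert geo.l_HH == pytest.approx(math.sqrt(2.0), abs=1e-12)
        assert geo.theta == pytest.approx(90.0, abs=1e-9)

    def test_tetrahedral_angle_reconstruction(self):
        L = 20.0
        th = math.radians(109.47)
        mol = make_molecule([5, 5, 5], [1, 0, 0],
                            [math.cos(th), math.sin(th), 0], 1.0, 1.0)
        sp = np.array([0, 1, 1], dtype=np.int8)
        geo = geometry_stats((mol[None], sp, L))
        assert geo.theta == pytest.approx(109.47, abs=0.01)


class TestHbondCounts:
    def test_distant_molecules_have_no_bonds(self):
        L = 30.0
        a = make_molecule([3, 3, 3], [1, 0, 0], [0, 1, 0])
        b = make_molecule([18, 18, 18], [1, 0, 0], [0, 1, 0])
        frames = np.vstack([a, b])[None]
        sp = np.array([0, 1, 1, 0, 1, 1], dtype=np.int8)
        assert hbond_count_distance((frames, sp, L)) == 0.0
        assert hbond_count_energy((frames, sp, L)) == 0.0

    def test_dimer_with_single_contact_counts_one_bond_each(self, hbond_dimer):
        pos, sp = hbond_dimer
        frames = (pos + 10.0)[None]  # shift into a 30 Å box
        assert hbond_count_distance((frames, sp, 30.0), r_cut=2.5) == 1.0

    def test_pair_energy_matches_independent_nine_term_sum(self, hbond_dimer):
        pos, sp = hbond_dimer
        L = 30.0
        frames = (pos + 10.0)[None]
        from cf1water import _kernels

        o_idx, h_idx = _kernels.greedy_assignment(frames[0], sp, 6, L)
        en = _kernels.molecule_pair_energies(frames[0], L, o_idx, h_idx)
        ref = 0.0
        for i in range(3):
            for j in range(3, 6):
                r = np.linalg.norm(pos[i] - pos[j])
                ref += oracle_pair_kj(int(sp[i]), int(sp[j]), r)
        assert en[0] == pytest.approx(ref, rel=1e-12)
        assert ref == pytest.approx(-23.9165, abs=1e-3)  # frozen oracle value

    def test_three_molecule_fixture_energy_criterion(self, hbond_dimer):
        # one bonded pair among three molecules -> 2/3 bonds per molecule
        pos, sp = hbond_dimer
        far = make_molecule([20, 20, 20], [1, 0, 0], [0, 1, 0])
        frames = np.vstack([pos + 5.0, far])[None]
        sp3 = np.concatenate([sp, [0, 1, 1]]).astype(np.int8)
        assert hbond_count_energy((frames, sp3, 40.0), e_cut=-9.0) == \
            pytest.approx(2.0 / 3.0)

    def test_distance_count_equals_twice_intermolecular_coordination(self):
        # cross-module consistency on a simulated liquid-like configuration
        rng = np.random.default_rng(4)
        from cf1water.engine import MCState, ParticleConfiguration, run_cmc

        c = ParticleConfiguration.random_molecular(24, 9.0, rng)
        st = MCState.create(c, 500.0, 55)
        stream = run_cmc(st, 150_000, 150_000, sample_interval=3_000)
        frames = np.asarray(stream.frames)
        sp = stream.species
        hb = hbond_count_distance((frames, sp, 9.0), r_cut=2.5)
        g_oh = compute_rdf((frames, sp, 9.0), "OH", 0.05)
        rho_h = (2 * 24) / 9.0**3
        r, n_oh = running_coordination(g_oh, rho_h)
        n_inter = float(np.interp(2.5, r, n_oh)) - 2.0
        assert hb == pytest.approx(2.0 * n_inter, rel=0.02)


class TestPairEnergyDistribution:
    def test_far_apart_pair_has_negligible_energy(self):
        # near half-box separation (all 9 site pairs inside one image)
        L = 18.0
        a = make_molecule([2, 2, 2], [1, 0, 0], [0, 1, 0])
        b = make_molecule([10.5, 2, 2], [-1, 0, 0], [0, -1, 0])
        frames = np.vstack([a, b])[None]
        sp = np.array([0, 1, 1, 0, 1, 1], dtype=np.int8)
        from cf1water import _kernels

        o_idx, h_idx = _kernels.greedy_assignment(frames[0], sp, 6, L)
        en = _kernels.molecule_pair_energies(frames[0], L, o_idx, h_idx)
        assert abs(en[0]) < 1.0

    def test_minimum_located_on_synthetic_bimodal_histogram(self):
        edges = np.arange(-40.0, 20.2, 0.2)
        c = 0.5 * (edges[:-1] + edges[1:])
        vals = (np.exp(-0.5 * ((c + 15) / 3) ** 2)
                + 8 * np.exp(-0.5 * (c / 2.5) ** 2))
        hist = Histogram1D(edges, vals * 100).density()
        from cf1water.analysis import _locate_pair_energy_minimum

        e_min = _locate_pair_energy_minimum(hist)
        # analytic minimum of the two-Gaussian mixture, found by fine scan
        xs = np.linspace(-20, -3, 20000)
        f = (np.exp(-0.5 * ((xs + 15) / 3) ** 2)
             + 8 * np.exp(-0.5 * (xs / 2.5) ** 2))
        assert e_min == pytest.approx(xs[np.argmin(f)], abs=0.4)


class TestTetrahedralOrder:
    def test_perfect_tetrahedron_scores_one(self):
        pos = perfect_tetrahedron([10, 10, 10], 2.8)
        qres = tetrahedral_q((pos[None], np.zeros(5, dtype=np.int8), 40.0))
        assert qres.q_values[0] == pytest.approx(1.0, abs=1e-12)

    def test_rotation_invariance(self):
        from scipy.spatial.transform import Rotation

        rot = Rotation.from_rotvec([0.3, -1.1, 0.7]).as_matrix()
        pos = perfect_tetrahedron([0, 0, 0], 2.8) @ rot.T + 15.0
        qres = tetrahedral_q((pos[None], np.zeros(5, dtype=np.int8), 40.0))
        assert qres.q_values[0] == pytest.approx(1.0, abs=1e-10)

    def test_collinear_neighbours_score_minus_three(self):
        # 4 neighbours in the same direction: all cos psi = 1
        center = np.array([10.0, 10.0, 10.0])
        pos = np.vstack([center] + [center + [d, 0, 0]
                                    for d in (1.0, 1.1, 1.2, 1.3)])
        qres = tetrahedral_q((pos[None], np.zeros(5, dtype=np.int8), 40.0))
        assert qres.q_values[0] == pytest.approx(
            1.0 - 0.375 * 6 * (4.0 / 3.0) ** 2, abs=1e-12)  # = -3

    def test_ideal_gas_mean_q_is_zero(self):
        rng = np.random.default_rng(5)
        frames = rng.random((40, 64, 3)) * 10.0
        qres = tetrahedral_q((frames, np.zeros(64, dtype=np.int8), 10.0))
        se = qres.q_values.std() / math.sqrt(len(qres.q_values) / 10)
        assert abs(qres.mean_q) < 3 * se

    def test_too_few_oxygens_rejected(self):
        with pytest.raises(ValueError):
            tetrahedral_q((np.zeros((1, 4, 3)), np.zeros(4, dtype=np.int8),
                           10.0))

    def test_q_never_exceeds_one_on_random_configs(self):
        rng = np.random.default_rng(6)
        frames = rng.random((20, 32, 3)) * 8.0
        qres = tetrahedral_q((frames, np.zeros(32, dtype=np.int8), 8.0))
        assert qres.q_values.max() <= 1.0 + 1e-12
        assert qres.q_values.min() >= -3.0 - 1e-12


class TestTranslationalTau:
    @staticmethod
    def _hist(values, r_max=5.0, dr=0.05):
        edges = np.arange(0, r_max + dr, dr)
        return Histogram1D(edges, np.zeros(len(edges) - 1),
                           np.full(len(edges) - 1, values)
                           if np.isscalar(values) else values, "rdf")

    def test_uniform_gas_gives_zero(self):
        assert translational_tau(self._hist(1.0), 5.0) == 0.0

    def test_empty_correlation_gives_one(self):
        g = self._hist(0.0)
        assert translational_tau(g, 5.0) == pytest.approx(1.0, rel=2e-2)

    def test_square_wave_by_hand_integration(self):
        # g = 2 on [0, rc/2], 0 on (rc/2, rc] -> integral |g-1| = rc -> tau = 1
        r_c = 5.0
        edges = np.arange(0, r_c + 0.05, 0.05)
        c = 0.5 * (edges[:-1] + edges[1:])
        vals = np.where(c <= r_c / 2, 2.0, 0.0)
        g = Histogram1D(edges, np.zeros(len(c)), vals, "rdf")
        assert translational_tau(g, r_c) == pytest.approx(1.0, rel=2e-2)

    def test_out_of_range_cutoff_rejected(self):
        with pytest.raises(ValueError):
            translational_tau(self._hist(1.0, r_max=3.0), 10.0)


def test_block_stats_matches_direct_blocking():
    rng = np.random.default_rng(7)
    x = rng.normal(size=1000)
    mean, err = block_stats(x, 10)
    blocks = x.reshape(10, 100).mean(axis=1)
    assert mean == pytest.approx(blocks.mean())
    assert err == pytest.approx(blocks.std(ddof=1) / math.sqrt(10))
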