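import numpy as np
import pytest
from scipy import special, stats

from synfrap.engine import (BOUND_UNBLEACHED, FREE_BLEACHED, FREE_UNBLEACHED,
                            EquilibrationPolicy, KineticParams, LatticeIndex,
                            QuiescentState, Simulation, equilibrate,
                            voxel_propensities)
from synfrap.geometry import CYTOSOL

from conftest import make_box_grid


class TestPropensities:
    def test_hop_rate_is_six_d_over_a_squared(self):
        """One free protein, all six faces open: total hop 6D/a^2 = 960/s
        for D = 0.1 um^2/s on the 25-nm lattice."""
        g = make_box_grid(5, 5, 5)
        sim = Simulation(g, KineticParams(D=0.1), n_proteins=0, seed=0)
        center = (3, 2, 2)  # +1 x-offset for the sealed padding
        v = int(sim.lattice.index_map[center])
        sim.counts[v, FREE_UNBLEACHED] = 1
        p = voxel_propensities(sim, center)
        assert p["hop_free_unbleached"] == pytest.approx(6 * 0.1e6 / 25 ** 2)
        assert p["hop_free_unbleached"] == pytest.approx(960.0)

    def test_blocked_faces_reduce_hops_proportionally(self):
        g = make_box_grid(3, 3, 3)
        sim = Simulation(g, KineticParams(D=0.1), n_proteins=0, seed=0)
        corner = (1, 0, 0)  # 3 faces open
        v = int(sim.lattice.index_map[corner])
        sim.counts[v, FREE_UNBLEACHED] = 1
        p = voxel_propensities(sim, corner)
        assert p["hop_free_unbleached"] == pytest.approx(480.0)

    def test_bound_protein_only_unbinds(self):
        g = make_box_grid(1, 1, 1, vesicles=[(0, 0, 0)])
        sim = Simulation(g, KineticParams(D=0.1, k_b=10, T=0.1),
                         n_proteins=0, seed=0)
        v = int(sim.lattice.index_map[1, 0, 0])
        sim.counts[v, BOUND_UNBLEACHED] = 1
        p = voxel_propensities(sim, (1, 0, 0))
        assert p["unbind_unbleached"] == pytest.approx(10.0)
        assert p["bind_unbleached"] == 0.0
        assert p["hop_free_unbleached"] == 0.0

    def test_empty_voxel_zero_propensity(self):
        g = make_box_grid(3, 3, 3)
        sim = Simulation(g, KineticParams(D=1.0), n_proteins=0, seed=0)
        assert voxel_propensities(sim, (1, 1, 1))["total"] == 0.0


class TestStep:
    def test_conservation_and_determinism(self, small_bouton):
        kp = KineticParams(D=0.3, k_b=10.0, T=0.1)
        sim1 = Simulation(small_bouton, kp, n_proteins=500, seed=11)
        sim1.advance(1.0)
        assert sim1.total_count() == 500
        assert (sim1.counts >= 0).all()
        sim2 = Simulation(small_bouton, kp, n_proteins=500, seed=11)
        sim2.advance(1.0)
        assert np.array_equal(sim1.counts, sim2.counts)
        sim3 = Simulation(small_bouton, kp, n_proteins=500, seed=12)
        sim3.advance(1.0)
        assert not np.array_equal(sim1.counts, sim3.counts)

    def test_single_step_moves_one_protein(self):
        g = make_box_grid(3, 3, 3)
        sim = Simulation(g, KineticParams(D=0.1), n_proteins=1, seed=4)
        before = sim.counts.copy()
        t = sim.step()
        assert t > 0
        moved = np.abs(sim.counts - before).sum()
        assert moved == 2  # one decrement, one increment

    def test_quiescent_state_raises(self):
        g = make_box_grid(2, 2, 2)
        sim = Simulation(g, KineticParams(D=0.0), n_proteins=10, seed=0)
        with pytest.raises(QuiescentState):
            sim.step()

    def test_two_voxel_symmetric_occupancy(self):
        """Pure hopping between two voxels: long-run occupancy is 50/50."""
        g = make_box_grid(2, 1, 1)
        sim = Simulation(g, KineticParams(D=1.0), n_proteins=40, seed=5)
        occ = np.zeros(2)
        for _ in range(400):
            sim.advance(sim.time + 0.01)
            occ += sim.counts[:, FREE_UNBLEACHED]
        assert occ[0] / occ.sum() == pytest.approx(0.5, abs=0.03)

    def test_uniform_stationary_occupancy_chi2(self):
        """Free diffusion in a sealed box: every voxel equally occupied
        (chi-square test at the 1% level on well-separated snapshots)."""
        g = make_box_grid(4, 3, 3)
        sim = Simulation(g, KineticParams(D=1.0), n_proteins=72, seed=6)
        nvox = sim.lattice.n_voxels
        counts = np.zeros(nvox)
        sim.advance(0.05)
        for _ in range(300):
            sim.advance(sim.time + 0.02)  # >> box mixing time
            counts += sim.counts[:, FREE_UNBLEACHED]
        chi2 = ((counts - counts.mean()) ** 2 / counts.mean()).sum()
        p = stats.chi2.sf(chi2, df=nvox - 1)
        assert p > 0.01

    def test_msd_matches_2dt_and_bessel_law(self):
        """1D lattice diffusion: MSD = 2Dt and the displacement law is the
        continuous-time random-walk Bessel distribution."""
        n = 201
        g = make_box_grid(n, 1, 1)
        D, a, t = 0.1, 25.0, 0.05
        sim = Simulation(g, KineticParams(D=D), n_proteins=0, seed=7)
        center = n // 2
        v = int(sim.lattice.index_map[center + 1, 0, 0])
        N = 20000
        sim.counts[v, FREE_UNBLEACHED] = N
        sim._requeue()
        sim.advance(t)
        profile = sim.counts[:, FREE_UNBLEACHED].astype(float)
        x = (sim.lattice.coords[:, 0] - (center + 1)) * a
        msd = (profile * x ** 2).sum() / N
        assert msd == pytest.approx(2 * D * 1e6 * t, rel=0.05)
        # exact law: P(j) = exp(-2kt) I_j(2kt), k = D/a^2 per direction
        k = D * 1e6 / a ** 2
        j = sim.lattice.coords[:, 0] - (center + 1)
        expected = N * special.ive(np.abs(j), 2 * k * t)
        keep = expected > 5
        chi2 = ((profile[keep] - expected[keep]) ** 2 / expected[keep]).sum()
        assert stats.chi2.sf(chi2, df=keep.sum() - 1) > 0.01

    def test_equilibrium_bound_fraction(self):
        """Sealed vesicle voxel, k_b*T = 1: half the proteins are bound in
        the long run (detailed balance of binding and unbinding)."""
        g = make_box_grid(1, 1, 1, vesicles=[(0, 0, 0)])
        kp = KineticParams(D=0.5, k_b=10.0, T=0.1)
        sim = Simulation(g, kp, n_proteins=1000, seed=8, init="uniform")
        sim.advance(1.0)  # ~10 binding timescales
        samples = []
        for _ in range(200):
            sim.advance(sim.time + 0.05)
            samples.append(sim.counts[:, BOUND_UNBLEACHED].sum())
        p_b = np.mean(samples) / 1000
        expected = (10.0 * 0.1) / (1 + 10.0 * 0.1)
        assert p_b == pytest.approx(expected, abs=0.02)


class TestDirectMethodOracle:
    """NSM trajectory statistics vs an independent direct-method Gillespie
    implementation on a 3x3x3 lattice with a binding voxel."""

    @staticmethod
    def _gillespie_direct(labels_ok, vesicle, shape, n0_voxel, D, kb, T,
                          t_end, rng):
        """Plain direct method: global propensity scan each event.
        State: list of (voxel_tuple, bound) per protein."""
        a = 25.0
        hop = D * 1e6 / a ** 2
        ku = 1.0 / T
        protein_pos = [tuple(n0_voxel)] * 0
        # proteins start in fixed voxel
        proteins = [[tuple(n0_voxel), False] for _ in range(3)]
        t = 0.0
        dirs = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                (0, 0, 1), (0, 0, -1)]
        while True:
            channels = []
            for i, (pos, bound) in enumerate(proteins):
                if bound:
                    channels.append((ku, i, "unbind", None))
                    continue
                for d in dirs:
                    tgt = (pos[0] + d[0], pos[1] + d[1], pos[2] + d[2])
                    if all(0 <= tgt[k] < shape[k] for k in range(3)) \
                            and labels_ok[tgt]:
                        channels.append((hop, i, "hop", tgt))
                if vesicle[pos]:
                    channels.append((kb, i, "bind", None))
            total = sum(c[0] for c in channels)
            if total == 0:
                return proteins
            t += rng.exponential(1.0 / total)
            if t > t_end:
                return proteins
            r = rng.random() * total
            acc = 0.0
            for c in channels:
                acc += c[0]
                if r < acc:
                    _, i, kind, tgt = c
                    if kind == "hop":
                        proteins[i][0] = tgt
                    elif kind == "bind":
                        proteins[i][1] = True
                    else:
                        proteins[i][1] = False
                    break
        return proteins

    def test_occupancy_distribution_matches(self):
        nrep = 10000
        D, kb, T, t_end = 0.3, 50.0, 0.05, 0.004
        g = make_box_grid(3, 3, 3, vesicles=[(1, 1, 1)])
        lat = LatticeIndex(g)
        start = (2, 1, 1)  # +1 x pad
        v0 = int(lat.index_map[start])
        # observable: number of proteins in the x<center half + bound count
        half = lat.coords[:, 0] <= 2
        kp = KineticParams(D=D, k_b=kb, T=T)

        nsm_obs = np.empty(nrep, dtype=int)
        for r in range(nrep):
            sim = Simulation(g, kp, n_proteins=0, seed=1000 + r, lattice=lat)
            sim.counts[v0, FREE_UNBLEACHED] = 3
            sim._requeue()
            sim.advance(t_end)
            free = sim.counts[:, FREE_UNBLEACHED]
            bound = sim.counts[:, BOUND_UNBLEACHED]
            nsm_obs[r] = 2 * int(bound.sum()) + int(free[half].sum())

        labels_ok = g.accessible_mask
        vesicle = np.zeros(g.labels.shape, dtype=bool)
        vesicle[2, 1, 1] = True
        rng = np.random.default_rng(999)
        ref_obs = np.empty(nrep, dtype=int)
        for r in range(nrep):
            proteins = self._gillespie_direct(labels_ok, vesicle,
                                              g.labels.shape, start,
                                              D, kb, T, t_end, rng)
            score = 0
            for pos, bound in proteins:
                if bound:
                    score += 2
                elif pos[0] <= 2:
                    score += 1
            ref_obs[r] = score

        values = sorted(set(nsm_obs) | set(ref_obs))
        n1 = np.array([(nsm_obs == v).sum() for v in values])
        n2 = np.array([(ref_obs == v).sum() for v in values])
        keep = (n1 + n2) >= 10
        table = np.vstack([n1[keep], n2[keep]])
        _, p, _, _ = stats.chi2_contingency(table)
        assert p > 0.01


class TestPeriodicBoundary:
    def test_wrap_resets_bleach_flag_and_conserves(self):
        """A bleached protein crossing the axon end re-enters unbleached on
        the opposite end; totals are conserved."""
        from synfrap.geometry import VoxelGrid
        labels = np.full((20, 1, 1), CYTOSOL, dtype=np.int8)
        g = VoxelGrid(labels=labels, center=(250.0, 12.5, 12.5),
                      semi_axes=(0.0, 0.0, 0.0), axon_diameter=50.0,
                      axon_length=500.0)
        sim = Simulation(g, KineticParams(D=1.0), n_proteins=200, seed=9)
        region = np.ones(sim.lattice.n_voxels, dtype=bool)
        sim.apply_instant_bleach(region)
        assert sim.species_totals()[FREE_UNBLEACHED] == 0
        sim.advance(0.5)
        totals = sim.species_totals()
        assert totals.sum() == 200
        # wrap events have re-injected unbleached protein
        assert totals[FREE_UNBLEACHED] > 0

    def test_unbleached_wrap_keeps_species(self):
        from synfrap.geometry import VoxelGrid
        labels = np.full((10, 1, 1), CYTOSOL, dtype=np.int8)
        g = VoxelGrid(labels=labels, center=(125.0, 12.5, 12.5),
                      semi_axes=(0.0, 0.0, 0.0), axon_diameter=50.0,
                      axon_length=250.0)
        sim = Simulation(g, KineticParams(D=1.0), n_proteins=50, seed=10)
        sim.advance(0.5)
        totals = sim.species_totals()
        assert totals[FREE_UNBLEACHED] == 50
        assert totals[FREE_BLEACHED] == 0


class TestBleaching:
    def test_instant_bleach_flags_everything_and_is_idempotent(self, small_bouton):
        sim = Simulation(small_bouton, KineticParams(D=0.1), n_proteins=300,
                         seed=1)
        region = np.ones(sim.lattice.n_voxels, dtype=bool)
        sim.apply_instant_bleach(region)
        assert sim.species_totals()[FREE_UNBLEACHED] == 0
        before = sim.counts.copy()
        sim.apply_instant_bleach(region)
        assert np.array_equal(sim.counts, before)
        assert sim.total_count() == 300

    def test_bleach_of_empty_region_is_noop(self, small_bouton):
        sim = Simulation(small_bouton, KineticParams(D=0.1), n_proteins=100,
                         seed=2)
        lat = sim.lattice
        # pick an accessible voxel set that holds no protein
        empty = (sim.counts.sum(axis=1) == 0)
        region = np.zeros(lat.n_voxels, dtype=bool)
        region[np.nonzero(empty)[0][:5]] = True
        before = sim.counts.copy()
        sim.apply_instant_bleach(region)
        assert np.array_equal(sim.counts, before)

    def test_continuous_bleach_requires_duration(self, small_bouton):
        sim = Simulation(small_bouton, KineticParams(D=0.1), n_proteins=10,
                         seed=3)
        region = np.ones(sim.lattice.n_voxels, dtype=bool)
        with pytest.raises(ValueError):
            sim.run_continuous_bleach(region, 0.0)


class TestEquilibrate:
    def test_uniform_no_binding_is_stationary_noop(self, small_bouton):
        sim = Simulation(small_bouton, KineticParams(D=0.5), n_proteins=400,
                         seed=13)
        report = equilibrate(sim, EquilibrationPolicy(horizon=0.5))
        assert report.stationary
        assert sim.time == pytest.approx(0.5)

    def test_axon_start_accumulates_bound_protein_in_bouton(self, small_bouton):
        """Proteins released in the axon bind up in the vesicle cluster until
        the binding balance n_b/n_ub = k_b*T holds per vesicle voxel."""
        kp = KineticParams(D=1.0, k_b=100.0, T=0.1)
        sim = Simulation(small_bouton, kp, n_proteins=2000, seed=14,
                         init="axon")
        lat = sim.lattice
        assert sim.counts[lat.in_synapse].sum() == 0
        equilibrate(sim, EquilibrationPolicy(horizon=6.0,
                                             check_stationarity=False))
        ves = lat.vesicle == 1
        n_b = n_ub = 0
        for _ in range(20):
            sim.advance(sim.time + 0.05)
            n_b += sim.counts[ves, BOUND_UNBLEACHED].sum()
            n_ub += sim.counts[ves, FREE_UNBLEACHED].sum()
        assert n_b > 0
        # balance over vesicle voxels: bound/free ratio approaches k_b*T = 10
        assert n_b / max(n_ub, 1) == pytest.approx(10.0, rel=0.15)

    def test_seeded_equilibration_reproducible(self, small_bouton):
        kp = KineticParams(D=0.2, k_b=10.0, T=0.1)
        sims = []
        for _ in range(2):
            sim = Simulation(small_bouton, kp, n_proteins=300, seed=15)
            equilibrate(sim, EquilibrationPolicy(horizon=0.3))
            sims.append(sim.counts.copy())
        assert np.array_equal(sims[0], sims[1])
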