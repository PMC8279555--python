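"""Metropolis moves, umbrella orchestration, and replica exchange."""

import numpy as np
import pytest

import chainfel as cf
from chainfel.oracles import RISModel, ris_sample
from chainfel.sampling import (
    KB, MCConfig, MCState, REFERENCE_LADDER, REMDConfig, WindowSchedule,
    metropolis_step, remd_exchange_decision, run_remd_umbrella,
    run_umbrella_windows,
)
from chainfel.wham import KB as KB_WHAM


class TestMetropolisStep:
    def test_downhill_always_accepted(self):
        s = MCState("a", 1.0)
        p = MCState("b", 1.0)
        for u in (0.0, 0.5, 0.999):
            assert metropolis_step(s, p, beta=1.0, u=u) is p

    def test_huge_uphill_always_rejected(self):
        s = MCState("a", 0.0)
        p = MCState("b", 1e6)
        assert metropolis_step(s, p, beta=1.0, u=1e-12) is s

    def test_two_state_occupancy_ratio(self):
        # E1 - E0 = kT ln 2 gives a 2:1 Boltzmann occupancy ratio
        beta = 1.0
        de = np.log(2.0) / beta
        rng = np.random.default_rng(42)
        state = 0
        n0 = 0
        n_steps = 100_000
        for _ in range(n_steps):
            proposal = 1 - state
            dE = de if proposal == 1 else -de
            cur = MCState(state, 0.0)
            prop = MCState(proposal, dE)
            state = metropolis_step(cur, prop, beta, float(rng.random())).value
            n0 += state == 0
        p0 = n0 / n_steps
        expected = 2.0 / 3.0
        se = np.sqrt(expected * (1 - expected) / n_steps)
        # correlated samples: allow 3 SE with a decorrelation factor ~ 2
        assert abs(p0 - expected) < 6 * se

    def test_invalid_u_rejected(self):
        with pytest.raises(ValueError):
            metropolis_step(MCState("a", 0.0), MCState("b", 0.0), 1.0, 1.5)


class TestExchangeDecision:
    def test_equal_energies_always_swap(self):
        assert remd_exchange_decision(5.0, 5.0, 0.4, 0.3, 0.999999)

    def test_equal_betas_always_swap(self):
        assert remd_exchange_decision(1.0, 9.0, 0.4, 0.4, 0.999999)

    def test_empirical_rate_matches_quadrature(self):
        # two 1D harmonic replicas: E = (kT/2)·z² with z standard normal
        t_cold, t_hot = 298.15, 400.0
        b1, b2 = 1 / (KB * t_cold), 1 / (KB * t_hot)
        rng = np.random.default_rng(3)
        n = 50_000
        e1 = 0.5 * KB * t_cold * rng.standard_normal(n) ** 2
        e2 = 0.5 * KB * t_hot * rng.standard_normal(n) ** 2
        accepted = np.mean([
            remd_exchange_decision(a, b, b1, b2, float(u))
            for a, b, u in zip(e1, e2, rng.random(n))
        ])

        # oracle: 2D Gauss-Hermite quadrature over the normal variables
        z, w = np.polynomial.hermite_e.hermegauss(201)
        w = w / np.sqrt(2 * np.pi)
        ea = 0.5 * KB * t_cold * z**2
        eb = 0.5 * KB * t_hot * z**2
        acc = np.minimum(1.0, np.exp((b1 - b2) * (ea[:, None] - eb[None, :])))
        expected = float(w @ acc @ w)
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(accepted - expected) < 3 * se


class TestSchedules:
    def test_centers_strictly_increasing_required(self):
        with pytest.raises(ValueError):
            WindowSchedule((3.0, 3.0, 4.0))

    def test_from_range_reproduces_reference_spacing(self):
        sched = WindowSchedule.from_range(3.0, 13.0, spacing=0.5)
        diffs = np.diff(sched.centers)
        np.testing.assert_allclose(diffs, 0.5, atol=1e-12)
        assert sched.k == 50.0

    def test_overlap_heuristic(self):
        wide = WindowSchedule.from_range(0.0, 10.0, spacing=2.0)
        tight = WindowSchedule.from_range(0.0, 10.0, spacing=0.3)
        assert not wide.check_overlap(298.15)
        assert tight.check_overlap(298.15)

    def test_default_ladder_is_reference_ten_temperatures(self):
        remd = REMDConfig()
        assert remd.ladder == REFERENCE_LADDER
        assert len(remd.ladder) == 10


class TestUmbrellaWindows:
    @pytest.fixture(scope="class")
    def small_run(self, warm_kernels):
        topo = cf.ChainTopology(8)
        sched = WindowSchedule.from_range(4.0, 9.0, spacing=0.5)
        mc = MCConfig(n_steps=4_000, equilibration=500, seed=5)
        hist = run_umbrella_windows(
            topo, cf.PotentialParams(), None, sched, mc, keep_dihedrals=True,
        )
        return topo, sched, mc, hist

    def test_window_metadata_recorded(self, small_run):
        topo, sched, mc, hist = small_run
        assert hist.n_windows == len(sched.centers)
        np.testing.assert_allclose(hist.bias_r0, sched.centers)
        np.testing.assert_allclose(hist.bias_k, 50.0)
        assert hist.metadata["seed"] == 5
        assert all(t == mc.n_steps // mc.sample_stride for t in hist.totals)

    def test_adjacent_windows_overlap(self, small_run):
        *_, hist = small_run
        assert hist.overlap_gaps() == []
        assert len(hist.overlap_components()) == 1

    def test_fixed_seed_bit_identical(self, small_run):
        topo, sched, mc, hist = small_run
        again = run_umbrella_windows(topo, cf.PotentialParams(), None, sched, mc)
        np.testing.assert_array_equal(hist.counts, again.counts)

    def test_dihedral_frames_kept_per_window(self, small_run):
        topo, sched, mc, hist = small_run
        assert hist.dihedrals is not None
        assert len(hist.dihedrals) == hist.n_windows
        assert hist.dihedrals[0].shape == (
            mc.n_steps // mc.sample_stride, topo.n_dihedrals,
        )

    def test_biased_window_mean_tracks_restraint(self, small_run):
        topo, sched, mc, hist = small_run
        # strongly biased windows should center near their restraint
        mid = hist.n_windows // 2
        mean_r = (hist.bin_centers * hist.counts[mid]).sum() / hist.counts[mid].sum()
        assert abs(mean_r - sched.centers[mid]) < 0.5

    def test_acceptance_monotonic_in_step_size(self, warm_kernels):
        topo = cf.ChainTopology(8)
        sched = WindowSchedule((6.0,), k=10.0)
        rates = []
        for max_step in (5.0, 30.0, 90.0, 180.0):
            acc = []
            for seed in range(10):
                mc = MCConfig(n_steps=2_000, equilibration=200,
                              max_step=max_step, pivot_prob=0.0, seed=seed)
                h = run_umbrella_windows(topo, cf.PotentialParams(), None,
                                         sched, mc)
                acc.append(h.metadata["mean_acceptance"])
            rates.append(np.mean(acc))
        assert all(b <= a + 1e-9 for a, b in zip(rates, rates[1:]))


class TestThreeStateDetailedBalance:
    def test_stationary_distribution_matches_boltzmann(self, warm_kernels):
        # single-dihedral RIS chain: states t, g+, g- with energies 0, e, e
        model = RISModel(cf.ChainTopology(4), eps_g=2.9)
        t = 298.15
        _, states, _ = ris_sample(model, temperature=t, n_steps=200_000, seed=9)
        p_t = np.mean(states[:, 0] == 0)
        expected = 1.0 / (1.0 + 2.0 * np.exp(-2.9 / (KB * t)))
        se = np.sqrt(expected * (1 - expected) / states.shape[0])
        # sequential MC samples are correlated; allow a decorrelation factor
        assert abs(p_t - expected) < 3 * se * np.sqrt(10)


class TestREMD:
    def test_single_temperature_ladder_degenerates_to_plain_umbrella(self, warm_kernels):
        topo = cf.ChainTopology(8)
        sched = WindowSchedule.from_range(4.0, 8.0, spacing=0.5)
        mc = MCConfig(n_steps=2_000, equilibration=200, seed=7)
        remd = REMDConfig(ladder=(298.15,), seed=7)
        r = run_remd_umbrella(topo, cf.PotentialParams(), None, sched, remd, mc)
        plain = run_umbrella_windows(topo, cf.PotentialParams(), None, sched, mc)
        np.testing.assert_array_equal(r.histograms[298.15].counts, plain.counts)
        assert r.swap_attempts == 0

    def test_marginals_match_independent_single_t_runs(self, warm_kernels):
        topo = cf.ChainTopology(8)
        sched = WindowSchedule.from_range(5.0, 7.0, spacing=0.5)
        mc = MCConfig(n_steps=6_000, equilibration=600, seed=11)
        ladder = (298.15, 400.0, 500.0)
        r = run_remd_umbrella(
            topo, cf.PotentialParams(), None, sched,
            REMDConfig(ladder=ladder, exchange_interval=500, seed=11), mc,
        )
        for t in ladder:
            h = r.histograms[t]
            single = run_umbrella_windows(
                topo, cf.PotentialParams(), None, sched,
                MCConfig(n_steps=6_000, equilibration=600, seed=101,
                         temperature=t),
            )
            for w in range(h.n_windows):
                m_remd = (h.bin_centers * h.counts[w]).sum() / h.counts[w].sum()
                m_single = (
                    single.bin_centers * single.counts[w]
                ).sum() / single.counts[w].sum()
                sd = np.sqrt(
                    ((h.bin_centers - m_remd) ** 2 * h.counts[w]).sum()
                    / h.counts[w].sum()
                )
                se = sd / np.sqrt(h.counts[w].sum() / 10.0)  # correlation factor
                assert abs(m_remd - m_single) < 3 * se + 0.05

    def test_swaps_do_happen(self, warm_kernels):
        topo = cf.ChainTopology(8)
        sched = WindowSchedule((6.0,))
        mc = MCConfig(n_steps=4_000, equilibration=200, seed=13)
        r = run_remd_umbrella(
            topo, cf.PotentialParams(), None, sched,
            REMDConfig(ladder=(298.15, 340.0, 390.0), exchange_interval=250,
                       seed=13), mc,
        )
        assert r.swap_attempts > 0
        assert 0.0 < r.swap_acceptance <= 1.0
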