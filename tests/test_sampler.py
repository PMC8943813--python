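"""Monte Carlo machinery: acceptance, replica exchange, diagnostics."""

import math

import numpy as np
import pytest
from scipy import stats

from chromatinmc.chain import build_chain, initial_configuration
from chromatinmc.forcefield import ForceField
from chromatinmc.regions import GenomicInterval, NucleosomeSet
from chromatinmc.sampler import (
    MCState,
    RunControl,
    TemperatureLadder,
    Trajectory,
    autocorrelation_time,
    equilibration_cut,
    metropolis_run,
    optimize_ladder,
    replica_exchange_run,
    simulated_annealing,
    swap_probability,
    thin,
)


def _toy_topology(n_bp=3000):
    iv = GenomicInterval("chrT", 0, n_bp)
    ns = NucleosomeSet(iv, np.zeros(0, np.int64))
    return build_chain(ns)


class TestSwapProbability:
    def test_equal_energies(self):
        assert swap_probability(10.0, 10.0, 1.0, 0.5) == 1.0

    def test_equal_betas(self):
        assert swap_probability(3.0, 17.0, 0.7, 0.7) == 1.0

    def test_direct_evaluation(self):
        assert swap_probability(10.0, 15.0, 1.0, 0.8) == pytest.approx(
            math.exp(-1.0), abs=1e-15
        )

    def test_invalid_beta(self):
        with pytest.raises(ValueError):
            swap_probability(1.0, 2.0, -1.0, 0.5)


class TestMetropolis:
    def test_high_temperature_acceptance_near_one(self, elastic_ff):
        topo = _toy_topology()
        cfg = initial_configuration(topo, "straight")
        st = MCState(topo, elastic_ff, cfg, seed=0)
        st.run(5000, T=1e7)
        assert st.acceptance > 0.97

    def test_seed_determinism(self, elastic_ff):
        topo = _toy_topology()
        out = []
        for _ in range(2):
            cfg = initial_configuration(topo, "straight")
            st = MCState(topo, elastic_ff, cfg, seed=11)
            st.run(3000, T=1.0)
            out.append(st.config.pos.copy())
        np.testing.assert_array_equal(out[0], out[1])

    def test_frames_stay_orthonormal(self, elastic_ff):
        topo = _toy_topology()
        cfg = initial_configuration(topo, "straight")
        st = MCState(topo, elastic_ff, cfg, seed=1)
        st.run(5000, T=1.5)
        st.config.validate(tol=1e-9)


class TestReplicaExchange:
    def test_single_temperature_equals_metropolis(self, elastic_ff):
        topo = _toy_topology()
        control = RunControl(n_steps=5000, swap_interval=1000,
                             record_interval=500, seed=3)
        traj_a = metropolis_run(topo, elastic_ff, control)
        ladder = TemperatureLadder(np.array([1.0]))
        traj_b = replica_exchange_run(topo, elastic_ff, ladder, control)[0]
        np.testing.assert_array_equal(traj_a.positions[-1], traj_b.positions[-1])

    def test_marginal_matches_single_t_run(self, elastic_ff):
        """Replica exchange leaves each temperature's marginal invariant (KS)."""
        topo = _toy_topology(2000)
        control = RunControl(n_steps=120_000, swap_interval=2_000,
                            record_interval=200, seed=5)
        single = metropolis_run(topo, elastic_ff, control)
        ladder = TemperatureLadder(np.array([1.0, 1.6]))
        control2 = RunControl(n_steps=120_000, swap_interval=2_000,
                             record_interval=200, seed=17)
        paired = replica_exchange_run(topo, elastic_ff, ladder, control2)[0]
        burn = len(single) // 4
        ks = stats.ks_2samp(
            single.end_to_end[burn::5], paired.end_to_end[burn::5]
        )
        assert ks.pvalue > 0.01

    def test_trajectory_save_load_roundtrip(self, elastic_ff, tmp_path):
        topo = _toy_topology()
        control = RunControl(n_steps=3000, swap_interval=1000,
                             record_interval=500, seed=8)
        traj = metropolis_run(topo, elastic_ff, control)
        path = tmp_path / "traj.npz"
        traj.save(path)
        back = Trajectory.load(path)
        np.testing.assert_array_equal(back.steps, traj.steps)
        np.testing.assert_allclose(back.positions[-1], traj.positions[-1])
        assert back.meta["seed"] == 8

    def test_trajectory_metadata_and_monotone_steps(self, elastic_ff):
        topo = _toy_topology()
        control = RunControl(n_steps=4000, swap_interval=2000,
                             record_interval=500, seed=9)
        trajs = replica_exchange_run(
            topo, elastic_ff, TemperatureLadder(np.array([1.0, 1.5, 2.0])), control
        )
        assert len(trajs) == 3
        for t in trajs:
            assert np.all(np.diff(t.steps) > 0)
            assert t.meta["ladder"] == [1.0, 1.5, 2.0]


class TestLadder:
    def test_ladder_validation(self):
        with pytest.raises(ValueError):
            TemperatureLadder(np.array([1.0, 1.0]))

    def test_optimized_ladder_contract(self, elastic_ff):
        """Output strictly increasing with the same endpoints."""
        topo = _toy_topology(1500)
        ladder = TemperatureLadder.geometric(1.0, 2.5, 5)
        pilot = RunControl(n_steps=20_000, swap_interval=1_000,
                           record_interval=1_000, seed=2)
        out = optimize_ladder(topo, elastic_ff, ladder, pilot, max_iters=2)
        t = out.temperatures
        assert t[0] == pytest.approx(1.0)
        assert t[-1] == pytest.approx(2.5)
        assert np.all(np.diff(t) > 0)
        assert len(out) == 5


class TestSimulatedAnnealing:
    def test_energy_decreases_in_median(self, small_set):
        ff = ForceField()
        topo = build_chain(small_set)
        drops = []
        for seed in range(5):
            # random-walk start: large bend/twist energy, so relaxation
            # toward equilibrium must lower the energy
            cfg = initial_configuration(topo, "random_walk", seed=100 + seed)
            st_e0 = MCState(topo, ff, cfg.copy(), seed=0).energy.total
            out, _ = simulated_annealing(
                cfg, topo, ff, np.geomspace(3, 1, 4), 800, seed=seed
            )
            st_e1 = MCState(topo, ff, out, seed=0).energy.total
            drops.append(st_e1 - st_e0)
        assert np.median(drops) < 0

    def test_seeded_determinism(self, small_set, elastic_ff):
        topo = build_chain(small_set)
        outs = []
        for _ in range(2):
            cfg = initial_configuration(topo, "straight")
            out, ms = simulated_annealing(
                cfg, topo, elastic_ff, np.array([2.0, 1.0]), 500, seed=4
            )
            outs.append((out.pos.copy(), ms.amp_pivot))
        np.testing.assert_array_equal(outs[0][0], outs[1][0])
        assert outs[0][1] == outs[1][1]

    def test_increasing_schedule_rejected(self, small_set, elastic_ff):
        topo = build_chain(small_set)
        cfg = initial_configuration(topo, "straight")
        with pytest.raises(ValueError):
            simulated_annealing(cfg, topo, elastic_ff, np.array([1.0, 2.0]))


class TestAutocorrelation:
    def test_white_noise_tau_near_one(self):
        rng = np.random.default_rng(0)
        tau = autocorrelation_time(rng.normal(size=20_000))
        assert abs(tau - 1.0) < 0.2

    def test_ar1_closed_form(self):
        phi = 0.9
        rng = np.random.default_rng(1)
        x = np.empty(60_000)
        x[0] = 0.0
        eps = rng.normal(size=x.size)
        for i in range(1, x.size):
            x[i] = phi * x[i - 1] + eps[i]
        tau = autocorrelation_time(x[1000:])
        expected = (1 + phi) / (1 - phi)  # = 19
        assert abs(tau - expected) / expected < 0.25

    def test_constant_series_flagged(self):
        with pytest.raises(ValueError, match="constant"):
            autocorrelation_time(np.ones(1000))

    def test_too_short_series(self):
        rng = np.random.default_rng(2)
        x = np.cumsum(rng.normal(size=100))  # random walk: tau ~ n
        with pytest.raises(ValueError):
            autocorrelation_time(x)


class TestEquilibration:
    def test_stationary_from_start(self):
        rng = np.random.default_rng(3)
        e = rng.normal(size=2000)
        r = rng.normal(size=2000)
        assert equilibration_cut(e, r) == 0

    def test_step_shift_detected(self):
        rng = np.random.default_rng(4)
        k = 400
        e = np.concatenate([rng.normal(10, 0.5, k), rng.normal(0, 0.5, 1600)])
        r = np.concatenate([rng.normal(5, 0.5, k), rng.normal(0, 0.5, 1600)])
        cut = equilibration_cut(e, r)
        assert cut >= k

    def test_override_verbatim(self):
        assert equilibration_cut(np.ones(10), np.ones(10), override=7) == 7


class TestThin:
    def _fake_traj(self, n):
        return Trajectory(
            1.0, np.arange(1, n + 1) * 1000,
            [np.zeros((2, 3))] * n,
            np.zeros((n, 6)), np.zeros(n),
        )

    def test_tau_one_keeps_all(self):
        t = self._fake_traj(100)
        assert len(thin(t, 1.0)) == 100

    def test_paper_scale_counts(self):
        # 1e7 steps recorded every 1e3 -> 1e4 samples; tau = 1e4 steps = 10 samples
        t = self._fake_traj(10_000)
        assert len(thin(t, 10)) <= 1000

    def test_thinned_series_decorrelated(self):
        phi = 0.9
        rng = np.random.default_rng(5)
        x = np.empty(60_000)
        x[0] = 0.0
        for i in range(1, x.size):
            x[i] = phi * x[i - 1] + rng.normal()
        tau = autocorrelation_time(x)
        # integrated-tau thinning of an AR(1) leaves lag-1 correlation
        # ~exp(-2); the usual 2*tau safety stride decorrelates properly
        y = x[:: int(np.ceil(2 * tau))]
        r1 = np.corrcoef(y[:-1], y[1:])[0, 1]
        assert abs(r1) < 0.1
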