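import numpy as np
import pytest

import grnswitch as gs
from grnswitch import make_kernel, simulate_dssa

from reference_impl import reference_dssa


def _time_average(traj):
    times, counts = traj.counts_path()
    dt = np.diff(np.append(times, traj.t_final))
    return (counts[:, 0] * dt).sum() / traj.t_final


class TestExactness:
    def test_birth_death_stationary_mean(self, birth_death):
        """Long-run time average of the birth-death process matches the
        analytic Poisson stationary mean k/gamma = 10 within 5 SE."""
        traj = simulate_dssa(birth_death, t_max=5000.0, seed=1)
        # autocorrelation time of O-U-like count is 1/gamma = 1; effective
        # samples ~ T/2, stationary sd = sqrt(10)
        se = np.sqrt(10.0) / np.sqrt(5000.0 / 2)
        assert abs(_time_average(traj) - 10.0) < 5 * se

    def test_agrees_with_reference_implementation(self, birth_death):
        """Compiled event loop and the plain-Python reference produce the
        same stationary statistics within Monte Carlo error."""
        grid = np.linspace(500.0, 4000.0, 600)
        ref = reference_dssa(
            birth_death, None, 4000.0, np.random.default_rng(3), grid
        )
        traj = simulate_dssa(birth_death, t_max=4000.0, seed=4)
        times, counts = traj.counts_path()
        idx = np.searchsorted(times, grid, side="right") - 1
        mine = counts[idx, 0]
        se = np.sqrt(10.0) * np.sqrt(2 / 3500.0) * np.sqrt(2)
        assert abs(mine.mean() - ref.mean()) < 5 * se
        assert np.var(mine) == pytest.approx(np.var(ref), rel=0.35)

    def test_delayed_toggle_agrees_with_reference(self, toggle):
        """Delayed production: grid-sampled count moments from the compiled
        loop and the reference implementation agree."""
        kern = {"production": make_kernel("gamma", 2.0, 0.5)}
        grid = np.linspace(20.0, 400.0, 150)
        ref = np.mean(
            [
                reference_dssa(toggle, kern, 400.0, np.random.default_rng(s), grid)[:, 1]
                for s in (10, 11, 12)
            ]
        )
        runs = [simulate_dssa(toggle, kern, t_max=400.0, seed=s) for s in (13, 14, 15)]
        vals = []
        for traj in runs:
            times, counts = traj.counts_path()
            idx = np.searchsorted(times, grid, side="right") - 1
            vals.append(counts[idx, 1].mean())
        assert np.mean(vals) == pytest.approx(ref, rel=0.1)


class TestDelayMechanics:
    def test_no_completion_before_fixed_delay(self, delayed_birth):
        """First completion = first initiation + tau for a fixed kernel."""
        traj = simulate_dssa(
            delayed_birth, {"k": make_kernel("fixed", 2.0)}, t_max=10.0, seed=2
        )
        inits = traj.event_times[traj.event_kinds == 1]
        comps = traj.event_times[traj.event_kinds == 2]
        assert comps.min() >= 2.0
        assert comps[0] == pytest.approx(inits[0] + 2.0)

    def test_fixed_delay_completions_are_translated_initiations(self, delayed_birth):
        """With a fixed delay every completion is its initiation shifted by
        tau, in FIFO order — no completion lost or double-applied."""
        traj = simulate_dssa(
            delayed_birth, {"k": make_kernel("fixed", 3.0)}, t_max=50.0, seed=5
        )
        inits = traj.event_times[traj.event_kinds == 1]
        comps = traj.event_times[traj.event_kinds == 2]
        expected = inits + 3.0
        expected = expected[expected <= traj.t_final]
        assert np.allclose(comps, expected[: len(comps)])

    def test_fixed_delay_completion_count_is_poisson(self, delayed_birth):
        """Completions on [tau, T] form a Poisson process at the initiation
        rate k: the count has mean k(T - tau), checked by a CLT bound."""
        k, tau, T = 5.0, 2.0, 400.0
        traj = simulate_dssa(
            delayed_birth, {"k": make_kernel("fixed", tau)}, t_max=T, seed=6
        )
        n = int((traj.event_kinds == 2).sum())
        lam = k * (T - tau)
        assert abs(n - lam) < 5 * np.sqrt(lam)

    def test_gamma_delay_mean_count(self, delayed_birth):
        """Final count ~ k * E[time window] regardless of delay dispersion."""
        traj = simulate_dssa(
            delayed_birth, {"k": make_kernel("gamma", 2.0, 0.8)}, t_max=400.0, seed=7
        )
        lam = 5.0 * (400.0 - 2.0)
        assert abs(traj.final_state[0] - lam) < 5 * np.sqrt(lam) + 10


class TestContracts:
    def test_same_seed_identical_event_logs(self, toggle):
        kern = {"production": make_kernel("gamma", 2.0, 0.5)}
        a = simulate_dssa(toggle, kern, t_max=200.0, seed=9)
        b = simulate_dssa(toggle, kern, t_max=200.0, seed=9)
        assert np.array_equal(a.event_times, b.event_times)
        assert np.array_equal(a.event_kinds, b.event_kinds)
        assert np.array_equal(a.event_rx, b.event_rx)
        assert np.array_equal(a.final_state, b.final_state)

    def test_event_times_nondecreasing_counts_nonnegative(self, toggle):
        kern = {"production": make_kernel("bernoulli", 2.0, 0.5)}
        traj = simulate_dssa(toggle, kern, t_max=300.0, seed=10)
        assert np.all(np.diff(traj.event_times) >= 0)
        _, counts = traj.counts_path()
        assert counts.min() >= 0

    def test_missing_kernel_raises(self, toggle):
        with pytest.raises(KeyError):
            simulate_dssa(toggle, {}, t_max=10.0, seed=0)

    def test_zero_propensity_halts_at_t_max(self):
        net = gs.ReactionNetwork(
            species=["Q"],
            reactions=[gs.Reaction("death", "linear", (1.0,), (0,), (-1,))],
            initial_state=[3],
        )
        traj = simulate_dssa(net, t_max=50.0, seed=1)
        assert traj.t_final == 50.0
        assert traj.final_state[0] == 0

    def test_unbounded_run_rejected(self, birth_death):
        with pytest.raises(ValueError, match="unbounded"):
            simulate_dssa(birth_death, t_max=np.inf, seed=0)

    def test_phage_operator_conservation_along_trajectory(self, phage):
        kern = {"production": make_kernel("gamma", 5.0, 0.5)}
        traj = simulate_dssa(phage, kern, t_max=300.0, seed=11)
        _, counts = traj.counts_path()
        o = counts[:, 4] + counts[:, 5] + counts[:, 6]
        assert np.all(o == phage.metadata["operator_copies"])
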