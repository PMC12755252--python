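import numpy as np
import pytest
from scipy.integrate import quad

from grnswitch import reduced as rd


@pytest.fixture(scope="module")
def rates():
    """A generic rate set with RM2 scale separation and clear RM3 margins."""
    return rd.RMRates(
        H_to_I={"H": 1.0, "I": 1.2, "L": 0.9},
        L_to_I={"H": 0.8, "I": 1.1, "L": 1.0},
        I_to_H={"H": 80.0, "I": 40.0, "L": 25.0},
        I_to_L={"H": 20.0, "I": 60.0, "L": 75.0},
    )


@pytest.fixture(scope="module")
def tau(rates):
    # delay on the scale of the I-exit time so the memory weight Z_H(tau)
    # is well inside (0, 1)
    return 1.5 / rates.exit_rate_I("H")


class TestFailProbability:
    def test_limits(self, rates):
        assert rd.rm_fail_probability(rates, 0.0) == pytest.approx(
            rates.p_I_to("I", "H")
        )
        assert rd.rm_fail_probability(rates, 1e9) == pytest.approx(
            rates.p_I_to("H", "H")
        )

    def test_convex_combination_bounds(self, rates):
        lo = min(rates.p_I_to("I", "H"), rates.p_I_to("H", "H"))
        hi = max(rates.p_I_to("I", "H"), rates.p_I_to("H", "H"))
        for t in np.linspace(0.0, 0.5, 20):
            assert lo <= rd.rm_fail_probability(rates, t) <= hi

    def test_monotone_in_tau_under_rm3(self, rates):
        ts = np.linspace(0.0, 0.3, 30)
        vals = [rd.rm_fail_probability(rates, t) for t in ts]
        assert all(a < b for a, b in zip(vals, vals[1:]))

    def test_matches_discrete_chain_oracle(self, rates, tau):
        sim = rd.rm_discrete_simulate(rates, tau, K=128, n=100_000, seed=1)
        f = rd.rm_fail_probability(rates, tau)
        assert abs(f - sim["fail_probability"]) < 3 * sim["fail_se"]

    def test_oracle_converges_as_K_doubles(self, rates, tau):
        """Richardson-style check: the discrete-chain failure fraction
        approaches the continuous closed form as Delta -> 0."""
        f = rd.rm_fail_probability(rates, tau)
        errs = [
            abs(rd.rm_discrete_simulate(rates, tau, K=k, n=200_000, seed=2)[
                "fail_probability"] - f)
            for k in (8, 32, 128)
        ]
        assert errs[-1] < errs[0]
        assert errs[-1] < 0.01


class TestLoopTime:
    def test_density_normalizes(self, rates, tau):
        a, _ = quad(lambda t: rd.rm_loop_time_density(rates, tau, t), 0, tau)
        b, _ = quad(lambda t: rd.rm_loop_time_density(rates, tau, t), tau, np.inf)
        assert a + b == pytest.approx(1.0, abs=1e-9)

    def test_success_density_normalizes(self, rates, tau):
        a, _ = quad(lambda t: rd.rm_success_time_density(rates, tau, t), 0, tau)
        b, _ = quad(lambda t: rd.rm_success_time_density(rates, tau, t), tau, np.inf)
        assert a + b == pytest.approx(1.0, abs=1e-9)

    def test_branch_structure_at_tau(self, rates, tau):
        """Approaching the delay horizon the two branches differ exactly by
        the switch of the numerator rate (memory H -> memory I)."""
        eps = 1e-9
        left = rd.rm_loop_time_density(rates, tau, tau - eps)
        right = rd.rm_loop_time_density(rates, tau, tau + eps)
        assert right / left == pytest.approx(
            rates.I_to_H["I"] / rates.I_to_H["H"], rel=1e-5
        )

    def test_expected_loop_time_equals_quadrature(self, rates, tau):
        closed = rd.rm_expected_loop_time(rates, tau)
        assert closed == pytest.approx(
            rd.rm_expected_loop_time_quadrature(rates, tau), rel=1e-6
        )

    def test_expected_loop_time_matches_oracle(self, rates, tau):
        sim = rd.rm_discrete_simulate(rates, tau, K=128, n=200_000, seed=3)
        lt = sim["loop_times"]
        se = lt.std(ddof=1) / np.sqrt(len(lt))
        # the discrete chain overestimates times by O(Delta) (it counts
        # whole steps); allow that bias on top of the CLT band
        assert abs(rd.rm_expected_loop_time(rates, tau) - lt.mean()) < 3 * se + sim["delta"]

    def test_loop_time_histogram_matches_density(self, rates, tau):
        """Empirical loop-time distribution from the fine-Delta discrete
        chain is close to P(t) in total variation over a coarse binning."""
        sim = rd.rm_discrete_simulate(rates, tau, K=128, n=200_000, seed=4)
        edges = np.linspace(0, 5 * tau, 21)
        hist, _ = np.histogram(sim["loop_times"], bins=edges, density=True)
        centers = 0.5 * (edges[:-1] + edges[1:])
        dens = rd.rm_loop_time_density(rates, tau, centers)
        tv = 0.5 * np.sum(np.abs(hist - dens)) * np.diff(edges)[0]
        assert tv < 0.05

    def test_near_insensitivity_to_tau_under_rm2(self, rates, tau):
        """|dE[F_H]/dtau| is small relative to E[F_H]/tau when rates out of
        I dominate."""
        h = tau * 1e-4
        d = (
            rd.rm_expected_loop_time(rates, tau + h)
            - rd.rm_expected_loop_time(rates, tau - h)
        ) / (2 * h)
        assert abs(d) < 0.2 * rd.rm_expected_loop_time(rates, tau) / tau


class TestStepsPmf:
    def test_pmf_sums_to_one(self, rates, tau):
        # K=1 needs a delay below the fastest exit time so the single-step
        # jump probability stays < 1
        for K, t in ((1, tau / 2), (8, tau), (128, tau)):
            _, pmf, tail = rd.rm_loop_steps_pmf(rates, t, K=K)
            assert pmf.sum() + tail == pytest.approx(1.0, abs=1e-9)

    def test_single_step_memory_degenerate_case(self, rates, tau):
        k, pmf, tail = rd.rm_loop_steps_pmf(rates, tau / 2, K=1)
        assert pmf[0] > 0
        sim = rd.rm_discrete_simulate(rates, tau / 2, K=1, n=50_000, seed=5)
        assert sim["loop_steps"].min() >= 1

    def test_pmf_matches_oracle_histogram(self, rates, tau):
        K = 32
        sim = rd.rm_discrete_simulate(rates, tau, K=K, n=200_000, seed=6)
        k, pmf, _ = rd.rm_loop_steps_pmf(rates, tau, K=K, k_max=40)
        counts = np.bincount(sim["loop_steps"], minlength=41)[1:41]
        emp = counts / len(sim["loop_steps"])
        assert np.max(np.abs(emp - pmf)) < 0.01

    def test_too_coarse_discretization_rejected(self, rates):
        with pytest.raises(ValueError, match="per-step"):
            rd.rm_loop_steps_pmf(rates, tau=10.0, K=1)


class TestResidenceEstimate:
    def test_no_failures_limit(self, rates, tau):
        """f_H = 0 is unreachable for generic rates, but the estimate with
        the geometric factor removed equals E[S_H] + waiting time."""
        f = rd.rm_fail_probability(rates, tau)
        est = rd.rm_residence_estimate(rates, tau)
        wait = 1.0 / rates.H_to_I["H"]
        expected = f / (1 - f) * (rd.rm_expected_loop_time(rates, tau) + wait) + (
            rd.rm_expected_success_time(rates, tau) + wait
        )
        assert est == pytest.approx(expected)

    def test_geometric_mean_identity(self):
        # sum n f^n (1-f) = f/(1-f)
        f = 0.37
        n = np.arange(0, 2000)
        assert np.sum(n * f**n * (1 - f)) == pytest.approx(f / (1 - f))

    def test_monotone_increasing_in_tau(self, rates):
        ts = np.linspace(0.0, 0.3, 15)
        vals = [rd.rm_residence_estimate(rates, t) for t in ts]
        assert all(a < b for a, b in zip(vals, vals[1:]))


class TestExtendedModel:
    def test_equal_probabilities_reduce_to_geometric(self):
        assert rd.ext_expected_failures(0.4, 0.4) == pytest.approx(0.4 / 0.6)
        assert rd.ext_expected_failures(0.0, 0.0) == 0.0

    def test_matches_coin_sequence_oracle(self):
        sim = rd.ext_failures_simulate(0.3, 0.7, n=400_000, seed=7)
        assert abs(rd.ext_expected_failures(0.3, 0.7) - sim["expected_failures"]) < (
            3 * sim["se"]
        )

    def test_sigma_zero_reduces_to_fixed_delay_estimate(self, rates):
        mu = 0.02
        assert rd.ext_residence_estimate(rates, mu, 0.0) == pytest.approx(
            rd.rm_residence_estimate(rates, mu)
        )

    def test_diverges_at_unit_failure(self):
        with pytest.raises(ValueError):
            rd.ext_expected_failures(1.0, 0.5)

    def test_jensen_average_survival_increases_with_sigma(self, rates):
        mu = 1.5 / rates.exit_rate_I("H")
        sig = np.linspace(0.0, 0.95, 25) * mu
        z = np.array([
            0.5 * (rates.Z("H", mu - s) + rates.Z("H", mu + s)) for s in sig
        ])
        assert np.all(np.diff(z) > 0)

    def test_residence_estimate_decreasing_in_sigma(self, rates):
        mu = 1.5 / rates.exit_rate_I("H")
        sig = np.linspace(0.0, 0.95, 25) * mu
        vals = [rd.ext_residence_estimate(rates, mu, s) for s in sig]
        assert all(a > b for a, b in zip(vals, vals[1:]))


class TestAssumptions:
    def test_boundary_rm3_fails(self):
        r = rd.RMRates(
            H_to_I={"H": 1.0, "I": 1.0, "L": 1.0},
            L_to_I={"H": 1.0, "I": 1.0, "L": 1.0},
            I_to_H={"H": 50.0, "I": 50.0, "L": 50.0},
            I_to_L={"H": 50.0, "I": 50.0, "L": 50.0},
        )
        rep = rd.check_rm_assumptions(r, 0.01)
        assert not rep["rm3_pass"]
        assert rep["rm3_margin_H"] == 0.0

    def test_rm2_ratio_reported(self, rates):
        rep = rd.check_rm_assumptions(rates, 0.01)
        assert rep["rm2_pass"]
        assert rep["rm2_ratio"] == pytest.approx(
            min(rates.exit_rate_I(i) for i in "HIL")
            / max(max(rates.H_to_I.values()), max(rates.L_to_I.values()))
        )

    def test_sampled_rates_satisfy_rm2_rm3(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            r = rd.sample_rm3_rates(rng)
            rep = rd.check_rm_assumptions(r, 0.5 / r.exit_rate_I("H"))
            assert rep["rm2_pass"] and rep["rm3_pass"]
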