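import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import grnswitch as gs
from grnswitch.simulate import SymbolTrace
from grnswitch.regions import RegionSpec
from grnswitch.residence import attempt_statistics, residence_times

# symbol codes: 0=H, 1=L, 2=I, 3=gap


def trace(*pairs):
    t, c = zip(*pairs)
    return SymbolTrace(np.asarray(t, dtype=float), np.asarray(c, dtype=np.int8))


class TestRegionSpec:
    def test_fixed_points_classified_into_their_neighborhoods(self, toggle, toggle_regions):
        hi_lo, lo_hi = gs.find_steady_states(toggle)[::-1]
        assert toggle_regions.classify(hi_lo) == "H"
        assert toggle_regions.classify(lo_hi) == "L"

    def test_symmetry_line_is_I(self, toggle_regions):
        assert toggle_regions.classify([20, 20]) == "I"
        assert toggle_regions.classify([0, 0]) == "I"

    def test_classification_symmetric_under_relabel(self, toggle_regions):
        rng = np.random.default_rng(1)
        swap = {"H": "L", "L": "H", "I": "I", "gap": "gap"}
        for _ in range(50):
            q = rng.integers(0, 45, size=2)
            assert toggle_regions.classify(q[::-1]) == swap[toggle_regions.classify(q)]

    def test_overlapping_iband_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            RegionSpec(
                weights=np.array([1.0]), offset=0.0,
                theta_pos=2.0, theta_neg=2.0, iband_pos=2.5, iband_neg=1.0,
            )


class TestResidenceClock:
    def test_intermediate_exits_do_not_stop_the_clock(self):
        """Enter U0 at t=0, exit at 3, re-enter at 4, first enter U1 at 10:
        one U0 residence of length 10."""
        rec = residence_times(trace((0, 0), (3, 3), (4, 0), (10, 1)))
        assert rec.n_residences == 1
        assert rec.durations[0] == 10.0
        assert rec.states[0] == "H"

    def test_subsequent_residence_in_other_state(self):
        rec = residence_times(trace((0, 0), (3, 3), (4, 0), (10, 1), (25, 0)))
        assert list(rec.durations) == [10.0, 15.0]
        assert list(rec.states[:2]) == ["H", "L"]

    def test_residences_partition_span_between_transitions(self, toggle, toggle_regions):
        traj = gs.simulate_dssa(
            toggle, {"production": gs.make_kernel("gamma", 2.0, 1.0)},
            t_max=np.inf, seed=33, regions=toggle_regions,
            stop_after_entries=6, record_events=False, max_events=10**9,
        )
        rec = residence_times(traj)
        assert rec.durations.sum() == pytest.approx(
            rec.transition_times[-1] - rec.transition_times[0]
        )
        assert rec.transition_times[-1] <= traj.t_final
        assert np.all(rec.durations > 0)
        # states strictly alternate
        assert all(a != b for a, b in zip(rec.states, rec.states[1:]))

    def test_no_transition_warns_empty(self, toggle, toggle_regions):
        traj = gs.simulate_dssa(
            toggle, {"production": gs.make_kernel("fixed", 3.0)},
            t_max=50.0, seed=34, regions=toggle_regions, record_events=False,
        )
        with pytest.warns(UserWarning, match="never completed"):
            rec = residence_times(traj)
        assert rec.n_residences == 0

    def test_mean_consistent_across_independent_seeds(self, toggle, toggle_regions):
        """Pooled mean residence from two independent seeds agree within
        joint CLT bands (self-consistency of the measurement)."""
        kern = {"production": gs.make_kernel("gamma", 2.0, 1.5)}
        means, ses = [], []
        for seed in (35, 36):
            traj = gs.simulate_dssa(
                toggle, kern, t_max=np.inf, seed=seed, regions=toggle_regions,
                stop_after_entries=26, record_events=False, max_events=10**9,
            )
            d = residence_times(traj).to_frame(discard_first=True)["duration"]
            means.append(d.mean())
            ses.append(d.std(ddof=1) / np.sqrt(len(d)))
        assert abs(means[0] - means[1]) < 5 * np.hypot(*ses)


class TestAttemptParsing:
    def test_two_failed_then_success(self):
        """Symbol path H I H I H I L: two failed loops, one success, with
        the hand-traced waits and excursions."""
        tr = trace((0, 0), (2, 2), (3, 0), (7, 2), (9, 0), (14, 2), (15, 1))
        rec = attempt_statistics(tr, discard_first=False)
        df = rec.attempts
        assert list(df["outcome"]) == ["fail", "fail", "success"]
        assert list(df["wait"]) == [2.0, 4.0, 5.0]
        assert list(df["excursion"]) == [1.0, 2.0, 1.0]
        s = rec.summary()
        assert s["attempts_per_residency"] == 3.0
        assert s["expected_failures"] == 2.0

    def test_direct_success_has_no_failures(self):
        rec = attempt_statistics(trace((0, 0), (4, 2), (6, 1)), discard_first=False)
        s = rec.summary()
        assert s["n_failed"] == 0
        assert s["n_successful"] == 1

    def test_gap_crossings_do_not_create_attempts(self):
        # H -> gap -> H wandering without entering I is part of the wait
        tr = trace((0, 0), (1, 3), (2, 0), (5, 2), (6, 1))
        df = attempt_statistics(tr, discard_first=False).attempts
        assert len(df) == 1
        assert df["wait"].iloc[0] == 5.0

    def test_decomposition_identity_on_simulated_run(self, toggle, toggle_regions):
        """Attempts exactly partition each residency, so reconstructing the
        mean residence time from pooled attempt statistics must reproduce
        the directly measured mean."""
        traj = gs.simulate_dssa(
            toggle, {"production": gs.make_kernel("gamma", 2.0, 1.2)},
            t_max=np.inf, seed=37, regions=toggle_regions,
            stop_after_entries=10, record_events=False, max_events=10**9,
        )
        direct = residence_times(traj).to_frame(discard_first=True)["duration"].mean()
        est = attempt_statistics(traj).summary()["eq_residence_estimate"]
        assert est == pytest.approx(direct, rel=1e-9)

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(st.lists(st.sampled_from([0, 1, 2, 3]), min_size=2, max_size=60))
    def test_parser_invariants_on_random_symbol_paths(self, codes):
        """On arbitrary symbol sequences: waits/excursions are positive,
        every residency ends with at most one success, and failed counts
        are consistent with outcome labels."""
        import warnings

        times = np.cumsum(np.ones(len(codes)))
        tr = SymbolTrace(times, np.asarray(codes, dtype=np.int8))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)  # pathless sequences
            rec = attempt_statistics(tr, discard_first=False)
        df = rec.attempts
        if len(df):
            assert (df["wait"] > 0).all()
            assert (df["excursion"] > 0).all()
            assert set(df["outcome"]) <= {"fail", "success"}
            # at most one success per residency
            assert (
                df[df["outcome"] == "success"].groupby("residency").size() <= 1
            ).all()
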