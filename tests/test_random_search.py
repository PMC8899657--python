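import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oprars.gain_constraints import HAConfiguration
from oprars.objective import IntelligibilityResult, QuadraticTestObjective
from oprars.random_search import (DecaySchedule, accept_candidate,
                                  count_search_space, default_schedules,
                                  eq2_delta, eq3_delta, gen1_run, gen2_run,
                                  gen3_run)


class TestSchedules:
    def test_eq2_endpoints(self):
        s = default_schedules()["ig"]  # initial 10, stepsize 0.1
        assert eq2_delta(s, 0) == 10.0
        assert eq2_delta(s, 750) == pytest.approx(0.1)
        assert eq2_delta(s, 1) == pytest.approx(10 - 9.9 / 750)
        assert eq2_delta(default_schedules()["ct"], 750) == pytest.approx(1.0)

    def test_eq3_values(self):
        s = DecaySchedule(mode="eq3", half_range=15.0, initial_delta=15.0,
                          stepsize=1.0)
        assert eq3_delta(s, 749) == pytest.approx(0.0)
        assert eq3_delta(s, 750) == 0.0  # floored
        assert eq3_delta(s, 375) == pytest.approx(374 * 15 / 750)
        h = DecaySchedule(mode="eq3", half_range=7.0, initial_delta=7.0,
                          stepsize=0.1)
        assert eq3_delta(h, 1) == pytest.approx(748 * 7 / 750)

    def test_eq3_index_bounds(self):
        s = DecaySchedule(mode="eq3")
        with pytest.raises(IndexError):
            eq3_delta(s, 0)
        with pytest.raises(IndexError):
            eq3_delta(s, 751)

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(0, 749))
    def test_both_schedules_non_increasing(self, k):
        for sched in default_schedules("eq2").values():
            assert eq2_delta(sched, k + 1) <= eq2_delta(sched, k)
        for sched in default_schedules("eq3").values():
            if k >= 1:
                assert eq3_delta(sched, k + 1) <= eq3_delta(sched, k)


class TestAcceptance:
    @pytest.mark.parametrize("inc,cand,expect", [
        ((90.0, -1.0), (92.0, -5.0), True),   # higher score wins
        ((90.0, -1.0), (90.0, -0.5), True),   # likelihood tie-break
        ((90.0, -1.0), (90.0, -1.0), False),  # exact tie keeps incumbent
        ((90.0, -1.0), (88.0, 10.0), False),  # score dominates likelihood
    ])
    def test_rules(self, inc, cand, expect):
        assert accept_candidate(inc, cand) is expect


def _hidden_optimum(seed):
    rng = np.random.default_rng(seed)
    return np.concatenate([np.round(rng.uniform(25, 45, 5)),
                           np.round(rng.uniform(-8, 8, 5), 1)])


class TestRunners:
    def test_gen1_seeded_determinism(self):
        obj = QuadraticTestObjective(_hidden_optimum(5))
        a = gen1_run(obj, budget=40, seed=9)
        b = gen1_run(obj, budget=40, seed=9)
        assert a.trace_frame().equals(b.trace_frame())
        assert np.array_equal(a.best_config.params(), b.best_config.params())

    def test_gen1_budget_one_takes_best_init(self):
        obj = QuadraticTestObjective(_hidden_optimum(6))
        st_ = gen1_run(obj, budget=1, seed=2)
        df = st_.trace_frame()
        assert (df.iteration <= 1).all()
        init_best = max(
            (r for _, r in df[df.iteration == 0].iterrows()),
            key=lambda r: (r.score, r.likelihood))
        assert st_.best_result.score_percent >= init_best.score
        assert len(df[df.iteration == 0]) == 4

    @pytest.mark.parametrize("runner,kw,total", [
        (gen2_run, dict(per_channel_budget=150), 750),
        (gen3_run, dict(ct_budget=250, ig_budget=500), 750),
    ])
    def test_total_iteration_budget_is_750(self, runner, kw, total):
        obj = QuadraticTestObjective(_hidden_optimum(7))
        st_ = runner(obj, seed=1, **kw)
        assert st_.iteration == total

    def test_gen3_gains_pinned_during_ct_phase(self):
        obj = QuadraticTestObjective(_hidden_optimum(8))
        st_ = gen3_run(obj, ct_budget=30, ig_budget=40, seed=4)
        df = st_.trace_frame()
        phase1 = df[(df.channel_phase == 1) & (df.iteration >= 1)]
        dig_cols = [c for c in df.columns if c.startswith("dig_")]
        assert (phase1[dig_cols].to_numpy() == 0.0).all()

    def test_gen2_untuned_channels_hold_baseline(self):
        obj = QuadraticTestObjective(_hidden_optimum(9))
        st_ = gen2_run(obj, per_channel_budget=20, seed=4)
        df = st_.trace_frame()
        # while tuning channel 1, channels 2-5 stay at baseline (35, 0)
        ph1 = df[(df.channel_phase == 1) & (df.iteration >= 1)]
        for c in range(2, 6):
            assert (ph1[f"ct_{c}"] == 35.0).all()
            assert (ph1[f"dig_{c}"] == 0.0).all()

    def test_best_score_trace_non_decreasing(self):
        """Rollback guarantees a monotone best-so-far trajectory."""
        for runner, kw in [(gen1_run, dict(budget=60)),
                           (gen2_run, dict(per_channel_budget=12)),
                           (gen3_run, dict(ct_budget=20, ig_budget=40))]:
            obj = QuadraticTestObjective(_hidden_optimum(10))
            st_ = runner(obj, seed=3, **kw)
            df = st_.trace_frame()
            best = -np.inf
            for _, row in df[df.accepted].iterrows():
                assert row.score >= best - 1e-12
                best = max(best, row.score)

    def test_candidates_respect_global_ranges(self):
        obj = QuadraticTestObjective(_hidden_optimum(11))
        st_ = gen1_run(obj, budget=80, seed=5)
        df = st_.trace_frame()
        for c in range(1, 6):
            assert df[f"ct_{c}"].between(20, 50).all()
            assert df[f"dig_{c}"].between(-10, 10).all()
            # grid alignment
            assert np.allclose(df[f"ct_{c}"] % 1.0, 0.0)
            r = df[f"dig_{c}"].to_numpy() / 0.1
            assert np.allclose(r, np.round(r), atol=1e-6)

    def test_perturbations_stay_within_decayed_range(self):
        """Candidates lie within ±(Δ + stepsize/2) of the thread incumbent."""
        obj = QuadraticTestObjective(_hidden_optimum(12))
        sched = default_schedules("eq2", 50)
        st_ = gen1_run(obj, budget=50, seed=6, schedules=sched)
        df = st_.trace_frame()
        for t in range(4):
            sub = df[df.thread == t].reset_index(drop=True)
            inc = sub.iloc[0]
            for _, row in sub.iloc[1:].iterrows():
                i = int(row.iteration)
                d_ct = sched["ct"].delta(i) + 0.5
                d_ig = sched["ig"].delta(i) + 0.05
                for c in range(1, 6):
                    assert abs(row[f"ct_{c}"] - inc[f"ct_{c}"]) <= d_ct + 1e-9 \
                        or row[f"ct_{c}"] in (20.0, 50.0)
                    assert abs(row[f"dig_{c}"] - inc[f"dig_{c}"]) <= d_ig + 1e-9 \
                        or row[f"dig_{c}"] in (-10.0, 10.0)
                if row.accepted:
                    inc = row

    def test_search_matches_exhaustive_toy_enumeration(self):
        """One channel: gen1 does at least as well as brute force over a
        coarse 5-CT × 3-offset enumeration grid."""
        opt = np.array([37.0, 0.3])  # between the coarse grid points
        obj = QuadraticTestObjective(opt)
        cts = np.array([20.0, 27.0, 34.0, 41.0, 48.0])
        digs = np.array([-0.4, 0.0, 0.4])
        brute = max((obj(HAConfiguration(np.array([ct]), np.array([dg]))).key()
                     for ct in cts for dg in digs))
        st_ = gen1_run(obj, budget=300, seed=7, n_channels=1,
                       schedules=default_schedules("eq2", 300))
        assert obj(st_.best_config).key() >= brute

    def test_different_seeds_converge_to_correlated_gains(self):
        """Two independent runs recover strongly correlated offset vectors."""
        opt = _hidden_optimum(13)
        obj = QuadraticTestObjective(opt)
        a = gen1_run(obj, budget=400, seed=21,
                     schedules=default_schedules("eq2", 400))
        b = gen1_run(obj, budget=400, seed=22,
                     schedules=default_schedules("eq2", 400))
        r = np.corrcoef(a.best_config.dig, b.best_config.dig)[0, 1]
        assert r >= 0.9

    def test_objective_failure_aborts_with_context(self):
        def broken(cfg):
            raise FloatingPointError("simulated blow-up")
        from oprars.random_search import ObjectiveError
        with pytest.raises(ObjectiveError, match="ct="):
            gen1_run(broken, budget=5, seed=0)


class TestSearchSpace:
    def test_study_scale_count(self):
        assert count_search_space() == pytest.approx(7.776e18, rel=1e-6)

    def test_small_counts(self):
        from oprars.prescription import ChannelBank
        one = ChannelBank(edges_hz=[100, 700, 1400, 2800, 5600, 8000])
        assert count_search_space(ig_span=0.2, ig_step=0.1,
                                  ct_span=3, ct_step=1) == (2 * 3) ** 5

    def test_indivisible_span_rejected(self):
        with pytest.raises(ValueError):
            count_search_space(ig_span=20, ig_step=0.3)
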