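import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm

from conftest import make_session, make_trial, scored_trials
from tpsd.performance import (
    best_window_dprime,
    best_window_trials,
    classify_trial,
    dprime,
    lick_threshold_from_pretrial,
    outcome_rates,
    score_session,
    session_performance_frame,
    sessions_to_threshold,
)
from tpsd.simulate import naive_preset, simulate_session, wt_like
from tpsd.task import SessionConfig

# High-precision inverse-normal oracle values (scipy.stats.norm.ppf).
CLAMPED_EXTREME_DPRIME = 4.6526957480816815  # Phi^-1(0.99) - Phi^-1(0.01)
WT_EXPERT_DPRIME = 3.2950580339888242        # Phi^-1(0.995) - Phi^-1(0.236)


class TestClassifyTrial:
    cfg = SessionConfig()

    @pytest.mark.parametrize(
        "stype,licks,expected",
        [
            ("preferred", [1.3, 1.4], "Hit"),
            ("preferred", [0.2], "Miss"),
            ("preferred", [], "Miss"),
            ("nonpreferred", [0.4], "CR"),
            ("nonpreferred", [1.05], "FA"),
            ("nonpreferred", [2.0], "CR"),  # window is half-open at 2.0
        ],
    )
    def test_outcomes(self, stype, licks, expected):
        assert classify_trial(make_trial(1, stype, licks), self.cfg) == expected

    def test_criterion_above_one(self):
        t = make_trial(1, "preferred", [1.1, 1.3])
        assert classify_trial(t, self.cfg, criterion=3) == "Miss"
        assert classify_trial(t, self.cfg, criterion=2) == "Hit"

    def test_unsorted_licks_rejected(self):
        t = make_trial(1, "preferred", [1.0, 1.2])
        t.lick_times = np.array([1.2, 1.0])  # bypass constructor validation
        with pytest.raises(ValueError):
            classify_trial(t, self.cfg)


class TestDprime:
    def test_symmetry_point(self):
        assert dprime(0.5, 0.5) == 0.0

    def test_extreme_rates_clamped_to_99_and_1_percent(self):
        assert dprime(1.0, 0.0) == pytest.approx(CLAMPED_EXTREME_DPRIME, abs=1e-12)

    def test_expert_rates(self):
        assert dprime(0.995, 0.236) == pytest.approx(WT_EXPERT_DPRIME, abs=1e-12)

    def test_intermediate_rates_never_altered(self):
        # 0.999 is beyond the 99% clamp value but must pass through unchanged.
        assert dprime(0.999, 0.5) == pytest.approx(norm.ppf(0.999), abs=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            dprime(1.2, 0.5)
        with pytest.raises(ValueError):
            dprime(0.5, -0.1)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(a=st.floats(0, 1), b=st.floats(0, 1))
    def test_antisymmetry(self, a, b):
        assert dprime(a, b) == pytest.approx(-dprime(b, a), abs=1e-12)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        a=st.floats(0.011, 0.989), b=st.floats(0.011, 0.989),
        eps=st.floats(0.0005, 0.01),
    )
    def test_strict_monotonicity(self, a, b, eps):
        if a + eps < 0.99:
            assert dprime(a + eps, b) > dprime(a, b)
        if b + eps < 0.99:
            assert dprime(a, b + eps) < dprime(a, b)


def brute_force_best_window(trials, window):
    """Independent oracle: enumerate every window explicitly."""
    n = len(trials)
    w = min(window, n)
    best = None
    for s in range(n - w + 1):
        sub = trials[s : s + w]
        pref = [t for t in sub if t.stimulus_type == "preferred"]
        nonpref = [t for t in sub if t.stimulus_type == "nonpreferred"]
        if not pref or not nonpref:
            continue
        h = sum(t.outcome == "Hit" for t in pref) / len(pref)
        f = sum(t.outcome == "FA" for t in nonpref) / len(nonpref)
        d = dprime(h, f)
        if best is None or d > best[0]:
            best = (d, s + 1)
    return best


class TestBestWindow:
    def test_short_session_uses_whole_session(self):
        trials = scored_trials([("preferred", "Hit")] * 75 + [("nonpreferred", "CR")] * 75)
        perf = best_window_dprime(trials, window=150)
        assert perf.window_start == 1 and perf.window_length == 150
        assert perf.dprime == perf.session_dprime_full

    def test_perfect_first_half_then_chance(self, rng):
        first = scored_trials(
            [("preferred", "Hit")] * 100 + [("nonpreferred", "CR")] * 50)
        rng.shuffle(first)
        second = []
        for i in range(150):
            stype = "preferred" if rng.random() < 0.5 else "nonpreferred"
            respond = rng.random() < 0.5
            second.append((stype, ("Hit" if respond else "Miss")
                           if stype == "preferred" else ("FA" if respond else "CR")))
        trials = [make_trial(i + 1, s, [1.5] if o in ("Hit", "FA") else [], o)
                  for i, (s, o) in enumerate(
                      [(t.stimulus_type, t.outcome) for t in first] + second)]
        perf = best_window_dprime(trials, window=150)
        assert perf.window_start == 1
        assert perf.dprime == pytest.approx(CLAMPED_EXTREME_DPRIME)
        assert brute_force_best_window(trials, 150)[0] == pytest.approx(perf.dprime)

    def test_uniform_session_ties_break_to_earliest(self):
        block = [("preferred", "Hit"), ("nonpreferred", "FA")] * 100
        perf = best_window_dprime(scored_trials(block), window=150)
        assert perf.window_start == 1

    def test_single_stimulus_type_rejected(self):
        trials = scored_trials([("preferred", "Hit")] * 200)
        with pytest.raises(ValueError):
            best_window_dprime(trials)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_bruteforce_on_random_sessions(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(160, 400))
        specs = []
        for _ in range(n):
            stype = "preferred" if rng.random() < 0.7 else "nonpreferred"
            respond = rng.random() < (0.9 if stype == "preferred" else rng.uniform(0.2, 0.9))
            specs.append((stype, ("Hit" if respond else "Miss") if stype == "preferred"
                          else ("FA" if respond else "CR")))
        trials = scored_trials(specs)
        perf = best_window_dprime(trials, window=150)
        oracle = brute_force_best_window(trials, 150)
        assert perf.dprime == pytest.approx(oracle[0], abs=1e-12)
        assert perf.window_start == oracle[1]

    def test_best_window_trials_subset(self):
        trials = scored_trials(
            [("preferred", "Hit"), ("nonpreferred", "CR")] * 120)
        sub = best_window_trials(trials, window=150)
        assert len(sub) == 150
        assert sub[0] is trials[0]


class TestOutcomeRateConservation:
    def test_rates_sum_to_one(self, rng):
        rec = simulate_session("m", wt_like(), 3, SessionConfig(n_trials=300), rng)
        score_session(rec)
        r = outcome_rates(rec.trials)
        assert r.hit_rate + r.miss_rate == pytest.approx(1.0, abs=1e-12)
        assert r.cr_rate + r.fa_rate == pytest.approx(1.0, abs=1e-12)

    def test_degenerate_all_preferred_pretrial(self, rng):
        from tpsd.task import pretrial_config
        rec = simulate_session("m", wt_like(), 1, pretrial_config(50), rng)
        score_session(rec)
        r = outcome_rates(rec.trials)
        assert r.n_nonpreferred == 0
        assert r.hit_rate + r.miss_rate == pytest.approx(1.0)
        assert np.isnan(r.fa_rate) and np.isnan(r.cr_rate)


class TestSessionsToThreshold:
    @pytest.mark.parametrize(
        "curve,thr,expected",
        [([0.2, 0.8, 1.2], 1.0, 3), ([1.1, 0.4], 1.0, 1), ([0.9, 0.9], 1.0, None)],
    )
    def test_examples(self, curve, thr, expected):
        assert sessions_to_threshold(curve, thr) == expected

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            sessions_to_threshold([], 1.0)


class TestLickThreshold:
    def _pretrial(self, counts):
        specs = [("preferred", [1.0 + 0.06 * k for k in range(c)]) for c in counts]
        return make_session(specs, phase="pretrial")

    def test_zero_variance(self):
        assert lick_threshold_from_pretrial(self._pretrial([4, 4, 4, 4])).threshold == 4.0

    def test_sample_sd_with_n_minus_one(self):
        # counts [2, 4, 6]: mean 4, sample SD 2 -> threshold 2
        assert lick_threshold_from_pretrial(self._pretrial([2, 4, 6])).threshold == pytest.approx(2.0)

    def test_floored_at_zero(self):
        # counts [0, 1]: 0.5 - 0.7071... -> 0
        assert lick_threshold_from_pretrial(self._pretrial([0, 1])).threshold == 0.0

    def test_fewer_than_two_trials_rejected(self):
        with pytest.raises(ValueError):
            lick_threshold_from_pretrial(self._pretrial([3]))


class TestDprimeConvergence:
    def test_full_session_dprime_converges_to_analytic(self):
        # Large-n simulated session: d' -> Phi^-1(p_hit) - Phi^-1(p_fa).
        preset = dataclasses.replace(
            naive_preset(), p_hit_initial=0.9, p_hit_final=0.9,
            p_fa_initial=0.4, p_fa_final=0.4)
        cfg = SessionConfig(n_trials=10_000, preferred_fraction=0.5)
        rec = simulate_session("m", preset, 1, cfg, np.random.default_rng(77))
        score_session(rec)
        r = outcome_rates(rec.trials)
        expected = norm.ppf(0.9) - norm.ppf(0.4)
        assert dprime(r.hit_rate, r.fa_rate) == pytest.approx(expected, abs=0.05)


class TestPerformanceFrame:
    def test_frame_columns_and_pretrial_skipped(self, rng):
        from tpsd.task import pretrial_config
        sessions = [
            simulate_session("m1", wt_like(), 1, pretrial_config(20), rng),
            simulate_session("m1", wt_like(), 2, SessionConfig(n_trials=200), rng),
        ]
        df = session_performance_frame(sessions)
        assert list(df.columns) == [
            "mouse_id", "genotype", "session", "d_prime_best", "window_start",
            "hit_rate", "miss_rate", "cr_rate", "fa_rate", "d_prime_full"]
        assert df["session"].tolist() == [2]
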