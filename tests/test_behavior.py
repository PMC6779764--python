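"""Curvature index, start-time detection, and time-response curves."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from fitime.behavior import (
    curvature_index,
    detect_start_time,
    session_behavior_summary,
    time_response_histogram,
)

T = 12.0
METHODS = ["fry_discrete", "trapezoid_continuous"]

times_strategy = st.lists(
    st.floats(min_value=0.0, max_value=T, allow_nan=False), min_size=1, max_size=60
)


def brute_force_start(responses, T):
    """Independent oracle: evaluate D(s) at every candidate with plain loops."""
    t = sorted(responses)
    m = len(t)
    best_s, best_d = None, -np.inf
    for s in sorted({0.0, T, *t}):
        n1 = sum(1 for x in t if x < s)
        r = m / T
        r1 = n1 / s if s > 0 else 0.0
        r2 = (m - n1) / (T - s) if s < T else 0.0
        d = s * (r - r1) + (T - s) * (r2 - r)
        if d > best_d + 1e-12:
            best_d, best_s = d, s
    return best_s, best_d


class TestCurvature:
    @pytest.mark.parametrize("method", METHODS)
    @pytest.mark.parametrize("n", [4, 10, 1000])
    def test_constant_rate_gives_zero(self, method, n):
        """One press at the end of each equal segment = constant rate = 0."""
        t = np.arange(1, n + 1) * (T / n)
        res = curvature_index(t, T, n_segments=n, method=method)
        assert res.value == pytest.approx(0.0, abs=1e-12)

    def test_all_late_hand_evaluated(self):
        """All responses in the final segment: R1=R2=R3=0 gives 3/4 for n=4."""
        res = curvature_index([11.0, 11.2, 11.5], T, n_segments=4)
        assert res.value == pytest.approx(3 / 4)

    def test_all_early_hand_evaluated(self):
        """All responses at the start: R1=...=R4=m gives -3/4 for n=4."""
        res = curvature_index([0.01, 0.02, 0.03], T, n_segments=4)
        assert res.value == pytest.approx(-3 / 4)

    @pytest.mark.parametrize("method", METHODS)
    def test_rate_duplication_invariance(self, method):
        rng = np.random.default_rng(5)
        t = np.sort(rng.uniform(0, T, 40))
        a = curvature_index(t, T, method=method).value
        b = curvature_index(np.sort(np.tile(t, 3)), T, method=method).value
        assert b == pytest.approx(a, abs=1e-12)

    @pytest.mark.parametrize("method", METHODS)
    def test_time_rescaling_invariance(self, method):
        rng = np.random.default_rng(6)
        t = np.sort(rng.uniform(0, T, 30))
        a = curvature_index(t, T, method=method).value
        b = curvature_index(5.0 * t, 5.0 * T, method=method).value
        assert b == pytest.approx(a, abs=1e-9)

    @settings(derandomize=True, max_examples=150, deadline=None)
    @given(times=times_strategy, n=st.integers(2, 50))
    def test_bounds(self, times, n):
        fry = curvature_index(times, T, n_segments=n).value
        assert abs(fry) <= (n - 1) / n + 1e-12
        trap = curvature_index(times, T, method="trapezoid_continuous").value
        assert abs(trap) <= 1.0 + 1e-12

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(times=times_strategy, data=st.data())
    def test_moving_a_response_later_never_decreases_curvature(self, times, data):
        i = data.draw(st.integers(0, len(times) - 1))
        shift = data.draw(st.floats(0.0, T - times[i], allow_nan=False))
        moved = list(times)
        moved[i] = times[i] + shift
        for method in METHODS:
            before = curvature_index(times, T, method=method).value
            after = curvature_index(moved, T, method=method).value
            assert after >= before - 1e-9

    def test_discrete_and_continuous_agree_at_large_n(self):
        """Step-counting and polygon variants share the dense-record limit.

        They differ by O(1/n_responses), so agreement to 0.01 needs records
        of a few hundred responses as well as a fine segment grid.
        """
        rng = np.random.default_rng(7)
        for _ in range(50):
            t = np.sort(rng.uniform(0, T, rng.integers(300, 1000)))
            fry = curvature_index(t, T, n_segments=1000).value
            trap = curvature_index(t, T, method="trapezoid_continuous").value
            assert fry == pytest.approx(trap, abs=0.01)

    def test_zero_responses_flagged_undefined(self):
        res = curvature_index([], T)
        assert not res.defined and np.isnan(res.value)

    def test_invalid_inputs_raise(self):
        with pytest.raises(ValueError):
            curvature_index([1.0], T, n_segments=1)
        with pytest.raises(ValueError):
            curvature_index([13.0], T)


class TestStartDetection:
    def test_step_pattern_detects_first_high_press(self):
        res = detect_start_time([8.0, 8.5, 9.0, 9.5, 10.0], T)
        assert res.valid and res.start == pytest.approx(8.0)
        assert res.objective == pytest.approx(20 / 3)

    def test_too_few_responses_invalid(self):
        assert not detect_start_time([], T).valid
        assert not detect_start_time([5.0], T, r_min=2).valid

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(300):
            t = np.sort(rng.uniform(0, T, rng.integers(2, 30)))
            res = detect_start_time(t, T)
            s, d = brute_force_start(t, T)
            assert res.start == pytest.approx(s)
            assert res.objective == pytest.approx(d)

    def test_recovery_bias_and_rmse(self):
        """Bias < 0.25 s and RMSE < 1 s at a 20-fold rate ratio.

        The estimator returns a response time, so its bias is about one
        inter-press interval of the high state (1/rate_high); rates are
        chosen with rate_high fast enough for the stated bias bound.
        """
        rng = np.random.default_rng(99)
        rl, rh, n = 0.25, 5.0, 500
        errs = []
        for _ in range(n):
            s = float(np.clip(rng.normal(7.8, 1.0), 0.5, T - 0.5))
            lo = rng.uniform(0, s, rng.poisson(rl * s))
            hi = rng.uniform(s, T, rng.poisson(rh * (T - s)))
            res = detect_start_time(np.sort(np.concatenate([lo, hi])), T)
            if res.valid:
                errs.append(res.start - s)
        e = np.asarray(errs)
        assert abs(e.mean()) < 0.25
        assert np.sqrt((e**2).mean()) < 1.0

    def test_out_of_range_responses_raise(self):
        with pytest.raises(ValueError):
            detect_start_time([-1.0, 3.0], T)


class TestTimeResponseHistogram:
    @staticmethod
    def _trials(times_by_animal):
        rows = []
        for animal, tlists in times_by_animal.items():
            for i, tl in enumerate(tlists):
                rows.append(
                    {
                        "animal_id": animal,
                        "session_id": f"{animal}_s",
                        "trial_index": i,
                        "drug": "saline",
                        "stim": "NoStim",
                        "onset_s": 20.0 * i,
                        "iti_s": 6.0,
                        "reward_time_s": np.nan,
                        "trial_end_s": 12.0,
                        "true_start_s": np.nan,
                        "response_times": tl,
                    }
                )
        return pd.DataFrame(rows)

    def test_single_response_peaks_at_its_time(self):
        out = time_response_histogram(self._trials({"a": [[6.0]]}), T)
        curve = out["normalized"].loc["a"]
        assert curve.max() == pytest.approx(1.0)
        assert abs(curve.idxmax() - 6.0) <= 0.1

    def test_normalization_is_rate_invariant(self):
        base = [[2.0, 5.0, 9.0], [3.0, 7.0]]
        doubled = [[x for x in tl for _ in range(2)] for tl in base]
        out = time_response_histogram(
            self._trials({"a": base, "b": doubled}), T
        )
        assert np.allclose(
            out["normalized"].loc["a"], out["normalized"].loc["b"], atol=1e-12
        )

    def test_no_responses_flagged_not_divided(self):
        out = time_response_histogram(self._trials({"a": [[]]}), T)
        assert out["empty"] == ["a"]
        assert np.isnan(out["normalized"].loc["a"]).all()


class TestSummary:
    def test_scalloped_condition_has_positive_curvature(self):
        trials = TestTimeResponseHistogram._trials(
            {"a": [[9.0, 10.0, 11.0], [8.5, 10.5, 11.5]]}
        )
        s = session_behavior_summary(trials)
        assert len(s) == 1
        assert s["curvature"].iloc[0] > 0

    def test_start_means_follow_generative_ordering(self):
        from fitime.config import SimConfig
        from fitime.synthgen import simulate_behavior

        cfg = SimConfig(seed=3, n_animals=3, session_minutes=25.0, animal_start_sd=0.0)
        s = session_behavior_summary(simulate_behavior(cfg))
        g = s.groupby(["drug", "stim"])["mean_start_s"].mean()
        assert g[("muscimol", "20Hz")] > g[("muscimol", "NoStim")]

    def test_empty_cells_yield_missing_rows(self):
        trials = TestTimeResponseHistogram._trials({"a": [[]]})
        s = session_behavior_summary(trials)
        assert np.isnan(s["curvature"]).all()
        assert np.isnan(s["mean_start_s"]).all()
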