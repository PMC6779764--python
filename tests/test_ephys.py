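"""Waveform features, unit classification, binning, ramping, PETH."""

import numpy as np
import pandas as pd
import pytest

from fitime.config import SimConfig
from fitime.ephys import (
    WaveformError,
    bin_firing,
    build_peth,
    classify_units,
    extract_features,
    filter_units,
    fit_ramping,
)
from fitime.synthgen import SpikeUnit, simulate_waveforms, waveform_template, _spawn

from conftest import make_trials, poisson_unit

FS = 40000.0


class TestFeatures:
    @pytest.mark.parametrize("p2t,hw", [(0.6, 0.30), (0.25, 0.13), (0.8, 0.4)])
    def test_designed_features_recovered(self, p2t, hw):
        f = extract_features(waveform_template(p2t, hw, FS), FS)
        assert f.peak_to_trough_ms == pytest.approx(p2t, abs=1.0 / FS * 1e3)
        assert f.half_peak_width_ms == pytest.approx(hw, abs=0.03)

    def test_polarity_invariance(self):
        w = waveform_template(0.6, 0.3, FS)
        a = extract_features(w, FS)
        b = extract_features(-w, FS)
        assert a.peak_to_trough_ms == b.peak_to_trough_ms
        assert a.half_peak_width_ms == b.half_peak_width_ms

    def test_resampling_invariance(self):
        w = waveform_template(0.6, 0.3, FS)
        x = np.arange(w.size)
        w2 = np.interp(np.arange(0, w.size - 0.5, 0.5), x, w)
        a = extract_features(w, FS)
        b = extract_features(w2, 2 * FS)
        assert b.peak_to_trough_ms == pytest.approx(a.peak_to_trough_ms, abs=0.03)
        assert b.half_peak_width_ms == pytest.approx(a.half_peak_width_ms, abs=0.03)

    def test_flat_waveform_raises(self):
        with pytest.raises(WaveformError):
            extract_features(np.zeros(50), FS)


class TestClassification:
    @staticmethod
    def _features(n, seed):
        cfg = SimConfig(seed=seed)
        wf = simulate_waveforms(cfg, n, _spawn(seed, "wf"))
        feats = [
            extract_features(w, FS, f"u{i:03d}") for i, w in enumerate(wf["waveform"])
        ]
        return feats, wf["true_class"].to_numpy()

    def test_well_separated_classes_recovered(self):
        feats, truth = self._features(300, 21)
        out = classify_units(feats, seed=0)
        assert (out["klass"].to_numpy() == truth).mean() >= 0.99
        assert (out["posterior"] >= 0.5).all()

    def test_order_invariance(self):
        feats, _ = self._features(80, 22)
        a = classify_units(feats, seed=0).set_index("unit_id")["klass"]
        rng = np.random.default_rng(1)
        perm = rng.permutation(len(feats))
        b = classify_units([feats[i] for i in perm], seed=0).set_index("unit_id")["klass"]
        assert a.sort_index().equals(b.sort_index())

    def test_single_class_all_same_label(self):
        cfg = SimConfig(seed=4, frac_fsi=0.0)
        wf = simulate_waveforms(cfg, 60, _spawn(4, "wf"))
        feats = [extract_features(w, FS, f"u{i}") for i, w in enumerate(wf["waveform"])]
        out = classify_units(feats, seed=0)
        assert out["klass"].nunique() == 1
        assert out["klass"].iloc[0] == "MSN"


class TestFilter:
    def _unit(self, uid, rate):
        return SpikeUnit(uid, "s0", "a0", "saline", np.arange(5.0), np.zeros(8), FS, rate)

    def test_rate_threshold_is_strict(self):
        units = [self._unit("slow", 0.05), self._unit("edge", 0.1), self._unit("ok", 0.2)]
        classified = pd.DataFrame(
            {"unit_id": ["slow", "edge", "ok"], "klass": ["MSN"] * 3}
        )
        kept, report = filter_units(units, classified)
        assert [u.unit_id for u in kept] == ["ok"]
        assert report["n_below_rate"] == 2

    def test_class_filter_and_identity(self):
        units = [self._unit("a", 1.0), self._unit("b", 1.0)]
        classified = pd.DataFrame({"unit_id": ["a", "b"], "klass": ["MSN", "FSI"]})
        kept, report = filter_units(units, classified)
        assert [u.unit_id for u in kept] == ["a"] and report["n_other_class"] == 1
        kept_all, _ = filter_units(units, classified, klass=None)
        assert len(kept_all) == 2


class TestBinning:
    def test_half_open_bin_conventions(self):
        trials = make_trials(1)
        u = SpikeUnit("u", "s0", "a0", "saline", np.array([0.005, 12.0]), np.zeros(8), FS, 1.0)
        mat = bin_firing(u, trials, bin_s=0.01)
        assert mat[0, 0] == 1  # 0.005 s lands in bin 0
        assert mat.sum() == 1  # spike at exactly 12.0 s is outside [0, 12)

    def test_count_conservation_and_concatenation(self):
        rng = np.random.default_rng(3)
        trials = make_trials(20)
        u = poisson_unit(lambda t: 4.0 + 0 * t, 4.0, 20, rng)
        mat = bin_firing(u, trials, bin_s=0.01)
        assert mat.shape == (20, 1200)
        assert mat.sum() == u.spike_times.size  # iti=0 and end=12: all in-interval
        top = bin_firing(u, trials.iloc[:8], bin_s=0.01)
        bottom = bin_firing(u, trials.iloc[8:], bin_s=0.01)
        assert np.array_equal(np.vstack([top, bottom]), mat)

    def test_misaligned_spikes_raise(self):
        trials = make_trials(2)
        u = SpikeUnit("u", "s0", "a0", "saline", np.array([500.0]), np.zeros(8), FS, 1.0)
        with pytest.raises(ValueError):
            bin_firing(u, trials)


class TestRamping:
    def test_slope_matches_closed_form_oracle(self):
        rng = np.random.default_rng(8)
        trials = make_trials(15)
        u = poisson_unit(lambda t: 2.0 + 0.4 * t, 7.0, 15, rng)
        fit = fit_ramping(u, trials, bin_s=0.1)
        rates = bin_firing(u, trials, bin_s=0.1) / 0.1
        x = np.tile((np.arange(120) + 0.5) * 0.1, 15)
        y = rates.ravel()
        slope = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()
        assert fit.slope == pytest.approx(slope, rel=1e-10)

    def test_strong_ramp_detected_with_accurate_slope(self):
        rng = np.random.default_rng(9)
        trials = make_trials(60)
        u = poisson_unit(lambda t: 1.0 + 0.5 * t, 7.0, 60, rng)
        fit = fit_ramping(u, trials, bin_s=0.1)
        assert fit.is_ramping and fit.p_time < 1e-6
        assert fit.slope == pytest.approx(0.5, abs=0.06)

    def test_exactly_constant_rate_zero_slope(self):
        trials = make_trials(4)
        spikes = np.concatenate([k * 12.0 + np.arange(12) + 0.5 for k in range(4)])
        u = SpikeUnit("u", "s0", "a0", "saline", spikes, np.zeros(8), FS, 1.0)
        fit = fit_ramping(u, trials, bin_s=1.0)
        assert fit.slope == pytest.approx(0.0, abs=1e-12)
        assert not fit.is_ramping

    def test_silent_unit_convention(self):
        trials = make_trials(3)
        u = SpikeUnit("u", "s0", "a0", "saline", np.empty(0), np.zeros(8), FS, 0.0)
        fit = fit_ramping(u, trials)
        assert fit.slope == 0.0 and fit.p_time == 1.0 and not fit.is_ramping


class TestPeth:
    @staticmethod
    def _ramp_population(n_pos=8, n_neg=8, seed=30):
        rng = np.random.default_rng(seed)
        trials = make_trials(40)
        units = []
        for i in range(n_pos):
            units.append(poisson_unit(lambda t: 1.0 + 0.6 * t, 9.0, 40, rng, unit_id=f"pos{i}"))
        for i in range(n_neg):
            units.append(poisson_unit(lambda t: 8.0 - 0.6 * t, 9.0, 40, rng, unit_id=f"neg{i}"))
        return units, trials

    def test_ramp_population_pc1_dominates_and_sorts_by_sign(self):
        units, trials = self._ramp_population()
        out = build_peth(units, trials)
        assert out["explained_var_ratio"] > 0.9
        top = out["order"][:8]
        assert all(u.startswith("pos") for u in top)

    def test_sort_is_stable_under_unit_shuffling(self):
        units, trials = self._ramp_population(seed=31)
        out = build_peth(units, trials)
        rng = np.random.default_rng(0)
        shuffled = [units[i] for i in rng.permutation(len(units))]
        out2 = build_peth(shuffled, trials)
        assert out["order"] == out2["order"]

    def test_rows_are_zscored(self):
        units, trials = self._ramp_population(seed=32)
        out = build_peth(units, trials)
        means = out["matrix"].mean(axis=1)
        assert np.allclose(means, 0.0, atol=0.05)

    def test_zero_variance_unit_excluded_with_placeholder(self):
        units, trials = self._ramp_population(n_pos=3, n_neg=3, seed=33)
        silent = SpikeUnit("silent", "s0", "a0", "saline", np.empty(0), np.zeros(8), FS, 0.0)
        out = build_peth(units + [silent], trials)
        assert out["excluded"] == ["silent"]
        assert out["order"][-1] == "silent"
        assert (out["matrix"].loc["silent"] == 0).all()
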