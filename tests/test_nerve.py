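"""Spike detection, firing-rate change, unit matching, distension response."""

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from nocimap import nerve, simulate
from nocimap.nerve import SpikeTrain
from nocimap.simulate import Recording, UnitSpec


def _f1(detected, truth, tol_s=0.002):
    detected = np.asarray(detected)
    used = np.zeros(len(detected), dtype=bool)
    tp = 0
    for t in truth:
        if len(detected) == 0:
            break
        d = np.abs(detected - t)
        i = int(np.argmin(d))
        if d[i] <= tol_s and not used[i]:
            used[i] = True
            tp += 1
    fp = len(detected) - tp
    fn = len(truth) - tp
    return 2 * tp / max(2 * tp + fp + fn, 1)


class TestDetectSpikes:
    def test_noiseless_planted_spikes_found_exactly(self):
        rec, truth = simulate.simulate_recording(
            duration_s=10, units=[UnitSpec(100.0, 1.5, 1.5)], noise_uv=0.0,
            drug_window=(5, 10), seed=4,
        )
        train = nerve.detect_spikes(rec, threshold_uv=20.0)
        planted = truth["units"][0]["times_s"]
        assert len(train.times_s) == len(planted)
        for t in planted:
            assert np.min(np.abs(train.times_s - t)) <= 2e-4

    def test_pure_noise_false_rate_below_half_hz(self):
        rec, _ = simulate.simulate_recording(
            duration_s=60, units=[], noise_uv=15.0, drug_window=(30, 60), seed=3
        )
        train = nerve.detect_spikes(rec)
        assert len(train.times_s) / 60.0 < 0.5

    def test_f1_at_five_times_noise_rms(self):
        rec, truth = simulate.simulate_recording(
            duration_s=60, units=[UnitSpec(75.0, 1.0, 1.0)], noise_uv=15.0,
            drug_window=(30, 60), seed=2,
        )
        train = nerve.detect_spikes(rec)
        assert _f1(train.times_s, truth["units"][0]["times_s"]) >= 0.95

    def test_count_monotone_nonincreasing_in_threshold(self):
        rec, _ = simulate.simulate_recording(
            duration_s=20, units=[UnitSpec(100.0, 5.0, 5.0)], noise_uv=15.0,
            drug_window=(10, 20), seed=5,
        )
        counts = [
            len(nerve.detect_spikes(rec, threshold_uv=t).times_s)
            for t in (30.0, 50.0, 70.0, 90.0)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_zero_noise_without_threshold_rejected(self):
        rec = Recording(np.zeros(40_000), 20_000.0, (1.0, 2.0))
        with pytest.raises(ValueError):
            nerve.detect_spikes(rec)

    def test_event_gaps_respect_dead_time(self):
        rec, _ = simulate.simulate_recording(
            duration_s=30, units=[UnitSpec(120.0, 20.0, 20.0)], noise_uv=10.0,
            drug_window=(15, 30), seed=6,
        )
        train = nerve.detect_spikes(rec, dead_time_ms=2.0)
        assert (np.diff(train.times_s) >= 0.002 - 1e-12).all()


class TestRateAndPeakChange:
    def test_planted_step_recovered_within_one_hz(self):
        rec, _ = simulate.simulate_recording(
            duration_s=900, units=[UnitSpec(120.0, 2.0, 12.0)], noise_uv=12.0,
            drug_window=(600, 720), seed=9,
        )
        train = nerve.detect_spikes(rec, noise_window=(0, 300))
        _, pc = nerve.rate_and_peak_change(train, drug_onset_s=600)
        assert abs(pc.delta - 10.0) <= 1.0

    def test_null_poisson_bias_below_one_hz(self):
        rec, _ = simulate.simulate_recording(
            duration_s=900, units=[UnitSpec(120.0, 5.0, 5.0)], noise_uv=12.0,
            drug_window=(600, 720), seed=10,
        )
        train = nerve.detect_spikes(rec, noise_window=(0, 300))
        _, pc = nerve.rate_and_peak_change(train, drug_onset_s=600)
        assert abs(pc.delta) < 1.0

    def test_percent_change_arithmetic(self):
        pc = nerve.PeakChange(baseline_rate=4.0, peak_rate=6.0, peak_time_s=0.0)
        assert pc.percent_change == pytest.approx(50.0)

    def test_time_shift_leaves_delta_invariant(self):
        rng = np.random.default_rng(1)
        times = np.sort(rng.uniform(0, 900, 3000))
        train = SpikeTrain(times, np.ones_like(times), 50.0, 10.0, 900.0)
        shifted = SpikeTrain(times + 0.0, np.ones_like(times), 50.0, 10.0, 900.0)
        _, a = nerve.rate_and_peak_change(train, drug_onset_s=600)
        _, b = nerve.rate_and_peak_change(shifted, drug_onset_s=600)
        assert a.delta == pytest.approx(b.delta)

    def test_short_baseline_warns(self):
        times = np.sort(np.random.default_rng(0).uniform(0, 120, 500))
        train = SpikeTrain(times, np.ones_like(times), 50.0, 10.0, 120.0)
        with pytest.warns(UserWarning):
            nerve.rate_and_peak_change(train, drug_onset_s=60)


class TestConcentrationResponse:
    def test_identical_values_give_zero_sem(self):
        table, _ = nerve.concentration_response({1.0: [5.0, 5.0, 5.0]})
        assert table["sem"].iloc[0] == 0.0

    def test_empty_group_omitted_with_warning(self):
        with pytest.warns(UserWarning):
            table, _ = nerve.concentration_response({0.1: [], 1.0: [2.0, 3.0]})
        assert list(table["concentration"]) == [1.0]

    def test_hill_fit_recovers_ec50_within_factor_two(self):
        rng = np.random.default_rng(8)
        concs = [0.01, 0.03, 0.1, 0.3, 1.0, 3.0]
        data = {
            c: list(10.0 * c / (0.3 + c) + rng.normal(0, 0.5, 6)) for c in concs
        }
        _, fit = nerve.concentration_response(data, fit_hill=True)
        assert 0.15 <= fit["ec50"] <= 0.6
        assert 5.0 <= fit["emax"] <= 20.0

    def test_hill_with_single_concentration_rejected(self):
        with pytest.raises(ValueError):
            nerve.concentration_response({1.0: [2.0]}, fit_hill=True)


class TestMatchUnits:
    def test_single_unit_forms_one_cluster(self):
        rec, _ = simulate.simulate_recording(
            duration_s=30, units=[UnitSpec(150.0, 3.0, 3.0)], noise_uv=15.0,
            drug_window=(15, 30), seed=13,
        )
        train = nerve.detect_spikes(rec)
        ua = nerve.match_units(rec, train)
        assert ua.n_units == 1
        assert len(ua.labels) == len(nerve.extract_snippets(rec, train))

    def test_two_units_assigned_with_high_accuracy(self):
        rec, truth = simulate.simulate_recording(
            duration_s=60,
            units=[UnitSpec(225.0, 2.0, 2.0), UnitSpec(75.0, 2.0, 2.0)],
            noise_uv=15.0, drug_window=(30, 60), seed=12,
        )
        train = nerve.detect_spikes(rec)
        ua = nerve.match_units(rec, train)
        t1 = np.array(truth["units"][0]["times_s"])
        t2 = np.array(truth["units"][1]["times_s"])
        lab_true = np.array(
            [0 if np.min(np.abs(t1 - t)) < np.min(np.abs(t2 - t)) else 1
             for t in train.times_s]
        )
        k = max(ua.n_units, 2)
        conf = np.zeros((k, k))
        for a, b in zip(ua.labels, lab_true):
            conf[a, b] += 1
        r, c = linear_sum_assignment(-conf)
        assert conf[r, c].sum() / len(lab_true) >= 0.9

    def test_duplicate_templates_merged(self):
        # two "units" with identical waveforms must collapse to one
        rec, _ = simulate.simulate_recording(
            duration_s=30,
            units=[UnitSpec(150.0, 2.0, 2.0), UnitSpec(150.0, 2.0, 2.0)],
            noise_uv=12.0, drug_window=(15, 30), seed=14,
        )
        train = nerve.detect_spikes(rec)
        ua = nerve.match_units(rec, train)
        assert ua.n_units == 1

    def test_too_few_events_rejected(self):
        rec, _ = simulate.simulate_recording(
            duration_s=2, units=[UnitSpec(150.0, 1.0, 1.0)], noise_uv=10.0,
            drug_window=(1, 2), seed=15,
        )
        train = nerve.detect_spikes(rec)
        if len(train.times_s) < 10:
            with pytest.raises(ValueError):
                nerve.match_units(rec, train)


class TestDistensionResponse:
    @staticmethod
    def _pressure(fs=1000.0, duration=120.0):
        t = np.arange(int(duration * fs)) / fs
        p = np.interp(t, [0, 30, 90, 120], [0, 0, 60, 0])
        return p, fs

    def test_flat_rate_not_responsive(self):
        p, fs = self._pressure()
        rng = np.random.default_rng(0)
        times = np.sort(rng.uniform(0, 120, 240))
        train = SpikeTrain(times, np.ones_like(times), 50.0, 10.0, 120.0)
        out = nerve.distension_response(train, p, fs)
        assert not out["responsive"]

    def test_planted_rate_increase_detected(self):
        p, fs = self._pressure()
        above = p > 20.0
        t_axis = np.arange(len(p)) / fs
        rng = np.random.default_rng(1)
        lo = np.sort(rng.uniform(0, 120, 240))
        lo = lo[~above[(lo * fs).astype(int)]]  # 2 Hz below threshold
        hi_span = t_axis[above]
        hi = np.sort(rng.uniform(hi_span[0], hi_span[-1], int(8 * (hi_span[-1] - hi_span[0]))))
        times = np.unique(np.concatenate([lo, hi]))
        train = SpikeTrain(times, np.ones_like(times), 50.0, 10.0, 120.0)
        out = nerve.distension_response(train, p, fs)
        assert out["responsive"]
        assert out["rate_above_hz"] > out["rate_below_hz"]

    def test_subthreshold_ramp_rejected(self):
        p, fs = self._pressure()
        times = np.sort(np.random.default_rng(2).uniform(0, 120, 100))
        train = SpikeTrain(times, np.ones_like(times), 50.0, 10.0, 120.0)
        with pytest.raises(ValueError):
            nerve.distension_response(train, 0.25 * p, fs, pressure_threshold=20.0)
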