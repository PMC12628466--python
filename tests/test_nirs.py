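"""NIRS reduction: optode averaging, window means against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from erythroflux.errors import DegenerateInputError, ProtocolError
from erythroflux.nirs import (
    WINDOW_S,
    baseline_value,
    decile_bins,
    exercise_summary,
    occlusion_summary,
    optode_average,
    recovery_values,
)
from erythroflux.synthetic import NirsKinetics, NirsTrace, generate_nirs_trace

from oracles import optode_mean_oracle, window_mean_oracle


def make_trace(rest_s=300.0, work_s=600.0, rec_s=180.0, fill=0.0, n_optodes=3):
    total = rest_s + work_s + rec_s
    n = int(round(total * 10)) + 1
    t = np.arange(n) / 10.0
    sig = np.full((n_optodes, n), float(fill))
    marks = {
        "rest": (0.0, rest_s),
        "work": (rest_s, rest_s + work_s),
        "recovery": (rest_s + work_s, total),
    }
    return t, sig, marks


def trace_from(t, o2hb, hhb, marks):
    return NirsTrace(time_s=t, o2hb=o2hb, hhb=hhb, phase_marks=marks)


class TestOptodeAverage:
    def test_identical_optodes_pass_through(self):
        t, sig, marks = make_trace(fill=7.0)
        tr = optode_average(trace_from(t, sig, sig, marks))
        assert tr.n_optodes == 1
        assert np.all(tr.o2hb == 7.0)

    def test_mean_of_1_2_3_is_2(self):
        t, sig, marks = make_trace()
        sig = sig.copy()
        sig[0], sig[1], sig[2] = 1.0, 2.0, 3.0
        tr = optode_average(trace_from(t, sig, sig, marks))
        assert np.all(tr.hhb == 2.0)

    def test_random_trace_matches_loop_oracle(self, rng):
        t, _, marks = make_trace(work_s=120.0)
        o2 = rng.normal(20, 3, (3, t.size))
        hh = rng.normal(15, 3, (3, t.size))
        tr = optode_average(trace_from(t, o2, hh, marks))
        want = optode_mean_oracle([list(row) for row in hh])
        assert np.allclose(tr.hhb[0], want)


class TestBaseline:
    def test_constant_rest_returns_constant(self):
        t, sig, marks = make_trace(fill=4.5)
        assert baseline_value(trace_from(t, sig, sig, marks))["o2hb"] == pytest.approx(4.5)

    def test_window_isolates_last_30s(self):
        t, sig, marks = make_trace()
        hh = sig.copy()
        hh[:, (t > 270.0) & (t <= 300.0)] = 8.0
        out = baseline_value(trace_from(t, sig, hh, marks))
        assert out["hhb"] == pytest.approx(8.0)
        assert out["o2hb"] == pytest.approx(0.0)

    def test_linear_ramp_matches_analytic_window_mean(self):
        t, sig, marks = make_trace()
        ramp = np.tile(0.1 * t, (3, 1))  # 0.1 uM/s over the whole trace
        out = baseline_value(trace_from(t, ramp, ramp, marks))
        window = t[(t > 300.0 - WINDOW_S) & (t <= 300.0)]
        assert out["o2hb"] == pytest.approx(0.1 * window.mean())

    def test_short_rest_rejected(self):
        t, sig, marks = make_trace(rest_s=20.0)
        with pytest.raises(ProtocolError):
            baseline_value(trace_from(t, sig, sig, marks))


class TestDecileBins:
    def test_constant_signal_gives_ten_constant_bins(self):
        t, sig, marks = make_trace(fill=3.0)
        bins = decile_bins(trace_from(t, sig, sig, marks))
        assert bins["hhb"].shape == (10,)
        assert np.allclose(bins["hhb"], 3.0)

    def test_linear_ramp_matches_bruteforce_windows(self):
        """A 0->10 uM HHb ramp over 600 s: each bin equals the loop-oracle mean."""
        t, sig, marks = make_trace(work_s=600.0)
        work = (t >= 300.0) & (t < 900.0)
        hh = sig.copy()
        hh[:, work] = 10.0 * (t[work] - 300.0) / 600.0
        hh[:, t >= 900.0] = 10.0
        tr = trace_from(t, sig, hh, marks)
        bins = decile_bins(tr)
        for k in range(1, 11):
            anchor = 300.0 + k * 60.0
            want = window_mean_oracle(t, hh[0], anchor - 30.0, anchor)
            assert bins["hhb"][k - 1] == pytest.approx(want, abs=1e-12)

    @pytest.mark.parametrize("work_s", [480.0, 613.7, 900.0])
    def test_variable_duration_always_ten_bins(self, work_s):
        t, sig, marks = make_trace(work_s=work_s)
        bins = decile_bins(trace_from(t, sig, sig, marks))
        assert all(v.shape == (10,) for v in bins.values())

    def test_too_short_exercise_rejected(self):
        tr = generate_nirs_trace(70.0, seed=0)
        marks = dict(tr.phase_marks)
        marks["work"] = (300.0, 350.0)
        marks["recovery"] = (350.0, tr.phase_marks["recovery"][1])
        short = NirsTrace(
            time_s=tr.time_s, o2hb=tr.o2hb, hhb=tr.hhb, phase_marks=marks
        )
        with pytest.raises(ProtocolError):
            decile_bins(short)

    @given(st.integers(0, 2**31 - 1))
    def test_every_bin_equals_its_bruteforce_window(self, seed):
        """Property: summary values are exactly brute-force means on random traces."""
        tr = optode_average(generate_nirs_trace(480.0, seed=seed))
        bins = decile_bins(tr)
        base = baseline_value(tr)
        assert base["hhb"] == pytest.approx(
            window_mean_oracle(tr.time_s, tr.hhb[0], 270.0, 300.0), abs=1e-9
        )
        for k in range(1, 11):
            anchor = 300.0 + k * 48.0
            want = window_mean_oracle(tr.time_s, tr.hhb[0], anchor - 30.0, anchor)
            assert bins["hhb"][k - 1] == pytest.approx(want, abs=1e-9)


class TestRecoveryAndSummaries:
    def test_step_recovery_returns_step_level(self):
        t, sig, marks = make_trace()
        hh = sig.copy()
        hh[:, t >= 900.0] = 6.0
        out = recovery_values(trace_from(t, sig, hh, marks))
        assert np.allclose(out["hhb"], 6.0)

    def test_recovery_anchor_times(self, rng):
        tr = optode_average(generate_nirs_trace(600.0, seed=13))
        out = recovery_values(tr)
        work_end = tr.phase_marks["work"][1]
        for i, dt in enumerate((60.0, 90.0, 120.0)):
            want = window_mean_oracle(
                tr.time_s, tr.o2hb[0], work_end + dt - 30.0, work_end + dt
            )
            assert out["o2hb"][i] == pytest.approx(want, abs=1e-9)

    def test_thb_equals_sum_of_signal_summaries(self):
        tr = generate_nirs_trace(540.0, seed=17)
        summary = exercise_summary(tr)
        assert np.allclose(
            summary.bins["thb"], summary.bins["o2hb"] + summary.bins["hhb"]
        )
        assert summary.baseline["thb"] == pytest.approx(
            summary.baseline["o2hb"] + summary.baseline["hhb"]
        )

    def test_offset_invariance_of_summaries(self):
        tr = generate_nirs_trace(480.0, seed=23)
        shifted = NirsTrace(
            time_s=tr.time_s, o2hb=tr.o2hb + 5.0, hhb=tr.hhb + 5.0,
            phase_marks=tr.phase_marks,
        )
        a, b = exercise_summary(tr), exercise_summary(shifted)
        assert np.allclose(b.bins["hhb"], a.bins["hhb"] + 5.0)
        assert b.baseline["o2hb"] == pytest.approx(a.baseline["o2hb"] + 5.0)


class TestOcclusion:
    def test_constant_signal_all_values_equal(self):
        tr = generate_nirs_trace(
            300.0, phase="occlusion",
            kinetics=NirsKinetics(noise_sd=0.0, o2hb_drop=0.0, hhb_rise=0.0),
            seed=0,
        )
        s = occlusion_summary(tr)
        assert np.allclose(s.bins["hhb"], s.baseline["hhb"])
        assert np.allclose(s.recovery["hhb"], s.baseline["hhb"])

    def test_monotone_drift_gives_monotone_minutes(self):
        tr = generate_nirs_trace(
            300.0, phase="occlusion", kinetics=NirsKinetics(noise_sd=0.0), seed=0
        )
        s = occlusion_summary(tr)
        assert s.bins["hhb"].shape == (5,)
        assert np.all(np.diff(s.bins["hhb"]) > 0)
        assert np.all(np.diff(s.bins["o2hb"]) < 0)

    def test_protocol_length_mismatch_rejected(self):
        tr = generate_nirs_trace(420.0, phase="occlusion", seed=0)  # 7 min occlusion
        with pytest.raises(ProtocolError):
            occlusion_summary(tr)
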