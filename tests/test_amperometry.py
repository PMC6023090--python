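"""Step segmentation, exponential-rise fits, calibration and selectivity."""

import math

import numpy as np
import pytest

from ampersense import (
    AmperogramTrace,
    AmpTruth,
    InjectionSchedule,
    simulate_amperometry,
)
from ampersense.amperometry import (
    LN20,
    StepSegment,
    build_calibration,
    fit_step,
    response_time,
    segment_steps,
    selectivity_profile,
    StepFit,
)
from ampersense.errors import CalibrationError, ScheduleError


def _trace(n_steps=5, interval=60.0, start=60.0, duration=None, **truth_kw):
    truth = AmpTruth(**{"noise_sigma": 0.0, "drift": 0.0, **truth_kw})
    schedule = InjectionSchedule.uniform(start, interval, n_steps, 1e-4)
    duration = duration or start + n_steps * interval + interval
    return simulate_amperometry(truth, schedule, duration, sample_rate=10.0), truth


class TestSegmentSteps:
    def test_five_injections_five_segments(self):
        trace, _ = _trace(n_steps=5, interval=60.0, start=60.0, duration=360.0)
        segments = segment_steps(trace)
        assert len(segments) == 5
        assert [s.t_start for s in segments] == list(trace.schedule.times)
        # cumulative concentrations label the segments
        assert segments[-1].conc_after == pytest.approx(5e-4)

    def test_boundaries_match_schedule_exactly(self):
        trace, _ = _trace(n_steps=4)
        segments = segment_steps(trace)
        for seg, t0 in zip(segments, trace.schedule.times):
            assert seg.time[0] >= t0
            assert seg.time[0] - t0 < 0.11

    def test_event_beyond_trace_rejected(self):
        trace, _ = _trace(n_steps=3)
        bad = InjectionSchedule.uniform(60.0, 60.0, 3, 1e-4)
        clipped = AmperogramTrace(
            time=trace.time[:500], current=trace.current[:500], schedule=bad
        )
        with pytest.raises(ScheduleError):
            segment_steps(clipped)


class TestFitStep:
    def test_noiseless_rise_recovers_tau_and_t95(self):
        """i(t) = 2 uA + 5 uA (1 - exp(-t/2.44)) fits to tau=2.44, t95=7.31 s."""
        t = np.arange(0.0, 60.0, 0.1)
        i = 2e-6 + 5e-6 * (1.0 - np.exp(-t / 2.44))
        seg = StepSegment(t, i, 0.0, 0.0, 1e-4, "histamine")
        fit = fit_step(seg)
        assert fit.converged and not fit.null_step
        assert fit.tau == pytest.approx(2.44, rel=1e-4)
        assert fit.t95 == pytest.approx(7.31, abs=0.01)
        assert fit.t95 / fit.tau == pytest.approx(LN20)
        assert fit.delta_i_ss == pytest.approx(5e-6, rel=1e-4)

    def test_flat_segment_is_null_step(self):
        rng = np.random.default_rng(0)
        t = np.arange(0.0, 30.0, 0.1)
        seg = StepSegment(t, 2e-6 + rng.normal(0, 1e-8, len(t)), 0.0, 0.0, 1e-4, "histamine")
        fit = fit_step(seg)
        assert fit.null_step

    def test_too_short_segment_rejected(self):
        t = np.arange(0.0, 1.0, 0.1)
        seg = StepSegment(t, np.ones_like(t), 0.0, 0.0, 1e-4, "histamine")
        with pytest.raises(CalibrationError):
            fit_step(seg)

    def test_noisy_tau_recovery_in_median(self):
        """Across seeds the median fitted tau stays within 10% of truth."""
        taus = []
        for seed in range(40):
            truth = AmpTruth(noise_sigma=0.05e-6, drift=0.0)
            schedule = InjectionSchedule.uniform(30.0, 60.0, 1, 1e-4)
            trace = simulate_amperometry(truth, schedule, 120.0, 10.0, seed=seed)
            fit = fit_step(segment_steps(trace)[0])
            if fit.converged:
                taus.append(fit.tau)
        assert abs(np.median(taus) - 2.44) / 2.44 < 0.10


class TestResponseTime:
    @staticmethod
    def _fit(t95, conc=1e-4):
        tau = t95 / LN20
        return StepFit(0.0, 1e-6, tau, t95, 0.99, conc)

    def test_mean_and_sd_of_first_three(self):
        mean, sd = response_time([self._fit(4.0), self._fit(5.0), self._fit(6.0)])
        assert mean == pytest.approx(5.0)
        assert sd == pytest.approx(1.0)

    def test_identical_values_zero_sd(self):
        mean, sd = response_time([self._fit(5.0)] * 3)
        assert sd == 0.0

    def test_too_few_fits_rejected(self):
        with pytest.raises(CalibrationError):
            response_time([self._fit(4.0), self._fit(5.0)], k=3)


class TestBuildCalibration:
    def test_noiseless_staircase_recovers_sensitivity(self):
        trace, truth = _trace(n_steps=8)
        cal = build_calibration(trace)
        assert cal.sensitivity == pytest.approx(truth.sensitivity, rel=0.03)
        assert cal.blank_sigma == pytest.approx(0.0, abs=1e-12)
        assert cal.lod == pytest.approx(0.0, abs=1e-12)
        assert cal.t95_mean == pytest.approx(truth.tau * LN20, rel=0.05)

    def test_noisy_staircase_lod_near_3sigma_over_slope(self):
        truth = AmpTruth()  # default noise 0.0903 uA, slope 23.3 uA/mM
        schedule = InjectionSchedule.uniform(120.0, 60.0, 10, 1e-4)
        trace = simulate_amperometry(truth, schedule, 840.0, 10.0, seed=3)
        cal = build_calibration(trace)
        assert cal.sensitivity == pytest.approx(truth.sensitivity, rel=0.10)
        assert cal.lod == pytest.approx(3 * truth.noise_sigma / truth.sensitivity, rel=0.35)

    def test_hard_saturation_caps_linear_range(self):
        """A staircase that bends flat above 1.6 mM reports an upper bound <= 1.6 mM."""
        trace, truth = _trace(n_steps=24, c_sat=1.6e-3)
        # flatten the response completely above c_sat to mimic full saturation
        t_sat = trace.schedule.times[15]  # 16th injection reaches 1.6 mM
        i = trace.current.copy()
        cap = i[np.searchsorted(trace.time, t_sat + 50.0)]
        mask = trace.time > t_sat + 50.0
        i[mask] = cap
        flat = AmperogramTrace(trace.time, i, trace.schedule, trace.sample_rate)
        cal = build_calibration(flat)
        assert cal.linear_range[1] <= 1.6e-3 + 1e-9

    def test_time_shift_invariance(self):
        trace, _ = _trace(n_steps=6)
        shifted = AmperogramTrace(
            trace.time + 500.0,
            trace.current,
            InjectionSchedule(
                tuple(
                    type(e)(e.time + 500.0, e.analyte, e.delta_conc)
                    for e in trace.schedule.events
                )
            ),
            trace.sample_rate,
        )
        c1 = build_calibration(trace)
        c2 = build_calibration(shifted)
        assert c2.sensitivity == pytest.approx(c1.sensitivity, rel=1e-9)
        assert c2.lod == pytest.approx(c1.lod, abs=1e-15)

    def test_degenerate_currents_rejected(self):
        schedule = InjectionSchedule.uniform(60.0, 60.0, 4, 1e-4)
        t = np.arange(0.0, 330.0, 0.1)
        flat = AmperogramTrace(t, np.full_like(t, 2e-6), schedule, 10.0)
        with pytest.raises(CalibrationError):
            build_calibration(flat)


class TestSelectivity:
    @staticmethod
    def _cal(sens):
        from ampersense.amperometry import Calibration

        return Calibration(
            points=((1e-4, sens * 1e-4),), sensitivity=sens, intercept=0.0,
            r_squared=1.0, linear_range=(1e-4, 1e-3), lod=1e-5, blank_sigma=1e-8,
            t95_mean=5.0, t95_sd=0.5,
        )

    def test_normalization_to_histamine(self):
        rel = selectivity_profile(
            {"histamine": self._cal(0.030), "putrescine": self._cal(0.015),
             "cadaverine": self._cal(0.006)}
        )
        assert rel == pytest.approx({"histamine": 1.0, "putrescine": 0.5, "cadaverine": 0.2})
        assert list(rel) == ["histamine", "putrescine", "cadaverine"]  # descending order

    def test_single_analyte(self):
        assert selectivity_profile({"histamine": self._cal(0.02)}) == {"histamine": 1.0}

    def test_missing_histamine_rejected(self):
        with pytest.raises(CalibrationError):
            selectivity_profile({"putrescine": self._cal(0.02)})

    def test_four_analyte_ordering_preserved(self):
        rel = selectivity_profile(
            {"histamine": self._cal(0.030), "putrescine": self._cal(0.015),
             "cadaverine": self._cal(0.006), "tyrosine": self._cal(0.006)}
        )
        order = list(rel)
        assert order[0] == "histamine" and order[1] == "putrescine"
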