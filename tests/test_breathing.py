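"""Breathing curves: sinusoid generation, phase assignment, gating, file formats."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import transitqa as tq
from transitqa.breathing import cyclic_distance
from transitqa.errors import DegenerateTraceError, FormatError, InvalidArgumentError


def _phase_err(a, b):
    return np.max(cyclic_distance(a, b))


class TestMakeSinusoid:
    @pytest.mark.parametrize(
        "t, pos, phase",
        [
            (0.0, 1.0, 0.0),  # cosine maximum = inhalation peak
            (2.0, -1.0, 50.0),  # trough at half period = exhalation
            (1.0, 0.0, 25.0),
        ],
    )
    def test_analytic_samples(self, t, pos, phase):
        c = tq.make_sinusoid(4.0, 2.0, 12.0, dt=0.5)
        i = int(round(t / 0.5))
        assert c.positions[i] == pytest.approx(pos, abs=1e-12)
        assert c.phases[i] == pytest.approx(phase, abs=1e-9)

    def test_invalid_arguments(self):
        with pytest.raises(InvalidArgumentError):
            tq.make_sinusoid(0.0, 2.0, 12.0)
        with pytest.raises(InvalidArgumentError):
            tq.make_sinusoid(4.0, 2.0, 12.0, dt=0.0)
        with pytest.raises(InvalidArgumentError):
            tq.make_sinusoid(4.0, 2.0, 2.0)  # shorter than one period

    def test_curve_invariants_enforced(self):
        with pytest.raises(InvalidArgumentError):
            tq.BreathingCurve([0.0, 0.1, 0.3], [0.0, 1.0, 0.0])  # non-uniform
        with pytest.raises(InvalidArgumentError):
            tq.BreathingCurve([0.0, 0.1], [0.0, np.nan])
        with pytest.raises(InvalidArgumentError):
            tq.BreathingCurve([0.0, 0.1], [0.0, 1.0], phases=[0.0, 100.0])


class TestAssignPhases:
    def test_recovers_analytic_sinusoid_phase(self):
        ref = tq.make_sinusoid(4.0, 2.0, 30.0)
        rec = tq.assign_phases(tq.BreathingCurve(ref.times, ref.positions))
        one_sample = 100.0 * ref.dt / 4.0
        assert _phase_err(rec.phases, ref.phases) <= one_sample

    def test_idempotent_up_to_one_sample(self):
        ref = tq.make_sinusoid(3.5, 1.0, 21.0)
        once = tq.assign_phases(tq.BreathingCurve(ref.times, ref.positions))
        twice = tq.assign_phases(once)
        assert _phase_err(once.phases, twice.phases) <= 100.0 * ref.dt / 3.5

    def test_endpoint_peaks_define_phase_zero(self):
        # exactly two peaks, both at the trace boundaries
        c = tq.make_sinusoid(4.0, 2.0, 4.0)
        rec = tq.assign_phases(tq.BreathingCurve(c.times, c.positions))
        one_sample = 100.0 * c.dt / 4.0
        assert cyclic_distance(rec.phases[0], 0.0) <= one_sample
        assert cyclic_distance(rec.phases[-1], 0.0) <= one_sample

    def test_constant_trace_is_degenerate(self):
        t = np.arange(100) / 30.0
        with pytest.raises(DegenerateTraceError):
            tq.assign_phases(tq.BreathingCurve(t, np.zeros(100)))

    def test_noisy_trace_phase_stays_close(self, rng):
        ref = tq.make_sinusoid(4.0, 2.0, 40.0)
        noisy = ref.positions + rng.normal(0.0, 0.0359, ref.n)
        rec = tq.assign_phases(tq.BreathingCurve(ref.times, noisy))
        # sub-sample peak refinement keeps phase error well under 5%
        assert _phase_err(rec.phases, ref.phases) < 5.0

    def test_offset_invariance(self):
        ref = tq.make_sinusoid(4.0, 2.0, 20.0)
        base = tq.assign_phases(tq.BreathingCurve(ref.times, ref.positions))
        shifted = tq.assign_phases(
            tq.BreathingCurve(ref.times, ref.positions + 3.7)
        )
        w = tq.GatingWindow(50.0, 10.0)
        assert np.array_equal(tq.gating_mask(base, w), tq.gating_mask(shifted, w))


class TestGatingWindow:
    def test_bounds_constructor(self):
        w = tq.GatingWindow.from_bounds(40.0, 60.0)
        assert (w.center, w.half_width) == (50.0, 10.0)
        w = tq.GatingWindow.from_bounds(95.0, 5.0)  # wraps through 0
        assert (w.center, w.half_width) == (0.0, 5.0)

    def test_validation(self):
        with pytest.raises(InvalidArgumentError):
            tq.GatingWindow(100.0, 10.0)
        with pytest.raises(InvalidArgumentError):
            tq.GatingWindow(50.0, 0.0)
        with pytest.raises(InvalidArgumentError):
            tq.GatingWindow(50.0, 60.0)

    def test_mask_40_60_selects_trough_interval(self, sin_curve):
        m = tq.gating_mask(sin_curve, tq.GatingWindow(50.0, 10.0))
        tmod = sin_curve.times % 4.0
        expected = (tmod >= 1.6 - 1e-9) & (tmod <= 2.4 + 1e-9)
        assert np.array_equal(m, expected)

    def test_full_cycle_window_gates_everything(self, sin_curve):
        assert tq.gating_mask(sin_curve, tq.GatingWindow(50.0, 50.0)).all()

    def test_wraparound_window(self, sin_curve):
        m = tq.gating_mask(sin_curve, tq.GatingWindow(0.0, 5.0))
        ph = sin_curve.phases
        expected = (ph >= 95.0 - 1e-9) | (ph <= 5.0 + 1e-9)
        assert np.array_equal(m, expected)

    def test_mask_requires_phases(self, sin_curve):
        bare = tq.BreathingCurve(sin_curve.times, sin_curve.positions)
        with pytest.raises(InvalidArgumentError):
            tq.gating_mask(bare, tq.GatingWindow(50.0, 10.0))


class TestDutyCycle:
    @pytest.mark.parametrize(
        "window, expected",
        [((50.0, 10.0), 0.20), ((50.0, 20.0), 0.40), ((50.0, 50.0), 1.0)],
    )
    def test_sinusoid_duty_cycle(self, sin_curve, window, expected):
        # phase is uniform in time for a sinusoid, so duty = window span / 100;
        # closed window boundaries admit one extra sample per breathing cycle
        one_sample_per_cycle = sin_curve.dt / 4.0
        dc = tq.duty_cycle(sin_curve, tq.GatingWindow(*window))
        assert abs(dc - expected) <= one_sample_per_cycle + 2.0 / sin_curve.n

    @given(
        hw1=st.floats(1.0, 50.0),
        hw2=st.floats(1.0, 50.0),
        center=st.floats(0.0, 99.0),
    )
    def test_monotone_in_half_width(self, hw1, hw2, center):
        curve = tq.make_sinusoid(4.0, 2.0, 12.0)
        lo, hi = sorted((hw1, hw2))
        assert tq.duty_cycle(curve, tq.GatingWindow(center, lo)) <= tq.duty_cycle(
            curve, tq.GatingWindow(center, hi)
        )


class TestTraceIO:
    def test_csv_round_trip(self, tmp_path, sin_curve):
        p = tmp_path / "trace.csv"
        tq.write_breathing_csv(sin_curve, p)
        back = tq.read_breathing_csv(p)
        np.testing.assert_allclose(back.times, sin_curve.times, rtol=1e-10)
        np.testing.assert_allclose(back.positions, sin_curve.positions, rtol=1e-10, atol=1e-12)
        np.testing.assert_allclose(back.phases, sin_curve.phases, rtol=1e-10, atol=1e-9)

    def test_csv_without_phases(self, tmp_path, sin_curve):
        p = tmp_path / "trace.csv"
        tq.write_breathing_csv(tq.BreathingCurve(sin_curve.times, sin_curve.positions), p)
        assert not tq.read_breathing_csv(p).has_phases

    def test_csv_bad_header_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("t,x\n0,0\n0.1,1\n")
        with pytest.raises(FormatError):
            tq.read_breathing_csv(p)

    def test_vxp_round_trip(self, tmp_path, sin_curve):
        p = tmp_path / "trace.vxp"
        tq.write_vxp(sin_curve, p)
        back = tq.read_vxp(p)
        np.testing.assert_allclose(back.times, sin_curve.times, atol=2e-9)
        np.testing.assert_allclose(back.positions, sin_curve.positions, atol=1e-8)
        assert _phase_err(back.phases, sin_curve.phases) < 1e-6

    def test_vxp_requires_layout(self, tmp_path):
        p = tmp_path / "bad.vxp"
        p.write_text("Version=1.6\n[Data]\n0.1,0.2,0\n")
        with pytest.raises(FormatError):
            tq.read_vxp(p)
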