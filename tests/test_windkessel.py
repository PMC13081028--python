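"""Three-element Windkessel: interpolation, integration, tuning."""

import numpy as np
import pytest

from aortaflow.synthetic import WaveformSpec, generate_inlet_waveform
from aortaflow.windkessel import (
    FlowWaveform,
    PressureTargets,
    PressureTrace,
    WindkesselParams,
    flow_from_velocity,
    fourier_interpolate,
    pressure_summary,
    split_outlet_flows,
    tune_windkessel,
    windkessel_pressure,
)

PARAMS = WindkesselParams(R=0.09, C=0.3, r=0.91)


def constant_waveform(q0=100.0, n=15, T=0.12):
    t = np.linspace(0.0, T, n, endpoint=False)
    return FlowWaveform(times=t, flows=np.full(n, q0), period_T=T)


class TestFlowFromVelocity:
    def test_unit_arithmetic(self):
        wf = flow_from_velocity([10.0] * 5, [0.01] * 5, frame_dt_s=0.01)
        assert np.allclose(wf.flows, 100.0)  # 10 cm/s * 0.01 cm^2 = 0.1 mL/s
        assert wf.period_T == pytest.approx(0.05)

    def test_zero_velocity_frame_gives_zero_flow(self):
        wf = flow_from_velocity([10.0, 0.0, 5.0], [0.01] * 3, frame_dt_s=0.01)
        assert wf.flows[1] == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            flow_from_velocity([1.0, 2.0], [0.01], frame_dt_s=0.01)

    def test_trapezoid_mean_matches_quadrature_oracle(self, rng):
        v = rng.uniform(5, 20, 15)
        a = rng.uniform(0.008, 0.012, 15)
        wf = flow_from_velocity(v, a, frame_dt_s=0.008)
        q = v * a * 1000.0
        t = np.arange(15) * 0.008
        oracle = np.trapezoid(np.append(q, q[0]), np.append(t, 15 * 0.008)) / (15 * 0.008)
        assert wf.mean_flow() == pytest.approx(oracle, abs=1e-9)


class TestFourierInterpolation:
    def test_constant_waveform_gives_constant_interpolant(self):
        fi = fourier_interpolate(constant_waveform(), n_modes=20)
        tt = np.linspace(0, 0.36, 500)
        assert np.allclose(fi(tt), 100.0, atol=1e-9)
        assert np.allclose(fi.derivative(tt), 0.0, atol=1e-7)

    def test_single_harmonic_reproduced_exactly(self):
        T = 0.12
        t = np.linspace(0, T, 15, endpoint=False)
        wf = FlowWaveform(t, 100 + 50 * np.sin(2 * np.pi * t / T), T)
        fi = fourier_interpolate(wf, n_modes=7)
        tt = np.linspace(0, T, 1000)
        assert np.max(np.abs(fi(tt) - (100 + 50 * np.sin(2 * np.pi * tt / T)))) < 1e-10

    def test_random_samples_interpolated_at_nodes(self, rng):
        T = 0.12
        t = np.linspace(0, T, 15, endpoint=False)
        q = rng.uniform(50, 150, 15)
        fi = fourier_interpolate(FlowWaveform(t, q, T), n_modes=7)
        assert np.max(np.abs(fi(t) - q)) < 1e-9

    def test_periodicity_by_construction(self, rng):
        T = 0.12
        t = np.linspace(0, T, 15, endpoint=False)
        fi = fourier_interpolate(FlowWaveform(t, rng.uniform(0, 1, 15), T), n_modes=7)
        tt = np.linspace(0, T, 77)
        assert np.allclose(fi(tt), fi(tt + T), atol=1e-12)

    def test_nodes_reading_also_interpolates(self, mouse_waveform):
        fi = fourier_interpolate(mouse_waveform, n_modes=20, interpret="points")
        assert np.max(np.abs(fi(mouse_waveform.times) - mouse_waveform.flows)) < 1e-6


class TestPressureIntegration:
    def test_constant_inflow_converges_to_total_resistance_level(self):
        trace = windkessel_pressure(constant_waveform(100.0), PARAMS, n_cycles=30)
        assert trace.converged
        assert trace.pressures[-1] == pytest.approx(100.0 * (PARAMS.R + PARAMS.r), rel=5e-3)

    def test_zero_inflow_decays_with_rc_time_constant(self):
        wf = constant_waveform(0.0)
        p0 = 100.0
        trace = windkessel_pressure(wf, PARAMS, n_cycles=1, max_cycles=1, p0=p0)
        # fit log-linear decay: p = p0 exp(-t/(r C))
        tau_fit = -1.0 / np.polyfit(trace.times, np.log(trace.pressures), 1)[0]
        assert tau_fit == pytest.approx(PARAMS.r * PARAMS.C, rel=1e-3)

    def test_pulsatile_mean_pressure_is_mean_flow_times_resistance(self, mouse_waveform):
        trace = windkessel_pressure(mouse_waveform, PARAMS, n_cycles=30)
        summary = pressure_summary(trace)
        expected = mouse_waveform.mean_flow() * (PARAMS.R + PARAMS.r)
        assert summary.map == pytest.approx(expected, rel=5e-3)

    def test_linearity_in_flow(self, mouse_waveform):
        s = 2.5
        scaled = FlowWaveform(
            mouse_waveform.times, s * mouse_waveform.flows, mouse_waveform.period_T
        )
        t1 = windkessel_pressure(mouse_waveform, PARAMS, n_cycles=30, cycle_tol_mmHg=1e-5)
        t2 = windkessel_pressure(scaled, PARAMS, n_cycles=30, cycle_tol_mmHg=1e-5)
        assert np.allclose(t2.pressures, s * t1.pressures, rtol=1e-4)

    def test_grid_refinement_changes_summaries_below_0p1_percent(self, mouse_waveform):
        T = mouse_waveform.period_T
        s1 = pressure_summary(
            windkessel_pressure(mouse_waveform, PARAMS, n_cycles=30, dt=T / 200)
        )
        s2 = pressure_summary(
            windkessel_pressure(mouse_waveform, PARAMS, n_cycles=30, dt=T / 400)
        )
        assert abs(s1.systolic - s2.systolic) / s2.systolic < 1e-3
        assert abs(s1.diastolic - s2.diastolic) / s2.diastolic < 1e-3

    def test_periodic_steady_state(self, mouse_waveform):
        trace = windkessel_pressure(
            mouse_waveform, PARAMS, n_cycles=8, cycle_tol_mmHg=1e-6, max_cycles=100
        )
        map_p = float(np.mean(trace.pressures))
        assert abs(trace.pressures[0] - trace.pressures[-1]) < 1e-5 * map_p

    def test_coarse_dt_rejected(self, mouse_waveform):
        with pytest.raises(ValueError):
            windkessel_pressure(mouse_waveform, PARAMS, dt=mouse_waveform.period_T / 10)


class TestPressureSummary:
    def test_constant_trace(self):
        t = np.linspace(0, 0.12, 100)
        s = pressure_summary(PressureTrace(t, np.full(100, 100.0), True))
        assert (s.systolic, s.diastolic, s.amplitude) == (100.0, 100.0, 0.0)
        assert s.map == pytest.approx(100.0)

    def test_sinusoid_trace(self):
        t = np.linspace(0, 0.12, 2001)
        p = 100 + 20 * np.sin(2 * np.pi * t / 0.12)
        s = pressure_summary(PressureTrace(t, p, True))
        assert s.systolic == pytest.approx(120.0, rel=1e-5)
        assert s.diastolic == pytest.approx(80.0, rel=1e-5)
        assert s.map == pytest.approx(100.0, rel=1e-5)
        assert s.amplitude == pytest.approx(40.0, rel=1e-4)

    def test_unconverged_trace_warns(self):
        t = np.linspace(0, 0.12, 100)
        with pytest.warns(UserWarning):
            pressure_summary(PressureTrace(t, np.full(100, 90.0), False))


class TestTuning:
    def test_self_consistency_with_forward_generated_targets(self, mouse_waveform):
        truth = WindkesselParams(R=0.08, C=0.25, r=0.85)
        targets = pressure_summary(windkessel_pressure(mouse_waveform, truth, n_cycles=30))
        params, report = tune_windkessel(mouse_waveform, targets, tol=0.05)
        assert report.max_error <= 0.05

    def test_total_resistance_identity(self, mouse_waveform):
        targets = PressureTargets(systolic=120.0, diastolic=80.0)
        params, report = tune_windkessel(mouse_waveform, targets, tol=0.05)
        rtot = params.R + params.r
        assert rtot == pytest.approx(
            report.achieved.map / mouse_waveform.mean_flow(), rel=0.05
        )

    def test_slack_tolerance_accepts_initial_guess(self, mouse_waveform):
        targets = PressureTargets(systolic=120.0, diastolic=80.0)
        params, report = tune_windkessel(mouse_waveform, targets, tol=1.0)
        assert report.iterations == 1

    @pytest.mark.parametrize("seed", range(20))
    def test_five_percent_criterion_across_seeded_pairs(self, seed):
        r = np.random.default_rng(seed)
        wf = generate_inlet_waveform(
            WaveformSpec(
                period_s=r.uniform(0.1, 0.15),
                mean_flow=r.uniform(60, 150),
                pulsatility=r.uniform(2.0, 3.5),
                n_samples=15,
                seed=seed,
            )
        )
        dia = r.uniform(70, 90)
        targets = PressureTargets(systolic=dia + r.uniform(25, 45), diastolic=dia)
        params, report = tune_windkessel(wf, targets, tol=0.05)
        assert report.max_error <= 0.05
        assert set(report.errors) == {"systolic", "diastolic", "map", "amplitude"}


class TestOutletSplit:
    def test_single_outlet_gets_everything(self):
        assert split_outlet_flows(100.0, [0.02]) == pytest.approx([100.0])

    def test_equal_areas_split_evenly(self):
        assert np.allclose(split_outlet_flows(100.0, [0.01, 0.01]), [50.0, 50.0])

    def test_murray_exponent(self):
        # areas 1:4 -> flows 1:8
        q = split_outlet_flows(90.0, [1.0, 4.0])
        assert np.allclose(q, [10.0, 80.0])
        assert q.sum() == pytest.approx(90.0, abs=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            split_outlet_flows(100.0, [])
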