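"""Lumped (0D) outlet hemodynamics: three-element Windkessel tuning.

Each aortic outlet is represented by a proximal resistance R, a compliance
C and a distal resistance r.  The outlet pressure obeys

    dp/dt + p/(r C) = (Q/C) (1 + R/r) + R dQ/dt,

forced by the periodic volumetric flow Q(t).  The waveform is represented
by a truncated trigonometric (Fourier) interpolant so dQ/dt is available
analytically, and the ODE is integrated with classical RK4 over repeated
cardiac cycles until the pressure trace is periodic.

Units are mouse-scale and match the reported pressures: mmHg, uL/s and s
(R, r in mmHg*s/uL; C in uL/mmHg).

The tuner adjusts (R, C, r) until systolic, diastolic, mean arterial and
pulse pressures of the converged trace are all within a relative tolerance
(5% by default) of the prescribed targets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

__all__ = [
    "FlowWaveform",
    "WindkesselParams",
    "PressureTrace",
    "PressureTargets",
    "flow_from_velocity",
    "fourier_interpolate",
    "FourierInterpolant",
    "windkessel_pressure",
    "pressure_summary",
    "tune_windkessel",
    "split_outlet_flows",
    "TuningReport",
    "TuningError",
]


@dataclass
class FlowWaveform:
    """One cardiac cycle of volumetric inflow samples.

    times : s, strictly increasing in [0, period_T); flows : uL/s.
    The waveform is treated as T-periodic.
    """

    times: np.ndarray
    flows: np.ndarray
    period_T: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.flows = np.asarray(self.flows, dtype=float)
        if len(self.times) != len(self.flows):
            raise ValueError("times and flows must have equal length")
        if not (self.period_T > 0):
            raise ValueError("period_T must be positive")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.times[-1] >= self.period_T:
            raise ValueError("times must lie in [0, period_T)")

    def mean_flow(self) -> float:
        """Trapezoid-rule cycle mean with periodic closure (uL/s)."""
        t = np.append(self.times, self.times[0] + self.period_T)
        q = np.append(self.flows, self.flows[0])
        return float(np.trapezoid(q, t) / self.period_T)


@dataclass(frozen=True)
class WindkesselParams:
    """Per-outlet (R, C, r): proximal resistance, compliance, distal resistance."""

    R: float  # mmHg*s/uL
    C: float  # uL/mmHg
    r: float  # mmHg*s/uL

    def __post_init__(self) -> None:
        if not (self.R > 0 and self.C > 0 and self.r > 0):
            raise ValueError(f"R, C, r must all be positive, got {self}")


@dataclass
class PressureTrace:
    times: np.ndarray
    pressures: np.ndarray
    converged: bool

    def __post_init__(self) -> None:
        if len(self.times) != len(self.pressures):
            raise ValueError("times and pressures must have equal length")


@dataclass
class PressureTargets:
    """Tuning targets in mmHg.

    ``map`` may be None, in which case the mean-pressure criterion is
    self-consistent: the achieved cycle average is accepted as its own
    target (the cycle-average reading of mean arterial pressure).
    ``amplitude`` defaults to systolic - diastolic.
    """

    systolic: float
    diastolic: float
    map: float | None = None
    amplitude: float | None = None

    def __post_init__(self) -> None:
        # >= admits degenerate summaries (a constant trace); the tuner
        # additionally requires a strictly positive pulse amplitude
        if not (self.systolic >= self.diastolic > 0):
            raise ValueError("need systolic >= diastolic > 0")
        if self.amplitude is None:
            self.amplitude = self.systolic - self.diastolic
        if self.map is not None:
            eps = 1e-9 * max(abs(self.systolic), 1.0)
            if not (self.diastolic - eps <= self.map <= self.systolic + eps):
                raise ValueError("map must lie between diastolic and systolic")


def flow_from_velocity(mean_velocity_cm_s, area_cm2, frame_dt_s: float) -> FlowWaveform:
    """Per-frame inflow from phase-resolved mean velocity and lumen area.

    Q_i = v_i * A_i, converted from cm^3/s to uL/s (x1000); the cardiac
    period is the frame count times the frame spacing.
    """
    v = np.asarray(mean_velocity_cm_s, dtype=float)
    a = np.asarray(area_cm2, dtype=float)
    if v.shape != a.shape:
        raise ValueError(f"velocity ({v.shape}) and area ({a.shape}) length mismatch")
    if np.any(a < 0):
        raise ValueError("areas must be non-negative")
    q = v * a * 1000.0  # cm^3/s -> uL/s
    n = len(v)
    times = np.arange(n) * frame_dt_s
    return FlowWaveform(times=times, flows=q, period_T=n * frame_dt_s)


class FourierInterpolant:
    """Truncated trigonometric series fit to one period of samples.

    Evaluable at arbitrary times and analytically differentiable, which is
    what the Windkessel forcing term R*dQ/dt needs.  Coefficients come from
    a least-squares fit of the [1, cos(k w t), sin(k w t)] basis, so
    non-uniform sampling is handled; when ``2*n_modes + 1 >= n_samples``
    the fit interpolates the samples exactly.
    """

    def __init__(self, times, values, period: float, n_modes: int):
        times = np.asarray(times, dtype=float)
        values = np.asarray(values, dtype=float)
        n_modes = int(min(n_modes, max(1, (len(times) - 1) // 2)))
        self.period = float(period)
        self.n_modes = n_modes
        self.omega = 2.0 * np.pi / self.period
        A = self._basis(times)
        coef, *_ = np.linalg.lstsq(A, values, rcond=None)
        self.coef = coef

    def _basis(self, t):
        t = np.atleast_1d(np.asarray(t, dtype=float))
        cols = [np.ones_like(t)]
        for k in range(1, self.n_modes + 1):
            cols.append(np.cos(k * self.omega * t))
            cols.append(np.sin(k * self.omega * t))
        return np.column_stack(cols)

    def __call__(self, t):
        out = self._basis(t) @ self.coef
        return float(out[0]) if np.isscalar(t) else out

    def derivative(self, t):
        tt = np.atleast_1d(np.asarray(t, dtype=float))
        cols = [np.zeros_like(tt)]
        for k in range(1, self.n_modes + 1):
            kw = k * self.omega
            cols.append(-kw * np.sin(kw * tt))
            cols.append(kw * np.cos(kw * tt))
        out = np.column_stack(cols) @ self.coef
        return float(out[0]) if np.isscalar(t) else out

    def resample(self, n: int) -> FlowWaveform:
        t = np.linspace(0.0, self.period, n, endpoint=False)
        return FlowWaveform(times=t, flows=self(t), period_T=self.period)


def fourier_interpolate(
    waveform: FlowWaveform, n_modes: int = 20, interpret: str = "modes"
) -> FourierInterpolant:
    """Fourier interpolation of one flow cycle.

    ``interpret="modes"`` (default) retains ``n_modes`` harmonics, capped at
    the Nyquist limit of the sample count.  ``interpret="points"`` reads the
    number as a resampling node count: the waveform is first interpolated at
    full available order, resampled to ``n_modes`` uniform points, and
    re-interpolated — the alternative reading of an "N-node" Fourier
    interpolation.
    """
    if n_modes < 1:
        raise ValueError("n_modes must be >= 1")
    if interpret == "modes":
        return FourierInterpolant(
            waveform.times, waveform.flows, waveform.period_T, n_modes
        )
    if interpret == "points":
        full = FourierInterpolant(
            waveform.times, waveform.flows, waveform.period_T, len(waveform.times)
        )
        wf = full.resample(n_modes)
        return FourierInterpolant(wf.times, wf.flows, wf.period_T, n_modes)
    raise ValueError("interpret must be 'modes' or 'points'")


def windkessel_pressure(
    waveform: FlowWaveform,
    params: WindkesselParams,
    n_cycles: int = 8,
    dt: float | None = None,
    p0: float | None = None,
    cycle_tol_mmHg: float = 0.1,
    n_modes: int = 20,
    max_cycles: int = 50,
) -> PressureTrace:
    """Integrate the outlet pressure ODE to a periodic steady state.

    RK4 with time step ``dt`` (default T/200; must satisfy dt < T/20) for at
    least ``n_cycles`` cardiac cycles, continuing up to ``max_cycles`` until
    the max cycle-to-cycle pressure change falls below ``cycle_tol_mmHg``.
    Returns the last-cycle trace.
    """
    T = waveform.period_T
    if dt is None:
        dt = T / 200.0
    if not (dt < T / 20.0):
        raise ValueError(f"dt={dt} too coarse; need dt < period/20 = {T / 20.0}")
    q = fourier_interpolate(waveform, n_modes=n_modes)
    R, C, r = params.R, params.C, params.r

    def rhs(t, p):
        return -p / (r * C) + (q(t) / C) * (1.0 + R / r) + R * q.derivative(t)

    n_steps = int(round(T / dt))
    dt = T / n_steps  # snap so each cycle is an integer number of steps
    if p0 is None:
        p0 = waveform.mean_flow() * (R + r)
    p = float(p0)
    prev_cycle = None
    converged = False
    times = np.linspace(0.0, T, n_steps + 1)
    for cycle in range(max_cycles):
        trace = np.empty(n_steps + 1)
        trace[0] = p
        for i in range(n_steps):
            t = times[i]
            k1 = rhs(t, p)
            k2 = rhs(t + dt / 2, p + dt / 2 * k1)
            k3 = rhs(t + dt / 2, p + dt / 2 * k2)
            k4 = rhs(t + dt, p + dt * k3)
            p = p + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
            if not np.isfinite(p):
                raise FloatingPointError(
                    f"pressure integration diverged (dt={dt}, params={params})"
                )
            trace[i + 1] = p
        converged = (
            prev_cycle is not None
            and np.max(np.abs(trace - prev_cycle)) < cycle_tol_mmHg
        )
        prev_cycle = trace
        if converged and cycle + 1 >= n_cycles:
            break
    return PressureTrace(times=times, pressures=prev_cycle, converged=converged)


def pressure_summary(trace: PressureTrace) -> PressureTargets:
    """Systolic (max), diastolic (min), MAP (cycle time-average), amplitude."""
    if not trace.converged:
        warnings.warn("pressure trace not converged; summary may be transient")
    p = trace.pressures
    t = trace.times
    sys_p = float(np.max(p))
    dia_p = float(np.min(p))
    map_p = float(np.trapezoid(p, t) / (t[-1] - t[0]))
    return PressureTargets(
        systolic=sys_p, diastolic=dia_p, map=map_p, amplitude=sys_p - dia_p
    )


@dataclass
class TuningReport:
    errors: dict = field(default_factory=dict)
    max_error: float = np.inf
    iterations: int = 0
    achieved: PressureTargets | None = None


class TuningError(RuntimeError):
    def __init__(self, message, best_params, report):
        super().__init__(message)
        self.best_params = best_params
        self.report = report


def _relative_errors(achieved: PressureTargets, targets: PressureTargets) -> dict:
    errs = {
        "systolic": abs(achieved.systolic - targets.systolic) / targets.systolic,
        "diastolic": abs(achieved.diastolic - targets.diastolic) / targets.diastolic,
        "amplitude": abs(achieved.amplitude - targets.amplitude) / targets.amplitude,
    }
    # mean pressure: self-consistent (zero error) when no explicit target
    errs["map"] = (
        0.0 if targets.map is None else abs(achieved.map - targets.map) / targets.map
    )
    return errs


def tune_windkessel(
    waveform: FlowWaveform,
    targets: PressureTargets,
    tol: float = 0.05,
    max_iter: int = 40,
    r_fraction: float = 0.09,
    n_cycles: int = 8,
) -> tuple[WindkesselParams, TuningReport]:
    """Tune (R, C, r) so all four pressure summaries hit the targets.

    Stage 1 is a damped fixed point exploiting the dominant sensitivities:
    total resistance sets the pressure level (scaled by the target/achieved
    mean-pressure ratio), compliance sets the pulse amplitude.  If the
    systolic/diastolic split is still outside ``tol``, stage 2 polishes all
    three knobs (log R_total, log C, logit R-fraction) with Nelder-Mead on
    the maximum relative error.  Raises :class:`TuningError` with the best
    iterate if the criterion cannot be met within ``max_iter`` evaluations.
    """
    qmean = waveform.mean_flow()
    if qmean <= 0:
        raise ValueError("waveform mean flow must be positive")
    if not (targets.systolic > targets.diastolic):
        raise ValueError("tuning requires systolic > diastolic targets")
    T = waveform.period_T
    level = targets.map if targets.map is not None else 0.5 * (
        targets.systolic + targets.diastolic
    )

    rtot = level / qmean
    # diastolic decay over ~2/3 of the cycle sets the RC time constant
    tau = (2.0 * T / 3.0) / np.log(targets.systolic / targets.diastolic)
    frac = r_fraction
    cap = tau / ((1.0 - frac) * rtot)

    n_eval = 0
    best = None

    def evaluate(rtot_, cap_, frac_):
        nonlocal n_eval, best
        n_eval += 1
        params = WindkesselParams(R=frac_ * rtot_, C=cap_, r=(1.0 - frac_) * rtot_)
        trace = windkessel_pressure(waveform, params, n_cycles=n_cycles)
        ach = pressure_summary(trace)
        errs = _relative_errors(ach, targets)
        maxerr = max(errs.values())
        if best is None or maxerr < best[3]:
            best = (params, ach, errs, maxerr)
        return params, ach, errs, maxerr

    # stage 1: damped fixed point on level (R+r) and amplitude (C)
    for _ in range(12):
        params, ach, errs, maxerr = evaluate(rtot, cap, frac)
        if maxerr <= tol:
            return params, TuningReport(errs, maxerr, n_eval, ach)
        lvl_target = targets.map if targets.map is not None else level
        lvl_ach = ach.map if targets.map is not None else 0.5 * (
            ach.systolic + ach.diastolic
        )
        rtot *= (lvl_target / lvl_ach) ** 0.8
        cap *= (ach.amplitude / targets.amplitude) ** 0.8

    # stage 2: simplex polish on all three knobs
    def objective(x):
        rt, cp = np.exp(x[0]), np.exp(x[1])
        fr = 1.0 / (1.0 + np.exp(-x[2]))
        try:
            return evaluate(rt, cp, fr)[3]
        except (FloatingPointError, ValueError):
            return 1e6

    x0 = np.array([np.log(rtot), np.log(cap), np.log(frac / (1.0 - frac))])
    budget = max(max_iter - n_eval, 20)
    minimize(
        objective, x0, method="Nelder-Mead",
        options={"maxfev": budget, "xatol": 1e-4, "fatol": tol * 1e-3},
    )
    params, ach, errs, maxerr = best
    report = TuningReport(errs, maxerr, n_eval, ach)
    if maxerr <= tol:
        return params, report
    raise TuningError(
        f"tuning failed: max relative error {maxerr:.3%} > tol {tol:.0%}",
        params, report,
    )


def split_outlet_flows(total_mean_flow: float, outlet_areas_cm2) -> np.ndarray:
    """Murray-type flow split: per-outlet flows proportional to area^(3/2)."""
    areas = np.asarray(outlet_areas_cm2, dtype=float)
    if areas.size == 0:
        raise ValueError("outlet_areas_cm2 must be non-empty")
    if np.any(areas <= 0):
        raise ValueError("outlet areas must be positive")
    w = areas ** 1.5
    return total_mean_flow * w / np.sum(w)
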