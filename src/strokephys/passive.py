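"""Passive membrane properties, rheobase and recording QC.

Input resistance is the ordinary-least-squares slope of steady-state
voltage deflection against injected hyperpolarising current; the
membrane time constant comes from a nonlinear exponential fit
V(t) = y0 + A exp(-(t - X0)/tau) to the charging phase; capacitance is
tau / R_in (1000 tau[ms] / R[MOhm] in pF).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import linregress

from .io import InsufficientDataError, RunConfig, ValidationError, VoltageSweep
from .spikes import detect_spikes

__all__ = [
    "ExponentialFit",
    "PassiveResult",
    "RheobaseResult",
    "resting_membrane_potential",
    "input_resistance",
    "membrane_time_constant",
    "membrane_capacitance",
    "rheobase",
    "series_resistance_qc",
]

_DEFAULT = RunConfig()


@dataclass
class ExponentialFit:
    """Result of the charging-phase fit V(t) = y0 + A exp(-(t - X0)/tau)."""

    y0: float
    A: float
    X0: float  # ms, fixed at step onset
    tau: float | None  # ms, None when not converged
    rss: float
    converged: bool


@dataclass
class PassiveResult:
    """Per-cell passive summary with QC."""

    rmp_mV: float
    r_in_MOhm: float
    tau_ms: float | None
    capacitance_pF: float | None
    rheobase_pA: float | None
    series_r_change_pct: float | None = None
    qc_passed: bool = True


@dataclass
class RheobaseResult:
    rheobase_pA: float | None
    per_repeat_pA: tuple[float | None, float | None]

    @property
    def any_repeat_undefined(self) -> bool:
        return any(r is None for r in self.per_repeat_pA)


def _step_or_raise(sweep: VoltageSweep):
    step = sweep.step
    if step is None:
        raise ValidationError(f"sweep {sweep.sweep_id} carries no step descriptor")
    return step


def resting_membrane_potential(sweep: VoltageSweep, config: RunConfig = _DEFAULT) -> float:
    """Mean membrane potential over the pre-stimulus baseline window (mV)."""
    window_ms = config.baseline_window_ms
    step = sweep.step
    onset_idx = (
        int(round(step.onset_s * sweep.sampling_rate)) if step is not None else sweep.n_samples
    )
    n_win = int(round(window_ms / sweep.dt_ms))
    if n_win > onset_idx:
        raise InsufficientDataError(
            f"baseline window ({window_ms} ms) longer than the pre-stimulus "
            f"baseline ({onset_idx * sweep.dt_ms:.1f} ms)"
        )
    return float(np.mean(sweep.voltage[onset_idx - n_win : onset_idx]))


def _steady_state_mv(sweep: VoltageSweep, config: RunConfig) -> float:
    step = _step_or_raise(sweep)
    end = int(round((step.onset_s + step.duration_s) * sweep.sampling_rate))
    n_win = int(round(config.steady_state_window_ms / sweep.dt_ms))
    n_win = min(n_win, end)
    return float(np.mean(sweep.voltage[end - n_win : end]))


def input_resistance(
    sweeps: Sequence[VoltageSweep],
    rmp: float | None = None,
    config: RunConfig = _DEFAULT,
) -> tuple[float, dict]:
    """OLS slope of steady-state voltage change versus injected current.

    Parameters
    ----------
    sweeps : hyperpolarising step family (>= 2 distinct amplitudes).
    rmp : mV, optional
        Reference potential; defaults to each sweep's own baseline.

    Returns
    -------
    r_in_MOhm : float
    diagnostics : dict with the per-step deltas and regression stats.
    """
    amps, dvs = [], []
    for sweep in sweeps:
        step = _step_or_raise(sweep)
        base = rmp if rmp is not None else resting_membrane_potential(sweep, config)
        amps.append(step.amplitude_pA)
        dvs.append(_steady_state_mv(sweep, config) - base)
    if len(set(amps)) < 2:
        raise InsufficientDataError("input resistance needs >= 2 distinct step amplitudes")
    fit = linregress(amps, dvs)
    r_in = fit.slope * 1000.0  # mV/pA -> MOhm
    return float(r_in), {
        "amplitudes_pA": list(amps),
        "delta_v_mV": list(dvs),
        "intercept_mV": float(fit.intercept),
        "r_value": float(fit.rvalue),
    }


def membrane_time_constant(sweep: VoltageSweep, config: RunConfig = _DEFAULT) -> ExponentialFit:
    """Fit the charging phase of one hyperpolarising step.

    The window starts ``tau_fit_skip_samples`` after onset (pipette
    transient) and spans ``tau_fit_n_tau`` estimated time constants; the
    initial tau estimate (63%-of-deflection time) is refined once.
    X0 is fixed at the step onset.
    """
    step = _step_or_raise(sweep)
    v = sweep.voltage
    dt = sweep.dt_ms
    onset = int(round(step.onset_s * sweep.sampling_rate))
    end = int(round((step.onset_s + step.duration_s) * sweep.sampling_rate))

    y0_init = _steady_state_mv(sweep, config)
    v_onset = float(v[max(onset - 1, 0)])
    a_init = v_onset - y0_init
    if abs(a_init) < 1e-9:
        return ExponentialFit(y0=y0_init, A=0.0, X0=onset * dt, tau=None, rss=0.0, converged=False)

    # 63% rule for the initial tau, then one iteration of window sizing
    target = v_onset - 0.632 * a_init
    seg = v[onset:end]
    crossed = np.nonzero((seg - target) * np.sign(a_init) <= 0)[0]
    tau_guess = (float(crossed[0]) + 1.0) * dt if crossed.size else (end - onset) * dt / 5.0

    t_ms = np.arange(v.size) * dt
    x0 = onset * dt

    def run_fit(tau0: float) -> tuple[np.ndarray, np.ndarray, np.ndarray] | None:
        lo = onset + config.tau_fit_skip_samples
        hi = min(end, onset + int(round(config.tau_fit_n_tau * tau0 / dt)))
        if hi - lo < 4:
            return None
        tt, yy = t_ms[lo:hi], v[lo:hi]

        def model(t, y0, A, tau):
            return y0 + A * np.exp(-(t - x0) / tau)

        try:
            popt, _ = curve_fit(
                model,
                tt,
                yy,
                p0=[y0_init, a_init, tau0],
                bounds=([-np.inf, -np.inf, 1e-3], [np.inf, np.inf, np.inf]),
                maxfev=5000,
            )
        except RuntimeError:
            return None
        resid = yy - model(tt, *popt)
        return popt, resid, tt

    result = run_fit(tau_guess)
    if result is not None:
        result2 = run_fit(float(result[0][2]))
        if result2 is not None:
            result = result2
    if result is None:
        return ExponentialFit(y0=y0_init, A=a_init, X0=x0, tau=None, rss=np.nan, converged=False)
    (y0, A, tau), resid, _ = result
    return ExponentialFit(
        y0=float(y0), A=float(A), X0=x0, tau=float(tau), rss=float(np.sum(resid**2)), converged=True
    )


def membrane_capacitance(tau_ms: float, r_in_MOhm: float) -> float:
    """C = tau / R_in, reported in pF (1000 tau[ms] / R[MOhm])."""
    if not r_in_MOhm > 0:
        raise ValidationError("input resistance must be > 0")
    if not tau_ms > 0:
        raise ValidationError("tau must be > 0")
    return 1000.0 * tau_ms / r_in_MOhm


def _repeat_rheobase(sweeps: Sequence[VoltageSweep], config: RunConfig) -> float | None:
    spiking_amps = []
    for sweep in sweeps:
        step = _step_or_raise(sweep)
        if detect_spikes(sweep, config):
            spiking_amps.append(step.amplitude_pA)
    return float(min(spiking_amps)) if spiking_amps else None


def rheobase(
    repeat1: Sequence[VoltageSweep],
    repeat2: Sequence[VoltageSweep],
    config: RunConfig = _DEFAULT,
) -> RheobaseResult:
    """Lowest spiking current per repeat, averaged across the two repeats.

    A repeat with no spiking step is flagged undefined; the average then
    falls back to the defined repeat (or None when both are undefined).
    """
    r1 = _repeat_rheobase(repeat1, config)
    r2 = _repeat_rheobase(repeat2, config)
    defined = [r for r in (r1, r2) if r is not None]
    mean = float(np.mean(defined)) if defined else None
    return RheobaseResult(rheobase_pA=mean, per_repeat_pA=(r1, r2))


def series_resistance_qc(rs_before_MOhm: float, rs_after_MOhm: float, max_change: float = 0.20) -> tuple[bool, float]:
    """Exclusion rule: fail iff |after - before| / before exceeds 20%.

    Returns (passed, percent_change); the boundary itself passes.
    """
    if not rs_before_MOhm > 0:
        raise ValidationError("series resistance must be > 0")
    change = (rs_after_MOhm - rs_before_MOhm) / rs_before_MOhm
    return abs(change) <= max_change + 1e-12, change * 100.0
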