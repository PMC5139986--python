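"""Input protocols, ODE time-stepping of both compartments, signal conditioning.

Simulations are driven by an :class:`InputTimeline`: a uniformly sampled
table of the five systemic inputs.  Unspecified inputs are held at their
baseline values (the inputs are not independently modelled, so the model has
no spontaneous dynamics).  Both compartments are integrated jointly with a
stiff-safe solver; output sampling (default 1 Hz) is decoupled from the
internal solver steps.

Signal conditioning mirrors common fNIRS practice: laser-Doppler flux is
normalised to the median of an initial baseline window (2 min by default),
series are smoothed with a centred 1-min sliding-window average, and coarse
series are upsampled by linear interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from . import cerebral as cer
from . import scalp as sca
from .config import RunConfig, default_config
from .errors import ConvergenceError
from .observation import cco_output, compartment_haemoglobin, merge_signals
from .types import (
    INPUT_BASELINES,
    INPUT_NAMES,
    INPUT_RANGES,
    HaemoglobinSignals,
    SystemicInputs,
)

__all__ = [
    "InputTimeline",
    "build_step_protocol",
    "build_multifrequency_protocol",
    "run_simulation",
    "SimulationResult",
    "normalise_flux",
    "moving_average",
    "resample_linear",
]


@dataclass
class InputTimeline:
    """Uniformly sampled systemic input table (columns t + the five inputs)."""

    df: pd.DataFrame
    meta: str = ""

    def __post_init__(self) -> None:
        missing = [c for c in ("t", *INPUT_NAMES) if c not in self.df.columns]
        if missing:
            raise ValueError(f"timeline is missing columns: {missing}")
        t = self.df["t"].to_numpy(dtype=float)
        if len(t) < 2:
            raise ValueError("timeline needs at least two samples")
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise ValueError("timeline time grid must be strictly increasing")
        if not np.allclose(dt, dt[0], rtol=1e-9, atol=1e-12):
            raise ValueError("timeline time grid must be uniform")

    @property
    def t(self) -> np.ndarray:
        return self.df["t"].to_numpy(dtype=float)

    @property
    def dt(self) -> float:
        t = self.t
        return float(t[1] - t[0])

    def inputs_at(self, time: float) -> SystemicInputs:
        """Linearly interpolated systemic inputs at ``time``."""
        t = self.t
        values = {
            name: float(np.interp(time, t, self.df[name].to_numpy(dtype=float)))
            for name in INPUT_NAMES
        }
        return SystemicInputs(**values)

    @classmethod
    def constant(cls, duration: float, dt: float = 1.0, **values: float) -> "InputTimeline":
        t = np.arange(0.0, duration + 0.5 * dt, dt)
        data = {"t": t}
        for name in INPUT_NAMES:
            data[name] = np.full_like(t, values.get(name, INPUT_BASELINES[name]))
        return cls(pd.DataFrame(data), meta="constant")


def _check_plausible(name: str, value: float) -> None:
    lo, hi = INPUT_RANGES[name]
    span = hi - lo
    if not (lo - span <= value <= hi + span):
        raise ValueError(
            f"{name}={value} is far outside the declared plausibility range "
            f"[{lo}, {hi}]"
        )


def build_step_protocol(
    variable: str | dict[str, tuple[float, float]],
    low: float | None = None,
    high: float | None = None,
    *,
    t_step: float = 120.0,
    t_return: float = 420.0,
    t_total: float = 600.0,
    dt: float = 1.0,
) -> InputTimeline:
    """Square-wave protocol: step from ``low`` to ``high`` and back.

    ``variable`` is one of the five input names (``low`` defaults to the
    baseline and ``high`` to the upper end of the input's simulation range),
    or a mapping name -> (low, high) for simultaneous aligned steps.  All
    other inputs are held at baseline.
    """
    if isinstance(variable, str):
        if variable not in INPUT_NAMES:
            raise ValueError(f"unknown input variable {variable!r}")
        lo = INPUT_BASELINES[variable] if low is None else low
        hi = INPUT_RANGES[variable][1] if high is None else high
        steps = {variable: (lo, hi)}
    else:
        if low is not None or high is not None:
            raise ValueError("pass low/high inside the mapping for multi-input steps")
        steps = dict(variable)
    if not 0.0 <= t_step < t_return <= t_total:
        raise ValueError("timings must satisfy 0 <= t_step < t_return <= t_total")

    t = np.arange(0.0, t_total + 0.5 * dt, dt)
    data = {"t": t}
    for name in INPUT_NAMES:
        data[name] = np.full_like(t, INPUT_BASELINES[name])
    desc = []
    for name, (lo, hi) in steps.items():
        if name not in INPUT_NAMES:
            raise ValueError(f"unknown input variable {name!r}")
        _check_plausible(name, lo)
        _check_plausible(name, hi)
        wave = np.full_like(t, lo)
        wave[(t >= t_step) & (t < t_return)] = hi
        data[name] = wave
        desc.append(f"{name}: {lo} -> {hi} -> {lo}")
    return InputTimeline(pd.DataFrame(data), meta="step " + "; ".join(desc))


#: Default oscillation frequencies [Hz] for the multi-frequency protocol; all
#: complete an integer number of cycles over the default 600 s segment, so
#: the input deviations are mutually near-orthogonal.
DEFAULT_FREQUENCIES = {
    "Pa": 0.020,
    "PaCO2": 0.035,
    "SaO2": 0.010,
    "u": 0.025,
    "Flux_y": 0.015,
}

#: Default oscillation amplitudes (half the distance from baseline to the
#: range bound, so excursions stay inside the simulation ranges).
DEFAULT_AMPLITUDES = {"Pa": 12.5, "PaCO2": 1.25, "SaO2": 2.0, "u": 0.125, "Flux_y": 0.125}


def build_multifrequency_protocol(
    frequencies: dict[str, float] | None = None,
    amplitudes: dict[str, float] | None = None,
    *,
    t_baseline: float = 120.0,
    t_oscillation: float = 600.0,
    t_post: float = 120.0,
    dt: float = 1.0,
) -> InputTimeline:
    """Each input oscillates around baseline at its own frequency.

    Distinct frequencies make the input deviations linearly independent
    (pairwise correlations < 0.05 over the oscillatory segment), so the
    compartment responses are separable in principle.
    """
    freqs = dict(DEFAULT_FREQUENCIES if frequencies is None else frequencies)
    amps = dict(DEFAULT_AMPLITUDES if amplitudes is None else amplitudes)
    active = [n for n in freqs if amps.get(n, 0.0) != 0.0]
    if len({freqs[n] for n in active}) != len(active):
        raise ValueError("oscillation frequencies must be pairwise distinct")

    t = np.arange(0.0, t_baseline + t_oscillation + t_post + 0.5 * dt, dt)
    osc = (t >= t_baseline) & (t < t_baseline + t_oscillation)
    data = {"t": t}
    for name in INPUT_NAMES:
        base = INPUT_BASELINES[name]
        wave = np.full_like(t, base)
        a = amps.get(name, 0.0)
        if name in freqs and a != 0.0:
            phase = 2.0 * np.pi * freqs[name] * (t[osc] - t_baseline)
            wave[osc] = base + a * np.sin(phase)
        data[name] = wave
    return InputTimeline(pd.DataFrame(data), meta="multifrequency")


@dataclass
class SimulationResult:
    """Trajectories and NIRS outputs of a model run."""

    df: pd.DataFrame  # t + output columns (CSV layout)
    states: pd.DataFrame  # state and derived-variable trajectories
    cerebral: HaemoglobinSignals
    scalp: HaemoglobinSignals
    merged: HaemoglobinSignals

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)


def run_simulation(
    timeline: InputTimeline, config: RunConfig | None = None
) -> SimulationResult:
    """Integrate both compartments over ``timeline`` and compute NIRS outputs.

    Both compartments start at their steady state for the first input sample,
    so a held-baseline timeline produces flat outputs.  Integration uses
    LSODA with scaled absolute tolerances; outputs are sampled every
    ``config.sample_dt`` seconds regardless of internal solver steps.
    The run is deterministic.
    """
    if config is None:
        config = default_config()
    cp, sp = config.cerebral, config.scalp

    t_grid = timeline.t
    t0, tf = float(t_grid[0]), float(t_grid[-1])
    n_out = int(np.floor((tf - t0) / config.sample_dt + 1e-9)) + 1
    t_out = t0 + config.sample_dt * np.arange(n_out)

    inputs0 = timeline.inputs_at(t0)
    c0 = cer.cerebral_steady_state(inputs0, cp)
    s0 = sca.scalp_steady_state(inputs0.Pa, sca.scalp_flow(inputs0, sp), sp)
    y0 = np.concatenate([cer.state_to_vector(c0), [s0.Pv]])

    t_tab = timeline.t
    cols = {n: timeline.df[n].to_numpy(dtype=float) for n in INPUT_NAMES}

    def inputs_at(time: float) -> SystemicInputs:
        return SystemicInputs(
            **{n: float(np.interp(time, t_tab, cols[n])) for n in INPUT_NAMES}
        )

    def rhs(time: float, y: np.ndarray) -> np.ndarray:
        inputs = inputs_at(time)
        dy_c = cer._rhs(y[:9], inputs, cp)
        F = sca.scalp_flow(inputs, sp)
        state = sca.ScalpState(Pv=y[9], G=np.nan, r=np.nan, Va=np.nan, Vv=np.nan, F=F)
        dPv = sca.scalp_derivatives(state, inputs.Pa, F, sp)
        return np.concatenate([dy_c, [dPv]])

    atol = 1e-8 * np.concatenate([cer._STATE_SCALE, [10.0]])
    sol = solve_ivp(
        rhs,
        (t0, tf),
        y0,
        method="LSODA",
        t_eval=t_out,
        rtol=1e-6,
        atol=atol,
        max_step=max(timeline.dt, 1.0),
    )
    if not sol.success:
        raise ConvergenceError(
            f"ODE solver failed at t={sol.t[-1] if len(sol.t) else t0:.1f} s: "
            f"{sol.message}"
        )

    Y = sol.y
    pa = np.interp(t_out, t_tab, cols["Pa"])
    sao2 = np.interp(t_out, t_tab, cols["SaO2"])
    flux = np.interp(t_out, t_tab, cols["Flux_y"])

    # Cerebral derived series
    r_c, Pv_c, O2 = Y[0], Y[1], Y[2]
    G_c = cp.G_n * r_c**4
    q_c = G_c * (pa - Pv_c)
    Va_c = cp.Va_n * r_c**2
    Vv_c = cp.Vv_nc + Pv_c * cp.Cv
    a = q_c * cp.c_tot / 100.0
    Sv_c = (a * sao2 + cp.D_O2 * O2) / (a + cp.D_O2 * cp.phi)

    # Scalp derived series
    if sp.variant == "flux":
        F_s = flux * sp.Fy_n
    else:
        F_s = sp.lam_Fx + sp.lam_Fx_p * pa
    G_s = F_s * sp.Gv / (sp.Gv * pa - F_s)
    r_s = (G_s / sp.G_n) ** 0.25
    Va_s = sp.Va_n * r_s**2
    Vv_s = sp.Vv_nc + Y[9] * sp.Cv

    obs = config.observation
    hb_c = compartment_haemoglobin(t_out, Va_c, Vv_c, sao2, Sv_c, obs, "cerebral")
    hb_s = compartment_haemoglobin(
        t_out, Va_s, Vv_s, sao2, np.full_like(t_out, sp.SvO2_n), obs, "scalp"
    )
    hb_m = merge_signals(hb_c, hb_s, config.merge)
    doxcco = cco_output(t_out, Y[3], obs)

    df = pd.DataFrame(
        {
            "t": t_out,
            "dHbO2_cerebral": hb_c.dHbO2,
            "dHHb_cerebral": hb_c.dHHb,
            "dHbO2_scalp": hb_s.dHbO2,
            "dHHb_scalp": hb_s.dHHb,
            "dHbO2_merged": hb_m.dHbO2,
            "dHHb_merged": hb_m.dHHb,
            "doxCCO": doxcco,
        }
    )
    states = pd.DataFrame(
        {
            "t": t_out,
            **{name: Y[i] for i, name in enumerate(cer.STATE_NAMES)},
            "Pv_s": Y[9],
            "flow_c": q_c,
            "SvO2_c": Sv_c,
            "Va_c": Va_c,
            "Vv_c": Vv_c,
            "F_s": F_s,
            "Va_s": Va_s,
            "Vv_s": Vv_s,
        }
    )
    return SimulationResult(df=df, states=states, cerebral=hb_c, scalp=hb_s, merged=hb_m)


def normalise_flux(
    values: np.ndarray, t: np.ndarray | None = None, baseline_duration: float = 120.0
) -> np.ndarray:
    """Normalise a raw flux series to the median of its initial baseline window.

    The median (rather than the mean) makes the baseline robust to outliers.
    """
    values = np.asarray(values, dtype=float)
    if t is None:
        t = np.arange(len(values), dtype=float)
    t = np.asarray(t, dtype=float)
    window = values[t <= t[0] + baseline_duration]
    if window.size == 0:
        raise ValueError("baseline window is empty")
    med = float(np.median(window))
    if med == 0:
        raise ValueError("baseline median is zero; cannot normalise")
    return values / med


def moving_average(values: np.ndarray, window: float, dt: float = 1.0) -> np.ndarray:
    """Centred sliding-window mean; edge windows shrink rather than trim.

    ``window`` is in seconds; it must be at least the sampling interval.
    Shrinking the window at the edges keeps short baseline segments intact.
    """
    if window < dt:
        raise ValueError(f"window ({window}s) must be >= sampling interval ({dt}s)")
    n = max(1, int(round(window / dt)))
    s = pd.Series(np.asarray(values, dtype=float))
    return s.rolling(window=n, center=True, min_periods=1).mean().to_numpy()


def resample_linear(
    t: np.ndarray, values: np.ndarray, target_dt: float
) -> tuple[np.ndarray, np.ndarray]:
    """Linear interpolation onto a uniform grid with spacing ``target_dt``.

    The first endpoint is preserved exactly; the last is preserved when the
    span is a multiple of ``target_dt``.
    """
    t = np.asarray(t, dtype=float)
    values = np.asarray(values, dtype=float)
    dt_src = np.diff(t)
    if np.any(dt_src <= 0) or not np.allclose(dt_src, dt_src[0], rtol=1e-9, atol=1e-12):
        raise ValueError("source grid must be uniform and strictly increasing")
    n = int(np.floor((t[-1] - t[0]) / target_dt + 1e-9))
    t_new = t[0] + target_dt * np.arange(n + 1)
    return t_new, np.interp(t_new, t, values)
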