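"""The cerebral compartment: regulated blood flow, oxygen delivery and metabolism.

Structure
---------
A single regulated arterial conductance drives flow through the compartment:

    G_c = G_n * r_c**4          (Poiseuille; r_c = radius relative to baseline)
    Va_c = Va_n * r_c**2        (arterial volume follows cross-sectional area)
    q    = G_c * (Pa - Pv_c)    (inflow)

with a venous Windkessel store

    dPv_c/dt = (G_c*(Pa - Pv_c) - Pv_c*Gv) / Cv
    Vv_c     = Vv_nc + Pv_c*Cv

Vascular tone relaxes first-order (time constant tau_r) towards a set-point
that carries autoregulation, CO2 reactivity, demand coupling and a slow
tissue-oxygen feedback:

    r_set = (Pa/Pa_n)**(-g_P) * (PaCO2/PaCO2_n)**g_C
            * (1 + g_u*(u - 1)) * (O2_filt/O2_n)**(-g_O2)

Oxygen is delivered by the blood (quasi-steady venous saturation SvO2 set by
a balance of convective supply and diffusive exchange with the tissue),
consumed at rate f3 of the metabolic chain, and buffered in a tissue pool:

    dO2/dt = D_O2*(phi*SvO2 - O2) - f3

The metabolic submodel is the three-reaction chain of
:mod:`fnirsim.metabolism`; the proton motive force obeys

    C_dp * d(dp)/dt = f1 + f2 + f3 - k_L*u*dp

so that raising demand u drains dp, which disinhibits the chain and raises
CMRO2 while simultaneously dilating the vasculature through g_u.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import root

from .errors import CalibrationError, ConvergenceError, ModelDomainError
from .metabolism import MetabolicRateParams, metabolic_rates
from .types import CerebralState, MetabolicState, SystemicInputs

__all__ = [
    "CerebralParams",
    "calibrate_cerebral",
    "baseline_state",
    "cerebral_derivatives",
    "cerebral_steady_state",
    "state_to_vector",
    "vector_to_state",
    "STATE_NAMES",
]

STATE_NAMES = (
    "r_c",
    "Pv_c",
    "O2",
    "CuA_ox",
    "CuA_red",
    "a3_ox",
    "a3_red",
    "dp",
    "O2_filt",
)

# Typical magnitude of each state variable, used to scale root solves.
_STATE_SCALE = np.array([1.0, 10.0, 0.024, 1.5e-3, 7e-4, 1.5e-3, 7e-4, 145.0, 0.024])


@dataclass(frozen=True)
class CerebralParams:
    """Parameters of the cerebral compartment.

    Baseline operating point
    ------------------------
    Pa_n, PaCO2_n, SaO2_n, u_n  baseline systemic inputs
    SvO2_n                      baseline venous saturation [%] (assumed 70,
                                not printed in the source model descriptions)
    O2_n                        baseline tissue O2 [mM]
    dp_n                        baseline proton motive force [mV]
    CMRO2_n                     baseline O2 consumption [mM/s]
    q_n                         baseline blood flow [volume/s]; 0.1 means the
                                compartment blood volume turns over in 10 s
    CuA_tot, a3_tot             total redox pool sizes [mM]
    ox_frac_n                   baseline oxidised fraction of each pool

    Vascular geometry (shared conventions with the scalp compartment)
    ------------------------------------------------------------------
    Rfrac_v    venous fraction of total vascular resistance at baseline
    vratio     venous:arterial volume ratio at baseline
    Volc_frac  fraction of baseline venous volume due to compliance

    Regulation gains (dimensionless exponents/slopes on the set-point)
    ------------------------------------------------------------------
    g_P    autoregulation: rising pressure constricts (g_P ~ 0.25 gives a
           flat flow-pressure plateau since flow ~ Pa**(1-4*g_P))
    g_C    CO2 reactivity: rising PaCO2 dilates
    g_u    demand coupling: rising u dilates (functional hyperaemia)
    g_O2   tissue-O2 feedback: surplus oxygen constricts (acts through the
           slow filtered O2_filt)

    Time constants / capacities
    ---------------------------
    tau_r     radius relaxation [s]
    tau_O2f   O2 feedback filter [s]
    C_dp      proton-motive-force capacity [mM/mV]

    Derived constants (set by :func:`calibrate_cerebral`)
    -----------------------------------------------------
    Pv_n, G_n, Gv, Cv, Va_n, Vv_n, Vv_nc   vascular calibration
    c_tot    O2-carrying capacity of blood in normalised units [mM]
    phi      dissolved-O2 per % venous saturation [mM/%]
    D_O2     blood-tissue O2 exchange coefficient [1/s]
    k_L      dp consumption coefficient [mM/(s*mV)]
    """

    # baseline operating point
    Pa_n: float = 100.0
    PaCO2_n: float = 40.0
    SaO2_n: float = 96.0
    u_n: float = 1.0
    SvO2_n: float = 70.0
    O2_n: float = 0.024
    dp_n: float = 145.0
    CMRO2_n: float = 0.035
    q_n: float = 0.1
    CuA_tot: float = 2.2e-3
    a3_tot: float = 2.2e-3
    ox_frac_n: float = 0.7
    # vascular geometry
    Rfrac_v: float = 0.1
    vratio: float = 3.0
    Volc_frac: float = 0.1
    # regulation gains
    g_P: float = 0.27
    g_C: float = 1.2
    g_u: float = 0.15
    g_O2: float = 0.15
    # time constants / capacities
    tau_r: float = 5.0
    tau_O2f: float = 30.0
    C_dp: float = 4.0e-3
    # metabolic rate coefficients
    metabolic: MetabolicRateParams = field(default_factory=MetabolicRateParams)
    # derived (calibrated) constants
    Pv_n: float = float("nan")
    G_n: float = float("nan")
    Gv: float = float("nan")
    Cv: float = float("nan")
    Va_n: float = float("nan")
    Vv_n: float = float("nan")
    Vv_nc: float = float("nan")
    c_tot: float = float("nan")
    phi: float = float("nan")
    D_O2: float = float("nan")
    k_L: float = float("nan")


#: Qualitative steady-state response targets used by default calibration:
#: sign of (dHbO2, dHHb) for a step of each input to the upper end of its
#: simulation range, plus monotonicity of CMRO2 in demand.
DEFAULT_TARGETS: dict[str, tuple[int, int]] = {
    "Pa": (-1, -1),
    "PaCO2": (+1, -1),
    "SaO2": (+1, -1),
    "u": (+1, -1),
}


def _with_derived(params: CerebralParams) -> CerebralParams:
    """Fill in the derived calibration constants so that the baseline is an
    exact fixed point of the dynamics."""
    if not (0.0 < params.Rfrac_v < 1.0 and 0.0 < params.Volc_frac < 1.0):
        raise CalibrationError(
            "Rfrac_v and Volc_frac must lie strictly between 0 and 1"
        )
    if params.vratio <= 0:
        raise CalibrationError("vratio must be positive")

    Pv_n = params.Rfrac_v * params.Pa_n
    G_n = params.q_n / (params.Pa_n - Pv_n)
    Gv = params.q_n / Pv_n
    Va_n = 1.0 / (1.0 + params.vratio)
    Vv_n = params.vratio / (1.0 + params.vratio)
    Cv = params.Volc_frac * Vv_n / Pv_n
    Vv_nc = (1.0 - params.Volc_frac) * Vv_n

    extraction = params.SaO2_n - params.SvO2_n
    if extraction <= 0:
        raise CalibrationError("baseline SvO2 must be below baseline SaO2")
    c_tot = params.CMRO2_n * 100.0 / (params.q_n * extraction)
    # Put the baseline capillary dissolved-O2 level at twice tissue O2 so the
    # diffusion gradient is well-defined; D_O2 then follows from the baseline
    # flux balance D_O2*(phi*SvO2_n - O2_n) = CMRO2_n.
    phi = 2.0 * params.O2_n / params.SvO2_n
    D_O2 = params.CMRO2_n / params.O2_n
    k_L = 3.0 * params.CMRO2_n / (params.u_n * params.dp_n)

    # Intercepts of the rate equations: f1 = f2 = f3 = CMRO2_n at baseline.
    m = params.metabolic
    cua_ox = params.ox_frac_n * params.CuA_tot
    cua_red = params.CuA_tot - cua_ox
    a3_ox = params.ox_frac_n * params.a3_tot
    a3_red = params.a3_tot - a3_ox
    lam_f1 = params.CMRO2_n - m.lam_f1_p * params.dp_n - m.lam_f1_a * math.log(cua_ox)
    lam_f2 = (
        params.CMRO2_n
        - m.lam_f2_p * params.dp_n
        - m.lam_f2_a * math.log(cua_red)
        - m.lam_f2_b * math.log(a3_ox)
    )
    lam_f3 = (
        params.CMRO2_n
        - m.lam_f3_p * params.dp_n
        - m.lam_f3_b * math.log(a3_red)
        - m.lam_f3_O * math.log(params.O2_n)
    )
    metabolic = dataclasses.replace(m, lam_f1=lam_f1, lam_f2=lam_f2, lam_f3=lam_f3)

    return dataclasses.replace(
        params,
        metabolic=metabolic,
        Pv_n=Pv_n,
        G_n=G_n,
        Gv=Gv,
        Cv=Cv,
        Va_n=Va_n,
        Vv_n=Vv_n,
        Vv_nc=Vv_nc,
        c_tot=c_tot,
        phi=phi,
        D_O2=D_O2,
        k_L=k_L,
    )


def baseline_state(params: CerebralParams) -> CerebralState:
    """The calibrated baseline state (a fixed point by construction)."""
    cua_ox = params.ox_frac_n * params.CuA_tot
    a3_ox = params.ox_frac_n * params.a3_tot
    met = MetabolicState(
        CuA_ox=cua_ox,
        CuA_red=params.CuA_tot - cua_ox,
        a3_ox=a3_ox,
        a3_red=params.a3_tot - a3_ox,
        dp=params.dp_n,
        O2=params.O2_n,
    )
    state = CerebralState(r_c=1.0, Pv_c=params.Pv_n, metabolic=met, O2_filt=params.O2_n)
    return _fill_derived(state, SystemicInputs.baseline(), params)


def venous_saturation(
    q: float, O2: float, SaO2: float, params: CerebralParams
) -> float:
    """Quasi-steady venous saturation [%] from the convection-diffusion balance

        q*c_tot*(SaO2 - SvO2)/100 = D_O2*(phi*SvO2 - O2)
    """
    a = q * params.c_tot / 100.0
    denom = a + params.D_O2 * params.phi
    return (a * SaO2 + params.D_O2 * O2) / denom


def _fill_derived(
    state: CerebralState, inputs: SystemicInputs, params: CerebralParams
) -> CerebralState:
    G = params.G_n * state.r_c**4
    q = G * (inputs.Pa - state.Pv_c)
    Va = params.Va_n * state.r_c**2
    Vv = params.Vv_nc + state.Pv_c * params.Cv
    Sv = venous_saturation(q, state.metabolic.O2, inputs.SaO2, params)
    _, _, f3 = metabolic_rates(state.metabolic, params.metabolic)
    return dataclasses.replace(
        state, G_c=G, Va_c=Va, Vv_c=Vv, flow=q, SvO2_c=Sv, CMRO2=f3
    )


def state_to_vector(state: CerebralState) -> np.ndarray:
    m = state.metabolic
    return np.array(
        [
            state.r_c,
            state.Pv_c,
            m.O2,
            m.CuA_ox,
            m.CuA_red,
            m.a3_ox,
            m.a3_red,
            m.dp,
            state.O2_filt,
        ]
    )


def vector_to_state(
    y: np.ndarray, inputs: SystemicInputs, params: CerebralParams
) -> CerebralState:
    met = MetabolicState(
        CuA_ox=y[3], CuA_red=y[4], a3_ox=y[5], a3_red=y[6], dp=y[7], O2=y[2]
    )
    state = CerebralState(r_c=y[0], Pv_c=y[1], metabolic=met, O2_filt=y[8])
    return _fill_derived(state, inputs, params)


def radius_setpoint(
    inputs: SystemicInputs, O2_filt: float, params: CerebralParams
) -> float:
    return (
        (inputs.Pa / params.Pa_n) ** (-params.g_P)
        * (inputs.PaCO2 / params.PaCO2_n) ** params.g_C
        * (1.0 + params.g_u * (inputs.u - params.u_n))
        * (O2_filt / params.O2_n) ** (-params.g_O2)
    )


def _rhs(y: np.ndarray, inputs: SystemicInputs, params: CerebralParams) -> np.ndarray:
    """Time derivative of the packed state vector."""
    r, Pv, O2, cua_ox, cua_red, a3_ox, a3_red, dp, O2f = y
    met = MetabolicState(
        CuA_ox=cua_ox, CuA_red=cua_red, a3_ox=a3_ox, a3_red=a3_red, dp=dp, O2=O2
    )
    f1, f2, f3 = metabolic_rates(met, params.metabolic)

    G = params.G_n * r**4
    q = G * (inputs.Pa - Pv)
    Sv = venous_saturation(q, O2, inputs.SaO2, params)

    r_set = radius_setpoint(inputs, O2f, params)
    dr = (r_set - r) / params.tau_r
    dPv = (G * (inputs.Pa - Pv) - Pv * params.Gv) / params.Cv
    dO2 = params.D_O2 * (params.phi * Sv - O2) - f3
    dcua_red = f1 - f2
    da3_red = f2 - f3
    ddp = (f1 + f2 + f3 - params.k_L * inputs.u * dp) / params.C_dp
    dO2f = (O2 - O2f) / params.tau_O2f

    out = np.array([dr, dPv, dO2, -dcua_red, dcua_red, -da3_red, da3_red, ddp, dO2f])
    if not np.all(np.isfinite(out)):
        raise ConvergenceError(
            f"non-finite cerebral derivative at state {y!r} with inputs {inputs!r}"
        )
    return out


def cerebral_derivatives(
    state: CerebralState, inputs: SystemicInputs, params: CerebralParams
) -> CerebralState:
    """Time derivative of ``state``, returned in the same container.

    Pool conservation is exact: the derivatives of the ox and red members of
    each pool sum to zero by construction.
    """
    dy = _rhs(state_to_vector(state), inputs, params)
    met = MetabolicState.__new__(MetabolicState)
    object.__setattr__(met, "CuA_ox", dy[3])
    object.__setattr__(met, "CuA_red", dy[4])
    object.__setattr__(met, "a3_ox", dy[5])
    object.__setattr__(met, "a3_red", dy[6])
    object.__setattr__(met, "dp", dy[7])
    object.__setattr__(met, "O2", dy[2])
    return CerebralState(r_c=dy[0], Pv_c=dy[1], metabolic=met, O2_filt=dy[8])


def cerebral_steady_state(
    inputs: SystemicInputs,
    params: CerebralParams,
    tol: float = 1e-8,
    initial: CerebralState | None = None,
) -> CerebralState:
    """Solve for the steady state of the cerebral compartment at ``inputs``.

    A reduced root solve is performed in (r_c, Pv_c, O2, CuA_red, a3_red, dp);
    pool totals are conserved and the O2 feedback filter equals O2 at steady
    state.  Deterministic given inputs and params.

    Raises
    ------
    ConvergenceError
        If the scaled residual norm exceeds ``tol``.
    """
    if initial is None:
        initial = baseline_state(params)
    y0 = state_to_vector(initial)
    cua_tot = initial.metabolic.CuA_total
    a3_tot = initial.metabolic.a3_total
    scale = _STATE_SCALE[[0, 1, 2, 4, 6, 7]]

    def expand(x: np.ndarray) -> np.ndarray:
        r, Pv, O2, cua_red, a3_red, dp = x * scale
        return np.array(
            [r, Pv, O2, cua_tot - cua_red, cua_red, a3_tot - a3_red, a3_red, dp, O2]
        )

    def residual(x: np.ndarray) -> np.ndarray:
        dy = _rhs(expand(x), inputs, params)
        # residuals for the reduced coordinates, scaled to comparable size
        return np.array(
            [
                dy[0] / scale[0],
                dy[1] / scale[1] * 0.01,  # Pv dynamics are stiff; de-weight
                dy[2] / scale[2],
                dy[4] / scale[3],
                dy[6] / scale[4],
                dy[7] / scale[5],
            ]
        )

    x0 = y0[[0, 1, 2, 4, 6, 7]] / scale
    sol = root(residual, x0, method="hybr", tol=1e-12)
    y = expand(sol.x)
    dy = _rhs(y, inputs, params)
    res = float(np.linalg.norm(dy / _STATE_SCALE))
    if res > tol:
        raise ConvergenceError(
            f"cerebral steady state did not converge at {inputs!r}: "
            f"scaled residual {res:.3e} > {tol:.1e}"
        )
    return vector_to_state(y, inputs, params)


def _hb_fractions(state: CerebralState, SaO2: float) -> tuple[float, float]:
    """(oxy, deoxy) haemoglobin content in volume*fraction units."""
    hbo2 = state.Va_c * SaO2 / 100.0 + state.Vv_c * state.SvO2_c / 100.0
    hhb = state.Va_c * (1.0 - SaO2 / 100.0) + state.Vv_c * (1.0 - state.SvO2_c / 100.0)
    return hbo2, hhb


def calibrate_cerebral(
    targets: dict[str, tuple[int, int]] | None = None,
    check_cmro2_monotone: bool = True,
    **overrides,
) -> CerebralParams:
    """Build a calibrated cerebral parameter set.

    Derived constants (vascular calibration, O2 transport coefficients and
    rate-equation intercepts) are computed analytically so that the baseline
    operating point is an exact fixed point of the dynamics.  The resulting
    parameter set is then verified against qualitative steady-state response
    targets: the sign of (dHbO2, dHHb) for a step of each input to the upper
    end of its range (``DEFAULT_TARGETS``), and monotonicity of CMRO2 in
    demand.  The procedure is deterministic.

    Parameters
    ----------
    targets
        Mapping input name -> (sign of dHbO2, sign of dHHb); pass ``{}`` to
        skip verification (e.g. for degenerate zero-gain parameter sets).
    **overrides
        Field overrides for :class:`CerebralParams` (e.g. ``g_C=0.8`` or
        ``metabolic=MetabolicRateParams(...)``).

    Raises
    ------
    CalibrationError
        Listing every violated target, if any.
    """
    if targets is None:
        targets = DEFAULT_TARGETS
    params = _with_derived(CerebralParams(**overrides))

    violations: list[str] = []
    base = baseline_state(params)
    base_inputs = SystemicInputs.baseline()
    hbo2_0, hhb_0 = _hb_fractions(base, base_inputs.SaO2)

    from .types import INPUT_RANGES  # local import to avoid cycle at module load

    for name, (sign_hbo2, sign_hhb) in targets.items():
        upper = INPUT_RANGES[name][1]
        inputs = base_inputs.replace(**{name: upper})
        ss = cerebral_steady_state(inputs, params)
        hbo2, hhb = _hb_fractions(ss, inputs.SaO2)
        d_hbo2, d_hhb = hbo2 - hbo2_0, hhb - hhb_0
        if sign_hbo2 != 0 and math.copysign(1, d_hbo2) != sign_hbo2:
            violations.append(
                f"{name} -> upper: dHbO2 has sign {math.copysign(1, d_hbo2):+.0f}, "
                f"target {sign_hbo2:+d} (value {d_hbo2:.3e})"
            )
        if sign_hhb != 0 and math.copysign(1, d_hhb) != sign_hhb:
            violations.append(
                f"{name} -> upper: dHHb has sign {math.copysign(1, d_hhb):+.0f}, "
                f"target {sign_hhb:+d} (value {d_hhb:.3e})"
            )

    if check_cmro2_monotone and targets:
        cmro2 = [
            cerebral_steady_state(base_inputs.replace(u=u), params).CMRO2
            for u in (0.75, 1.0, 1.25)
        ]
        if not (cmro2[0] <= cmro2[1] + 1e-12 and cmro2[1] <= cmro2[2] + 1e-12):
            violations.append(
                f"CMRO2 not monotone non-decreasing in u: {cmro2}"
            )

    if violations:
        raise CalibrationError(
            "calibration targets violated:\n  " + "\n  ".join(violations)
        )
    return params
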