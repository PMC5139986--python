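"""The extracerebral (scalp) compartment: a Windkessel with no regulation.

Flow through the scalp is driven by arterial pressure across a variable
arterial conductance (F = P*G, Ohm's-law analogue), with conductance set by
vessel geometry (G proportional to r**4, Poiseuille) and arterial volume by
cross-sectional area (Va proportional to r**2).  The venous side contributes
a small fixed resistance and acts as a volume store through a constant
compliance Cv:

    Vv = Vv_nc + Pv*Cv
    dPv/dt = (G*(Pa - Pv) - Pv*Gv) / Cv

Two flow estimates are supported.  The *pressure-based* variant predicts flow
from arterial pressure alone, F_x = lam_Fx + lam_Fx_p*Pa; the *flux-based*
variant rescales a measured, baseline-normalised laser-Doppler flux,
F_y = Flux_y * Fy_n.  In both cases the arterial conductance is back-computed
from the flow estimate, interpreting it as the steady through-flow the
vessels would carry at the current arterial pressure:

    G = F*Gv / (Gv*Pa - F)

which reproduces the steady-state venous divider Pv* = G*Pa/(G + Gv) and, at
baseline, the venous resistance share Pv/Pa = Rfrac_v.

The compartment is conditionally independent of the cerebral model: no scalp
variable depends on cerebral state.  No metabolism is modelled; arterial
saturation equals the systemic SaO2 and venous saturation is pinned at the
cerebral baseline venous saturation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .errors import CalibrationError, ModelDomainError
from .types import ScalpState, SystemicInputs

__all__ = [
    "ScalpParams",
    "PRESSURE_FLUX_TABLE",
    "fit_pressure_flow_coefficients",
    "scalp_flow_pressure",
    "scalp_flow_flux",
    "scalp_flow",
    "conductance_from_flow",
    "scalp_state_from_flow",
    "scalp_derivatives",
    "scalp_steady_state",
    "calibrate_scalp",
    "scalp_oxygen",
]

#: Synthetic pressure-flux calibration table (mean arterial pressure [mmHg],
#: scalp flux relative to its value at 100 mmHg).  This is a *synthetic*
#: stand-in for an experimental pressure/laser-Doppler data set that is not
#: distributed: it encodes weak scalp autoregulation (flow rises ~0.8-0.9%
#: per mmHg, i.e. nearly passively) with small deterministic scatter.  The
#: default lam_Fx/lam_Fx_p coefficients are obtained by a linear fit to it.
PRESSURE_FLUX_TABLE = np.array(
    [
        [75.0, 0.781],
        [80.0, 0.829],
        [85.0, 0.874],
        [90.0, 0.915],
        [95.0, 0.956],
        [100.0, 1.000],
        [105.0, 1.047],
        [110.0, 1.089],
        [115.0, 1.128],
        [120.0, 1.169],
        [125.0, 1.212],
    ]
)


def fit_pressure_flow_coefficients(
    table: np.ndarray | None = None, q_n: float = 0.1
) -> tuple[float, float]:
    """Fit F = lam_Fx + lam_Fx_p * Pa to a (pressure, relative flux) table.

    The relative flux column is scaled by the baseline flow ``q_n`` so the
    returned coefficients are in absolute normalised flow units.
    """
    if table is None:
        table = PRESSURE_FLUX_TABLE
    slope, intercept = np.polyfit(table[:, 0], table[:, 1] * q_n, 1)
    return float(intercept), float(slope)


_DEFAULT_LAM_FX, _DEFAULT_LAM_FX_P = fit_pressure_flow_coefficients()


@dataclass(frozen=True)
class ScalpParams:
    """Parameters and derived calibration constants of the scalp compartment.

    Control parameters (paper-stated defaults): ``Volc_frac`` and ``Rfrac_v``
    both 0.1, venous:arterial volume ratio ``vratio`` 3:1.  ``q_n`` is the
    baseline flow in normalised volume/s.  ``lam_Fx``/``lam_Fx_p`` are the
    pressure-based flow coefficients; ``Fy_n`` is the 'normal' flow by which
    a normalised laser-Doppler flux is multiplied in the flux-based variant
    (default: the pressure-model prediction at baseline pressure, so the two
    variants agree at baseline).  ``SvO2_n`` is the fixed venous saturation,
    equal to the cerebral baseline venous saturation.

    Derived constants are filled in by :func:`calibrate_scalp`.
    """

    Volc_frac: float = 0.1
    Rfrac_v: float = 0.1
    vratio: float = 3.0
    q_n: float = 0.1
    SvO2_n: float = 70.0
    lam_Fx: float = _DEFAULT_LAM_FX
    lam_Fx_p: float = _DEFAULT_LAM_FX_P
    Fy_n: float = float("nan")  # default set by calibrate_scalp
    variant: str = "pressure"  # "pressure" | "flux"
    # derived
    Pa_n: float = 100.0
    Pv_n: float = float("nan")
    G_n: float = float("nan")
    Gv: float = float("nan")
    Cv: float = float("nan")
    Va_n: float = float("nan")
    Vv_n: float = float("nan")
    Vv_nc: float = float("nan")

    def __post_init__(self) -> None:
        if self.variant not in ("pressure", "flux"):
            raise CalibrationError(
                f"scalp variant must be 'pressure' or 'flux', got {self.variant!r}"
            )


def scalp_flow_pressure(Pa: float, params: ScalpParams) -> float:
    """Pressure-based flow estimate F_x = lam_Fx + lam_Fx_p * Pa."""
    if Pa <= 0:
        raise ModelDomainError(f"Pa must be positive, got {Pa}")
    F = params.lam_Fx + params.lam_Fx_p * Pa
    if F <= 0:
        raise CalibrationError(
            f"pressure-based scalp flow is non-positive ({F:.4g}) at "
            f"Pa={Pa}; lam_Fx/lam_Fx_p parameterisation invalid in this range"
        )
    return F


def scalp_flow_flux(Flux_y: float, params: ScalpParams) -> float:
    """Flux-based flow estimate F_y = Flux_y * Fy_n."""
    if Flux_y <= 0:
        raise ModelDomainError(f"Flux_y must be positive, got {Flux_y}")
    return Flux_y * params.Fy_n


def scalp_flow(inputs: SystemicInputs, params: ScalpParams) -> float:
    """Flow estimate for the configured variant."""
    if params.variant == "flux":
        return scalp_flow_flux(inputs.Flux_y, params)
    return scalp_flow_pressure(inputs.Pa, params)


def conductance_from_flow(F: float, Pa: float, params: ScalpParams) -> float:
    """Arterial conductance implied by a steady through-flow F at pressure Pa.

    Solves F = G*(Pa - Pv*) with Pv* = G*Pa/(G + Gv), giving
    G = F*Gv/(Gv*Pa - F).
    """
    denom = params.Gv * Pa - F
    if denom <= 0:
        raise ModelDomainError(
            f"flow estimate {F:.4g} exceeds what the venous bed can pass at "
            f"Pa={Pa} (Gv*Pa={params.Gv * Pa:.4g})"
        )
    return F * params.Gv / denom


def scalp_state_from_flow(Pv: float, Pa: float, F: float, params: ScalpParams) -> ScalpState:
    """Assemble the full scalp state from venous pressure, arterial pressure
    and the flow estimate (G from the flow, r from G, Va from r, Vv from Pv)."""
    G = conductance_from_flow(F, Pa, params)
    r = (G / params.G_n) ** 0.25
    Va = params.Va_n * r**2
    Vv = params.Vv_nc + Pv * params.Cv
    return ScalpState(Pv=Pv, G=G, r=r, Va=Va, Vv=Vv, F=F)


def scalp_derivatives(
    state: ScalpState, Pa: float, flow_estimate: float, params: ScalpParams
) -> float:
    """dPv/dt [mmHg/s] of the venous Windkessel.

    The arterial conductance is back-computed from the flow estimate; venous
    pressure then relaxes towards the divider value G*Pa/(G+Gv) with time
    constant Cv/(G+Gv).
    """
    if Pa == state.Pv:
        raise ModelDomainError("Pa equals Pv: conductance back-calculation undefined")
    G = conductance_from_flow(flow_estimate, Pa, params)
    return (G * (Pa - state.Pv) - state.Pv * params.Gv) / params.Cv


def scalp_steady_state(Pa: float, flow_estimate: float, params: ScalpParams) -> ScalpState:
    """Steady state at constant Pa and flow estimate: Pv* = G*Pa/(G+Gv)."""
    G = conductance_from_flow(flow_estimate, Pa, params)
    Pv = G * Pa / (G + params.Gv)
    return scalp_state_from_flow(Pv, Pa, F=flow_estimate, params=params)


def calibrate_scalp(
    params: ScalpParams | None = None,
    baseline_inputs: SystemicInputs | None = None,
) -> tuple[ScalpParams, ScalpState]:
    """Derive the baseline calibration constants of the scalp compartment.

    Volumes are normalised so total blood volume is 1 at baseline with
    venous:arterial ratio ``vratio``; the venous resistance share is
    ``Rfrac_v`` (hence Pv_n = Rfrac_v*Pa_n, with post-venous pressure taken
    as zero) and the compliant share of venous volume is ``Volc_frac``
    (fixing Cv).  Returns the calibrated parameters and the baseline state,
    which satisfies dPv/dt = 0 exactly.
    """
    if params is None:
        params = ScalpParams()
    if baseline_inputs is None:
        baseline_inputs = SystemicInputs.baseline()
    if not (0.0 < params.Rfrac_v < 1.0 and 0.0 < params.Volc_frac < 1.0):
        raise CalibrationError("Rfrac_v and Volc_frac must lie strictly in (0, 1)")
    if params.vratio <= 0:
        raise CalibrationError("vratio must be positive")

    Pa_n = baseline_inputs.Pa
    Pv_n = params.Rfrac_v * Pa_n
    G_n = params.q_n / (Pa_n - Pv_n)
    Gv = params.q_n / Pv_n
    Va_n = 1.0 / (1.0 + params.vratio)
    Vv_n = params.vratio / (1.0 + params.vratio)
    Cv = params.Volc_frac * Vv_n / Pv_n
    Vv_nc = (1.0 - params.Volc_frac) * Vv_n

    Fy_n = params.Fy_n
    if not np.isfinite(Fy_n):
        Fy_n = params.lam_Fx + params.lam_Fx_p * Pa_n
    if Fy_n <= 0:
        raise CalibrationError(f"normal flux-based flow Fy_n must be positive, got {Fy_n}")

    calibrated = dataclasses.replace(
        params,
        Fy_n=Fy_n,
        Pa_n=Pa_n,
        Pv_n=Pv_n,
        G_n=G_n,
        Gv=Gv,
        Cv=Cv,
        Va_n=Va_n,
        Vv_n=Vv_n,
        Vv_nc=Vv_nc,
    )
    # Baseline state: by construction at flow q_n the divider gives Pv_n and
    # volumes sum to 1 with the requested split.
    base = scalp_steady_state(Pa_n, calibrated.q_n, calibrated)
    for name, value, target in [
        ("total volume", base.Va + base.Vv, 1.0),
        ("venous:arterial ratio", base.Vv / base.Va, params.vratio),
        ("venous pressure share", base.Pv / Pa_n, params.Rfrac_v),
        ("compliant venous share", base.Pv * Cv / base.Vv, params.Volc_frac),
    ]:
        if abs(value - target) > 1e-9 * max(1.0, abs(target)):
            raise CalibrationError(
                f"scalp baseline violates {name}: {value!r} != {target!r}"
            )
    return calibrated, base


def scalp_oxygen(state: ScalpState, SaO2: float, params: ScalpParams) -> tuple[float, float]:
    """(arterial, venous) saturation [%] of the scalp blood volumes.

    Arterial saturation tracks the systemic SaO2 instantaneously; venous
    saturation is fixed at the cerebral baseline venous saturation (no scalp
    metabolism is modelled, oxygen consumption is implicitly constant).
    """
    if not 0.0 <= SaO2 <= 100.0:
        raise ModelDomainError(f"SaO2 must lie in [0, 100], got {SaO2}")
    return SaO2, params.SvO2_n
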