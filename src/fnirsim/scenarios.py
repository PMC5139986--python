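"""False-positive / false-negative scenario machinery.

Functional activation is classically identified by a rise in HbO2 with a
simultaneous fall in HHb.  Because systemic factors (arterial pressure, CO2)
and superficial blood flow also move the NIRS signals, combinations of them
can mimic that signature with no change in demand (a false positive, FP) or
mask it when demand did rise (a false negative, FN).  Three FN archetypes are
distinguished: FN1 no haemodynamic change at all; FN2 HbO2 rises but HHb is
flat; FN3 both HbO2 and HHb rise.

The machinery here works on *steady-state* responses: a distance-based
classifier (lowest total absolute error against the templates), a response
surface sweep over the Pa x PaCO2 plane, and a seeded global optimisation
that searches input-step combinations reproducing a chosen template.
Template magnitudes are parameterised by the model's own response to a
demand step u = 1 -> 1.25 (exact excursions are not externally prescribed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import differential_evolution

from . import scalp as sca
from .cerebral import cerebral_steady_state, baseline_state
from .config import RunConfig, default_config
from .types import (
    INPUT_RANGES,
    SAO2_OPTIMISATION_UPPER,
    SystemicInputs,
)

__all__ = [
    "ResponseTemplate",
    "standard_templates",
    "activation_response",
    "steady_state_response",
    "classify_response",
    "sweep_response_surface",
    "optimise_scenario",
    "ScenarioResult",
]

TEMPLATE_ORDER = ("activation", "FN1", "FN2", "FN3")


@dataclass(frozen=True)
class ResponseTemplate:
    """Target steady-state (dHbO2, dHHb) pattern [uM] for one scenario label."""

    label: str
    dHbO2: float
    dHHb: float


def _cerebral_hb(state, SaO2: float, hb_scale: float) -> tuple[float, float]:
    hbo2 = hb_scale * (state.Va_c * SaO2 + state.Vv_c * state.SvO2_c) / 100.0
    hhb = hb_scale * (
        state.Va_c * (1.0 - SaO2 / 100.0) + state.Vv_c * (1.0 - state.SvO2_c / 100.0)
    )
    return hbo2, hhb


def steady_state_response(
    inputs: SystemicInputs, config: RunConfig
) -> tuple[float, float]:
    """Steady-state cerebral (dHbO2, dHHb) [uM] relative to the baseline state."""
    base_inputs = SystemicInputs.baseline()
    hb = config.observation.hb_scale
    b0 = baseline_state(config.cerebral)
    h0 = _cerebral_hb(b0, base_inputs.SaO2, hb)
    ss = cerebral_steady_state(inputs, config.cerebral)
    h = _cerebral_hb(ss, inputs.SaO2, hb)
    return h[0] - h0[0], h[1] - h0[1]


def activation_response(config: RunConfig, u_active: float = 1.25) -> tuple[float, float]:
    """The model's canonical activation response: steady-state effect of a
    pure demand step to ``u_active`` (dHbO2 > 0, dHHb < 0)."""
    return steady_state_response(SystemicInputs.baseline().replace(u=u_active), config)


def standard_templates(
    config: RunConfig | None = None, u_active: float = 1.25
) -> list[ResponseTemplate]:
    """Activation plus the three FN archetypes, scaled by the model's own
    activation response (a, b):  activation=(a, b), FN1=(0, 0), FN2=(a, 0),
    FN3=(a, -b) with b < 0 so FN3 has HHb *rising* by the magnitude it would
    normally fall."""
    if config is None:
        config = default_config()
    a, b = activation_response(config, u_active)
    return [
        ResponseTemplate("activation", a, b),
        ResponseTemplate("FN1", 0.0, 0.0),
        ResponseTemplate("FN2", a, 0.0),
        ResponseTemplate("FN3", a, -b),
    ]


def classify_response(
    dHbO2: float, dHHb: float, templates: list[ResponseTemplate]
) -> tuple[str, dict[str, float]]:
    """Nearest template by total absolute error |dHbO2-t1| + |dHHb-t2|.

    Ties are broken by template order in the list (documented, fixed).
    Returns the winning label and the per-template distances.
    """
    if not templates:
        raise ValueError("need at least one template")
    distances = {
        tpl.label: abs(dHbO2 - tpl.dHbO2) + abs(dHHb - tpl.dHHb) for tpl in templates
    }
    best = min(range(len(templates)), key=lambda i: distances[templates[i].label])
    return templates[best].label, distances


def sweep_response_surface(
    pa_values: np.ndarray | None = None,
    paco2_values: np.ndarray | None = None,
    u: float = 1.0,
    config: RunConfig | None = None,
    templates: list[ResponseTemplate] | None = None,
) -> pd.DataFrame:
    """Classified steady-state response surface over the Pa x PaCO2 plane.

    Simultaneous step changes in Pa and PaCO2 (and, for ``u`` > 1, demand)
    are applied and only the final steady state is classified.  Default grid:
    21 x 21 over the simulation ranges.  Deterministic.

    Returns a DataFrame with columns Pa, PaCO2, dHbO2, dHHb, label, distance.
    """
    if config is None:
        config = default_config()
    if pa_values is None:
        pa_values = np.linspace(*INPUT_RANGES["Pa"], 21)
    if paco2_values is None:
        paco2_values = np.linspace(*INPUT_RANGES["PaCO2"], 21)
    if templates is None:
        templates = standard_templates(config)

    base = SystemicInputs.baseline()
    rows = []
    for pa in np.asarray(pa_values, dtype=float):
        for co2 in np.asarray(paco2_values, dtype=float):
            x, y = steady_state_response(base.replace(Pa=pa, PaCO2=co2, u=u), config)
            label, dist = classify_response(x, y, templates)
            rows.append(
                {
                    "Pa": pa,
                    "PaCO2": co2,
                    "dHbO2": x,
                    "dHHb": y,
                    "label": label,
                    "distance": dist[label],
                }
            )
    return pd.DataFrame(rows)


@dataclass
class ScenarioResult:
    """Outcome of a scenario search."""

    template: ResponseTemplate
    inputs: dict[str, float]  # optimised step values per free variable
    w_scalp: float | None  # scalp merge weight, if the scalp was included
    achieved: tuple[float, float]  # (dHbO2, dHHb) at the optimum [uM]
    distance: float  # objective value at the optimum
    classification: str  # classifier label of the achieved output
    baseline_distance: float  # objective of the unperturbed scenario
    improved: bool
    message: str = ""


def _scenario_bounds(name: str) -> tuple[float, float]:
    lo, hi = INPUT_RANGES[name]
    if name == "SaO2":
        hi = SAO2_OPTIMISATION_UPPER  # spontaneous SaO2 rise deemed implausible
    return lo, hi


def optimise_scenario(
    template: ResponseTemplate | str,
    free_inputs: list[str],
    u: float = 1.0,
    config: RunConfig | None = None,
    seed: int = 0,
    include_scalp: bool = False,
    w_scalp_max: float = 2.0,
    maxiter: int = 40,
    popsize: int = 15,
    templates: list[ResponseTemplate] | None = None,
) -> ScenarioResult:
    """Search for input-step combinations whose steady state matches a template.

    The decision variables are step values of the ``free_inputs`` (within the
    simulation ranges; SaO2 is capped at its baseline), plus, when
    ``include_scalp`` is set, the scalp merge weight w_scalp in
    [0, ``w_scalp_max``] (the flux-based scalp response then contributes
    w_scalp * scalp steady-state deltas; include "Flux_y" among the free
    inputs to let superficial flow vary).  The objective is the classifier
    metric: total absolute error between the achieved steady-state
    (dHbO2, dHHb) and the template.  The optimiser is seeded differential
    evolution, so results are reproducible but, as for any non-convex search,
    neither unique nor necessarily optimal.
    """
    if config is None:
        config = default_config()
    if templates is None:
        templates = standard_templates(config)
    if isinstance(template, str):
        matches = [tpl for tpl in templates if tpl.label == template]
        if not matches:
            raise ValueError(f"unknown template {template!r}")
        template = matches[0]
    unknown = [n for n in free_inputs if n not in INPUT_RANGES]
    if unknown:
        raise ValueError(f"unknown free inputs: {unknown}")

    sp = config.scalp
    hb = config.observation.hb_scale
    base = SystemicInputs.baseline()
    cerebral_free = [n for n in free_inputs if n != "Flux_y"]
    flux_free = "Flux_y" in free_inputs
    if flux_free and not include_scalp:
        raise ValueError("Flux_y is only a decision variable when include_scalp=True")

    s_base = sca.scalp_steady_state(base.Pa, sp.q_n, sp)

    def scalp_deltas(flux: float) -> tuple[float, float]:
        s = sca.scalp_steady_state(base.Pa, flux * sp.Fy_n, sp)
        d_hbo2 = hb * (
            (s.Va - s_base.Va) * base.SaO2 + (s.Vv - s_base.Vv) * sp.SvO2_n
        ) / 100.0
        d_hhb = hb * (
            (s.Va - s_base.Va) * (1.0 - base.SaO2 / 100.0)
            + (s.Vv - s_base.Vv) * (1.0 - sp.SvO2_n / 100.0)
        )
        return d_hbo2, d_hhb

    def evaluate(x: np.ndarray) -> tuple[float, float]:
        values = dict(zip(cerebral_free, x))
        inputs = base.replace(u=u, **values)
        dx, dy = steady_state_response(inputs, config)
        if include_scalp:
            k = len(cerebral_free)
            flux = x[k] if flux_free else 1.0
            w = x[k + 1] if flux_free else x[k]
            sx, sy = scalp_deltas(flux)
            dx, dy = dx + w * sx, dy + w * sy
        return dx, dy

    def objective(x: np.ndarray) -> float:
        dx, dy = evaluate(x)
        return abs(dx - template.dHbO2) + abs(dy - template.dHHb)

    bounds = [_scenario_bounds(n) for n in cerebral_free]
    if include_scalp:
        if flux_free:
            bounds.append(INPUT_RANGES["Flux_y"])
        bounds.append((0.0, w_scalp_max))

    x_baseline = np.array(
        [getattr(base, n) for n in cerebral_free]
        + ([1.0] if flux_free else [])
        + ([0.0] if include_scalp else [])
    )
    baseline_distance = objective(x_baseline)

    result = differential_evolution(
        objective,
        bounds=bounds,
        seed=seed,
        maxiter=maxiter,
        popsize=popsize,
        tol=1e-8,
        polish=True,
    )
    improved = result.fun < baseline_distance - 1e-12
    if improved:
        x_best, best = result.x, float(result.fun)
        message = ""
    else:
        x_best, best = x_baseline, float(baseline_distance)
        message = "optimiser found no improvement over the unperturbed scenario"

    achieved = evaluate(x_best)
    label, _ = classify_response(*achieved, templates)
    values = dict(zip(cerebral_free, x_best))
    if flux_free:
        values["Flux_y"] = float(x_best[len(cerebral_free)])
    w_scalp = float(x_best[-1]) if include_scalp else None
    return ScenarioResult(
        template=template,
        inputs={k: float(v) for k, v in values.items()},
        w_scalp=w_scalp,
        achieved=(float(achieved[0]), float(achieved[1])),
        distance=best,
        classification=label,
        baseline_distance=float(baseline_distance),
        improved=improved,
        message=message,
    )
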