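"""Rate equations for the terminal reactions of the electron transport chain.

Three lumped redox reactions carry electrons from a reducing substrate to the
CuA centre of cytochrome c oxidase (rate f1), from CuA to the a3 centre (f2)
and finally onto O2 (f3).  Each rate is a linear function of the proton
motive force dp and of the natural logarithm of the relevant donor/acceptor
pool, so the chain slows as dp builds up and as a pool is depleted:

    f1 = lam_f1 + lam_f1_p*dp + lam_f1_a*log[CuA_ox]
    f2 = lam_f2 + lam_f2_p*dp + lam_f2_a*log[CuA_red] + lam_f2_b*log[a3_ox]
    f3 = lam_f3 + lam_f3_p*dp + lam_f3_b*log[a3_red] + lam_f3_O*log[O2]

Rates are expressed in O2-consumption-equivalent units [mM/s], so f3 is
directly the CMRO2-equivalent oxygen consumption.  A dependence on substrate
supply is deliberately omitted (assumed non-limiting in healthy volunteers).
Demand u acts on the rates only indirectly, through its effect on dp.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import ModelDomainError
from .types import MetabolicState


@dataclass(frozen=True)
class MetabolicRateParams:
    """Coefficients of the three rate equations.

    The slope coefficients (``*_p`` on dp, the others on log concentrations)
    are free model parameters; the intercepts ``lam_f1``, ``lam_f2`` and
    ``lam_f3`` are normally set by calibration so that f1 = f2 = f3 = CMRO2_n
    at the baseline operating point.  Note the intercept is *not* itself the
    baseline rate, because the other terms are non-zero at baseline.
    """

    # intercepts [mM/s]
    lam_f1: float = 0.0
    lam_f2: float = 0.0
    lam_f3: float = 0.0
    # proton-motive-force slopes [mM/s per mV]; negative: a large gradient
    # opposes further proton pumping
    lam_f1_p: float = -3.0e-4
    lam_f2_p: float = -3.0e-4
    lam_f3_p: float = -1.0e-4
    # log-concentration slopes [mM/s per ln-unit]
    lam_f1_a: float = 0.010
    lam_f2_a: float = 0.008
    lam_f2_b: float = 0.008
    lam_f3_b: float = 0.008
    lam_f3_O: float = 0.010

    def __post_init__(self) -> None:
        if self.lam_f3_O < 0:
            raise ModelDomainError(
                "lam_f3_O must be >= 0: the O2-consuming rate must not "
                f"increase as O2 -> 0 (got {self.lam_f3_O})"
            )


def _checked_log(value: float, pool: str) -> float:
    if value <= 0:
        raise ModelDomainError(
            f"cannot evaluate rate equations: pool {pool!r} is non-positive "
            f"({value!r})"
        )
    return math.log(value)


def metabolic_rates(
    state: MetabolicState, params: MetabolicRateParams
) -> tuple[float, float, float]:
    """Evaluate the three reaction rates (f1, f2, f3) [mM/s] at ``state``.

    Raises
    ------
    ModelDomainError
        If any concentration appearing inside a logarithm is non-positive;
        the message names the offending pool.
    """
    log_cua_ox = _checked_log(state.CuA_ox, "CuA_ox")
    log_cua_red = _checked_log(state.CuA_red, "CuA_red")
    log_a3_ox = _checked_log(state.a3_ox, "a3_ox")
    log_a3_red = _checked_log(state.a3_red, "a3_red")
    log_o2 = _checked_log(state.O2, "O2")

    f1 = params.lam_f1 + params.lam_f1_p * state.dp + params.lam_f1_a * log_cua_ox
    f2 = (
        params.lam_f2
        + params.lam_f2_p * state.dp
        + params.lam_f2_a * log_cua_red
        + params.lam_f2_b * log_a3_ox
    )
    f3 = (
        params.lam_f3
        + params.lam_f3_p * state.dp
        + params.lam_f3_b * log_a3_red
        + params.lam_f3_O * log_o2
    )
    return f1, f2, f3
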