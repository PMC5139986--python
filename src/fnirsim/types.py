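"""Shared domain types: systemic inputs, compartment states, NIRS signal containers.

Unit conventions used throughout the package
--------------------------------------------
time            seconds
pressures       mmHg
saturations     percent (0-100)
concentrations  mM (tissue); haemoglobin outputs are reported in uM
blood volumes   dimensionless, normalised so each compartment's total blood
                volume is 1 at baseline
blood flow      normalised volume units per second (baseline flow q_n sets the
                mean transit time, default 10 s)
proton motive   mV
force (dp)
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .errors import ModelDomainError

#: Baseline value of each systemic input variable.
INPUT_BASELINES: dict[str, float] = {
    "Pa": 100.0,
    "PaCO2": 40.0,
    "SaO2": 96.0,
    "u": 1.0,
    "Flux_y": 1.0,
}

#: (lower, upper) plausibility range of each systemic input for simulations.
INPUT_RANGES: dict[str, tuple[float, float]] = {
    "Pa": (75.0, 125.0),
    "PaCO2": (37.5, 42.5),
    "SaO2": (90.0, 100.0),
    "u": (0.75, 1.25),
    "Flux_y": (0.75, 1.25),
}

#: Upper bound on SaO2 used when *optimising* scenarios: a spontaneous rise in
#: arterial saturation is implausible in functional experiments, so the
#: baseline value is the admissible maximum for searches.
SAO2_OPTIMISATION_UPPER = 96.0

INPUT_NAMES = tuple(INPUT_BASELINES)


@dataclass(frozen=True)
class SystemicInputs:
    """One time sample of the five systemic driving variables.

    Pa      mean arterial pressure [mmHg]
    PaCO2   arterial partial pressure of CO2 [mmHg]
    SaO2    arterial O2 saturation [%]
    u       relative metabolic demand [-] (raised to represent activation)
    Flux_y  normalised laser-Doppler flux [-]
    """

    Pa: float = 100.0
    PaCO2: float = 40.0
    SaO2: float = 96.0
    u: float = 1.0
    Flux_y: float = 1.0

    def __post_init__(self) -> None:
        if not self.Pa > 0:
            raise ModelDomainError(f"Pa must be positive, got {self.Pa}")
        if not self.PaCO2 > 0:
            raise ModelDomainError(f"PaCO2 must be positive, got {self.PaCO2}")
        if not 0.0 <= self.SaO2 <= 100.0:
            raise ModelDomainError(f"SaO2 must lie in [0, 100], got {self.SaO2}")
        if not self.u > 0:
            raise ModelDomainError(f"u must be positive, got {self.u}")
        if not self.Flux_y > 0:
            raise ModelDomainError(f"Flux_y must be positive, got {self.Flux_y}")

    @classmethod
    def baseline(cls) -> "SystemicInputs":
        return cls(**INPUT_BASELINES)

    def replace(self, **changes: float) -> "SystemicInputs":
        return dataclasses.replace(self, **changes)

    def as_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class MetabolicState:
    """Redox pools, proton motive force and tissue oxygen.

    CuA_ox/CuA_red   oxidised/reduced CuA centre of CCO [mM]
    a3_ox/a3_red     oxidised/reduced a3 centre [mM]
    dp               proton motive force across the inner membrane [mV]
    O2               tissue oxygen concentration [mM]
    """

    CuA_ox: float
    CuA_red: float
    a3_ox: float
    a3_red: float
    dp: float
    O2: float

    @property
    def CuA_total(self) -> float:
        return self.CuA_ox + self.CuA_red

    @property
    def a3_total(self) -> float:
        return self.a3_ox + self.a3_red


@dataclass(frozen=True)
class CerebralState:
    """Full state of the cerebral compartment.

    r_c is the characteristic arterial radius relative to baseline; Pv_c the
    cerebral venous pressure; O2_filt a low-pass-filtered copy of tissue O2
    that carries the slow oxygen feedback on vascular tone.  Derived
    quantities (conductance, volumes, flow, venous saturation, CMRO2) are
    computed from these by the model, see :mod:`fnirsim.cerebral`.
    """

    r_c: float
    Pv_c: float
    metabolic: MetabolicState
    O2_filt: float
    # Derived, filled in by the cerebral model:
    G_c: float = float("nan")
    Va_c: float = float("nan")
    Vv_c: float = float("nan")
    flow: float = float("nan")
    SvO2_c: float = float("nan")
    CMRO2: float = float("nan")


@dataclass(frozen=True)
class ScalpState:
    """State of the extracerebral (scalp) Windkessel compartment.

    Pv is the venous pressure (the only dynamic variable); G, r, Va, Vv and F
    are derived from Pv, the arterial pressure and the flow estimate.
    """

    Pv: float
    G: float
    r: float
    Va: float
    Vv: float
    F: float


@dataclass(frozen=True)
class MergeWeights:
    """Non-negative weights for the merged (scalp + cerebral) NIRS output."""

    w_scalp: float = 1.0
    w_cerebral: float = 1.0

    def __post_init__(self) -> None:
        if self.w_scalp < 0 or self.w_cerebral < 0:
            raise ModelDomainError(
                f"merge weights must be non-negative, got "
                f"({self.w_scalp}, {self.w_cerebral})"
            )


@dataclass
class HaemoglobinSignals:
    """Time series of haemoglobin concentration changes from baseline [uM].

    The first sample of each series is 0 by construction (changes are taken
    against the first-sample baseline).
    """

    t: np.ndarray
    dHbO2: np.ndarray
    dHHb: np.ndarray
    compartment: str = "merged"

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.dHbO2 = np.asarray(self.dHbO2, dtype=float)
        self.dHHb = np.asarray(self.dHHb, dtype=float)
        if not (len(self.t) == len(self.dHbO2) == len(self.dHHb)):
            raise ValueError(
                "t, dHbO2 and dHHb must have equal length, got "
                f"{len(self.t)}, {len(self.dHbO2)}, {len(self.dHHb)}"
            )

    def __len__(self) -> int:
        return len(self.t)
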