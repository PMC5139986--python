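"""Convert compartment volumes/saturations into NIRS-comparable signals.

The NIRS-visible haemoglobin content of a compartment is estimated from its
normalised blood volumes and saturations, scaled by a single haematocrit /
vessel-density factor shared between compartments:

    HbO2 = hb_scale * (Va*Sa + Vv*Sv) / 100     [uM]
    HHb  = hb_scale * (Va*(1-Sa/100) + Vv*(1-Sv/100))

Outputs are reported as changes from the first-sample baseline, so every
series starts at exactly zero.  Absolute uM scaling of real measurements is
not identifiable from the model alone; ``hb_scale`` defaults to a typical
adult-head tissue haemoglobin content and outputs should be read as relative
unless the user supplies their own scale.

A merged output is a non-negative weighted sum of the scalp and cerebral
signals; merging is pure post-processing and does not affect model behaviour.
The cytochrome c oxidase output reports the change in oxidised CuA (the
NIRS-visible redox marker of the metabolic submodel) in uM.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import HaemoglobinSignals, MergeWeights

__all__ = [
    "ObservationParams",
    "compartment_haemoglobin",
    "merge_signals",
    "cco_output",
]


@dataclass(frozen=True)
class ObservationParams:
    #: total tissue haemoglobin [uM] corresponding to one unit of normalised
    #: blood volume; shared between compartments
    hb_scale: float = 84.0
    #: mM -> uM conversion for the CCO redox output
    cco_scale: float = 1000.0


def compartment_haemoglobin(
    t: np.ndarray,
    Va: np.ndarray,
    Vv: np.ndarray,
    sat_a: np.ndarray,
    sat_v: np.ndarray,
    params: ObservationParams | None = None,
    compartment: str = "cerebral",
) -> HaemoglobinSignals:
    """Haemoglobin change-from-baseline series for one compartment.

    ``Va``/``Vv`` are normalised arterial/venous volumes; ``sat_a``/``sat_v``
    the corresponding saturations [%] (scalars are broadcast).  Deltas are
    taken against the first sample.
    """
    if params is None:
        params = ObservationParams()
    t = np.asarray(t, dtype=float)
    series = [np.broadcast_to(np.asarray(x, dtype=float), t.shape) for x in (Va, Vv, sat_a, sat_v)]
    if any(s.shape != t.shape for s in series):
        raise ValueError("volume/saturation series must match the time grid length")
    Va, Vv, sat_a, sat_v = series

    hbo2 = params.hb_scale * (Va * sat_a + Vv * sat_v) / 100.0
    hhb = params.hb_scale * (Va * (1.0 - sat_a / 100.0) + Vv * (1.0 - sat_v / 100.0))
    return HaemoglobinSignals(
        t=t, dHbO2=hbo2 - hbo2[0], dHHb=hhb - hhb[0], compartment=compartment
    )


def merge_signals(
    cerebral: HaemoglobinSignals,
    scalp: HaemoglobinSignals,
    weights: MergeWeights | None = None,
) -> HaemoglobinSignals:
    """Weighted sum w_scalp*scalp + w_cerebral*cerebral, elementwise."""
    if weights is None:
        weights = MergeWeights()
    if len(cerebral) != len(scalp):
        raise ValueError(
            f"series lengths differ: cerebral {len(cerebral)}, scalp {len(scalp)}"
        )
    return HaemoglobinSignals(
        t=cerebral.t,
        dHbO2=weights.w_scalp * scalp.dHbO2 + weights.w_cerebral * cerebral.dHbO2,
        dHHb=weights.w_scalp * scalp.dHHb + weights.w_cerebral * cerebral.dHHb,
        compartment="merged",
    )


def cco_output(
    t: np.ndarray, CuA_ox: np.ndarray, params: ObservationParams | None = None
) -> np.ndarray:
    """Change in oxidised CuA from baseline [uM] (the NIRS CCO marker)."""
    if params is None:
        params = ObservationParams()
    CuA_ox = np.asarray(CuA_ox, dtype=float)
    if CuA_ox.shape != np.shape(t):
        raise ValueError("CuA_ox series must match the time grid length")
    return params.cco_scale * (CuA_ox - CuA_ox[0])
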