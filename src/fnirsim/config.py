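"""Run configuration: calibrated parameter blocks plus sampling options.

Parameters serialise to a flat-per-block YAML file; symbol names match the
model notation (``lam_f1_p`` for the dp-slope of f1, etc.).  Derived
calibration constants are never written: they are recomputed from the free
parameters on load, so a config file always describes a consistent model.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .cerebral import CerebralParams, calibrate_cerebral
from .metabolism import MetabolicRateParams
from .observation import ObservationParams
from .scalp import ScalpParams, calibrate_scalp
from .types import MergeWeights

__all__ = ["RunConfig", "default_config"]

# Fields of CerebralParams that are derived by calibration (not serialised).
_CEREBRAL_DERIVED = {
    "Pv_n", "G_n", "Gv", "Cv", "Va_n", "Vv_n", "Vv_nc",
    "c_tot", "phi", "D_O2", "k_L", "metabolic",
}
_SCALP_DERIVED = {"Pa_n", "Pv_n", "G_n", "Gv", "Cv", "Va_n", "Vv_n", "Vv_nc"}
_METABOLIC_INTERCEPTS = {"lam_f1", "lam_f2", "lam_f3"}


@dataclass
class RunConfig:
    """All parameter blocks needed to run a simulation."""

    cerebral: CerebralParams
    scalp: ScalpParams
    observation: ObservationParams = field(default_factory=ObservationParams)
    merge: MergeWeights = field(default_factory=MergeWeights)
    sample_dt: float = 1.0  # output sampling interval [s]
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    def to_dict(self) -> dict:
        cer = {
            k: v
            for k, v in dataclasses.asdict(self.cerebral).items()
            if k not in _CEREBRAL_DERIVED
        }
        cer.update(
            {
                k: v
                for k, v in dataclasses.asdict(self.cerebral.metabolic).items()
                if k not in _METABOLIC_INTERCEPTS
            }
        )
        sca = {
            k: v
            for k, v in dataclasses.asdict(self.scalp).items()
            if k not in _SCALP_DERIVED and not (isinstance(v, float) and math.isnan(v))
        }
        return {
            "cerebral": cer,
            "scalp": sca,
            "observation": dataclasses.asdict(self.observation),
            "merge": dataclasses.asdict(self.merge),
            "simulation": {"sample_dt": self.sample_dt, "seed": self.seed},
        }

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data or {})
        cer_block = dict(data.get("cerebral", {}))
        met_kwargs = {
            k: cer_block.pop(k)
            for k in list(cer_block)
            if k.startswith("lam_f") and k not in _METABOLIC_INTERCEPTS
        }
        if met_kwargs:
            cer_block["metabolic"] = MetabolicRateParams(**met_kwargs)
        cerebral = calibrate_cerebral(**cer_block)
        scalp, _ = calibrate_scalp(ScalpParams(**data.get("scalp", {})))
        observation = ObservationParams(**data.get("observation", {}))
        merge = MergeWeights(**data.get("merge", {}))
        sim = data.get("simulation", {})
        return cls(
            cerebral=cerebral,
            scalp=scalp,
            observation=observation,
            merge=merge,
            sample_dt=float(sim.get("sample_dt", 1.0)),
            seed=int(sim.get("seed", 0)),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def default_config(**simulation_options) -> RunConfig:
    """The documented default configuration (calibrated parameter blocks)."""
    cerebral = calibrate_cerebral()
    scalp, _ = calibrate_scalp()
    return RunConfig(cerebral=cerebral, scalp=scalp, **simulation_options)
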