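"""Deterministic synthetic fixtures: every analysis is testable without downloads.

``generate_fixture`` writes a small input CSV (plus, where relevant, a JSON
manifest of ground-truth properties) for a named protocol.  All randomness is
controlled by an explicit seed, so fixtures are bit-identical across runs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig, default_config
from .simulation import (
    build_multifrequency_protocol,
    build_step_protocol,
    run_simulation,
)
from .timeseries_io import write_timeseries_csv
from .types import INPUT_RANGES, MergeWeights

__all__ = ["FIXTURE_NAMES", "generate_fixture"]

FIXTURE_NAMES = (
    "step_Pa",
    "step_PaCO2",
    "step_SaO2",
    "step_u",
    "step_flux",
    "multifreq",
    "noisy_mixture",
)

#: True mixing weights used by the noisy_mixture fixture.
_MIXTURE_WEIGHTS = MergeWeights(w_scalp=0.3, w_cerebral=0.7)
_MIXTURE_NOISE_FRAC = 0.10  # noise sd as a fraction of signal range


def generate_fixture(
    name: str,
    seed: int = 0,
    outdir: str | Path = ".",
    config: RunConfig | None = None,
) -> dict[str, Path]:
    """Write the fixture ``name`` into ``outdir``; returns the paths written.

    Step fixtures are square-wave input timelines from the baseline to the
    upper end of the variable's range and back.  ``multifreq`` is the
    multi-frequency simultaneous-variation protocol.  ``noisy_mixture`` runs
    that protocol through the model, mixes the scalp and cerebral outputs
    with known non-negative weights, adds seeded Gaussian noise, and writes
    both the mixed "measurement" and the clean model signals, together with
    a manifest holding the true weights (for attribution tests).
    """
    if name not in FIXTURE_NAMES:
        raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if config is None:
        config = default_config()

    if name.startswith("step_"):
        var = {"step_flux": "Flux_y"}.get(name, name.removeprefix("step_"))
        timeline = build_step_protocol(var)
        path = outdir / f"{name}.csv"
        write_timeseries_csv(timeline.df, path)
        return {"inputs": path}

    if name == "multifreq":
        timeline = build_multifrequency_protocol()
        path = outdir / f"{name}.csv"
        write_timeseries_csv(timeline.df, path)
        return {"inputs": path}

    # noisy_mixture
    rng = np.random.default_rng(seed)
    timeline = build_multifrequency_protocol()
    import dataclasses

    cfg = dataclasses.replace(config, scalp=dataclasses.replace(config.scalp, variant="flux"))
    result = run_simulation(timeline, cfg)
    w = _MIXTURE_WEIGHTS
    mixed_hbo2 = w.w_scalp * result.scalp.dHbO2 + w.w_cerebral * result.cerebral.dHbO2
    mixed_hhb = w.w_scalp * result.scalp.dHHb + w.w_cerebral * result.cerebral.dHHb
    for series in (mixed_hbo2, mixed_hhb):
        series += rng.normal(0.0, _MIXTURE_NOISE_FRAC * np.ptp(series), size=series.shape)

    df = pd.DataFrame(
        {
            "t": result.df["t"],
            "dHbO2": mixed_hbo2,
            "dHHb": mixed_hhb,
        }
    )
    meas_path = outdir / "noisy_mixture.csv"
    write_timeseries_csv(df, meas_path)
    model_path = outdir / "noisy_mixture_model.csv"
    write_timeseries_csv(result.df, model_path)
    manifest = {
        "name": name,
        "seed": seed,
        "w_scalp": w.w_scalp,
        "w_cerebral": w.w_cerebral,
        "noise_fraction": _MIXTURE_NOISE_FRAC,
        "protocol": timeline.meta,
    }
    manifest_path = outdir / "noisy_mixture_manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return {"measured": meas_path, "model": model_path, "manifest": manifest_path}
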