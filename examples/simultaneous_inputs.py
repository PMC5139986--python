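"""Simultaneous multi-frequency variation of all five systemic inputs.

Each input oscillates at its own frequency, so the inputs are linearly
independent; because the two compartments weight the inputs differently,
their haemoglobin outputs are distinguishable - the basis for attributing
measured signals between them.
"""

import dataclasses

import numpy as np

from fnirsim import build_multifrequency_protocol, default_config, run_simulation

config = default_config()
config = dataclasses.replace(
    config, scalp=dataclasses.replace(config.scalp, variant="flux")
)

timeline = build_multifrequency_protocol()
res = run_simulation(timeline, config)

print(f"protocol: {timeline.meta}, {timeline.t[-1]:.0f} s at {1/timeline.dt:.0f} Hz")
print(f"cerebral dHbO2 range: [{res.df.dHbO2_cerebral.min():+.2f}, "
      f"{res.df.dHbO2_cerebral.max():+.2f}] uM")
print(f"scalp    dHbO2 range: [{res.df.dHbO2_scalp.min():+.2f}, "
      f"{res.df.dHbO2_scalp.max():+.2f}] uM")
r = np.corrcoef(res.df["dHbO2_cerebral"], res.df["dHbO2_scalp"])[0, 1]
print(f"correlation of cerebral vs scalp dHbO2 outputs: {r:+.2f}")

print(
    "\nReading: driven by the same systemic inputs, the compartments still"
    "\nproduce only weakly correlated outputs, so their relative contributions"
    "\nto a mixed measurement can in principle be separated."
)
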