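"""Attributing a mixed measurement between scalp and cerebral compartments.

A synthetic "measurement" is built by mixing the model's scalp and cerebral
outputs with known weights (0.3 / 0.7) plus 10% Gaussian noise, then handed
to the attribution fit, which recovers non-negative compartment weights by
least squares over the concatenated dHbO2 and dHHb series.  Cross-correlation
and dynamic-time-warping diagnostics are printed for each compartment.
"""

import json
import tempfile
from pathlib import Path

import pandas as pd

from fnirsim import (
    attribute_compartments,
    cross_correlate,
    dtw_compare,
    generate_fixture,
    rescale_to_range,
)

outdir = Path(tempfile.mkdtemp())
paths = generate_fixture("noisy_mixture", seed=1, outdir=outdir)
manifest = json.loads(paths["manifest"].read_text())
meas = pd.read_csv(paths["measured"])
model = pd.read_csv(paths["model"])

fit = attribute_compartments(
    meas["dHbO2"], meas["dHHb"],
    model["dHbO2_cerebral"], model["dHHb_cerebral"],
    model["dHbO2_scalp"], model["dHHb_scalp"],
)
print(f"true weights:      S = {manifest['w_scalp']:.2f}, C = {manifest['w_cerebral']:.2f}")
print(f"recovered weights: S = {fit.w_scalp:.3f}, C = {fit.w_cerebral:.3f} "
      f"(residual {fit.residual:.2f} uM)")

for comp in ("cerebral", "scalp"):
    ccf = cross_correlate(meas["dHbO2"], model[f"dHbO2_{comp}"], dt=1.0, max_lag=150.0)
    dtw = dtw_compare(
        meas["dHbO2"].to_numpy()[::4],
        rescale_to_range(model[f"dHbO2_{comp}"], meas["dHbO2"])[::4],
    )
    print(f"{comp:>9} dHbO2: CCF max {ccf.max_correlation:+.2f} at lag "
          f"{ccf.lag_at_max:+.0f} s; DTW W = {dtw.warp:.1f} samples, D = {dtw.distance:.1f}")

print(
    "\nReading: the non-negative fit recovers the known mixing weights despite"
    "\nthe noise; W and D summarise how much non-linear time warping each"
    "\ncompartment needs to explain the measurement (smaller is better)."
)
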