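"""CSV input/output for time series (RFC-4180 dialect, header row, time in s)."""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .simulation import InputTimeline
from .types import INPUT_BASELINES, INPUT_NAMES

__all__ = ["read_timeseries_csv", "write_timeseries_csv", "KNOWN_COLUMNS"]

logger = logging.getLogger("fnirsim")

#: Columns accepted in input CSV files besides the systemic inputs.
KNOWN_COLUMNS = {
    "t",
    *INPUT_NAMES,
    "dHbO2",
    "dHHb",
    "dHbO2_short",
    "dHHb_short",
    "dHbO2_long",
    "dHHb_long",
}


def read_timeseries_csv(path: str | Path) -> InputTimeline:
    """Parse a time-series CSV into an :class:`InputTimeline`.

    The file must have a header row and a strictly increasing ``t`` column
    [s].  Missing systemic-input columns are filled with their baseline
    values (and logged); unknown columns raise a descriptive error.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    if "t" not in df.columns:
        raise ValueError(f"{path}: missing required time column 't'")
    unknown = [c for c in df.columns if c not in KNOWN_COLUMNS]
    if unknown:
        raise ValueError(
            f"{path}: unknown columns {unknown}; expected a subset of "
            f"{sorted(KNOWN_COLUMNS)}"
        )
    t = df["t"].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError(f"{path}: time column must be strictly increasing")
    filled = []
    for name in INPUT_NAMES:
        if name not in df.columns:
            df[name] = INPUT_BASELINES[name]
            filled.append(name)
    if filled:
        logger.info("%s: columns %s filled with baseline values", path, filled)
    return InputTimeline(df, meta=f"loaded from {path}")


def write_timeseries_csv(df: pd.DataFrame, path: str | Path) -> None:
    """Write a time-series table to CSV at full precision (round-trip exact)."""
    df.to_csv(path, index=False, float_format="%.17g")
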