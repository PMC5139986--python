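"""Comparison and attribution analytics for measured vs modelled NIRS signals.

Similarity between a measured haemoglobin series and a model prediction is
assessed three ways, in increasing order of temporal flexibility:

* Pearson correlation (the lag-0 special case of the cross-correlation) —
  appropriate when signals are well aligned;
* normalised cross-correlation over lags up to a configurable maximum
  (default 2.5 min), reporting the maximum correlation and its lag —
  tolerates a constant delay;
* dynamic time warping (DTW) — aligns the signals with non-constant lags to
  minimise the accumulated distance, summarised by the degree of warping W
  (mean absolute difference of the alignment index vectors, in samples) and
  the final distance D.  Both are non-negative; (0, 0) indicates a perfect
  match.  Because DTW is scale-sensitive, model series are min-max rescaled
  into the range of the measurement first.

Finally, a measurement that mixes scalp and cerebral contributions in
unknown proportion is attributed between them by a non-negative weighted
least-squares fit over the concatenated HbO2 and HHb series (both signals
are assumed contaminated by scalp to the same degree, so a single weight
pair is shared).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls

__all__ = [
    "CCFResult",
    "DTWResult",
    "AttributionResult",
    "pearson_correlation",
    "cross_correlate",
    "rescale_to_range",
    "dtw_compare",
    "attribute_compartments",
]


@dataclass
class CCFResult:
    """Normalised cross-correlation over a symmetric lag window."""

    lags: np.ndarray  # [s], negative = modelled leads measured
    correlation: np.ndarray
    max_correlation: float
    lag_at_max: float

    def __post_init__(self) -> None:
        if np.any(np.abs(self.correlation) > 1.0 + 1e-9):
            raise ValueError("correlations must lie in [-1, 1]")


@dataclass
class DTWResult:
    """DTW alignment summary.

    ``index_query``/``index_reference`` are the alignment index vectors;
    ``warp`` W is their mean absolute difference [samples]; ``distance`` D is
    the accumulated pointwise distance along the optimal path.
    """

    index_query: np.ndarray
    index_reference: np.ndarray
    warp: float
    distance: float


@dataclass
class AttributionResult:
    """Non-negative two-compartment weights and fit diagnostics."""

    w_scalp: float
    w_cerebral: float
    fitted_dHbO2: np.ndarray
    fitted_dHHb: np.ndarray
    residual: float  # Euclidean norm over the concatenated signals


def _as_series(x, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError(f"{name} must be a non-empty 1-D series")
    return x


def pearson_correlation(x, y) -> float:
    """Pearson correlation coefficient (lag-0 cross-correlation)."""
    x, y = _as_series(x, "x"), _as_series(y, "y")
    if len(x) != len(y):
        raise ValueError("series must have equal length")
    return float(np.corrcoef(x, y)[0, 1])


def cross_correlate(
    measured, modelled, dt: float = 1.0, max_lag: float = 150.0
) -> CCFResult:
    """Normalised cross-correlation of two equally sampled series.

    Both series are demeaned internally and normalised by n*sd(x)*sd(y), so
    the lag-0 value equals the Pearson correlation and all values lie in
    [-1, 1].  Positive lag means the modelled series is shifted later in
    time.  ``max_lag`` defaults to 2.5 min.
    """
    x = _as_series(measured, "measured")
    y = _as_series(modelled, "modelled")
    if len(x) != len(y):
        raise ValueError("series must have equal length and sampling")
    n = len(x)
    k_max = min(int(np.floor(max_lag / dt)), n - 1)
    x = x - x.mean()
    y = y - y.mean()
    denom = n * x.std() * y.std()
    if denom == 0:
        raise ValueError("constant series have undefined cross-correlation")
    lags = np.arange(-k_max, k_max + 1)
    corr = np.empty(lags.shape)
    for i, k in enumerate(lags):
        if k >= 0:
            corr[i] = np.dot(x[k:], y[: n - k]) / denom
        else:
            corr[i] = np.dot(x[: n + k], y[-k:]) / denom
    best = int(np.argmax(corr))
    return CCFResult(
        lags=lags * dt,
        correlation=corr,
        max_correlation=float(corr[best]),
        lag_at_max=float(lags[best] * dt),
    )


def rescale_to_range(model, measured) -> np.ndarray:
    """Affine min-max mapping of ``model`` onto [min(measured), max(measured)].

    Puts modelled and measured signals on an equal footing before DTW, which
    (unlike correlation) is sensitive to scale.
    """
    m = _as_series(model, "model")
    d = _as_series(measured, "measured")
    d_min, d_max = d.min(), d.max()
    m_min, m_max = m.min(), m.max()
    if d_max == d_min:
        raise ValueError("measured series is constant; min-max rescaling undefined")
    if m_max == m_min:
        # A constant model maps to the midpoint of the measured range.
        return np.full_like(m, 0.5 * (d_min + d_max))
    return d_min + (m - m_min) * (d_max - d_min) / (m_max - m_min)


def dtw_compare(measured, modelled) -> DTWResult:
    """Dynamic time warping with a symmetric step pattern.

    Local distance is the absolute difference; steps are (1,1), (1,0), (0,1)
    with unit weights and no global window; alignment is closed-end (both
    endpoints matched).  The modelled series should be pre-rescaled with
    :func:`rescale_to_range`.  Ties in the backtrace prefer the diagonal,
    then the query step (deterministic).
    """
    x = _as_series(measured, "measured")
    y = _as_series(modelled, "modelled")
    n, m = len(x), len(y)
    cost = np.abs(x[:, None] - y[None, :])
    acc = np.full((n, m), np.inf)
    acc[0, 0] = cost[0, 0]
    for i in range(n):
        for j in range(m):
            if i == 0 and j == 0:
                continue
            best = np.inf
            if i > 0 and j > 0:
                best = acc[i - 1, j - 1]
            if i > 0:
                best = min(best, acc[i - 1, j])
            if j > 0:
                best = min(best, acc[i, j - 1])
            acc[i, j] = cost[i, j] + best

    # Backtrace (diagonal preferred on ties).
    path = [(n - 1, m - 1)]
    i, j = n - 1, m - 1
    while (i, j) != (0, 0):
        candidates = []
        if i > 0 and j > 0:
            candidates.append((acc[i - 1, j - 1], (i - 1, j - 1)))
        if i > 0:
            candidates.append((acc[i - 1, j], (i - 1, j)))
        if j > 0:
            candidates.append((acc[i, j - 1], (i, j - 1)))
        _, (i, j) = min(candidates, key=lambda c: c[0])
        path.append((i, j))
    path.reverse()
    idx_q = np.array([p[0] for p in path])
    idx_r = np.array([p[1] for p in path])
    return DTWResult(
        index_query=idx_q,
        index_reference=idx_r,
        warp=float(np.mean(np.abs(idx_q - idx_r))),
        distance=float(acc[n - 1, m - 1]),
    )


def attribute_compartments(
    measured_dHbO2,
    measured_dHHb,
    cerebral_dHbO2,
    cerebral_dHHb,
    scalp_dHbO2,
    scalp_dHHb,
) -> AttributionResult:
    """Attribute a measurement between scalp and cerebral model signals.

    Finds (S, C) >= 0 minimising ||measured - S*scalp - C*cerebral||_2 jointly
    over the concatenated HbO2 and HHb series (a single weight pair shared by
    both signals, no lag or warping).  Deterministic.

    Raises
    ------
    ValueError
        If a model signal pair has zero norm or the two are collinear.
    """
    series = [
        _as_series(s, name)
        for s, name in [
            (measured_dHbO2, "measured_dHbO2"),
            (measured_dHHb, "measured_dHHb"),
            (cerebral_dHbO2, "cerebral_dHbO2"),
            (cerebral_dHHb, "cerebral_dHHb"),
            (scalp_dHbO2, "scalp_dHbO2"),
            (scalp_dHHb, "scalp_dHHb"),
        ]
    ]
    if len({len(s) for s in series}) != 1:
        raise ValueError("all six series must be aligned to the same length")
    meas = np.concatenate(series[0:2])
    cer = np.concatenate(series[2:4])
    scalp = np.concatenate(series[4:6])

    n_scalp, n_cer = np.linalg.norm(scalp), np.linalg.norm(cer)
    if n_scalp == 0 or n_cer == 0:
        raise ValueError("model signals must have non-zero norm")
    cosine = abs(np.dot(scalp, cer)) / (n_scalp * n_cer)
    if cosine > 1.0 - 1e-10:
        raise ValueError("scalp and cerebral model signals are collinear")

    A = np.column_stack([scalp, cer])
    weights, residual = nnls(A, meas)
    S, C = float(weights[0]), float(weights[1])
    n = len(series[0])
    fitted = A @ weights
    return AttributionResult(
        w_scalp=S,
        w_cerebral=C,
        fitted_dHbO2=fitted[:n],
        fitted_dHHb=fitted[n:],
        residual=float(residual),
    )
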