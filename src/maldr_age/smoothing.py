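"""Local linear (loess, degree 1) smoothing with tricube weights.

Coverage curves are smoothed per age group before the monotone-ratio
test.  The smoother fits a weighted straight line over the nearest
``ceil(span * n)`` neighbours of each position (neighbourhoods are
contiguous because positions are sorted), with tricube weights
``(1 - u^3)^3`` on the normalised distances, and evaluates the fit at the
position itself.  A local linear fit reproduces exactly linear inputs,
which anchors its correctness tests.
"""

from __future__ import annotations

import warnings

import numpy as np

_TINY = 1e-300


def loess_smooth(positions, values, span: float = 0.3) -> np.ndarray:
    """Smooth ``values`` observed at sorted ``positions``.

    Parameters
    ----------
    positions : array-like
        Strictly increasing coordinates.
    values : array-like
        One observation per position.
    span : float
        Fraction of points in each local window, in (0, 1].

    Returns
    -------
    numpy.ndarray
        Smoothed values, clipped at 0, same length as the input.  With
        fewer than 5 positions smoothing is skipped and the input is
        returned unchanged (with a warning).
    """
    x = np.asarray(positions, dtype=float)
    y = np.asarray(values, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("positions and values must be 1-D of equal length")
    if not 0.0 < span <= 1.0:
        raise ValueError(f"span must lie in (0, 1]; got {span!r}")
    n = x.size
    if n < 5:
        warnings.warn("fewer than 5 positions: smoothing skipped",
                      stacklevel=2)
        return y.copy()
    if np.any(np.diff(x) <= 0):
        raise ValueError("positions must be strictly increasing")

    w = min(n, max(2, int(np.ceil(span * n))))

    # nearest-w neighbourhoods are contiguous windows in sorted order
    starts = np.empty(n, dtype=np.int64)
    lo = 0
    for i in range(n):
        while lo + w < n and x[lo + w] - x[i] < x[i] - x[lo]:
            lo += 1
        starts[i] = lo

    idx = starts[:, None] + np.arange(w)[None, :]
    z = x[idx] - x[:, None]          # centred abscissae
    yy = y[idx]
    d = np.abs(z)
    dmax = d.max(axis=1, keepdims=True)
    dmax = np.where(dmax <= 0, 1.0, dmax)
    u = np.clip(d / dmax, 0.0, 1.0)
    wt = (1.0 - u**3) ** 3

    s0 = wt.sum(axis=1)
    s1 = (wt * z).sum(axis=1)
    s2 = (wt * z * z).sum(axis=1)
    t0 = (wt * yy).sum(axis=1)
    t1 = (wt * z * yy).sum(axis=1)
    denom = s0 * s2 - s1 * s1
    scale = np.maximum(s0 * s2, _TINY)
    with np.errstate(divide="ignore", invalid="ignore"):
        fitted = np.where(denom > 1e-10 * scale,
                          (s2 * t0 - s1 * t1) / np.where(denom == 0, 1.0,
                                                         denom),
                          t0 / np.maximum(s0, _TINY))
    return np.maximum(fitted, 0.0)
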