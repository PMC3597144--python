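"""Locally weighted polynomial smoothing with AICc-driven span selection.

Probe intensities within one copy-number state are noisy, and the noise grows
with the copy number, so raw junction intensities cannot be compared
directly. Each crossover track is therefore smoothed by loess: at every point
a quadratic polynomial is fitted to the nearest-neighbour window under
tricube weights. The window width (span) is chosen per candidate by scanning
a percentage grid and minimising the small-sample corrected Akaike
information criterion

    AICc = n ln(RSS/n) + n (n + tr L) / (n - tr L - 2),

where ``tr L`` is the trace of the loess smoothing operator. The smallest
span attaining the minimal AICc wins, so flat criteria resolve toward the
least smoothing.

Numerical choices: windows are the k = ceil(span/100 * n) nearest points
(stable tie-break toward lower index); tricube weights are scaled slightly
past the farthest window point so it keeps a positive weight; the local
polynomial degree falls back from 2 to k - 1 in windows too small for a
quadratic; RSS is floored at (1e-8 x data scale)^2 per point so that
exact-fit series tie across spans instead of comparing rounding noise.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence, Tuple

import numpy as np

from .params import Parameters


class LoessError(ValueError):
    """Raised for infeasible spans or series too short to smooth."""


def _window_size(span_pct: float, n: int) -> int:
    return min(n, int(math.ceil(span_pct / 100.0 * n)))


def loess_fit(values: Sequence[float], span_pct: float) -> Tuple[np.ndarray, float]:
    """Smooth ``values`` at the given span; return (fitted, operator trace).

    Raises :class:`LoessError` when the window holds fewer than two points.
    """
    y = np.asarray(values, dtype=float)
    n = y.size
    if n < 2:
        raise LoessError(f"need at least 2 values to smooth, got {n}")
    k = _window_size(span_pct, n)
    if k < 2:
        raise LoessError(f"span {span_pct}% gives a {k}-point window for n={n}")
    x = np.arange(n, dtype=float)
    fitted = np.empty(n)
    trace = 0.0
    for i in range(n):
        dist = np.abs(x - x[i])
        order = np.argsort(dist, kind="stable")[:k]
        d = dist[order]
        h = d.max() * (1.0 + 1e-7)
        w = (1.0 - (d / h) ** 3) ** 3
        degree = min(2, k - 1)
        design = np.vander(x[order] - x[i], N=degree + 1, increasing=True)
        wx = design * w[:, None]
        # l_i = e0^T (X^T W X)^+ X^T W  gives the smoother row at point i
        core = np.linalg.pinv(design.T @ wx)
        li = (core @ wx.T)[0]
        fitted[i] = float(li @ y[order])
        self_pos = int(np.nonzero(order == i)[0][0])
        trace += float(li[self_pos])
    return fitted, trace


def smooth_loess(values: Sequence[float], span_pct: float) -> np.ndarray:
    """Loess-smoothed copy of ``values`` (same length)."""
    fitted, _ = loess_fit(values, span_pct)
    return fitted


def aicc_for_span(values: Sequence[float], span_pct: float) -> float:
    """AICc of the loess fit at one span; +inf when the criterion is undefined.

    The criterion is undefined when the effective number of parameters leaves
    no residual degrees of freedom (n - trace - 2 <= 0).
    """
    y = np.asarray(values, dtype=float)
    n = y.size
    fitted, trace = loess_fit(y, span_pct)
    if n - trace - 2.0 <= 0.0:
        return math.inf
    rss = float(np.sum((y - fitted) ** 2))
    scale = max(1.0, float(np.max(np.abs(y))) if n else 1.0)
    floor = n * (1e-8 * scale) ** 2
    rss = max(rss, floor)
    return n * math.log(rss / n) + n * (n + trace) / (n - trace - 2.0)


def select_loess_span(values: Sequence[float], params: Optional[Parameters] = None) -> int:
    """Smallest grid span (percent) minimising AICc over the span grid.

    Grid values whose window holds fewer than two points, or whose criterion
    is undefined, are skipped; an error is raised if no grid value is usable
    or the series has fewer than four points.
    """
    params = params or Parameters()
    y = np.asarray(values, dtype=float)
    if y.size < 4:
        raise LoessError(f"span selection needs at least 4 values, got {y.size}")
    best_span = None
    best_aicc = math.inf
    for span in params.span_grid():
        if _window_size(span, y.size) < 2:
            continue
        aicc = aicc_for_span(y, span)
        if aicc < best_aicc:
            best_aicc = aicc
            best_span = span
    if best_span is None:
        raise LoessError(
            f"no feasible span in grid {params.span_grid_lo}..{params.span_grid_hi} "
            f"for a series of {y.size} values"
        )
    return best_span
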