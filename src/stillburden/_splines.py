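"""Natural cubic spline regression basis.

A single shared basis implementation backs the nonlinear covariate terms
and the spline exposure-response curves, so that fitted curves serialize
to (knots, coefficients) and evaluate identically everywhere.  The basis
is the standard natural (restricted) cubic spline: cubic between knots,
linear beyond the boundary knots.  Linear tail behaviour is what makes
extrapolated curve segments well defined (and flaggable) rather than
exploding cubically.
"""

from __future__ import annotations

import numpy as np


def spline_knots(x: np.ndarray, df: int) -> np.ndarray:
    """Knot locations for a natural cubic spline with ``df`` columns.

    ``df + 1`` knots are placed at equally spaced quantiles of ``x``,
    including the observed minimum and maximum as boundary knots.

    Raises
    ------
    ValueError
        if the quantiles are not strictly increasing (degenerate data).
    """
    if df < 2:
        raise ValueError(f"spline df must be >= 2, got {df}")
    x = np.asarray(x, dtype=float)
    qs = np.linspace(0.0, 1.0, df + 1)
    knots = np.quantile(x, qs)
    if not np.all(np.diff(knots) > 0):
        raise ValueError(
            "degenerate spline knots: data quantiles are not strictly "
            f"increasing ({knots!r}); too little variation for df={df}"
        )
    return knots


def natural_spline_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Evaluate the natural cubic spline basis (no intercept column).

    With ``K`` knots the basis has ``K - 1`` columns: the identity term
    plus ``K - 2`` curvature terms.  Outside the boundary knots every
    curvature term is exactly linear, so the spanned function space has
    linear tails.
    """
    x = np.asarray(x, dtype=float)
    knots = np.asarray(knots, dtype=float)
    K = len(knots)
    if K < 3:
        raise ValueError("need at least 3 knots for a natural cubic spline")

    def d(j: int) -> np.ndarray:
        # ((x - k_j)_+^3 - (x - k_K)_+^3) / (k_K - k_j)
        num = np.clip(x - knots[j], 0.0, None) ** 3
        num -= np.clip(x - knots[-1], 0.0, None) ** 3
        return num / (knots[-1] - knots[j])

    cols = [x]
    dK1 = d(K - 2)
    for j in range(K - 2):
        cols.append(d(j) - dK1)
    return np.column_stack(cols)
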