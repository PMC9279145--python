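"""Cubic B-spline spatial basis."""

from __future__ import annotations

import numpy as np
from scipy.interpolate import BSpline

__all__ = ["spline_basis"]


def spline_basis(n_bins: int, df: int) -> np.ndarray:
    """Normalized cubic B-spline basis evaluated at uniformly spaced bin
    midpoints on [0, 1].

    Returns an ``(n_bins, df)`` matrix. Knots are clamped with uniformly
    spaced interior knots, so the basis is a partition of unity: every row
    sums to 1 and all entries are nonnegative.
    """
    degree = 3
    if df < degree + 1:
        raise ValueError(f"df must be >= {degree + 1} for cubic splines, got {df}")
    if df > n_bins:
        raise ValueError(f"df ({df}) cannot exceed n_bins ({n_bins})")
    n_interior = df - (degree + 1)
    interior = np.linspace(0.0, 1.0, n_interior + 2)[1:-1]
    knots = np.concatenate(
        [np.zeros(degree + 1), interior, np.ones(degree + 1)]
    )
    x = (np.arange(n_bins) + 0.5) / n_bins
    basis = BSpline.design_matrix(x, knots, degree).toarray()
    assert basis.shape == (n_bins, df)
    return basis
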