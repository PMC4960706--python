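"""Natural cubic spline basis for time-course regression.

A natural cubic spline is a piecewise cubic that is linear beyond its
boundary knots (second derivative zero there).  With K knots the spline
space has dimension K; dropping the constant leaves ``df = K - 1`` basis
columns for a regression that carries its own intercept.  The reduced
basis is built from truncated third powers::

    d_k(x) = [ (x - xi_k)_+^3 - (x - xi_K)_+^3 ] / (xi_K - xi_k)
    N_1(x) = x,   N_{k+1}(x) = d_k(x) - d_{K-1}(x),  k = 1..K-2

which enforces the natural boundary conditions exactly.  Boundary knots
sit at the min/max design time; interior knots at quantiles of the
distinct design times.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SplineBasis", "natural_spline_basis"]


@dataclass(frozen=True)
class SplineBasis:
    """Evaluated natural cubic spline basis.

    Attributes
    ----------
    times : design times the basis was built from (and ``basis`` rows).
    df : number of basis columns.
    knots : all knots, boundary knots first/last.
    basis : ``len(times) x df`` matrix.
    """

    times: np.ndarray
    df: int
    knots: np.ndarray
    basis: np.ndarray = field(repr=False)

    @property
    def boundary_knots(self) -> tuple[float, float]:
        return float(self.knots[0]), float(self.knots[-1])

    @property
    def interior_knots(self) -> np.ndarray:
        return self.knots[1:-1]

    def evaluate(self, t) -> np.ndarray:
        """Evaluate the basis at arbitrary times (rows) -> ``len(t) x df``."""
        return _reduced_basis(np.asarray(t, dtype=float), self.knots)


def _reduced_basis(t: np.ndarray, knots: np.ndarray) -> np.ndarray:
    # scale to the boundary-knot interval so basis values are O(1)
    span = knots[-1] - knots[0]
    xi = (knots - knots[0]) / span
    t = (np.asarray(t, dtype=float) - knots[0]) / span
    K = len(xi)

    def d(k, x):  # truncated-power difference quotient
        return (np.clip(x - xi[k], 0, None) ** 3 - np.clip(x - xi[K - 1], 0, None) ** 3) / (
            xi[K - 1] - xi[k]
        )

    cols = [t]
    dlast = d(K - 2, t)
    for k in range(K - 2):
        cols.append(d(k, t) - dlast)
    return np.column_stack(cols)


def natural_spline_basis(times, df: int = 3) -> SplineBasis:
    """Build a natural cubic spline basis with ``df`` columns.

    Boundary knots at min/max of the distinct times, ``df - 1`` interior
    knots at evenly spaced quantiles of the distinct times.  Requires at
    least ``df + 1`` distinct time values.
    """
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise ValueError("times must be a non-empty 1-D sequence")
    distinct = np.unique(t)
    if distinct.size < df + 1:
        raise ValueError(
            f"need at least {df + 1} distinct times for a {df}-df natural spline, "
            f"got {distinct.size}"
        )
    probs = np.arange(1, df) / df
    interior = np.quantile(distinct, probs)
    knots = np.concatenate([[distinct[0]], interior, [distinct[-1]]])
    if np.unique(knots).size != knots.size:
        raise ValueError("degenerate knot sequence (duplicate knots)")
    basis = _reduced_basis(t, knots)
    return SplineBasis(times=t, df=df, knots=knots, basis=basis)
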