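"""Cox-de Boor B-spline basis functions.

The free-form deformation is parameterized by a control-point grid whose
influence is spread by tensor-product B-spline bases
``T(x, y) = sum_i sum_j phi_i(x) phi_j(y) c_ij``.  The recursion here is the
reference definition used to validate the transform backend.
"""

from __future__ import annotations

import numpy as np

__all__ = ["bspline_basis", "uniform_knots"]


def uniform_knots(n_basis: int, order: int, start: float = 0.0,
                  spacing: float = 1.0) -> np.ndarray:
    """Uniform knot sequence supporting ``n_basis`` splines of a given order."""
    return start + spacing * np.arange(n_basis + order + 1, dtype=np.float64)


def bspline_basis(i: int, k: int, x: float, knots: np.ndarray) -> float:
    """Cox-de Boor recursion for the i-th B-spline basis of order ``k``.

    Order 0 is the indicator of ``[t_i, t_{i+1})``; higher orders blend the
    two lower-order neighbours with the convention that 0/0 terms vanish::

        phi_i^k(x) = (x - t_i)/(t_{i+k} - t_i) phi_i^{k-1}(x)
                   + (t_{i+k+1} - x)/(t_{i+k+1} - t_{i+1}) phi_{i+1}^{k-1}(x)
    """
    knots = np.asarray(knots, dtype=np.float64)
    if k < 0:
        raise ValueError("order must be nonnegative")
    if i < 0 or i + k + 1 >= len(knots):
        raise ValueError("basis index out of range for the knot sequence")
    if not (knots[0] <= x <= knots[-1]):
        raise ValueError("x outside the knot span")
    if k == 0:
        return 1.0 if knots[i] <= x < knots[i + 1] else 0.0
    left_den = knots[i + k] - knots[i]
    right_den = knots[i + k + 1] - knots[i + 1]
    left = 0.0 if left_den == 0 else (x - knots[i]) / left_den * bspline_basis(i, k - 1, x, knots)
    right = 0.0 if right_den == 0 else (knots[i + k + 1] - x) / right_den * bspline_basis(i + 1, k - 1, x, knots)
    return left + right
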