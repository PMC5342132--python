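"""Independent brute-force oracles the test suite checks the package against.

Each oracle is implemented from first principles, separately from the code
path it validates: ray-casting point-in-polygon, a direct dual quadratic
program for the soft-margin RBF-SVM, and Student-t tail probability by
numerical quadrature.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.integrate import quad
from scipy.optimize import minimize


def ray_cast_inside(px: float, py: float, vertices: list[tuple[float, float]]) -> bool:
    """Classic even-odd ray casting: does (px, py) lie inside the polygon?

    Points exactly on an edge are resolved arbitrarily by the crossing
    rule; callers should avoid boundary points when comparing conventions.
    """
    inside = False
    n = len(vertices)
    for i in range(n):
        x1, y1 = vertices[i]
        x2, y2 = vertices[(i + 1) % n]
        if (y1 > py) != (y2 > py):
            x_cross = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
            if px < x_cross:
                inside = not inside
    return inside


def _rbf(X: np.ndarray, Y: np.ndarray, gamma: float) -> np.ndarray:
    d2 = (X**2).sum(1)[:, None] + (Y**2).sum(1)[None, :] - 2 * X @ Y.T
    return np.exp(-gamma * np.clip(d2, 0.0, None))


def dual_svm_predictor(X: np.ndarray, y01: np.ndarray, C: float, gamma: float):
    """Fit a soft-margin RBF-SVM by solving the dual QP directly (SLSQP).

    Maximizes ``sum(a) - 0.5 a' Q a`` subject to ``0 <= a <= C`` and
    ``y' a = 0`` with ``Q_ij = y_i y_j K(x_i, x_j)``; the intercept comes
    from the KKT conditions at free support vectors.  Returns a predict
    function mapping test points to labels in {0, 1}.
    """
    y = np.where(np.asarray(y01) == 1, 1.0, -1.0)
    n = len(y)
    Q = _rbf(X, X, gamma) * np.outer(y, y)

    res = minimize(
        lambda a: 0.5 * a @ Q @ a - a.sum(),
        np.zeros(n),
        jac=lambda a: Q @ a - 1.0,
        bounds=[(0.0, C)] * n,
        constraints=[{"type": "eq", "fun": lambda a: a @ y, "jac": lambda a: y}],
        method="SLSQP",
        options={"maxiter": 500, "ftol": 1e-10},
    )
    a = res.x
    K = _rbf(X, X, gamma)
    free = (a > 1e-6 * C) & (a < C * (1 - 1e-6))
    if free.any():
        b = float(np.mean(y[free] - (a * y) @ K[:, free]))
    else:
        f = (a * y) @ K
        up = ((y > 0) & (a < C * (1 - 1e-6))) | ((y < 0) & (a > 1e-6 * C))
        lo_set = (y - f)[~up]
        hi_set = (y - f)[up]
        lo = lo_set.max() if len(lo_set) else -np.inf
        hi = hi_set.min() if len(hi_set) else np.inf
        b = float((lo + hi) / 2) if np.isfinite(lo + hi) else 0.0

    def predict(Xt: np.ndarray) -> np.ndarray:
        return ((a * y) @ _rbf(X, Xt, gamma) + b > 0).astype(int)

    return predict


def student_t_two_tailed_p(t: float, df: int) -> float:
    """Two-tailed Student-t tail probability by numerical quadrature."""
    c = math.gamma((df + 1) / 2) / (math.sqrt(df * math.pi) * math.gamma(df / 2))
    pdf = lambda x: c * (1 + x * x / df) ** (-(df + 1) / 2)
    tail, _ = quad(pdf, abs(t), np.inf)
    return 2.0 * tail
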