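"""Independent reference implementations used only to check the package.

Each oracle recomputes a quantity from first principles (closed-form
formulas, step-up enumeration, or a generic QP solver) without calling the
code path it validates.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from scipy.optimize import minimize


def welch_oracle(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    """Welch t, Welch-Satterthwaite df and two-sided p from the formulas."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    va = ((a - a.mean()) ** 2).sum() / (na - 1)
    vb = ((b - b.mean()) ** 2).sum() / (nb - 1)
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def bh_oracle(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values by direct enumeration."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adjusted = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        value = min(p[idx] / (rank_from_top / m), 1.0)
        running_min = min(running_min, value)
        adjusted[idx] = running_min
    return adjusted


def quantile_normalize_oracle(values: np.ndarray) -> np.ndarray:
    """Mean-of-order-statistics transform for tie-free columns."""
    target = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values, dtype=float)
    for j in range(values.shape[1]):
        ranks = np.argsort(np.argsort(values[:, j]))
        out[:, j] = target[ranks]
    return out


def kappa_oracle(matrix: np.ndarray) -> float:
    """2-norm condition number as the singular-value ratio."""
    sigma = np.linalg.svd(np.asarray(matrix, dtype=float), compute_uv=False)
    return float(sigma.max() / sigma.min())


def nusvr_dual_oracle(
    X: np.ndarray, y: np.ndarray, nu: float, C: float = 1.0
) -> np.ndarray:
    """Linear-kernel nu-SVR weight vector from the dual quadratic program.

    Solves (libsvm scaling) min 1/2 (a-a*)' Q (a-a*) - y'(a-a*) subject to
    sum(a-a*) = 0, sum(a+a*) = C nu l, 0 <= a_i, a*_i <= C, with a generic
    SLSQP solver, then returns w = X' (a-a*).  Practical for l <= ~15.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    l = len(y)
    Q = X @ X.T

    def objective(z: np.ndarray) -> float:
        beta = z[:l] - z[l:]
        return 0.5 * beta @ Q @ beta - y @ beta

    def gradient(z: np.ndarray) -> np.ndarray:
        g = Q @ (z[:l] - z[l:]) - y
        return np.concatenate([g, -g])

    constraints = [
        {
            "type": "eq",
            "fun": lambda z: np.sum(z[:l] - z[l:]),
            "jac": lambda z: np.concatenate([np.ones(l), -np.ones(l)]),
        },
        {
            "type": "eq",
            "fun": lambda z: np.sum(z) - C * nu * l,
            "jac": lambda z: np.ones(2 * l),
        },
    ]
    z0 = np.full(2 * l, C * nu / 2.0)
    result = minimize(
        objective,
        z0,
        jac=gradient,
        bounds=[(0.0, C)] * (2 * l),
        constraints=constraints,
        method="SLSQP",
        options={"maxiter": 2000, "ftol": 1e-14},
    )
    beta = result.x[:l] - result.x[l:]
    return X.T @ beta


def pearson_oracle(x: np.ndarray, y: np.ndarray) -> float:
    """Product-moment correlation straight from the definition."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    dx, dy = x - x.mean(), y - y.mean()
    return float((dx * dy).sum() / np.sqrt((dx**2).sum() * (dy**2).sum()))
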