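"""Minimal linear soft-margin SVM tuned for very small problems.

The decoding pipeline fits tens of thousands of SVMs on matrices of roughly
20 x 60 (nights x frequency bins); permutation inference multiplies that by
the number of label shuffles.  General-purpose solvers spend most of their
time in per-call validation at this size, so we solve the standard C-SVC
dual directly with SMO (sequential minimal optimization, maximal-violating-
pair working-set selection), i.e. the same optimization problem libsvm
solves::

    min_w,b  0.5 ||w||^2  +  C * sum_i max(0, 1 - y_i (w . x_i + b))

The bias is unregularized (kept out of ||w||^2), which matters here: the
sharpened spectral features share a large common offset, and a regularized
bias cannot centre the decision function in the strongly regularized
regime these feature scales put C=1 into.

Probability estimates use Platt scaling: a two-parameter logistic
``P(y=+1 | f) = 1 / (1 + exp(A f + B))`` fitted to training decision values
by Newton's method with Platt's smoothed targets.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["LinearSVM", "platt_fit", "platt_predict"]


@njit(cache=True, fastmath=False)
def _smo_fit(K, y, C, tol, max_iter):  # pragma: no cover - jitted
    """SMO on the C-SVC dual given the Gram matrix K (n x n).

    Working-set selection is the maximal violating pair; returns the dual
    variables and the bias.  At the optimum ``y_i - f_i`` equals the bias
    for every free support vector, so b is the midpoint of the KKT bounds.
    """
    n = K.shape[0]
    alpha = np.zeros(n)
    f = np.zeros(n)                       # f_i = sum_j alpha_j y_j K_ij  (no bias)
    for _ in range(max_iter):
        # v_i = y_i - f_i; pick i maximizing v over I_up, j minimizing v over I_low
        i = -1
        j = -1
        v_up = -1e300
        v_low = 1e300
        for t in range(n):
            v = y[t] - f[t]
            up = (y[t] > 0 and alpha[t] < C) or (y[t] < 0 and alpha[t] > 0)
            low = (y[t] > 0 and alpha[t] > 0) or (y[t] < 0 and alpha[t] < C)
            if up and v > v_up:
                v_up = v
                i = t
            if low and v < v_low:
                v_low = v
                j = t
        if i < 0 or j < 0 or v_up - v_low < tol:
            break
        eta = K[i, i] + K[j, j] - 2.0 * K[i, j]
        if eta < 1e-12:
            eta = 1e-12
        # bounds on alpha_j
        s = y[i] * y[j]
        if s > 0:
            lo = max(0.0, alpha[i] + alpha[j] - C)
            hi = min(C, alpha[i] + alpha[j])
        else:
            lo = max(0.0, alpha[j] - alpha[i])
            hi = min(C, C + alpha[j] - alpha[i])
        e_i = f[i] - y[i]
        e_j = f[j] - y[j]
        aj_new = alpha[j] + y[j] * (e_i - e_j) / eta
        if aj_new < lo:
            aj_new = lo
        elif aj_new > hi:
            aj_new = hi
        if abs(aj_new - alpha[j]) < 1e-15:
            continue
        ai_new = alpha[i] + s * (alpha[j] - aj_new)
        # snap to the box so bound tests stay exact under roundoff
        if ai_new < 1e-12:
            ai_new = 0.0
        elif ai_new > C - 1e-12:
            ai_new = C
        if aj_new < 1e-12:
            aj_new = 0.0
        elif aj_new > C - 1e-12:
            aj_new = C
        di = (ai_new - alpha[i]) * y[i]
        dj = (aj_new - alpha[j]) * y[j]
        alpha[i] = ai_new
        alpha[j] = aj_new
        for t in range(n):
            f[t] += di * K[i, t] + dj * K[j, t]
    # bias from the KKT bounds (midpoint; equals y - f on free SVs)
    v_up = -1e300
    v_low = 1e300
    n_free = 0
    b_free = 0.0
    for t in range(n):
        v = y[t] - f[t]
        if 0.0 < alpha[t] < C:
            n_free += 1
            b_free += v
        up = (y[t] > 0 and alpha[t] < C) or (y[t] < 0 and alpha[t] > 0)
        low = (y[t] > 0 and alpha[t] > 0) or (y[t] < 0 and alpha[t] < C)
        if up and v > v_up:
            v_up = v
        if low and v < v_low:
            v_low = v
    b = b_free / n_free if n_free > 0 else 0.5 * (v_up + v_low)
    return alpha, b


class LinearSVM:
    """Linear soft-margin classifier with labels in {-1, +1}.

    Parameters
    ----------
    C : float
        Misclassification cost (box constraint on the dual variables).
    tol : float
        KKT violation gap at which SMO stops.
    max_iter : int
        Safety cap on SMO pair updates.
    """

    def __init__(self, C: float = 1.0, tol: float = 1e-6, max_iter: int = 100_000):
        if C <= 0:
            raise ValueError("C must be positive")
        self.C = float(C)
        self.tol = float(tol)
        self.max_iter = int(max_iter)
        self.coef_: np.ndarray | None = None
        self.intercept_: float = 0.0

    def fit(self, X: np.ndarray, y: np.ndarray) -> "LinearSVM":
        X = np.ascontiguousarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        if X.ndim != 2 or y.shape != (X.shape[0],):
            raise ValueError("X must be (n, d) with matching y of length n")
        if not (np.all(np.abs(y) == 1.0)):
            raise ValueError("labels must be -1/+1")
        if np.all(y == y[0]):
            raise ValueError("both classes must be present")
        K = X @ X.T
        alpha, b = _smo_fit(K, y, self.C, self.tol, self.max_iter)
        self.coef_ = X.T @ (alpha * y)
        self.intercept_ = float(b)
        self._alpha = alpha
        return self

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        if self.coef_ is None:
            raise RuntimeError("fit first")
        return np.asarray(X, dtype=np.float64) @ self.coef_ + self.intercept_

    def predict(self, X: np.ndarray) -> np.ndarray:
        # decision value exactly 0 -> deterministic assignment to -1 (first class)
        return np.where(self.decision_function(X) > 0.0, 1.0, -1.0)


def platt_fit(decision: np.ndarray, y: np.ndarray, max_iter: int = 100) -> tuple[float, float]:
    """Fit Platt's sigmoid ``P(y=+1|f) = 1/(1+exp(A f + B))`` on training data.

    Uses Platt's smoothed targets ``(N+ + 1)/(N+ + 2)`` and ``1/(N- + 2)`` and
    a damped Newton iteration on the two parameters (the standard libsvm
    internal algorithm).
    """
    f = np.asarray(decision, dtype=np.float64)
    y = np.asarray(y)
    n_pos = int(np.sum(y > 0))
    n_neg = int(np.sum(y < 0))
    t = np.where(y > 0, (n_pos + 1.0) / (n_pos + 2.0), 1.0 / (n_neg + 2.0))
    A, B = 0.0, np.log((n_neg + 1.0) / (n_pos + 1.0))
    eps = 1e-12

    def nll(A, B):
        z = A * f + B
        # stable log(1+exp(z)) etc.
        return float(np.sum(np.where(z >= 0, t * z + np.log1p(np.exp(-z)),
                                     (t - 1.0) * z + np.log1p(np.exp(z)))))

    prev = nll(A, B)
    for _ in range(max_iter):
        z = A * f + B
        p = np.where(z >= 0, np.exp(-z) / (1.0 + np.exp(-z)), 1.0 / (1.0 + np.exp(z)))
        q = 1.0 - p
        d1 = t - p
        d2 = p * q
        g1 = float(np.sum(f * d1))
        g2 = float(np.sum(d1))
        if abs(g1) < 1e-10 and abs(g2) < 1e-10:
            break
        h11 = float(np.sum(f * f * d2)) + eps
        h22 = float(np.sum(d2)) + eps
        h12 = float(np.sum(f * d2))
        det = h11 * h22 - h12 * h12
        dA = -(h22 * g1 - h12 * g2) / det
        dB = -(-h12 * g1 + h11 * g2) / det
        # backtracking line search along the Newton direction
        step = 1.0
        while step >= 1e-10:
            A_new, B_new = A + step * dA, B + step * dB
            val = nll(A_new, B_new)
            if val < prev + 1e-12:
                A, B, prev = A_new, B_new, val
                break
            step *= 0.5
        else:
            break
    return float(A), float(B)


def platt_predict(decision: np.ndarray, A: float, B: float) -> np.ndarray:
    """Probability of the +1 class given decision values."""
    z = A * np.asarray(decision, dtype=np.float64) + B
    return np.where(z >= 0, np.exp(-z) / (1.0 + np.exp(-z)), 1.0 / (1.0 + np.exp(z)))
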