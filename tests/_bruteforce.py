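"""Independent brute-force implementation of the two-step classifier.

Used as the oracle in tests and in the acceptance script: explicit Python
loops over channels, leave-one-subject-out splits and outer folds, with
each soft-margin linear SVM solved by direct numerical minimization of its
primal objective (Nelder-Mead with restarts on the exact hinge loss).
Nothing here shares code with the package's decoder.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize


def svm_primal_fit(X: np.ndarray, y: np.ndarray, C: float = 1.0) -> tuple[np.ndarray, float]:
    """Solve the soft-margin primal exactly in its slack-variable QP form.

    minimize 0.5||w||^2 + C sum_i xi_i
    subject to  xi_i >= 0  and  xi_i >= 1 - y_i (w.x_i + b)

    General-purpose constrained minimization (SLSQP), nothing shared with
    the package's SMO solver.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, d = X.shape

    def objective(p):
        w, xi = p[:d], p[d + 1:]
        return 0.5 * np.dot(w, w) + C * np.sum(xi)

    def jac(p):
        g = np.zeros(d + 1 + n)
        g[:d] = p[:d]
        g[d + 1:] = C
        return g

    constraints = [
        {"type": "ineq",
         "fun": lambda p: p[d + 1:] - (1.0 - y * (X @ p[:d] + p[d])),
         "jac": lambda p: np.hstack([y[:, None] * X, y[:, None], np.eye(n)])},
        {"type": "ineq",
         "fun": lambda p: p[d + 1:],
         "jac": lambda p: np.hstack([np.zeros((n, d + 1)), np.eye(n)])},
    ]
    p0 = np.zeros(d + 1 + n)
    p0[d + 1:] = 1.0
    res = minimize(objective, p0, jac=jac, method="SLSQP", constraints=constraints,
                   options={"maxiter": 2000, "ftol": 1e-14})
    p = res.x
    w = p[:d]
    return w, _optimal_bias(X, y, w, C)


def _optimal_bias(X: np.ndarray, y: np.ndarray, w: np.ndarray, C: float) -> float:
    """Exact 1-D minimization of the hinge sum over the bias.

    The hinge objective is piecewise linear and convex in b with kinks at
    ``y_i - w.x_i``; when the minimizer is an interval (degenerate ties,
    no free support vector) the midpoint is returned — the same convention
    the package's SMO uses, so the two implementations are comparable on
    degenerate inputs.
    """
    kinks = np.sort(y - X @ w)

    def hinge(b):
        return float(np.sum(np.maximum(0.0, 1.0 - y * (X @ w + b))))

    vals = np.array([hinge(b) for b in kinks])
    lo = vals.min()
    at_min = kinks[vals <= lo + 1e-12]
    return float((at_min.min() + at_min.max()) / 2.0)


def two_step_loso(
    X: np.ndarray,
    y: np.ndarray,
    subjects: np.ndarray,
    C: float = 1.0,
) -> dict:
    """Leave-one-subject-out evaluation of the full two-step procedure.

    For every held-out subject: per-channel SVMs cross-validated
    leave-one-subject-out *within* the training set give channel
    accuracies (the weights), the weighted channel average feeds the main
    SVM, and the held-out subject's two nights are scored.  Returns
    validation/training accuracies and the averaged absolute weights.
    """
    n, G, B = X.shape
    subj_u = sorted(set(subjects.tolist()))
    val_correct = 0
    val_total = 0
    train_acc = []
    inner_w = np.zeros((G, B))
    outer_w = np.zeros(B)
    n_folds = 0

    for held in subj_u:
        val_mask = np.array([s == held for s in subjects])
        Xtr, ytr, str_ = X[~val_mask], y[~val_mask], subjects[~val_mask]
        tr_subj = sorted(set(str_.tolist()))

        # step 1: channel accuracies by inner leave-one-subject-out
        ch_acc = np.zeros(G)
        ch_w = np.zeros((G, B))
        for g in range(G):
            correct = 0
            total = 0
            for inner_held in tr_subj:
                im = np.array([s == inner_held for s in str_])
                w, b = svm_primal_fit(Xtr[~im][:, g, :], ytr[~im], C)
                pred = np.where(Xtr[im][:, g, :] @ w + b > 0, 1.0, -1.0)
                correct += int(np.sum(pred == ytr[im]))
                total += int(im.sum())
                ch_w[g] += np.abs(w)
            ch_acc[g] = correct / total
            ch_w[g] /= len(tr_subj)

        # step 2: weighted channel average + main SVM
        def weighted(A):
            out = np.zeros((A.shape[0], B))
            for i in range(A.shape[0]):
                for g in range(G):
                    out[i] += ch_acc[g] * A[i, g, :]
                out[i] /= ch_acc.sum()
            return out

        Xw_tr = weighted(Xtr)
        w, b = svm_primal_fit(Xw_tr, ytr, C)
        train_acc.append(float(np.mean(np.where(Xw_tr @ w + b > 0, 1.0, -1.0) == ytr)))
        Xw_val = weighted(X[val_mask])
        pred = np.where(Xw_val @ w + b > 0, 1.0, -1.0)
        val_correct += int(np.sum(pred == y[val_mask]))
        val_total += int(val_mask.sum())
        inner_w += ch_w
        outer_w += np.abs(w)
        n_folds += 1

    return {
        "validation_accuracy": val_correct / val_total,
        "training_accuracy": float(np.mean(train_acc)),
        "inner_weight_matrix": inner_w / n_folds,
        "outer_weights": outer_w / n_folds,
    }
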