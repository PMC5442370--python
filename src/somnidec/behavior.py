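"""Recognition-memory scoring and reprocessing-behaviour statistics.

Memory sensitivity is the signal-detection index d' = z(hit rate) -
z(false-alarm rate); overnight consolidation is post-sleep minus pre-sleep
d'.  "Reprocessing strength" of a night is the classifier's mean calibrated
probability of that night's true condition, averaged over all
cross-validation repetitions.  The module reports the full statistics
family: Spearman and partial rank correlations, multi-predictor OLS on
standardized variables with squared-semipartial variance decomposition, a
stage-by-strength slope-interaction test with cluster-robust (by subject)
standard errors, and a leverage-based influential-point filter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .decode import DecodingResult


def dprime(hits: int, n_old: int, false_alarms: int, n_new: int) -> float:
    """d' with log-linear extreme-rate correction (count+0.5)/(n+1).

    The correction keeps d' finite at perfect hit or zero false-alarm
    counts while leaving mid-range rates nearly untouched.
    """
    if n_old <= 0 or n_new <= 0:
        raise ValueError("n_old and n_new must be positive")
    if not (0 <= hits <= n_old and 0 <= false_alarms <= n_new):
        raise ValueError("counts out of range")
    hr = (hits + 0.5) / (n_old + 1.0)
    far = (false_alarms + 0.5) / (n_new + 1.0)
    return float(stats.norm.ppf(hr) - stats.norm.ppf(far))


def consolidation_table(behaviour: pd.DataFrame) -> pd.DataFrame:
    """Per subject-night overnight consolidation (post d' - pre d')."""
    rows = []
    for (subject, night), grp in behaviour.groupby(["subject", "night"]):
        d = {
            r.session: dprime(r.hits, r.n_old, r.false_alarms, r.n_new)
            for r in grp.itertuples(index=False)
        }
        if "pre" not in d or "post" not in d:
            raise ValueError(f"subject {subject} night {night} lacks a pre or post session")
        rows.append({
            "subject": subject, "night": night,
            "d_pre": d["pre"], "d_post": d["post"],
            "consolidation": d["post"] - d["pre"],
        })
    return pd.DataFrame(rows)


def night_strengths(result: DecodingResult) -> pd.DataFrame:
    """Per-night reprocessing strength from one cell's decoding result."""
    return pd.DataFrame({
        "subject": result.subjects,
        "night": result.nights,
        "strength": result.prob_correct,
    })


def reprocessing_strength(result: DecodingResult, subject) -> float:
    """A subject's mean probability-of-correct-class over its nights.

    Raises ``KeyError`` when the subject was not included in the cell; the
    caller treats that as a missing value (pairwise exclusion).
    """
    sel = result.subjects == subject
    if not sel.any():
        raise KeyError(f"subject {subject} not included in this cell")
    return float(np.nanmean(result.prob_correct[sel]))


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with average ranks; p from the t-approximation."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size != y.size or x.size < 5:
        raise ValueError("need >= 5 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def partial_spearman(x, y, z) -> tuple[float, float]:
    """Rank-based partial correlation of x and y controlling for z.

    All three variables are rank-transformed (average ranks), then the
    first-order partial Pearson correlation is computed on the ranks; p
    from the t distribution with n - 3 degrees of freedom.
    """
    x, y, z = (np.asarray(v, dtype=np.float64) for v in (x, y, z))
    if not (x.size == y.size == z.size) or x.size < 5:
        raise ValueError("need >= 5 complete triples")
    for v in (x, y, z):
        if np.ptp(v) == 0:
            raise ValueError("correlation undefined for a constant vector")
    rx, ry, rz = (stats.rankdata(v) for v in (x, y, z))
    rxy = np.corrcoef(rx, ry)[0, 1]
    rxz = np.corrcoef(rx, rz)[0, 1]
    ryz = np.corrcoef(ry, rz)[0, 1]
    denom = np.sqrt((1.0 - rxz**2) * (1.0 - ryz**2))
    if denom < 1e-12:
        raise ValueError("control variable collinear with x or y")
    r = (rxy - rxz * ryz) / denom
    n = x.size
    df = n - 3
    t = r * np.sqrt(df / max(1e-12, 1.0 - r**2))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(r), float(p)


@dataclass
class RegressionResult:
    beta: dict[str, float]             # standardized coefficients
    p_values: dict[str, float]
    variance_explained: dict[str, float]   # squared semipartial correlations
    r_squared: float
    n: int


def reprocessing_regression(predictors: pd.DataFrame, outcome) -> RegressionResult:
    """OLS of consolidation on standardized stage strengths.

    Listwise deletion over the joint model; per-predictor variance
    explained is the squared semipartial correlation
    ``t_j^2 (1 - R^2) / df_resid``.
    """
    y = np.asarray(outcome, dtype=np.float64)
    df = predictors.copy()
    df["_y"] = y
    df = df.dropna()
    if len(df) < 10:
        raise ValueError("need >= 10 complete cases")
    names = [c for c in predictors.columns]
    Xs = stats.zscore(df[names].to_numpy(), ddof=1)
    ys = stats.zscore(df["_y"].to_numpy(), ddof=1)
    if np.linalg.cond(Xs.T @ Xs) > 1e6:
        raise ValueError("collinear predictors (condition number > 1e6)")
    model = sm.OLS(ys, sm.add_constant(Xs)).fit()
    beta = dict(zip(names, model.params[1:]))
    pvals = dict(zip(names, model.pvalues[1:]))
    # squared semipartial correlation: R^2 drop when the predictor is removed
    sr2 = {}
    for i, name in enumerate(names):
        if len(names) == 1:
            sr2[name] = float(model.rsquared)
            continue
        reduced = sm.OLS(ys, sm.add_constant(np.delete(Xs, i, axis=1))).fit()
        sr2[name] = float(model.rsquared - reduced.rsquared)
    return RegressionResult(
        beta={k: float(v) for k, v in beta.items()},
        p_values={k: float(v) for k, v in pvals.items()},
        variance_explained=sr2,
        r_squared=float(model.rsquared),
        n=len(df),
    )


@dataclass
class InteractionResult:
    interaction_coef: float
    interaction_p: float
    slope_a: float
    slope_b: float
    n_obs: int


def slope_interaction_test(
    strength_a,
    strength_b,
    consolidation,
    groups=None,
) -> InteractionResult:
    """Do two stages' strength-consolidation slopes differ?

    Observations are stacked (two rows per unit: stage A and stage B) and
    consolidation is regressed on strength, a stage indicator, and their
    interaction; the interaction coefficient equals the difference of the
    stage-specific slopes.  Standard errors are cluster-robust by unit
    because the two rows of a unit are paired.
    """
    a = np.asarray(strength_a, dtype=np.float64)
    b = np.asarray(strength_b, dtype=np.float64)
    y = np.asarray(consolidation, dtype=np.float64)
    if a.size != b.size or a.size != y.size:
        raise ValueError("inputs must be aligned per unit")
    if a.size < 4:
        raise ValueError("too few paired observations")
    keep = np.isfinite(a) & np.isfinite(b) & np.isfinite(y)
    a, b, y = a[keep], b[keep], y[keep]
    g = np.arange(a.size) if groups is None else np.asarray(groups)[keep]

    strength = np.concatenate([a, b])
    stage = np.concatenate([np.zeros(a.size), np.ones(b.size)])
    yy = np.concatenate([y, y])
    gg = np.concatenate([g, g])
    X = sm.add_constant(np.column_stack([strength, stage, strength * stage]))
    fit = sm.OLS(yy, X).fit(cov_type="cluster", cov_kwds={"groups": gg})
    slope_a = float(fit.params[1])
    slope_b = float(fit.params[1] + fit.params[3])
    return InteractionResult(
        interaction_coef=float(fit.params[3]),
        interaction_p=float(fit.pvalues[3]),
        slope_a=slope_a,
        slope_b=slope_b,
        n_obs=int(yy.size),
    )


def leverage_filter(x, y, k: int = 3) -> np.ndarray:
    """Indices retained after removing the k highest-leverage observations.

    Leverage is the hat-matrix diagonal of the simple regression of y on x,
    ``h_i = 1/n + (x_i - xbar)^2 / sum (x - xbar)^2`` (so sum h = 2).
    """
    x = np.asarray(x, dtype=np.float64)
    n = x.size
    if k < 0 or k >= n:
        raise ValueError("k must satisfy 0 <= k < n")
    if n <= k + 3:
        raise ValueError("too few observations to remove k points")
    if k == 0:
        return np.arange(n)
    xbar = x.mean()
    ss = np.sum((x - xbar) ** 2)
    h = 1.0 / n + (x - xbar) ** 2 / ss
    drop = np.argsort(h, kind="stable")[-k:]
    return np.setdiff1d(np.arange(n), drop)
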