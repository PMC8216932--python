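"""Richness-predictor model fitting and information-theoretic comparison.

Candidate hypotheses for the elevational richness gradient are compared as
Gaussian identity-link GLMs (ordinary least squares) of per-site richness on
log-transformed predictors, ranked by the small-sample-corrected Akaike
information criterion

    AICc = -2 loglik + 2k + 2k(k+1)/(n - k - 1),

where k counts the intercept, the slopes and the residual variance.  Akaike
weights w_i = exp(-Delta_i/2)/sum_j exp(-Delta_j/2) quantify relative
evidence; variable importance is the sum of weights over models containing
the variable.  Models with any variance inflation factor >= 10 are screened
out before ranking.  A greedy forward-stepwise search (add the variable that
most lowers AICc; stop when no addition lowers it) produces the final model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.outliers_influence import variance_inflation_factor

#: the candidate set: hypothesis name -> list of predictor columns
DEFAULT_CANDIDATES: dict[str, tuple[str, ...]] = {
    "null": (),
    "MDE": ("MDE",),
    "VT": ("VT",),
    "CT": ("CT",),
    "CT+VT": ("CT", "VT"),
    "SR": ("SR",),
    "AP": ("AP",),
    "AT": ("AT",),
    "WS": ("WS",),
}

#: which hypothesis each candidate embodies
HYPOTHESIS_OF = {
    "null": "null",
    "MDE": "mid-domain effect",
    "VT": "habitat complexity",
    "CT": "habitat complexity",
    "CT+VT": "habitat complexity",
    "SR": "energy",
    "AP": "environment",
    "AT": "environment",
    "WS": "environment",
}


@dataclass
class FitResult:
    name: str
    predictors: tuple[str, ...]
    coef: dict[str, float]
    se: dict[str, float]
    std_slopes: dict[str, float]
    loglik: float
    k: int
    n: int
    adj_r2: float
    aicc: float
    model: object = None  # fitted statsmodels results, for downstream use


@dataclass
class ModelComparison:
    table: pd.DataFrame  # name, hypothesis, k, adj_r2, aicc, delta, weight
    fits: dict[str, FitResult]
    importance: dict[str, float]
    vif: dict[str, dict[str, float]]
    excluded: list[str] = field(default_factory=list)

    @property
    def best(self) -> str:
        return str(self.table.iloc[0]["model"])


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample corrected AIC; requires n - k - 1 > 0."""
    if n - k - 1 <= 0:
        raise ValueError(f"AICc undefined for n={n}, k={k} (need n > k + 1)")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def akaike_weights(aicc_values) -> np.ndarray:
    """Evidence weights from a vector of AICc values (invariant to shifts)."""
    a = np.asarray(aicc_values, dtype=float)
    if a.size == 0:
        raise ValueError("need at least one model")
    delta = a - a.min()
    w = np.exp(-delta / 2.0)
    return w / w.sum()


def vif(X: pd.DataFrame) -> dict[str, float]:
    """Variance inflation factor per predictor column (intercept added).

    With a single predictor VIF is 1 by definition.  Exact collinearity is
    reported as ``inf`` so callers can flag and exclude the model.
    """
    cols = list(X.columns)
    if len(cols) < 2:
        return {c: 1.0 for c in cols}
    Xc = sm.add_constant(np.asarray(X, dtype=float))
    out = {}
    for i, c in enumerate(cols):
        with np.errstate(divide="ignore"):
            v = variance_inflation_factor(Xc, i + 1)
        out[c] = float(v) if np.isfinite(v) else math.inf
    return out


def _log_transform(df: pd.DataFrame, cols) -> pd.DataFrame:
    """Natural-log transform, erroring on nonpositive values with context."""
    out = {}
    for c in cols:
        x = np.asarray(df[c], dtype=float)
        if np.any(x <= 0):
            i = int(np.flatnonzero(x <= 0)[0])
            raise ValueError(
                f"cannot log-transform {c!r}: nonpositive value {x[i]} at row {i} "
                f"(site {df.index[i]!r})"
            )
        out[c] = np.log(x)
    return pd.DataFrame(out, index=df.index)


def fit_gaussian(y, X: pd.DataFrame, name: str = "model") -> FitResult:
    """OLS fit of richness on the given (already transformed) predictors."""
    y = np.asarray(y, dtype=float)
    n = y.size
    Xd = sm.add_constant(X, has_constant="add") if len(X.columns) else pd.DataFrame(
        {"const": np.ones(n)}, index=X.index if len(X.index) == n else None
    )
    res = sm.OLS(y, np.asarray(Xd, dtype=float)).fit()
    k = len(Xd.columns) + 1  # + residual variance
    names = list(Xd.columns)
    coef = dict(zip(names, map(float, res.params)))
    se = dict(zip(names, map(float, res.bse)))
    # standardized partial slopes: slope * sd(x); predictors are z-scored
    std_slopes = {
        c: float(res.params[i] * np.std(np.asarray(X[c], dtype=float), ddof=1))
        for i, c in enumerate(names)
        if c != "const"
    }
    adj = float(res.rsquared_adj) if len(X.columns) else float("nan")
    return FitResult(
        name=name,
        predictors=tuple(X.columns),
        coef=coef,
        se=se,
        std_slopes=std_slopes,
        loglik=float(res.llf),
        k=k,
        n=n,
        adj_r2=adj,
        aicc=aicc(float(res.llf), k, n),
        model=res,
    )


def prepare_predictors(covariates: pd.DataFrame, mde_curve=None,
                       log: bool = True) -> pd.DataFrame:
    """Assemble the predictor table (MDE, VT, CT, SR, AP, AT, WS), log scale.

    ``covariates`` uses the reader's lowercase column names; the MDE column is
    the null-model mean richness curve aligned with the (elevation-sorted)
    sites.  All continuous variables are natural-log transformed.
    """
    mapping = {"VT": "vt_count", "CT": "ct_count", "SR": "sr", "AP": "ap",
               "AT": "at", "WS": "ws"}
    data = {k: covariates[v] for k, v in mapping.items() if v in covariates}
    df = pd.DataFrame(data, index=covariates.index)
    if mde_curve is not None:
        df.insert(0, "MDE", np.asarray(mde_curve, dtype=float))
    return _log_transform(df, df.columns) if log else df


def fit_polynomial(richness, elevation, max_degree: int = 4):
    """Polynomial regressions of richness on centred elevation, AICc-guided.

    Returns ``(best_degree, {degree: FitResult})``; the best degree minimizes
    AICc.  Elevation is centred and scaled for numerical conditioning (the
    fitted curve is unchanged).
    """
    elevation = np.asarray(elevation, dtype=float)
    richness = np.asarray(richness, dtype=float)
    if np.ptp(elevation) == 0:
        raise ValueError("constant elevation: polynomial fit undefined")
    if richness.size <= max_degree + 2:
        raise ValueError("need n > max_degree + 2 observations")
    z = (elevation - elevation.mean()) / elevation.std(ddof=0)
    if np.ptp(richness) == 0:
        # degenerate response: every degree fits exactly, so the intercept-only
        # model is selected by parsimony
        fits = {0: fit_gaussian(richness + 0.0, pd.DataFrame(index=range(richness.size)),
                                name="degree-0")}
        return 0, fits
    fits = {}
    for d in range(max_degree + 1):
        X = pd.DataFrame({f"z^{p}": z**p for p in range(1, d + 1)})
        fits[d] = fit_gaussian(richness, X, name=f"degree-{d}")
    best = min(fits, key=lambda d: fits[d].aicc)
    return best, fits


def polynomial_curve(fit: FitResult, elevation, at=None) -> np.ndarray:
    """Evaluate a `fit_polynomial` result on the original elevation scale."""
    elevation = np.asarray(elevation, dtype=float)
    at = elevation if at is None else np.asarray(at, dtype=float)
    z = (at - elevation.mean()) / elevation.std(ddof=0)
    y = np.full(z.shape, fit.coef["const"])
    for name, b in fit.coef.items():
        if name.startswith("z^"):
            y = y + b * z ** int(name[2:])
    return y


def compare_candidates(
    richness,
    predictors: pd.DataFrame,
    candidates: dict[str, tuple[str, ...]] | None = None,
    standardize: bool = True,
    vif_threshold: float = 10.0,
) -> ModelComparison:
    """Fit the candidate set, screen by VIF, rank by AICc.

    ``predictors`` should already be on the log scale (`prepare_predictors`);
    with ``standardize`` they are z-scored so slopes are standardized partial
    regression slopes.  Candidates whose max VIF >= 10 are excluded before
    weights are computed.
    """
    candidates = dict(candidates or DEFAULT_CANDIDATES)
    X_all = predictors.copy()
    if standardize:
        X_all = (X_all - X_all.mean()) / X_all.std(ddof=1)

    fits: dict[str, FitResult] = {}
    vifs: dict[str, dict[str, float]] = {}
    excluded = []
    for name, cols in candidates.items():
        missing = [c for c in cols if c not in X_all.columns]
        if missing:
            raise KeyError(f"candidate {name!r} needs missing predictors {missing}")
        X = X_all.loc[:, list(cols)]
        v = vif(X)
        vifs[name] = v
        if v and max(v.values()) >= vif_threshold:
            excluded.append(name)
            continue
        fits[name] = fit_gaussian(np.asarray(richness), X, name=name)

    names = list(fits)
    aiccs = np.array([fits[m].aicc for m in names])
    weights = akaike_weights(aiccs)
    delta = aiccs - aiccs.min()
    table = pd.DataFrame(
        {
            "model": names,
            "hypothesis": [HYPOTHESIS_OF.get(m, "custom") for m in names],
            "k": [fits[m].k for m in names],
            "adj_r2": [fits[m].adj_r2 for m in names],
            "aicc": aiccs,
            "delta_aicc": delta,
            "weight": weights,
        }
    ).sort_values("aicc", kind="stable", ignore_index=True)

    importance: dict[str, float] = {}
    for var in predictors.columns:
        importance[var] = float(
            sum(w for m, w in zip(names, weights) if var in fits[m].predictors)
        )
    return ModelComparison(table=table, fits=fits, importance=importance,
                           vif=vifs, excluded=excluded)


@dataclass
class StepwiseResult:
    entry_order: list[str]
    steps: pd.DataFrame  # step, variable, std_slope, adj_r2_increment, aicc
    final: FitResult


def forward_stepwise(richness, predictors: pd.DataFrame,
                     standardize: bool = True) -> StepwiseResult:
    """Greedy forward selection by AICc over single variables.

    Stage 1 picks the single variable with minimum AICc; each later stage adds
    the variable that most lowers AICc, stopping when no addition lowers it.
    Reported per-step adjusted-R² increments follow the entry order.
    """
    y = np.asarray(richness, dtype=float)
    X_all = predictors.copy()
    if standardize:
        X_all = (X_all - X_all.mean()) / X_all.std(ddof=1)
    remaining = list(X_all.columns)
    chosen: list[str] = []
    current = fit_gaussian(y, X_all.loc[:, []], name="null")
    rows = []
    prev_adj = 0.0
    while remaining:
        trials = {
            v: fit_gaussian(y, X_all.loc[:, chosen + [v]], name="+".join(chosen + [v]))
            for v in remaining
        }
        best_v = min(trials, key=lambda v: trials[v].aicc)
        if trials[best_v].aicc >= current.aicc and chosen:
            break
        if trials[best_v].aicc >= current.aicc and not chosen:
            break  # nothing beats the null model
        current = trials[best_v]
        chosen.append(best_v)
        remaining.remove(best_v)
        rows.append(
            {
                "step": len(chosen),
                "variable": best_v,
                "adj_r2_increment": current.adj_r2 - prev_adj,
                "adj_r2_total": current.adj_r2,
                "aicc": current.aicc,
            }
        )
        prev_adj = current.adj_r2
    steps = pd.DataFrame(rows)
    if not steps.empty:
        steps["std_slope_final"] = [current.std_slopes.get(v, np.nan)
                                    for v in steps["variable"]]
    return StepwiseResult(entry_order=chosen, steps=steps, final=current)


def simulate_coefficient_intervals(
    fit: FitResult,
    X: pd.DataFrame | np.ndarray,
    n_draws: int = 4000,
    seed: int = 0,
    ci: float = 0.95,
):
    """Percentile bands for the fitted mean curve by posterior-style simulation.

    Coefficient vectors are drawn from the estimated sampling distribution:
    sigma^2 from its scaled inverse-chi-square distribution, then
    beta ~ N(beta_hat, sigma^2 (X'X)^-1).  Under a flat prior this coincides
    with the Bayesian posterior of the Gaussian linear model, so the bands
    play the role of credible intervals.
    """
    res = fit.model
    if res is None:
        raise ValueError("FitResult carries no fitted model")
    rng = np.random.default_rng(seed)
    Xd = sm.add_constant(np.asarray(X, dtype=float), has_constant="add")
    if Xd.shape[1] != len(res.params):
        raise ValueError("design matrix width does not match fitted coefficients")
    df_resid = int(res.df_resid)
    if df_resid <= 0:
        raise ValueError("no residual degrees of freedom")
    s2 = float(res.mse_resid)
    xtx_inv = np.asarray(res.normalized_cov_params)  # (X'X)^-1
    try:
        L = np.linalg.cholesky(xtx_inv + 1e-12 * np.eye(xtx_inv.shape[0]))
    except np.linalg.LinAlgError as e:
        raise ValueError("singular coefficient covariance") from e
    sigma2 = df_resid * s2 / rng.chisquare(df_resid, size=n_draws)
    z = rng.standard_normal((n_draws, len(res.params)))
    betas = res.params + np.sqrt(sigma2)[:, None] * (z @ L.T)
    curves = betas @ Xd.T
    alpha = (1 - ci) / 2
    lo = np.percentile(curves, 100 * alpha, axis=0)
    hi = np.percentile(curves, 100 * (1 - alpha), axis=0)
    return lo, hi
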