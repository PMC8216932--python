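"""Family-level occurrence and community-type (CT) use along elevation.

Two model families:

* `fit_occurrence` — binomial logistic regression of a moss family's
  per-site presence/absence on elevation with linear and quadratic terms,
  yielding an occurrence-probability curve and a shape classification
  (increasing / decreasing / hump / U / flat).
* `fit_ct_use` — multinomial logistic regression of the substrate category
  (aquatic, stone, soil, woody) a specimen occupies on elevation, yielding
  proportional-use curves that sum to one at every elevation.

Default inference is maximum likelihood; curve uncertainty comes from a
parametric bootstrap.  An optional random-walk Metropolis mode (two chains,
10,000 iterations, burn-in 1,000, thinned by two, convergence by split
R-hat) samples the same likelihood under flat priors and is provided for
cross-checking — the estimands are identical under flat priors, so ML and
MCMC agree up to Monte Carlo error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .core_io import CT_CATEGORIES

log = logging.getLogger("elevpart")


# ---------------------------------------------------------------------------
# occurrence probability along elevation
# ---------------------------------------------------------------------------

@dataclass
class OccurrenceModel:
    family: str
    coef: dict[str, float]          # intercept, z, z2 on the log-odds scale
    elev_mean: float
    elev_scale: float
    shape: str                      # increasing | decreasing | hump | u | flat
    separation_flagged: bool
    grid: np.ndarray
    prob: np.ndarray
    band_lo: np.ndarray
    band_hi: np.ndarray

    def predict(self, elevation) -> np.ndarray:
        z = (np.asarray(elevation, float) - self.elev_mean) / self.elev_scale
        eta = self.coef["intercept"] + self.coef["z"] * z + self.coef["z2"] * z**2
        return 1.0 / (1.0 + np.exp(-eta))


def _classify_shape(b1: float, b2: float, z_lo: float, z_hi: float,
                    se1: float, se2: float, z_crit: float = 1.96) -> str:
    """Shape of eta(z) = b1 z + b2 z^2 over [z_lo, z_hi].

    Coefficients within ``z_crit`` standard errors of zero are treated as
    flat/linear; a vertex outside the observed span demotes a parabola to a
    monotone trend.
    """
    quad_sig = abs(b2) > z_crit * se2 if np.isfinite(se2) else abs(b2) > 1e-8
    lin_sig = abs(b1) > z_crit * se1 if np.isfinite(se1) else abs(b1) > 1e-8
    if quad_sig:
        vertex = -b1 / (2.0 * b2)
        if z_lo < vertex < z_hi:
            return "hump" if b2 < 0 else "u"
        # vertex outside the span: monotone over the observed range
        mid_slope = b1 + 2.0 * b2 * 0.5 * (z_lo + z_hi)
        return "increasing" if mid_slope > 0 else "decreasing"
    if lin_sig:
        return "increasing" if b1 > 0 else "decreasing"
    return "flat"


def fit_occurrence(presence, elevation, family: str = "",
                   n_boot: int = 500, seed: int = 0,
                   n_grid: int = 100, ci: float = 0.95) -> OccurrenceModel:
    """Quadratic-logistic occurrence model for one family.

    ``presence`` is the 0/1 vector of the family's presence per site.  Needs
    at least one presence and one absence.  Complete or quasi-complete
    separation is detected (non-convergence or exploding standard errors) and
    handled with a ridge-penalized refit, flagged on the result.
    """
    y = np.asarray(presence, dtype=float)
    elev = np.asarray(elevation, dtype=float)
    if y.size != elev.size:
        raise ValueError("presence and elevation must have equal length")
    if y.min() == y.max():
        raise ValueError(
            f"family {family!r} has no {'absences' if y.min() == 1 else 'presences'}; "
            "occurrence model undefined"
        )
    mu, sd = elev.mean(), elev.std(ddof=0)
    z = (elev - mu) / sd
    X = sm.add_constant(np.column_stack([z, z**2]))

    flagged = False
    try:
        with np.errstate(all="ignore"):
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=100)
        params, bse = np.asarray(res.params), np.asarray(res.bse)
        if not np.all(np.isfinite(bse)) or np.max(np.abs(params)) > 15:
            raise PerfectSeparationLike()
    except Exception:
        # ridge-penalized fallback: keeps estimates finite under separation
        flagged = True
        log.warning("separation suspected for family %r; ridge-penalized refit", family)
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit_regularized(
            alpha=1.0 / y.size, L1_wt=0.0
        )
        params = np.asarray(res.params)
        bse = np.full(3, np.nan)

    coef = {"intercept": float(params[0]), "z": float(params[1]), "z2": float(params[2])}
    shape = _classify_shape(coef["z"], coef["z2"], z.min(), z.max(),
                            float(bse[1]), float(bse[2]))

    grid = np.linspace(elev.min(), elev.max(), n_grid)
    zg = (grid - mu) / sd
    Xg = sm.add_constant(np.column_stack([zg, zg**2]))
    eta = Xg @ params
    prob = 1.0 / (1.0 + np.exp(-eta))

    # parametric bootstrap band: resample y from the fitted probabilities
    rng = np.random.default_rng(seed)
    p_hat = 1.0 / (1.0 + np.exp(-(X @ params)))
    curves = np.empty((n_boot, n_grid))
    for b in range(n_boot):
        yb = rng.binomial(1, p_hat).astype(float)
        if yb.min() == yb.max():
            curves[b] = prob
            continue
        try:
            with np.errstate(all="ignore"):
                rb = sm.GLM(yb, X, family=sm.families.Binomial()).fit(maxiter=50)
            pb = np.asarray(rb.params)
            if np.max(np.abs(pb)) > 30:
                raise PerfectSeparationLike()
        except Exception:
            rb = sm.GLM(yb, X, family=sm.families.Binomial()).fit_regularized(
                alpha=1.0 / y.size, L1_wt=0.0
            )
            pb = np.asarray(rb.params)
        curves[b] = 1.0 / (1.0 + np.exp(-(Xg @ pb)))
    alpha = (1 - ci) / 2
    lo = np.percentile(curves, 100 * alpha, axis=0)
    hi = np.percentile(curves, 100 * (1 - alpha), axis=0)

    return OccurrenceModel(
        family=family, coef=coef, elev_mean=mu, elev_scale=sd, shape=shape,
        separation_flagged=flagged, grid=grid, prob=prob,
        band_lo=lo, band_hi=hi,
    )


class PerfectSeparationLike(Exception):
    """Internal marker: the ML fit diverged the way separation makes it."""


# ---------------------------------------------------------------------------
# multinomial community-type use
# ---------------------------------------------------------------------------

@dataclass
class CTUseModel:
    family: str
    categories: list[str]            # ordered; first is the reference
    coef: np.ndarray                 # (n_categories-1, 2): intercept, slope in z
    elev_mean: float
    elev_scale: float
    grid: np.ndarray
    proportions: pd.DataFrame        # grid x categories, rows sum to 1
    band_lo: pd.DataFrame | None = None
    band_hi: pd.DataFrame | None = None
    degenerate: bool = False
    mcmc: dict = field(default_factory=dict)

    def predict(self, elevation) -> pd.DataFrame:
        z = (np.asarray(elevation, float) - self.elev_mean) / self.elev_scale
        return pd.DataFrame(
            _mn_probs(self.coef, z), columns=self.categories,
        )


def _mn_probs(coef: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Multinomial-logit probabilities; reference category has eta = 0."""
    z = np.atleast_1d(np.asarray(z, float))
    eta = np.zeros((z.size, coef.shape[0] + 1))
    eta[:, 1:] = coef[:, 0] + np.outer(z, coef[:, 1])
    eta -= eta.max(axis=1, keepdims=True)
    p = np.exp(eta)
    return p / p.sum(axis=1, keepdims=True)


def _mn_loglik(coef_flat: np.ndarray, z: np.ndarray, y_idx: np.ndarray,
               n_cat: int) -> float:
    coef = coef_flat.reshape(n_cat - 1, 2)
    p = _mn_probs(coef, z)
    return float(np.log(np.clip(p[np.arange(z.size), y_idx], 1e-300, None)).sum())


def fit_ct_use(
    community_types,
    elevation,
    family: str = "",
    reference: str = "soil",
    n_boot: int = 300,
    seed: int = 0,
    n_grid: int = 100,
    ci: float = 0.95,
    method: str = "ml",
    mcmc_chains: int = 2,
    mcmc_iter: int = 10_000,
    mcmc_burn: int = 1_000,
    mcmc_thin: int = 2,
) -> CTUseModel:
    """Multinomial CT-use model for one family's specimens.

    ``community_types`` holds one category per specimen; ``elevation`` the
    specimen's site elevation.  The reference category (default ``soil``) is
    the denominator of the log-odds; if it was not observed, the first
    observed category substitutes.  ``method='mcmc'`` additionally runs
    random-walk Metropolis chains on the same likelihood (flat prior) and
    stores posterior means and split R-hat diagnostics.
    """
    cts = pd.Series(community_types).astype(str)
    elev = np.asarray(elevation, dtype=float)
    if len(cts) != elev.size:
        raise ValueError("community_types and elevation must have equal length")
    unknown = set(cts) - set(CT_CATEGORIES)
    if unknown:
        raise ValueError(f"unknown community types {sorted(unknown)}")
    observed = [c for c in CT_CATEGORIES if c in set(cts)]

    mu, sd = elev.mean(), (elev.std(ddof=0) or 1.0)
    z = (elev - mu) / sd
    grid = np.linspace(elev.min(), elev.max(), n_grid)
    zg = (grid - mu) / sd

    if len(observed) == 1:
        log.warning("family %r uses a single community type %r", family, observed[0])
        props = pd.DataFrame({observed[0]: np.ones(n_grid)})
        return CTUseModel(
            family=family, categories=observed, coef=np.zeros((0, 2)),
            elev_mean=mu, elev_scale=sd, grid=grid, proportions=props,
            degenerate=True,
        )

    ref = reference if reference in observed else observed[0]
    categories = [ref] + [c for c in observed if c != ref]
    cat_idx = {c: i for i, c in enumerate(categories)}
    y_idx = cts.map(cat_idx).to_numpy()
    n_cat = len(categories)

    coef = _fit_mn_ml(z, y_idx, n_cat)
    props = pd.DataFrame(_mn_probs(coef, zg), columns=categories)

    rng = np.random.default_rng(seed)
    band_lo = band_hi = None
    if n_boot > 0:
        p_obs = _mn_probs(coef, z)
        boot = np.empty((n_boot, n_grid, n_cat))
        for b in range(n_boot):
            yb = np.array([rng.choice(n_cat, p=p_obs[i]) for i in range(z.size)])
            if len(np.unique(yb)) < 2:
                boot[b] = props.to_numpy()
                continue
            cb = _fit_mn_ml(z, yb, n_cat)
            boot[b] = _mn_probs(cb, zg)
        a = (1 - ci) / 2
        band_lo = pd.DataFrame(np.percentile(boot, 100 * a, axis=0), columns=categories)
        band_hi = pd.DataFrame(np.percentile(boot, 100 * (1 - a), axis=0), columns=categories)

    mcmc_out: dict = {}
    if method == "mcmc":
        mcmc_out = _mn_metropolis(
            z, y_idx, n_cat, coef, rng,
            chains=mcmc_chains, n_iter=mcmc_iter, burn=mcmc_burn, thin=mcmc_thin,
        )

    return CTUseModel(
        family=family, categories=categories, coef=coef,
        elev_mean=mu, elev_scale=sd, grid=grid, proportions=props,
        band_lo=band_lo, band_hi=band_hi, mcmc=mcmc_out,
    )


def _fit_mn_ml(z: np.ndarray, y_idx: np.ndarray, n_cat: int) -> np.ndarray:
    """ML multinomial-logit coefficients (intercept + slope per non-reference
    category) via statsmodels MNLogit, BFGS fallback on non-convergence."""
    X = sm.add_constant(z)
    with np.errstate(all="ignore"):
        try:
            res = sm.MNLogit(_onehot_codes(y_idx, n_cat), X).fit(
                disp=False, maxiter=200
            )
            params = np.asarray(res.params)  # (2, n_cat-1)
            if not np.all(np.isfinite(params)) or np.max(np.abs(params)) > 25:
                raise PerfectSeparationLike()
            return params.T.copy()
        except Exception:
            from scipy.optimize import minimize

            x0 = np.zeros(2 * (n_cat - 1))
            # tiny ridge keeps separation-prone fits bounded
            obj = lambda c: -_mn_loglik(c, z, y_idx, n_cat) + 1e-4 * np.sum(c**2)
            sol = minimize(obj, x0, method="BFGS")
            return sol.x.reshape(n_cat - 1, 2)


def _onehot_codes(y_idx: np.ndarray, n_cat: int) -> np.ndarray:
    out = np.zeros((y_idx.size, n_cat))
    out[np.arange(y_idx.size), y_idx] = 1.0
    return out


def _mn_metropolis(z, y_idx, n_cat, coef_ml, rng, chains=2, n_iter=10_000,
                   burn=1_000, thin=2) -> dict:
    """Random-walk Metropolis on the multinomial likelihood with flat priors.

    Chains start jittered around the ML estimate; kept draws are post-burn-in
    and thinned.  Convergence is summarized by the split R-hat per parameter.
    """
    dim = coef_ml.size
    step = 0.15 / np.sqrt(max(z.size, 1) / 50.0)
    kept = []
    for _ in range(chains):
        x = coef_ml.ravel() + 0.5 * rng.standard_normal(dim)
        ll = _mn_loglik(x, z, y_idx, n_cat)
        draws = []
        for it in range(n_iter):
            prop = x + step * rng.standard_normal(dim)
            llp = _mn_loglik(prop, z, y_idx, n_cat)
            if np.log(rng.random()) < llp - ll:
                x, ll = prop, llp
            if it >= burn and (it - burn) % thin == 0:
                draws.append(x.copy())
        kept.append(np.array(draws))
    kept_arr = np.stack(kept)  # (chains, n_kept, dim)
    means = kept_arr.reshape(-1, dim).mean(axis=0)
    return {
        "posterior_mean": means.reshape(n_cat - 1, 2),
        "r_hat": _split_rhat(kept_arr),
        "n_kept_per_chain": kept_arr.shape[1],
        "chains": chains,
    }


def _split_rhat(chains: np.ndarray) -> np.ndarray:
    """Split R-hat per parameter from an array (chains, draws, dim)."""
    c, n, d = chains.shape
    half = n // 2
    split = chains[:, : 2 * half].reshape(2 * c, half, d)
    m, _ = split.shape[0], split.shape[1]
    chain_means = split.mean(axis=1)
    chain_vars = split.var(axis=1, ddof=1)
    W = chain_vars.mean(axis=0)
    B = half * chain_means.var(axis=0, ddof=1)
    var_hat = (half - 1) / half * W + B / half
    return np.sqrt(var_hat / np.where(W > 0, W, np.nan))
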