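"""Distribution-category rules and category/dispersal effect models.

Species shared between two distant regions are classed by range geometry
(continuous, fragmented, disjunct) or as migratory, and by family-level
dispersal ability (good, poor).  The question is whether these classes
predict intraspecific barcode divergence.

The model is a Gaussian linear mixed model fitted by maximum likelihood:

    y_s = mu + category effect + (optional covariate slope) + b_family + e_s

with a family-level random intercept b ~ N(0, sigma_f^2) to absorb
phylogenetic correlation, and — when ``heteroscedastic`` — a separate
residual SD per category, since e.g. migratory species are far less variable
than the rest.  The marginal likelihood is maximised directly: the fixed
effects are profiled out by generalised least squares at each variance
configuration, and the variance parameters are optimised numerically from a
small fixed set of starting points, so fits are deterministic.

Significance of a factor is assessed by a likelihood-ratio test between the
model including it (with per-category variances) and the null without it
(single variance), counting both mean and variance parameters in the degrees
of freedom: for a 4-level category that is 3 mean contrasts + 3 variance
ratios = 6 df.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sps

logger = logging.getLogger("barcodegap")

INTERMEDIATE_COUNTRIES = ("germany", "czech_republic", "poland")
BALTIC_STATES = ("lithuania", "latvia", "estonia")

MAX_GAP_KM = 500.0  # distribution gap defining a disjunct range


@dataclass
class PresenceTable:
    """Per-species occupancy of the countries between the two study regions.

    ``province_fraction_*`` is the fraction of provinces occupied in the
    named country; ``max_gap_km`` the largest gap in the range between the
    regions.  Any ``None`` field is treated as missing data.
    """

    species: str
    germany: bool | None
    czech_republic: bool | None
    poland: bool | None
    lithuania: bool | None
    latvia: bool | None
    estonia: bool | None
    nw_russia: bool | None
    province_fraction_germany: float | None
    province_fraction_poland: float | None
    max_gap_km: float | None
    migratory_flag: bool | None


def assign_distribution_category(row: PresenceTable) -> str:
    """Classify a species' distribution as one of the four categories.

    Precedence: migratory overrides everything; a range gap above 500 km
    makes the species disjunct; presence in every intermediate country
    (Germany, Czech Republic, Poland, north-western Russia, and at least two
    of the three Baltic states) with at least half the provinces occupied in
    both Germany and Poland makes it continuous; anything else is fragmented.
    Country absences alone never force "disjunct" — only the gap does.
    """
    for name in (
        "germany", "czech_republic", "poland", "lithuania", "latvia", "estonia",
        "nw_russia", "province_fraction_germany", "province_fraction_poland",
        "max_gap_km", "migratory_flag",
    ):
        if getattr(row, name) is None:
            raise ValueError(f"presence table for {row.species!r} is missing field {name!r}")
    if row.migratory_flag:
        return "migratory"
    if row.max_gap_km > MAX_GAP_KM:
        return "disjunct"
    countries_ok = all(getattr(row, c) for c in INTERMEDIATE_COUNTRIES) and row.nw_russia
    baltics_ok = sum(bool(getattr(row, b)) for b in BALTIC_STATES) >= 2
    provinces_ok = (
        row.province_fraction_germany >= 0.5 and row.province_fraction_poland >= 0.5
    )
    if countries_ok and baltics_ok and provinces_ok:
        return "continuous"
    return "fragmented"


@dataclass
class CategoryFit:
    """A fitted category-effect model."""

    response_name: str
    categories: list[str]  # empty for a null (intercept-only) model
    category_means: dict[str, float]
    category_sds: dict[str, float]
    family_re_sd: float
    covariate_slope: float | None
    loglik: float
    n: int
    n_params: int
    heteroscedastic: bool
    beta: np.ndarray = None  # mean parameters (cell means [+ covariate slope])
    beta_cov: np.ndarray = None  # GLS covariance of beta


@dataclass
class LRTResult:
    chi_sq: float
    df: int
    p_value: float


def _neg_profile_loglik(theta, y, X, fam_blocks, obs_cat, n_cats, het, use_re):
    """Negative profile log-likelihood over variance parameters.

    theta = per-category log residual SDs (or a single one) followed by the
    log family-intercept SD when the random effect is present.  Fixed effects
    are profiled out by GLS.
    """
    if het:
        log_s = theta[:n_cats]
        sigma2 = np.exp(2.0 * log_s)[obs_cat]
    else:
        sigma2 = np.full(len(y), np.exp(2.0 * theta[0]))
    sf2 = np.exp(2.0 * theta[-1]) if use_re else 0.0

    p = X.shape[1]
    XtViX = np.zeros((p, p))
    XtViy = np.zeros(p)
    ytViy = 0.0
    logdet = 0.0
    for idx in fam_blocks:
        d = sigma2[idx]
        dinv = 1.0 / d
        Xf = X[idx]
        yf = y[idx]
        XtViX += (Xf * dinv[:, None]).T @ Xf
        XtViy += Xf.T @ (dinv * yf)
        ytViy += float(np.sum(dinv * yf * yf))
        logdet += float(np.sum(np.log(d)))
        if use_re:
            t = float(dinv.sum())
            c = sf2 / (1.0 + sf2 * t)
            u = Xf.T @ dinv  # X' D^-1 1
            v = float(np.dot(dinv, yf))  # 1' D^-1 y
            XtViX -= c * np.outer(u, u)
            XtViy -= c * v * u
            ytViy -= c * v * v
            logdet += float(np.log1p(sf2 * t))
    try:
        beta = np.linalg.solve(XtViX, XtViy)
    except np.linalg.LinAlgError:
        return 1e12, None, None
    quad = ytViy - float(beta @ XtViy)
    n = len(y)
    nll = 0.5 * (n * np.log(2.0 * np.pi) + logdet + quad)
    if not np.isfinite(nll):
        return 1e12, None, None
    return nll, beta, XtViX


def fit_category_model(
    response,
    category=None,
    family=None,
    heteroscedastic: bool = True,
    covariate=None,
    response_name: str = "response",
    max_iter: int = 500,
) -> CategoryFit:
    """Fit the category-effect mixed model by maximum likelihood.

    ``category=None`` fits the null model (grand mean, single residual SD).
    ``family=None`` — or a single family — drops the random intercept, in
    which case the homoscedastic model without covariate reduces exactly to
    one-way ANOVA: fitted category means equal sample means.

    The optimiser runs from three fixed starting points (pooled residual SD,
    half and double it); the best likelihood wins, making the fit
    deterministic for given data.
    """
    y = np.asarray(response, dtype=float)
    n = len(y)
    if not np.all(np.isfinite(y)):
        raise ValueError("response contains non-finite values")

    if category is not None:
        cats = sorted(set(category))
        if len(cats) < 2:
            raise ValueError("need at least 2 categories")
        counts = pd.Series(list(category)).value_counts()
        if (counts < 3).any():
            small = sorted(counts[counts < 3].index)
            raise ValueError(f"categories with fewer than 3 species: {small}")
        cat_idx = np.array([cats.index(c) for c in category])
        X = np.zeros((n, len(cats)))
        X[np.arange(n), cat_idx] = 1.0  # cell-means coding
    else:
        cats = []
        cat_idx = np.zeros(n, dtype=int)
        X = np.ones((n, 1))
        heteroscedastic = False

    if covariate is not None:
        cov = np.asarray(covariate, dtype=float)
        X = np.hstack([X, (cov - cov.mean())[:, None]])

    if family is not None:
        fams = pd.Series(list(family))
        use_re = fams.nunique() > 1
        fam_blocks = [np.flatnonzero(fams.values == f) for f in fams.unique()] if use_re else [np.arange(n)]
    else:
        use_re = False
        fam_blocks = [np.arange(n)]

    n_cats = len(cats) if cats else 1
    het = bool(heteroscedastic and cats)

    # closed form when no random effect and a single residual variance
    if not use_re and not het:
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        s2 = float(resid @ resid) / n
        ll = -0.5 * n * (np.log(2.0 * np.pi * s2) + 1.0)
        theta_hat = np.array([0.5 * np.log(s2)])
        _, beta, XtViX = _neg_profile_loglik(theta_hat, y, X, fam_blocks, cat_idx, 1, False, False)
        return _pack_fit(response_name, cats, beta, XtViX, theta_hat, ll, n, het, use_re,
                         covariate is not None, cat_idx, s2=s2)

    n_var = (n_cats if het else 1) + (1 if use_re else 0)
    s0 = max(float(np.std(y)), 1e-6)
    starts = []
    for scale in (1.0, 0.5, 2.0):
        th = np.full(n_var, np.log(s0 * scale))
        if use_re:
            th[-1] = np.log(s0 * scale * 0.5)
        starts.append(th)

    best = None
    for th0 in starts:
        res = optimize.minimize(
            lambda th: _neg_profile_loglik(th, y, X, fam_blocks, cat_idx, n_cats, het, use_re)[0],
            th0,
            method="Nelder-Mead",
            options={"maxiter": max_iter * n_var, "xatol": 1e-8, "fatol": 1e-10},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun) or best.fun >= 1e12:
        raise RuntimeError(
            f"category model did not converge (best objective {best.fun if best else 'n/a'})"
        )
    theta_hat = best.x
    nll, beta, XtViX = _neg_profile_loglik(theta_hat, y, X, fam_blocks, cat_idx, n_cats, het, use_re)
    return _pack_fit(response_name, cats, beta, XtViX, theta_hat, -nll, n, het, use_re,
                     covariate is not None, cat_idx)


def _pack_fit(name, cats, beta, XtViX, theta, ll, n, het, use_re, has_cov, cat_idx, s2=None):
    n_cats = len(cats) if cats else 1
    if het:
        sds = {c: float(np.exp(theta[i])) for i, c in enumerate(cats)}
    else:
        s = float(np.sqrt(s2)) if s2 is not None else float(np.exp(theta[0]))
        sds = {c: s for c in (cats or ["all"])}
    fam_sd = float(np.exp(theta[-1])) if use_re else 0.0
    if cats:
        means = {c: float(beta[i]) for i, c in enumerate(cats)}
    else:
        means = {"all": float(beta[0])}
    slope = float(beta[-1]) if has_cov else None
    n_mean = len(beta)
    n_var = (n_cats if het else 1) + (1 if use_re else 0)
    return CategoryFit(
        response_name=name,
        categories=list(cats),
        category_means=means,
        category_sds=sds,
        family_re_sd=fam_sd,
        covariate_slope=slope,
        loglik=float(ll),
        n=n,
        n_params=n_mean + n_var,
        heteroscedastic=het,
        beta=np.asarray(beta, dtype=float),
        beta_cov=np.linalg.inv(XtViX),
    )


def lrt(full: CategoryFit, null: CategoryFit) -> LRTResult:
    """Likelihood-ratio test between a full model and a nested null.

    chi^2 = 2(loglik_full - loglik_null), clamped at zero; degrees of freedom
    are the difference in parameter count (mean and variance parameters).
    """
    if full.n != null.n:
        raise ValueError("models were fitted to different data (n differs)")
    df = full.n_params - null.n_params
    if df < 1:
        raise ValueError("null model is not nested in the full model (df < 1)")
    chi = max(0.0, 2.0 * (full.loglik - null.loglik))
    return LRTResult(chi_sq=chi, df=df, p_value=float(sps.chi2.sf(chi, df)))


def pairwise_contrasts(fit: CategoryFit) -> pd.DataFrame:
    """Wald z-tests for all pairwise category mean differences (no
    multiplicity correction)."""
    if not fit.categories:
        raise ValueError("null model has no category contrasts")
    rows = []
    for i, a in enumerate(fit.categories):
        for j, b in enumerate(fit.categories):
            if j <= i:
                continue
            diff = fit.beta[i] - fit.beta[j]
            var = fit.beta_cov[i, i] + fit.beta_cov[j, j] - 2.0 * fit.beta_cov[i, j]
            z = diff / np.sqrt(var)
            rows.append(
                {
                    "category_a": a,
                    "category_b": b,
                    "difference": diff,
                    "se": float(np.sqrt(var)),
                    "z": float(z),
                    "p_value": float(2.0 * sps.norm.sf(abs(z))),
                }
            )
    return pd.DataFrame(rows)


def ratio_response(
    stats,
    exclude_intra_above_nn: bool = True,
    zero_floor: bool = False,
) -> pd.Series:
    """Per-species log10(max intraspecific distance / NN distance).

    Species with undefined or zero NN distance are always excluded.  Species
    whose maximum intraspecific distance exceeds the NN distance are excluded
    by default (they sit on the wrong side of the barcode gap and dominate
    the ratio).  Zero intraspecific distances make the log undefined and are
    excluded, unless ``zero_floor`` replaces them by half the smallest
    nonzero max_intra.  Exclusion counts are logged.
    """
    rows = [(s.species, s.max_intra, s.nn_dist) for s in stats]
    n_zero_nn = sum(1 for _, _, nn in rows if not np.isfinite(nn) or nn == 0.0)
    rows = [r for r in rows if np.isfinite(r[2]) and r[2] > 0.0]
    n_above = 0
    if exclude_intra_above_nn:
        n_above = sum(1 for _, mi, nn in rows if mi > nn)
        rows = [r for r in rows if r[1] <= r[2]]
    zeros = [r for r in rows if r[1] == 0.0]
    if zero_floor and zeros:
        nonzero = [r[1] for r in rows if r[1] > 0.0]
        floor = 0.5 * min(nonzero) if nonzero else np.nan
        rows = [(sp, (mi if mi > 0 else floor), nn) for sp, mi, nn in rows]
    else:
        rows = [r for r in rows if r[1] > 0.0]
    logger.info(
        "ratio response: excluded %d species with zero/undefined NN, %d with "
        "max_intra > NN, %d with zero max_intra",
        n_zero_nn, n_above, 0 if zero_floor else len(zeros),
    )
    return pd.Series(
        [np.log10(mi / nn) for _, mi, nn in rows],
        index=[sp for sp, _, _ in rows],
        name="log10_intra_over_nn",
    )
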