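"""Cohort statistics for longitudinal aneurysm biomarkers.

Implements the statistical layer applied to per-mouse records of geometry,
hemodynamic and microstructural metrics with right-censored lifespans:

* group-wise Spearman rank correlations (exact permutation p for small
  groups, t-approximation otherwise),
* normalization of mutant (MU) metric values to age- and sex-matched
  wild-type (WT) cell means,
* a Gaussian Tobit regression of lifespan on a normalized metric, where
  mice alive at the study endpoint contribute upper-tail survival
  probabilities to the likelihood, summarized by a McFadden pseudo-R^2,
* a linear-mixed-model three-way ANOVA (age x sex x genotype fixed
  effects, random intercept per mouse) with estimated-marginal-mean
  pairwise contrasts.  The mixed-model solve is delegated to statsmodels;
  this module owns the term tests and contrast construction.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import minimize

import statsmodels.api as sm
from patsy import build_design_matrices, dmatrices
from statsmodels.tools import numdiff

__all__ = [
    "spearman_by_group",
    "normalize_to_wt",
    "tobit_fit",
    "TobitResult",
    "lmm_anova",
    "LMMAnovaResult",
    "last_measurement_per_mouse",
]

METRIC_COLUMNS = (
    "max_diameter_mm",
    "aer",
    "mean_osi",
    "mean_tawss",
    "mean_ecap",
    "mean_rrt",
    "von_mises_kPa",
    "porosity_pct",
)


# ---------------------------------------------------------------- Spearman


def _exact_spearman_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p for Spearman rho (average-rank ties)."""
    xr = sps.rankdata(x)
    yr = sps.rankdata(y)
    xc = xr - xr.mean()
    yc = yr - yr.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    perms = np.array(list(itertools.permutations(yc)))
    rhos = (perms @ xc) / denom
    return float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))


def spearman_by_group(
    table: pd.DataFrame,
    x_col: str,
    y_col: str,
    by=("sex", "genotype"),
    min_n: int = 3,
    exact_below: int = 10,
) -> pd.DataFrame:
    """Spearman rho and two-sided p per group.

    Groups with fewer than ``min_n`` complete pairs, or with zero variance
    in either variable, are flagged and carry NaN statistics.  Exact
    permutation p-values are computed for groups below ``exact_below``
    observations (small-group regime), the t-approximation otherwise.
    """
    rows = []
    for keys, grp in table.groupby(list(by), observed=True):
        if not isinstance(keys, tuple):
            keys = (keys,)
        sub = grp[[x_col, y_col]].dropna()
        x = sub[x_col].to_numpy(dtype=float)
        y = sub[y_col].to_numpy(dtype=float)
        n = len(sub)
        rec = dict(zip(by, keys))
        rec["n"] = n
        if n < min_n:
            rec.update(r=np.nan, p=np.nan, flag="too_few")
        elif np.ptp(x) == 0 or np.ptp(y) == 0:
            rec.update(r=np.nan, p=np.nan, flag="zero_variance")
        else:
            res = sps.spearmanr(x, y)
            rho = float(res.statistic)
            if n < exact_below:
                p = _exact_spearman_p(x, y, rho)
            else:
                p = float(res.pvalue)
            rec.update(r=rho, p=p, flag="ok")
        rows.append(rec)
    return pd.DataFrame(rows)


# ----------------------------------------------------- WT normalization


def normalize_to_wt(
    table: pd.DataFrame,
    metrics=None,
    suffix: str = "_wtnorm",
) -> pd.DataFrame:
    """Divide metric values by the age- and sex-matched WT cell mean.

    Every row (MU and WT alike) in an (age_mo, sex) cell is divided by the
    mean of the WT rows of that cell, so WT cell means normalize to exactly
    1.  Returns a copy with ``<metric><suffix>`` columns appended; a cell
    without any WT row raises, naming the cell.
    """
    if metrics is None:
        metrics = [c for c in METRIC_COLUMNS if c in table.columns]
    out = table.copy()
    for metric in metrics:
        wt = table[table["genotype"] == "WT"]
        wt_means = wt.groupby(["age_mo", "sex"], observed=True)[metric].mean()
        norm = np.full(len(table), np.nan)
        for (age, sex), idx in table.groupby(["age_mo", "sex"], observed=True).groups.items():
            if (age, sex) not in wt_means.index or np.isnan(wt_means.loc[(age, sex)]):
                raise ValueError(
                    f"no WT rows for cell (age_mo={age}, sex={sex}) "
                    f"needed to normalize {metric!r}"
                )
            norm[table.index.get_indexer(idx)] = (
                table.loc[idx, metric].to_numpy() / wt_means.loc[(age, sex)]
            )
        out[metric + suffix] = norm
    return out


def last_measurement_per_mouse(table: pd.DataFrame) -> pd.DataFrame:
    """One row per mouse: the measurement at the last available age.

    This is the documented selection rule feeding lifespan regressions when
    mice carry repeated measurements.
    """
    idx = table.groupby("mouse_id", observed=True)["age_mo"].idxmax()
    return table.loc[idx].reset_index(drop=True)


# ---------------------------------------------------------------- Tobit


@dataclass
class TobitResult:
    """Right-censored Gaussian regression summary."""

    slope: float
    intercept: float
    scale: float
    pseudo_r2: float
    n_censored: int
    n_observed: int
    se_slope: float
    se_intercept: float
    loglik: float
    converged: bool

    def slope_ci(self, level: float = 0.95) -> tuple[float, float]:
        z = sps.norm.ppf(0.5 + level / 2)
        return (self.slope - z * self.se_slope, self.slope + z * self.se_slope)


def _tobit_negll(theta, x, y, cens):
    b0, b1, log_s = theta
    s = np.exp(log_s)
    z = (y - b0 - b1 * x) / s
    ll = np.where(cens, sps.norm.logsf(z), sps.norm.logpdf(z) - log_s)
    return -float(np.sum(ll))


def tobit_fit(
    lifespan_days,
    censored,
    x,
    pseudo_r2_kind: str = "mcfadden",
) -> TobitResult:
    """Maximum-likelihood Tobit regression of lifespan on one predictor.

    Uncensored rows contribute the Gaussian density; right-censored rows
    (animals alive at the endpoint, recorded at the censoring bound)
    contribute the upper-tail probability.  Goodness of fit is summarized
    by McFadden's pseudo-R^2, 1 - ll_model/ll_null (Cox-Snell available via
    ``pseudo_r2_kind="cox_snell"``).
    """
    y = np.asarray(lifespan_days, dtype=float)
    cens = np.asarray(censored, dtype=bool)
    xv = np.asarray(x, dtype=float)
    if not (len(y) == len(cens) == len(xv)):
        raise ValueError("inputs must have equal length")
    if len(y) < 5:
        raise ValueError("need at least 5 rows")
    if np.all(cens):
        raise ValueError("all rows censored: likelihood unidentifiable")

    xm = float(np.mean(xv))
    xc = xv - xm  # centered predictor for conditioning

    def fit_model(with_slope: bool):
        # OLS start (exact MLE optimum when nothing is censored)
        if with_slope and np.ptp(xc) > 0:
            b1_0 = float(np.cov(xc, y, bias=True)[0, 1] / np.var(xc))
        else:
            b1_0 = 0.0
        b0_0 = float(np.mean(y) - b1_0 * np.mean(xc))
        resid = y - b0_0 - b1_0 * xc
        s0 = max(float(np.std(resid)), 1e-6)
        theta0 = np.array([b0_0, b1_0, np.log(s0)])
        if with_slope:
            fun = lambda th: _tobit_negll(th, xc, y, cens)
        else:
            fun = lambda th: _tobit_negll(np.array([th[0], 0.0, th[1]]), xc, y, cens)
            theta0 = theta0[[0, 2]]
        res = minimize(fun, theta0, method="BFGS", options={"gtol": 1e-10, "maxiter": 500})
        if not res.success:
            # flat likelihoods (heavy censoring, weak predictors) can defeat
            # BFGS line searches; polish with a derivative-free simplex
            res2 = minimize(
                fun, res.x, method="Nelder-Mead",
                options={"xatol": 1e-10, "fatol": 1e-12, "maxfev": 4000},
            )
            if res2.fun <= res.fun:
                res = res2
        return res, fun

    if np.ptp(xc) == 0:
        # degenerate predictor: slope is unidentifiable, defined as 0
        res0, _ = fit_model(False)
        b0, log_s = res0.x
        return TobitResult(
            slope=0.0, intercept=float(b0), scale=float(np.exp(log_s)),
            pseudo_r2=0.0, n_censored=int(cens.sum()), n_observed=int((~cens).sum()),
            se_slope=np.nan, se_intercept=np.nan,
            loglik=-float(res0.fun), converged=bool(res0.success),
        )

    res, fun = fit_model(True)
    b0c, b1, log_s = res.x
    ll_model = -float(res.fun)
    res_null, _ = fit_model(False)
    ll_null = -float(res_null.fun)

    n = len(y)
    if pseudo_r2_kind == "mcfadden":
        pr2 = 1.0 - ll_model / ll_null if ll_null != 0 else 0.0
    elif pseudo_r2_kind == "cox_snell":
        pr2 = 1.0 - np.exp(2.0 * (ll_null - ll_model) / n)
    else:
        raise ValueError("pseudo_r2_kind must be 'mcfadden' or 'cox_snell'")
    pr2 = float(np.clip(pr2, 0.0, 1.0))

    hess = numdiff.approx_hess(res.x, fun)
    try:
        cov = np.linalg.inv(hess)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    except np.linalg.LinAlgError:
        se = np.full(3, np.nan)
    # un-center the intercept: y = b0c + b1*(x - xm)  ->  intercept = b0c - b1*xm
    intercept = float(b0c - b1 * xm)
    se_intercept = float(np.sqrt(max(se[0] ** 2 + (xm * se[1]) ** 2, 0.0)))
    return TobitResult(
        slope=float(b1), intercept=intercept, scale=float(np.exp(log_s)),
        pseudo_r2=pr2, n_censored=int(cens.sum()), n_observed=int((~cens).sum()),
        se_slope=float(se[1]), se_intercept=se_intercept,
        loglik=ll_model, converged=bool(res.success),
    )


# ------------------------------------------------------------ LMM / ANOVA


def _independent_columns(X: np.ndarray, tol: float = 1e-9) -> list[int]:
    """Indices of a maximal linearly independent column subset, in order."""
    kept: list[int] = []
    basis = np.empty((X.shape[0], 0))
    for j in range(X.shape[1]):
        col = X[:, j]
        if basis.shape[1]:
            resid = col - basis @ np.linalg.lstsq(basis, col, rcond=None)[0]
        else:
            resid = col
        if np.linalg.norm(resid) > tol * max(np.linalg.norm(col), 1.0):
            kept.append(j)
            basis = np.column_stack([basis, col])
    return kept


@dataclass
class LMMAnovaResult:
    anova: pd.DataFrame
    contrasts: pd.DataFrame
    re_variance: float
    converged: bool


def lmm_anova(
    table: pd.DataFrame,
    response: str,
    factors=("age_mo", "sex", "genotype"),
    group: str = "mouse_id",
) -> LMMAnovaResult:
    """Three-way ANOVA on a mixed model with a random intercept per mouse.

    Fixed effects are all main effects and interactions of the (categorical)
    factors under sum-to-zero coding; Wald F statistics are formed per term
    from the REML fixed-effect covariance with residual denominator degrees
    of freedom.  Rank-deficient designs (empty cells) are handled as lme4
    does, by dropping collinear design columns in order; affected terms lose
    the corresponding numerator degrees of freedom.  Pairwise
    estimated-marginal-mean contrasts are reported for genotype within each
    sex x age cell and sex within each genotype x age cell; contrasts
    touching an empty cell are flagged unestimable.
    """
    data = table.copy()
    for f in factors:
        data[f] = data[f].astype(str)
    data = data.dropna(subset=[response]).reset_index(drop=True)

    terms_expr = " * ".join(f"C({f}, Sum)" for f in factors)
    formula = f"{response} ~ {terms_expr}"
    y_mat, x_mat = dmatrices(formula, data, return_type="dataframe")
    design_info = x_mat.design_info
    X = np.asarray(x_mat)
    kept = _independent_columns(X)
    X_kept = X[:, kept]

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(np.asarray(y_mat).ravel(), X_kept, groups=data[group])
        fit = model.fit(reml=True)

    k_fe = X_kept.shape[1]
    beta = np.asarray(fit.fe_params)
    cov = np.asarray(fit.cov_params())[:k_fe, :k_fe]
    n_obs = len(data)
    df_den = n_obs - k_fe

    full_to_kept = {c: i for i, c in enumerate(kept)}
    rows = []
    for term, sl in design_info.term_name_slices.items():
        if term == "Intercept":
            continue
        idx = [full_to_kept[c] for c in range(X.shape[1])[sl] if c in full_to_kept]
        q = len(idx)
        if q == 0:
            rows.append({"term": term, "F": np.nan, "df_num": 0, "df_den": df_den, "p": np.nan})
            continue
        lb = beta[idx]
        vs = cov[np.ix_(idx, idx)]
        fstat = float(lb @ np.linalg.solve(vs, lb) / q)
        p = float(sps.f.sf(fstat, q, df_den))
        rows.append({"term": term, "F": fstat, "df_num": q, "df_den": df_den, "p": p})
    anova = pd.DataFrame(rows)

    lv = {f: sorted(data[f].unique()) for f in factors}
    present = set(map(tuple, data[list(factors)].itertuples(index=False, name=None)))

    def emm_row(cell: dict) -> np.ndarray:
        (m,) = build_design_matrices([design_info], pd.DataFrame([cell]))
        # dropped (collinear) columns are redundant for non-empty cells
        return np.asarray(m)[0][kept]

    def cell_tuple(cell: dict) -> tuple:
        return tuple(cell[f] for f in factors)

    contrast_rows = []

    def add_contrast(kind, fixed_cells, vary_factor, lv_hi, lv_lo):
        cell_hi = dict(fixed_cells, **{vary_factor: lv_hi})
        cell_lo = dict(fixed_cells, **{vary_factor: lv_lo})
        rec = dict(fixed_cells)
        rec["contrast"] = f"{kind}: {lv_hi} - {lv_lo}"
        if cell_tuple(cell_hi) not in present or cell_tuple(cell_lo) not in present:
            rec.update(estimate=np.nan, se=np.nan, z=np.nan, p=np.nan, flag="unestimable")
        else:
            L = emm_row(cell_hi) - emm_row(cell_lo)
            est = float(L @ beta)
            se = float(np.sqrt(L @ cov @ L))
            z = est / se if se > 0 else np.nan
            rec.update(
                estimate=est, se=se, z=z,
                p=float(2 * sps.norm.sf(abs(z))) if np.isfinite(z) else np.nan,
                flag="ok",
            )
        contrast_rows.append(rec)

    age_f, sex_f, geno_f = factors
    if len(lv[geno_f]) == 2:
        g_hi, g_lo = ("MU", "WT") if set(lv[geno_f]) == {"MU", "WT"} else tuple(lv[geno_f])
        for a in lv[age_f]:
            for s in lv[sex_f]:
                add_contrast("genotype", {age_f: a, sex_f: s}, geno_f, g_hi, g_lo)
    if len(lv[sex_f]) == 2:
        s_hi, s_lo = tuple(lv[sex_f])
        for a in lv[age_f]:
            for g in lv[geno_f]:
                add_contrast("sex", {age_f: a, geno_f: g}, sex_f, s_hi, s_lo)

    re_var = float(np.asarray(fit.cov_re).ravel()[0]) if fit.cov_re.size else 0.0
    return LMMAnovaResult(
        anova=anova,
        contrasts=pd.DataFrame(contrast_rows),
        re_variance=re_var,
        converged=bool(fit.converged),
    )
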