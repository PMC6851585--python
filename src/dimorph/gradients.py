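"""Among-population gradients in percent sexual dimorphism.

Explains population-level %SD with three predictor categories — demographic
(population size, density, sex ratio), geographic (longitude, latitude,
elevation) and bioclimatic (reduced set of WorldClim variables) — using
forward nested-model selection with F-tests, Shapiro-Wilk residual checks,
sex-specific trait-mean regressions, and a funnel-style heterogeneity
summary against population density.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.decomposition import PCA

__all__ = [
    "BioclimReduction",
    "GradientModel",
    "reduce_bioclim",
    "fit_gradient_models",
    "sex_specific_slopes",
    "funnel_summary",
    "CATEGORY_PREDICTORS",
]

#: documented, fixed entry order per predictor category
CATEGORY_PREDICTORS = {
    "demographic": ["pop_size", "density", "sex_ratio"],
    "geographic": ["lon", "lat", "elev"],
    "bioclimatic": ["bio1", "bio7", "bio12"],  # mean T, T range, precipitation
}

#: default independence threshold on |Spearman r| for bioclim reduction
BIOCLIM_RS_THRESHOLD = 0.8


@dataclass
class BioclimReduction:
    """Reduced bioclim predictor set with its PC congruence diagnostic."""

    selected: list
    corr_matrix: pd.DataFrame
    pc_check: float  # mean |corr| of population scores on first two PCs
    excluded_constant: list = field(default_factory=list)


@dataclass
class GradientModel:
    """A selected multiple regression of %SD on one predictor category."""

    response: tuple  # (trait, stage)
    category: str
    predictors: list  # selected, in entry order
    coefficients: dict  # name -> estimate (includes "Intercept")
    r_squared: float
    p_value: float  # overall F-test vs intercept-only (nan if none selected)
    shapiro_p: float
    n: int
    path: list = field(default_factory=list)  # (predictor, F, p, kept)

    def equation(self) -> str:
        terms = [f"{self.coefficients['Intercept']:.3f}"]
        for name in self.predictors:
            b = self.coefficients[name]
            terms.append(f"{'+' if b >= 0 else '-'} {abs(b):.3f}*{name}")
        return " ".join(terms)


# ---------------------------------------------------------------------------
def reduce_bioclim(
    pops: pd.DataFrame,
    threshold: float = BIOCLIM_RS_THRESHOLD,
    priority: list | None = None,
    max_k: int = 3,
) -> BioclimReduction:
    """Greedy reduction of the 19 bioclim variables to a mutually
    near-independent subset.

    Candidates are visited in ``priority`` order (default: annual mean
    temperature, annual temperature range, annual precipitation first, the
    rest in numeric order); a variable is kept when its |Spearman r| with
    every already-kept variable is below ``threshold``, until ``max_k``
    variables are retained. The PC check compares population scores on the
    first two principal components of the selected set against the full set.
    """
    bio_cols = [c for c in pops.columns if c.startswith("bio")]
    if len(pops) < 3:
        raise ValueError("need at least 3 populations")
    X = pops[bio_cols].astype(float)
    constant = [c for c in bio_cols if X[c].nunique() <= 1]
    if constant:
        warnings.warn(f"constant bioclim variables excluded: {constant}")
    usable = [c for c in bio_cols if c not in constant]
    corr = X[usable].corr(method="spearman")

    order = [v for v in (priority or CATEGORY_PREDICTORS["bioclimatic"])
             if v in usable]
    order += sorted((v for v in usable if v not in order),
                    key=lambda s: int(s[3:]))
    selected: list = []
    for v in order:
        if len(selected) >= max_k:
            break
        if all(abs(corr.loc[v, s]) < threshold for s in selected):
            selected.append(v)

    def scores(cols):
        Z = (X[cols] - X[cols].mean()) / X[cols].std().replace(0, 1)
        k = min(2, len(cols), len(pops) - 1)
        return PCA(n_components=k).fit_transform(Z.to_numpy())

    s_full, s_sel = scores(usable), scores(selected)
    ncomp = min(s_full.shape[1], s_sel.shape[1])
    congr = [
        abs(np.corrcoef(s_full[:, i], s_sel[:, i])[0, 1]) for i in range(ncomp)
    ]
    return BioclimReduction(
        selected=selected, corr_matrix=corr,
        pc_check=float(np.mean(congr)) if congr else np.nan,
        excluded_constant=constant,
    )


# ---------------------------------------------------------------------------
def fit_gradient_models(
    pct_sd_by_pop: pd.Series,
    predictors: pd.DataFrame,
    category: str,
    order: list | None = None,
    alpha: float = 0.05,
    response: tuple = ("", ""),
) -> GradientModel:
    """Forward nested-model selection of %SD on one predictor category.

    Predictors are added sequentially in the documented order; each addition
    is kept only when the F-test against the current model is significant at
    ``alpha``, so the accepted path has non-decreasing R^2 and every kept
    step a significant improvement. The winning model reports coefficients,
    R^2, overall p (F vs intercept-only) and the Shapiro-Wilk residual p.
    """
    names = order or CATEGORY_PREDICTORS.get(category)
    if names is None:
        raise ValueError(f"unknown category {category!r} and no order given")
    names = [n for n in names if n in predictors.columns]
    common = pct_sd_by_pop.dropna().index.intersection(predictors.index)
    y = pct_sd_by_pop.loc[common].astype(float)
    X = predictors.loc[common, names].astype(float)
    n = len(y)
    if n < 8:
        raise ValueError(f"need >=8 populations with defined %SD, got {n}")
    if len(names) >= n:
        raise ValueError("more candidate predictors than populations")

    kept: list = []
    path = []
    current = sm.OLS(y, np.ones((n, 1))).fit()
    for name in names:
        cols = kept + [name]
        cand = sm.OLS(y, sm.add_constant(X[cols])).fit()
        # F-test for the added regressor against the current model
        df_num = 1
        df_den = n - len(cols) - 1
        rss0, rss1 = current.ssr, cand.ssr
        if df_den <= 0 or rss1 <= 0:
            f, p = np.inf, 0.0
        else:
            f = (rss0 - rss1) / df_num / (rss1 / df_den)
            p = float(stats.f.sf(f, df_num, df_den))
        keep = p < alpha
        path.append((name, float(f), p, keep))
        if keep:
            kept.append(name)
            current = cand

    if kept:
        final = sm.OLS(y, sm.add_constant(X[kept])).fit()
        coefs = {"Intercept": float(final.params.iloc[0])}
        coefs.update({nm: float(b) for nm, b in zip(kept, final.params.iloc[1:])})
        r2 = float(final.rsquared)
        overall_p = float(final.f_pvalue)
        resid = final.resid
    else:
        coefs = {"Intercept": float(y.mean())}
        r2, overall_p = 0.0, np.nan
        resid = y - y.mean()
    shapiro_p = float(stats.shapiro(resid)[1]) if resid.nunique() > 2 else np.nan
    return GradientModel(
        response=response, category=category, predictors=kept,
        coefficients=coefs, r_squared=r2, p_value=overall_p,
        shapiro_p=shapiro_p, n=n, path=path,
    )


# ---------------------------------------------------------------------------
def sex_specific_slopes(
    means: pd.DataFrame,
    predictors: pd.DataFrame,
    variables: list,
) -> pd.DataFrame:
    """Separate per-sex regressions of population trait means on each
    bioclim variable; reports the female-minus-male slope difference.

    ``means`` has populations as index and columns "F" and "M" (predicted
    population means per sex). Returns one row per variable with slopes,
    standard errors, p-values and the slope difference with its Wald CI.
    """
    common = means.dropna().index.intersection(predictors.index)
    if len(common) < 4:
        raise ValueError(f"need >=4 populations, got {len(common)}")
    rows = []
    for var in variables:
        x = sm.add_constant(predictors.loc[common, var].astype(float))
        fits = {}
        for sex in ("F", "M"):
            fits[sex] = sm.OLS(means.loc[common, sex].astype(float), x).fit()
        bF, bM = (float(fits[s].params.iloc[1]) for s in "FM")
        sF, sM = (float(fits[s].bse.iloc[1]) for s in "FM")
        diff = bF - bM
        se_diff = float(np.hypot(sF, sM))
        z = diff / se_diff if se_diff > 0 else np.nan
        rows.append({
            "variable": var,
            "slope_F": bF, "se_F": sF, "p_F": float(fits["F"].pvalues.iloc[1]),
            "slope_M": bM, "se_M": sM, "p_M": float(fits["M"].pvalues.iloc[1]),
            "slope_diff": diff, "se_diff": se_diff,
            "diff_low": diff - 1.959963984540054 * se_diff,
            "diff_high": diff + 1.959963984540054 * se_diff,
            "p_diff": float(2 * stats.norm.sf(abs(z))) if np.isfinite(z) else np.nan,
            "n": int(len(common)),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
def funnel_summary(
    pct_sd_by_pop: pd.Series,
    density_by_pop: pd.Series,
    n_perm: int = 1000,
    seed: int = 0,
) -> dict:
    """Density-related location and heterogeneity trends in %SD.

    Reports (i) the Spearman correlation between density and %SD, and
    (ii) a funnel-style heterogeneity trend: the Spearman correlation
    between density and |%SD - median %SD| with a permutation p-value
    (populations shuffled). A negative heterogeneity trend means more
    variable dimorphism in sparser populations.
    """
    common = pct_sd_by_pop.dropna().index.intersection(density_by_pop.dropna().index)
    if len(common) < 8:
        raise ValueError(f"need >=8 populations, got {len(common)}")
    y = pct_sd_by_pop.loc[common].to_numpy(dtype=float)
    d = density_by_pop.loc[common].to_numpy(dtype=float)
    out = {"n": int(len(common))}
    if np.ptp(d) == 0:
        warnings.warn("constant density: trends undefined")
        out.update(location_rs=np.nan, location_p=np.nan,
                   heterogeneity_rs=np.nan, heterogeneity_p=np.nan)
        return out
    loc_rs, loc_p = stats.spearmanr(d, y)
    dev = np.abs(y - np.median(y))
    if np.ptp(dev) == 0:
        het_rs = 0.0
        het_p = 1.0
    else:
        het_rs = float(stats.spearmanr(d, dev)[0])
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(dev)
            if abs(stats.spearmanr(d, perm)[0]) >= abs(het_rs) - 1e-12:
                count += 1
        het_p = (count + 1) / (n_perm + 1)
    out.update(
        location_rs=float(loc_rs), location_p=float(loc_p),
        heterogeneity_rs=float(het_rs), heterogeneity_p=float(het_p),
    )
    return out
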