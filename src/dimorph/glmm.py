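"""Generalized linear mixed models with independent random intercepts.

The estimation scheme follows the standard mixed-model toolchain for this
kind of design: Gaussian responses are fitted by (restricted) maximum
likelihood with the residual variance profiled out, non-Gaussian responses
(Poisson, Bernoulli/binomial, Gamma) by maximum likelihood under the Laplace
approximation, with the joint mode of fixed effects and random effects found
by penalized iteratively reweighted least squares. Random effects are
independent intercepts (e.g. maternal family within population, population,
individual/observation level), which keeps every linear solve sparse.

With all random-effect standard deviations fixed at zero the fit collapses
exactly to the corresponding generalized linear model — a property the test
suite checks against an independent GLM implementation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, sparse
from scipy.sparse.linalg import splu
from scipy.stats import chi2 as chi2_dist
from scipy.stats import norm as norm_dist
import statsmodels.api as sm

from .design import DesignInfo, build_design, prediction_row

__all__ = ["MixedGLM", "MixedGLMResults", "PredictedMean", "type2_anova"]

_FAMILIES = {
    "gaussian": lambda: sm.families.Gaussian(),
    "poisson": lambda: sm.families.Poisson(),
    "binomial": lambda: sm.families.Binomial(),
    "gamma": lambda: sm.families.Gamma(link=sm.families.links.Log()),
}

_MIN_LOG_SD = np.log(1e-6)


class SingleSexError(ValueError):
    """Raised when a contrast is inestimable because a factor has one level."""


@dataclass
class PredictedMean:
    """A model-based (marginal) group mean on the response scale."""

    group: dict
    estimate: float
    ci_low: float
    ci_high: float
    link_estimate: float
    link_se: float

    def as_dict(self) -> dict:
        d = dict(self.group)
        d.update(
            estimate=self.estimate,
            ci_low=self.ci_low,
            ci_high=self.ci_high,
            link_estimate=self.link_estimate,
            link_se=self.link_se,
        )
        return d


def _sparse_logdet(M: sparse.spmatrix) -> float:
    """log det of a symmetric positive-definite sparse matrix via LU."""
    lu = splu(M.tocsc())
    return float(np.sum(np.log(np.abs(lu.U.diagonal()))))


class MixedGLM:
    """Mixed model with fixed effects and independent random intercepts.

    Parameters
    ----------
    endog : array, shape (n,)
    exog : array, shape (n, p)
        Fixed-effect design matrix; must include the intercept column.
    vc : dict, optional
        Mapping random-term name -> integer group codes of shape (n,).
        Each term contributes one variance component (random intercepts).
    family : {"gaussian", "poisson", "binomial", "gamma"}
    design_info : DesignInfo, optional
        Column/term bookkeeping; required for predicted means and type-2
        ANOVA.
    """

    def __init__(self, endog, exog, vc=None, family="gaussian", design_info=None):
        self.endog = np.asarray(endog, dtype=float)
        self.exog = np.asarray(exog, dtype=float)
        if self.exog.ndim != 2 or self.exog.shape[0] != self.endog.shape[0]:
            raise ValueError("exog must be (n, p) aligned with endog")
        if family not in _FAMILIES:
            raise ValueError(f"unknown family {family!r}; choose from {sorted(_FAMILIES)}")
        self.family_name = family
        self.family = _FAMILIES[family]()
        self.design_info = design_info
        self.vc_names: list[str] = []
        self._z_blocks: list[sparse.csr_matrix] = []
        self._z_levels: list[np.ndarray] = []
        n = len(self.endog)
        for name, codes in (vc or {}).items():
            codes = np.asarray(codes)
            levels, inv = np.unique(codes, return_inverse=True)
            if len(levels) < 2:
                warnings.warn(f"random term {name!r} has <2 levels; dropped")
                continue
            Z = sparse.csr_matrix(
                (np.ones(n), (np.arange(n), inv)), shape=(n, len(levels))
            )
            self.vc_names.append(name)
            self._z_blocks.append(Z)
            self._z_levels.append(levels)
        self._Z = sparse.hstack(self._z_blocks).tocsr() if self._z_blocks else None
        self._block_sizes = [Z.shape[1] for Z in self._z_blocks]

    # ------------------------------------------------------------------
    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        response: str,
        terms: list,
        vc_terms: list | None = None,
        family: str = "gaussian",
        categorical: dict | None = None,
    ) -> "MixedGLM":
        """Build the model from a tidy DataFrame.

        ``terms`` follow :func:`dimorph.design.build_design`; ``vc_terms``
        name grouping columns (use e.g. a combined population:family label
        column for nesting).
        """
        for t in terms:
            for v in (t,) if isinstance(t, str) else t:
                s = data[v]
                if not pd.api.types.is_numeric_dtype(s) and s.nunique() < 2:
                    raise SingleSexError(
                        f"factor {v!r} has a single level ({s.iloc[0]!r}); "
                        "its contrast is inestimable"
                    )
        X, info = build_design(data, terms, categorical=categorical)
        vc = {name: pd.factorize(data[name])[0] for name in (vc_terms or [])}
        return cls(data[response].to_numpy(dtype=float), X, vc=vc, family=family,
                   design_info=info)

    # ------------------------------------------------------------------
    @property
    def n_vc(self) -> int:
        return len(self.vc_names)

    def _expand_sds(self, sds: np.ndarray) -> np.ndarray:
        """Per-term SDs -> per-random-level SDs (length q)."""
        return np.repeat(sds, self._block_sizes)

    # -------------------------- Gaussian path --------------------------
    def _gaussian_profile(self, rel_sd: np.ndarray, reml: bool):
        """Profiled deviance for Gaussian; rel_sd are SDs relative to sigma_e."""
        y, X = self.endog, self.exog
        n, p = X.shape
        if self._Z is None or np.all(rel_sd <= 1e-10):
            beta, rss, *_ = np.linalg.lstsq(X, y, rcond=None)
            r2 = float(np.sum((y - X @ beta) ** 2))
            dof = n - p if reml else n
            sigma2 = r2 / dof
            m2ll = dof * np.log(2 * np.pi * sigma2) + dof
            if reml:
                sign, ld = np.linalg.slogdet(X.T @ X)
                m2ll += ld
            xtvix = X.T @ X
            return m2ll, beta, np.zeros(0), sigma2, xtvix
        rel_sd = np.maximum(rel_sd, 1e-10)
        lam = self._expand_sds(rel_sd) ** 2  # relative variances, length q
        Z = self._Z
        q = Z.shape[1]
        H = (Z.T @ Z).tocsc() + sparse.diags(1.0 / lam)
        lu = splu(H)
        ZtX = Z.T @ X
        Zty = Z.T @ y
        HinvZtX = lu.solve(np.asarray(ZtX.todense()) if sparse.issparse(ZtX) else ZtX)
        HinvZty = lu.solve(Zty)
        xtvix = X.T @ X - ZtX.T @ HinvZtX
        xtviy = X.T @ y - ZtX.T @ HinvZty
        beta = np.linalg.solve(xtvix, xtviy)
        b = HinvZty - HinvZtX @ beta
        resid = y - X @ beta - Z @ b
        r2 = float(resid @ resid + b @ (b / lam))
        logdet_v = float(np.sum(np.log(np.abs(lu.U.diagonal())))) + float(np.sum(np.log(lam)))
        dof = n - p if reml else n
        sigma2 = r2 / dof
        m2ll = dof * np.log(2 * np.pi * sigma2) + dof + logdet_v
        if reml:
            sign, ld = np.linalg.slogdet(xtvix)
            m2ll += ld
        return m2ll, beta, b, sigma2, xtvix

    # ------------------------- Laplace path ----------------------------
    def _pirls(self, sds: np.ndarray, scale: float, start=None,
               maxiter: int = 200, tol: float = 1e-6):
        """Penalized IRLS joint mode of (beta, b) for given SDs/dispersion."""
        y, X = self.endog, self.exog
        n, p = X.shape
        fam = self.family
        link = fam.link
        use_z = self._Z is not None and np.any(sds > 1e-10)
        if use_z:
            sds = np.maximum(sds, 1e-10)
            d = self._expand_sds(sds) ** 2
            Z = self._Z
            q = Z.shape[1]
            A = sparse.hstack([sparse.csr_matrix(X), Z]).tocsr()
            pen = np.concatenate([np.zeros(p), 1.0 / d])
        else:
            d = np.zeros(0)
            q = 0
            A = sparse.csr_matrix(X)
            pen = np.zeros(p)

        if start is not None and len(start) == p + q:
            coef = start.copy()
        else:
            coef = np.zeros(p + q)
            mu0 = fam.starting_mu(y)
            coef[0] = link(np.mean(mu0))
        eta = A @ coef
        obj_old = np.inf
        converged = False
        W = None
        for _ in range(maxiter):
            mu = link.inverse(eta)
            dmu = link.inverse_deriv(eta)
            var = fam.variance(mu) * scale
            w = dmu**2 / np.maximum(var, 1e-12)
            z = eta + (y - mu) / np.maximum(dmu, 1e-12)
            W = sparse.diags(w)
            M = (A.T @ W @ A).tocsc() + sparse.diags(pen + 1e-12)
            rhs = A.T @ (w * z)
            coef_new = splu(M).solve(rhs)
            eta_new = A @ coef_new
            mu_new = link.inverse(eta_new)
            ll = float(np.sum(fam.loglike_obs(y, mu_new, scale=scale)))
            b = coef_new[p:]
            obj = -2 * ll + float(b @ (b / d)) if q else -2 * ll
            step = 1.0
            while not np.isfinite(obj) and step > 1e-4:
                step /= 2
                coef_new = coef + step * (coef_new - coef)
                eta_new = A @ coef_new
                mu_new = link.inverse(eta_new)
                ll = float(np.sum(fam.loglike_obs(y, mu_new, scale=scale)))
                b = coef_new[p:]
                obj = -2 * ll + float(b @ (b / d)) if q else -2 * ll
            coef, eta = coef_new, eta_new
            if abs(obj_old - obj) < tol * (abs(obj) + 0.1):
                converged = True
                obj_old = obj
                break
            obj_old = obj
        mu = link.inverse(eta)
        dmu = link.inverse_deriv(eta)
        w = dmu**2 / np.maximum(fam.variance(mu) * scale, 1e-12)
        return coef, w, obj_old, converged

    def _laplace_m2ll(self, coef, w, obj, sds):
        p = self.exog.shape[1]
        if self._Z is None or not np.any(sds > 1e-10):
            return obj
        sds = np.maximum(sds, 1e-10)
        d = self._expand_sds(sds) ** 2
        Z = self._Z
        W = sparse.diags(w)
        H = (Z.T @ W @ Z).tocsc() + sparse.diags(1.0 / d)
        return obj + _sparse_logdet(H) + float(np.sum(np.log(d)))

    # ------------------------------ fit --------------------------------
    def fit(
        self,
        reml: bool = True,
        fix_vc: dict | None = None,
        start_sd: float = 0.5,
        maxiter: int = 200,
        tol: float = 1e-6,
    ) -> "MixedGLMResults":
        """Fit the model.

        Parameters
        ----------
        reml : bool
            Restricted maximum likelihood (Gaussian only; ignored otherwise).
        fix_vc : dict, optional
            Random-term name -> fixed standard deviation (0 removes the term
            from estimation; the fit then matches the corresponding GLM).
        start_sd : float
            Starting value for free random-effect SDs.
        """
        fix_vc = dict(fix_vc or {})
        unknown = set(fix_vc) - set(self.vc_names)
        if unknown:
            raise ValueError(f"fix_vc names not in model: {sorted(unknown)}")
        free = [i for i, nm in enumerate(self.vc_names) if nm not in fix_vc]
        fixed_sd = np.array(
            [fix_vc.get(nm, np.nan) for nm in self.vc_names], dtype=float
        )

        if self.family_name == "gaussian":
            return self._fit_gaussian(reml, free, fixed_sd, start_sd, maxiter, tol)
        return self._fit_laplace(free, fixed_sd, start_sd, maxiter, tol)

    def _assemble_sds(self, theta, free, fixed_sd):
        sds = fixed_sd.copy()
        for j, i in enumerate(free):
            sds[i] = np.exp(np.clip(theta[j], _MIN_LOG_SD, 8.0))
        return np.nan_to_num(sds)

    def _fit_gaussian(self, reml, free, fixed_sd, start_sd, maxiter, tol):
        n, p = self.exog.shape

        def objective(theta):
            rel = self._assemble_sds(theta, free, fixed_sd)
            return self._gaussian_profile(rel, reml)[0]

        converged = True
        if free:
            x0 = np.full(len(free), np.log(start_sd))
            res = optimize.minimize(
                objective, x0, method="Nelder-Mead",
                options={"xatol": 1e-5, "fatol": 1e-7, "maxiter": 200 * len(free) + 200},
            )
            theta = res.x
            converged = bool(res.success)
        else:
            theta = np.zeros(0)
        rel = self._assemble_sds(theta, free, fixed_sd)
        m2ll, beta, b, sigma2, xtvix = self._gaussian_profile(rel, reml)
        cov_beta = sigma2 * np.linalg.inv(xtvix)
        vc_sd = {nm: float(rel[i] * np.sqrt(sigma2)) for i, nm in enumerate(self.vc_names)}
        k = p + len(free) + 1
        return MixedGLMResults(
            model=self, params=beta, cov_params_=cov_beta, random_effects=b,
            vc_sd=vc_sd, scale=sigma2, llf=-0.5 * m2ll, df_model=k,
            converged=converged, reml=reml,
        )

    def _fit_laplace(self, free, fixed_sd, start_sd, maxiter, tol):
        n, p = self.exog.shape
        est_scale = self.family_name == "gamma"
        n_extra = 1 if est_scale else 0
        warm = {"coef": None}

        def objective(theta):
            sds = self._assemble_sds(theta[: len(free)], free, fixed_sd)
            scale = float(np.exp(np.clip(theta[len(free)], -10, 10))) if est_scale else 1.0
            coef, w, obj, _ = self._pirls(sds, scale, start=warm["coef"],
                                          maxiter=maxiter, tol=tol)
            warm["coef"] = coef
            return self._laplace_m2ll(coef, w, obj, sds)

        converged = True
        if free or est_scale:
            x0 = np.concatenate([
                np.full(len(free), np.log(start_sd)),
                np.full(n_extra, np.log(0.5)),
            ])
            res = optimize.minimize(
                objective, x0, method="Nelder-Mead",
                options={"xatol": 1e-4, "fatol": 1e-5,
                         "maxiter": 200 * len(x0) + 200},
            )
            theta = res.x
            converged = bool(res.success)
        else:
            theta = np.zeros(0)
        sds = self._assemble_sds(theta[: len(free)], free, fixed_sd)
        scale = float(np.exp(theta[len(free)])) if est_scale else 1.0
        coef, w, obj, inner_ok = self._pirls(sds, scale, maxiter=maxiter, tol=tol)
        m2ll = self._laplace_m2ll(coef, w, obj, sds)
        beta, b = coef[:p], coef[p:]
        # Schur complement for cov(beta): XtWX - XtWZ H^-1 ZtWX
        X = self.exog
        W = sparse.diags(w)
        XtWX = X.T @ (w[:, None] * X)
        if self._Z is not None and np.any(sds > 1e-10):
            d = self._expand_sds(np.maximum(sds, 1e-10)) ** 2
            Z = self._Z
            H = (Z.T @ W @ Z).tocsc() + sparse.diags(1.0 / d)
            ZtWX = np.asarray((Z.T @ W @ sparse.csr_matrix(X)).todense())
            S = XtWX - ZtWX.T @ splu(H).solve(ZtWX)
        else:
            S = XtWX
        cov_beta = np.linalg.inv(S)
        vc_sd = {nm: float(sds[i]) for i, nm in enumerate(self.vc_names)}
        k = p + len(free) + n_extra
        return MixedGLMResults(
            model=self, params=beta, cov_params_=cov_beta, random_effects=b,
            vc_sd=vc_sd, scale=scale, llf=-0.5 * m2ll, df_model=k,
            converged=converged and inner_ok, reml=False,
        )


class MixedGLMResults:
    """Fit results: estimates, uncertainties, diagnostics, predictions."""

    def __init__(self, model, params, cov_params_, random_effects, vc_sd,
                 scale, llf, df_model, converged, reml):
        self.model = model
        self.params = np.asarray(params)
        self._cov_params = np.asarray(cov_params_)
        self.random_effects = np.asarray(random_effects)
        self.vc_sd = vc_sd
        self.scale = scale
        self.llf = float(llf)
        self.df_model = int(df_model)
        self.converged = bool(converged)
        self.reml = reml

    # ------------------------------------------------------------------
    @property
    def aic(self) -> float:
        return -2 * self.llf + 2 * self.df_model

    def cov_params(self) -> np.ndarray:
        return self._cov_params

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self._cov_params))

    @property
    def fittedvalues(self) -> np.ndarray:
        eta = self.model.exog @ self.params
        if self.model._Z is not None and len(self.random_effects):
            eta = eta + self.model._Z @ self.random_effects
        return self.model.family.link.inverse(eta)

    @property
    def resid_pearson(self) -> np.ndarray:
        mu = self.fittedvalues
        var = self.model.family.variance(mu)
        if self.model.family_name == "gaussian":
            var = var * self.scale
        elif self.model.family_name == "gamma":
            var = var * self.scale
        return (self.model.endog - mu) / np.sqrt(var)

    def overdispersion_ratio(self) -> float:
        """Pearson chi-square over residual degrees of freedom."""
        r = self.resid_pearson
        dof = len(r) - self.model.exog.shape[1] - len(self.vc_sd)
        return float(np.sum(r**2) / max(dof, 1))

    # ------------------------------------------------------------------
    def wald_term(self, term, results=None) -> tuple[float, int, float]:
        """Joint Wald chi-square that all coefficients of ``term`` are zero."""
        info = self.model.design_info
        if info is None or term not in info.term_slices:
            raise ValueError(f"term {term!r} not in design")
        sl = info.term_slices[term]
        beta = self.params[sl]
        cov = self._cov_params[sl, sl.start:sl.stop]
        stat = float(beta @ np.linalg.solve(cov, beta))
        df = sl.stop - sl.start
        return stat, df, float(chi2_dist.sf(stat, df))

    def predicted_means(self, grouping, numeric_at=None, alpha=0.05,
                        with_cov=False):
        """Predicted marginal means for every level combination of ``grouping``.

        Non-focal categorical covariates are averaged uniformly over their
        levels on the link scale; random effects are set to zero. Wald
        intervals are formed on the link scale and back-transformed.
        """
        info = self.model.design_info
        if info is None:
            raise ValueError("predicted means require design_info")
        if isinstance(grouping, str):
            grouping = [grouping]
        for g in grouping:
            if g not in info.levels:
                raise ValueError(f"grouping factor {g!r} not in the model")
        combos = [{}]
        for g in grouping:
            combos = [dict(c, **{g: lv}) for c in combos for lv in info.levels[g]]
        rows = np.array([prediction_row(info, at, numeric_at) for at in combos])
        eta = rows @ self.params
        cov_eta = rows @ self._cov_params @ rows.T
        se = np.sqrt(np.maximum(np.diag(cov_eta), 0))
        zq = norm_dist.ppf(1 - alpha / 2)
        inv = self.model.family.link.inverse
        out = [
            PredictedMean(
                group=at,
                estimate=float(inv(e)),
                ci_low=float(inv(e - zq * s)),
                ci_high=float(inv(e + zq * s)),
                link_estimate=float(e),
                link_se=float(s),
            )
            for at, e, s in zip(combos, eta, se)
        ]
        if with_cov:
            return out, cov_eta
        return out

    # ------------------------------------------------------------------
    def summary(self) -> str:
        info = self.model.design_info
        names = info.column_names if info is not None else [
            f"x{i}" for i in range(len(self.params))
        ]
        lines = [
            f"MixedGLM ({self.model.family_name}"
            + (", REML" if self.reml else ", ML")
            + (")" if self.converged else ", NOT CONVERGED)"),
            f"  n = {len(self.model.endog)}, logLik = {self.llf:.3f}, "
            f"AIC = {self.aic:.3f}, scale = {self.scale:.4g}",
            f"  {'term':<28}{'coef':>12}{'se':>12}{'z':>9}{'p':>10}",
        ]
        for nm, b, s in zip(names, self.params, self.bse):
            z = b / s if s > 0 else np.nan
            p = 2 * norm_dist.sf(abs(z)) if np.isfinite(z) else np.nan
            lines.append(f"  {nm:<28}{b:>12.4f}{s:>12.4f}{z:>9.2f}{p:>10.3g}")
        if self.vc_sd:
            lines.append("  Random-effect SDs:")
            for nm, sd in self.vc_sd.items():
                lines.append(f"    {nm:<26}{sd:>12.4f}")
        return "\n".join(lines)


def type2_anova(model: MixedGLM, results: MixedGLMResults) -> pd.DataFrame:
    """Type-2 Wald chi-square tests for every non-intercept fixed term.

    Each term is tested after all other terms of the same or lower order:
    terms with higher-order relatives in the model are tested in a refit that
    omits those relatives; terms with none are tested in the full fit.
    """
    info = model.design_info
    if info is None:
        raise ValueError("type-2 ANOVA requires design_info")
    rows = []
    refit_cache: dict[tuple, MixedGLMResults] = {}
    for term in info.terms:
        if term == ():
            continue
        relatives = [
            t for t in info.terms
            if t != term and set(term) < set(t)
        ]
        if not relatives:
            stat, df, p = results.wald_term(term)
        else:
            keep = tuple(t for t in info.terms if t != () and t not in relatives)
            if keep not in refit_cache:
                cols = np.concatenate([
                    np.arange(info.term_slices[t].start, info.term_slices[t].stop)
                    for t in (((),) + keep)
                ])
                sub_info = DesignInfo(
                    terms=[()] + list(keep),
                    levels=dict(info.levels),
                    numeric=list(info.numeric),
                )
                pos = 0
                for t in sub_info.terms:
                    w = info.term_slices[t].stop - info.term_slices[t].start
                    sub_info.term_slices[t] = slice(pos, pos + w)
                    pos += w
                sub_info.column_names = [info.column_names[c] for c in cols]
                sub = MixedGLM(
                    model.endog, model.exog[:, cols],
                    vc={nm: codes for nm, codes in zip(
                        model.vc_names,
                        [Z.indices for Z in model._z_blocks],
                    )},
                    family=model.family_name, design_info=sub_info,
                )
                refit_cache[keep] = sub.fit(reml=results.reml,
                                            fix_vc=None)
            sub_res = refit_cache[keep]
            stat, df, p = sub_res.wald_term(term)
        rows.append({"term": ":".join(term), "chi2": stat, "df": df, "p": p})
    return pd.DataFrame(rows)
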