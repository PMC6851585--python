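"""Per-trait mixed-model battery.

For each trait the analysis fits mixed models at several scopes:

- a pooled-stage model (sex, stage, sex x stage fixed; maternal family and
  individual random) to test for temporal change in dimorphism;
- per-stage sex x race models (population random) for race-level contrasts;
- per-stage sex x population models (maternal family random) whose predicted
  means feed the population-level dimorphism and correlation stages;
- race-specific models when the sex x race interaction is significant.

Distribution families are chosen from the nature of the response (binary ->
binomial; non-negative integers -> count candidates; continuous -> gaussian/
gamma), then by AIC among admissible candidates, with mean-variance and
quantile diagnostics carried along. Overdispersed Poisson/binomial fits are
refitted with an observation-level random intercept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .glmm import MixedGLM, MixedGLMResults, SingleSexError, type2_anova

__all__ = [
    "ModelSpec",
    "TraitModel",
    "TraitModelResults",
    "select_family",
    "fit_trait_model",
    "check_overdispersion",
    "stagewise_models",
]

OVERDISPERSION_THRESHOLD = 1.5


@dataclass
class ModelSpec:
    """What to fit for one trait: scope, fixed terms, random terms, family."""

    trait: str
    stages: list  # one stage, or several (pooled-stage model)
    fixed_terms: list = field(default_factory=lambda: ["sex"])
    random_terms: list = field(default_factory=lambda: ["family_id"])
    family: str = "gaussian"
    scope: str = "overall"  # overall | race | population | pooled

    def __post_init__(self):
        if len(self.stages) > 1 and "ind_id" not in self.random_terms:
            # repeated measures across stages: individual random intercept
            self.random_terms = list(self.random_terms) + ["ind_id"]


# ---------------------------------------------------------------------------
def select_family(values, candidates=None, min_n: int = 20):
    """Choose a distribution family for a response vector.

    Hard support rules come first (binary -> binomial; non-negative integers
    -> count candidates; otherwise continuous candidates); among the
    admissible candidates the lowest intercept-only GLM AIC wins.

    Returns ``(family_name, diagnostics)`` where diagnostics include the
    per-candidate AICs, a mean-variance summary and a quantile discrepancy
    against draws simulated from each fitted candidate.
    """
    y = np.asarray(values, dtype=float)
    y = y[np.isfinite(y)]
    if len(y) < min_n:
        raise ValueError(f"need at least {min_n} observations, got {len(y)}")

    uniq = np.unique(y)
    is_binary = set(uniq) <= {0.0, 1.0}
    is_count = np.all(y >= 0) and np.allclose(y, np.round(y))

    if is_binary:
        admissible = ["binomial"]
    elif is_count:
        admissible = ["poisson", "gaussian"]
    elif np.all(y > 0):
        admissible = ["gaussian", "gamma"]
    else:
        admissible = ["gaussian"]
    if candidates is not None:
        admissible = [f for f in admissible if f in candidates]
        if not admissible:
            raise ValueError(
                f"no candidate family is admissible for this response "
                f"(support-admissible: binary={is_binary}, count={is_count})"
            )

    fams = {
        "gaussian": sm.families.Gaussian(),
        "poisson": sm.families.Poisson(),
        "binomial": sm.families.Binomial(),
        "gamma": sm.families.Gamma(link=sm.families.links.Log()),
    }
    X = np.ones((len(y), 1))
    aic = {}
    qq = {}
    rng = np.random.default_rng(0)
    for name in admissible:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(y, X, family=fams[name]).fit()
        aic[name] = float(res.aic)
        mu = float(res.fittedvalues[0])
        scale = float(res.scale)
        sim = _simulate_family(rng, name, mu, scale, size=len(y))
        qs = np.linspace(0.05, 0.95, 19)
        qq[name] = float(np.mean(np.abs(np.quantile(y, qs) - np.quantile(sim, qs))))

    chosen = min(aic, key=aic.get)
    diagnostics = {
        "aic": aic,
        "qq_discrepancy": qq,
        "mean": float(np.mean(y)),
        "variance": float(np.var(y, ddof=1)),
        "var_to_mean": float(np.var(y, ddof=1) / np.mean(y)) if np.mean(y) > 0 else np.nan,
        "admissible": admissible,
    }
    return chosen, diagnostics


def _simulate_family(rng, name, mu, scale, size):
    if name == "gaussian":
        return rng.normal(mu, np.sqrt(scale), size)
    if name == "poisson":
        return rng.poisson(mu, size).astype(float)
    if name == "binomial":
        return rng.binomial(1, mu, size).astype(float)
    shape = 1.0 / scale
    return rng.gamma(shape, mu / shape, size)


# ---------------------------------------------------------------------------
class TraitModel:
    """Mixed model for one trait at one scope (statsmodels-style wrapper)."""

    def __init__(self, data: pd.DataFrame, spec: ModelSpec):
        self.spec = spec
        df = data
        if "trait" in df.columns:
            df = df[df["trait"] == spec.trait]
        df = df[df["stage"].isin(spec.stages)]
        df = df[df["sex"].isin(["F", "M"])].copy()
        if df.empty:
            raise ValueError(f"no observations for {spec.trait} at {spec.stages}")
        if df["sex"].nunique() < 2:
            raise SingleSexError(
                f"{spec.trait}: only sex {df['sex'].iloc[0]!r} present"
            )
        terms = list(spec.fixed_terms)
        if len(spec.stages) > 1 and "stage" not in _flat(terms):
            terms += ["stage", ("sex", "stage")]
        vc = [t for t in spec.random_terms if t != "obs" and df[t].nunique() > 1]
        if "obs" in spec.random_terms:
            df = df.assign(obs=np.arange(len(df)))
            vc.append("obs")
        self.data = df
        self._terms = terms
        self._vc = vc
        self.model = MixedGLM.from_dataframe(
            df, "value", terms, vc_terms=vc, family=spec.family
        )

    def fit(self, anova: bool = True, check_dispersion: bool = True,
            **kwargs) -> "TraitModelResults":
        res = self.model.fit(**kwargs)
        ratio = np.nan
        if self.spec.family in ("poisson", "binomial"):
            ratio = res.overdispersion_ratio()
            if check_dispersion and ratio > OVERDISPERSION_THRESHOLD:
                _, refit = check_overdispersion(self, res, **kwargs)
                if refit is not None:
                    res = refit.raw
                    ratio = res.overdispersion_ratio()
        anova_tab = type2_anova(res.model, res) if anova else None
        return TraitModelResults(self, res, anova_tab, ratio)


def _flat(terms):
    out = set()
    for t in terms:
        out.update((t,) if isinstance(t, str) else t)
    return out


class TraitModelResults:
    """Fitted trait model: predicted sex means, type-2 ANOVA, diagnostics."""

    def __init__(self, trait_model: TraitModel, raw: MixedGLMResults,
                 anova: pd.DataFrame | None, overdispersion_ratio: float):
        self.trait_model = trait_model
        self.spec = trait_model.spec
        self.raw = raw
        self.anova = anova
        self.overdispersion_ratio = overdispersion_ratio

    # -- convenience ----------------------------------------------------
    @property
    def converged(self):
        return self.raw.converged

    @property
    def aic(self):
        return self.raw.aic

    def interaction_p(self, term) -> float:
        if self.anova is None:
            raise ValueError("fit with anova=True to get interaction tests")
        label = ":".join(term) if not isinstance(term, str) else term
        row = self.anova[self.anova["term"] == label]
        if row.empty:
            raise KeyError(f"term {label!r} not in ANOVA table")
        return float(row["p"].iloc[0])

    def groups(self) -> list:
        info = self.raw.model.design_info
        scope = self.spec.scope
        if scope == "race":
            return list(info.levels.get("race", []))
        if scope == "population":
            return list(info.levels.get("pop_id", []))
        return ["overall"]

    def sex_means(self, group: str = "overall"):
        """(pm_F, pm_M, link-scale covariance) for one scope group."""
        grouping = ["sex"]
        scope = self.spec.scope
        if scope == "race":
            grouping.append("race")
        elif scope == "population":
            grouping.append("pop_id")
        pms, cov = self.raw.predicted_means(grouping, with_cov=True)

        def match(sex):
            for k, pm in enumerate(pms):
                if pm.group["sex"] != sex:
                    continue
                if scope == "race" and pm.group["race"] != group:
                    continue
                if scope == "population" and pm.group["pop_id"] != group:
                    continue
                return k
            raise KeyError(f"no predicted mean for sex={sex}, group={group}")

        iF, iM = match("F"), match("M")
        return pms[iF], pms[iM], float(cov[iF, iM])

    def predicted(self) -> list:
        grouping = ["sex"]
        if self.spec.scope == "race":
            grouping.append("race")
        elif self.spec.scope == "population":
            grouping.append("pop_id")
        return self.raw.predicted_means(grouping)

    def summary(self) -> str:
        head = (f"TraitModel {self.spec.trait} [{'+'.join(self.spec.stages)}] "
                f"scope={self.spec.scope} family={self.spec.family}")
        parts = [head, self.raw.summary()]
        if not np.isnan(self.overdispersion_ratio):
            parts.append(f"  overdispersion ratio: {self.overdispersion_ratio:.3f}")
        if self.anova is not None:
            parts.append("  Type-2 Wald ANOVA:\n" +
                         self.anova.to_string(index=False))
        return "\n".join(parts)


def fit_trait_model(data: pd.DataFrame, spec: ModelSpec,
                    **kwargs) -> TraitModelResults:
    """Fit one trait model (see :class:`TraitModel`)."""
    return TraitModel(data, spec).fit(**kwargs)


# ---------------------------------------------------------------------------
def check_overdispersion(trait_model: TraitModel, results: MixedGLMResults,
                         threshold: float = OVERDISPERSION_THRESHOLD,
                         **fit_kwargs):
    """Pearson chi-square / residual df; refit with an observation-level
    random intercept when the ratio exceeds ``threshold``.

    For binary responses with one trial per observation the ratio is
    reported but the refit is skipped (the extra variance is not
    identifiable).
    """
    spec = trait_model.spec
    if spec.family not in ("poisson", "binomial"):
        raise ValueError("overdispersion check applies to poisson/binomial")
    ratio = results.overdispersion_ratio()
    if ratio <= threshold:
        return ratio, None
    y = trait_model.data["value"]
    if spec.family == "binomial" and set(np.unique(y)) <= {0.0, 1.0}:
        warnings.warn("binary response: observation-level refit skipped "
                      "(non-identifiable)")
        return ratio, None
    if "obs" in trait_model._vc:
        return ratio, None
    new_spec = ModelSpec(
        trait=spec.trait, stages=list(spec.stages),
        fixed_terms=list(spec.fixed_terms),
        random_terms=list(spec.random_terms) + ["obs"],
        family=spec.family, scope=spec.scope,
    )
    refit = TraitModel(trait_model.data, new_spec).fit(
        anova=False, check_dispersion=False, **fit_kwargs
    )
    return ratio, refit


# ---------------------------------------------------------------------------
def stagewise_models(
    obs: pd.DataFrame,
    families: dict | None = None,
    scopes=("overall", "population"),
    pooled_stages: dict | None = None,
    alpha: float = 0.05,
    anova: bool = True,
    race_specific: bool = True,
    traits=None,
    **fit_kwargs,
) -> dict:
    """Run the model battery; returns {(trait, stage, scope): results}.

    Per trait: per-stage models at each requested scope ("overall": sex
    [+race] fixed, maternal family random; "race": sex x race fixed,
    population random; "population": sex x population fixed, maternal
    random), plus a pooled-stage model with a sex x stage interaction and an
    individual-level random term when the trait spans several stages
    (key ``(trait, "pooled", "overall")``). When the sex x race interaction
    is significant at ``alpha`` and ``race_specific`` is set, entries for
    scope "race" are added from the interaction model.

    ``families`` overrides the per-trait automatic family choice.
    """
    families = dict(families or {})
    out: dict = {}
    trait_list = traits or sorted(obs["trait"].unique())
    for trait in trait_list:
        sub = obs[obs["trait"] == trait]
        stages = [s for s in ["wk2", "wk4", "wk8", "harvest"]
                  if s in set(sub["stage"])]
        if not stages:
            warnings.warn(f"{trait}: no stages present; skipped")
            continue

        stage_fams = {}
        for stage in stages:
            stage_df = sub[sub["stage"] == stage]
            if stage_df.empty:
                warnings.warn(f"{trait}/{stage}: missing; scope skipped")
                continue
            # family chosen per stage: stage mixtures would masquerade as
            # overdispersion in the pooled response
            fam = families.get(trait) or select_family(stage_df["value"])[0]
            stage_fams[stage] = fam
            multi_race = stage_df["race"].nunique() > 1 if "race" in stage_df else False
            if "overall" in scopes:
                fixed = ["sex", "race"] if multi_race else ["sex"]
                spec = ModelSpec(trait=trait, stages=[stage], fixed_terms=fixed,
                                 random_terms=["family_id"], family=fam,
                                 scope="overall")
                out[(trait, stage, "overall")] = fit_trait_model(
                    sub, spec, anova=anova, **fit_kwargs)
            if "race" in scopes and multi_race:
                spec = ModelSpec(trait=trait, stages=[stage],
                                 fixed_terms=["sex", "race", ("sex", "race")],
                                 random_terms=["pop_id"], family=fam,
                                 scope="race")
                res = fit_trait_model(sub, spec, anova=True, **fit_kwargs)
                trigger = True
                if race_specific:
                    try:
                        trigger = res.interaction_p(("sex", "race")) < alpha
                    except KeyError:
                        trigger = False
                if trigger:
                    out[(trait, stage, "race")] = res
            if "population" in scopes and stage_df["pop_id"].nunique() > 1:
                spec = ModelSpec(trait=trait, stages=[stage],
                                 fixed_terms=["sex", "pop_id", ("sex", "pop_id")],
                                 random_terms=["family_id"], family=fam,
                                 scope="population")
                out[(trait, stage, "population")] = fit_trait_model(
                    sub, spec, anova=False, **fit_kwargs)
            elif "population" in scopes:
                # single population: the per-stage overall model is the
                # per-population model
                spec = ModelSpec(trait=trait, stages=[stage],
                                 fixed_terms=["sex"],
                                 random_terms=["family_id"], family=fam,
                                 scope="overall")
                out[(trait, stage, "population")] = fit_trait_model(
                    sub, spec, anova=False, **fit_kwargs)

        pool = (pooled_stages or {}).get(trait) or [
            s for s in stages if s in ("wk4", "wk8")
        ]
        pool = [s for s in pool if s in stage_fams]
        if len(pool) > 1:
            fams_used = [stage_fams[s] for s in pool]
            fam = families.get(trait) or max(set(fams_used), key=fams_used.count)
            spec = ModelSpec(trait=trait, stages=pool, fixed_terms=["sex"],
                             random_terms=["family_id"], family=fam,
                             scope="pooled")
            out[(trait, "pooled", "overall")] = fit_trait_model(
                sub, spec, anova=anova, **fit_kwargs)
    return out
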