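"""Percent sexual dimorphism: derived traits, %SD, CIs, direction, reversals.

The central statistic is

    %SD = 100 * (mean_F - mean_M) / mean_M

on model-predicted means, positive values meaning female-biased expression.
Two interval conventions are carried side by side on every estimate:

``ci_low``/``ci_high``
    The field's published propagation rule applied literally: each bound is
    sqrt(bound_F^2 + bound_M^2) computed once with the two lower 95% bounds
    of the sex-specific predicted means and once with the two upper bounds.
    Note the resulting interval is a magnitude-style band not centred on the
    point estimate.
``delta_low``/``delta_high``
    A first-order (delta-method) Wald interval for the ratio, using the
    link-scale covariance of the two predicted means. This is the interval
    used for coverage-style checks.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "DimorphismEstimate",
    "ReversalReport",
    "derive_traits",
    "percent_sd",
    "percent_sd_ci",
    "percent_sd_delta_ci",
    "dimorphism_table",
    "detect_reversals",
]

#: |mean_M| below this is treated as an undefined denominator.
MEAN_M_FLOOR = 1e-8


@dataclass
class DimorphismEstimate:
    """%SD for one trait at one stage in one scope (overall/race/population)."""

    trait: str
    stage: str
    scope: str
    group: str  # "overall", a race label, or a population id
    mean_F: float
    mean_M: float
    pct_sd: float
    ci_low: float
    ci_high: float
    direction: str
    delta_low: float = math.nan
    delta_high: float = math.nan

    def as_dict(self) -> dict:
        return {
            "trait": self.trait, "stage": self.stage, "scope": self.scope,
            "group": self.group, "mean_F": self.mean_F, "mean_M": self.mean_M,
            "pct_sd": self.pct_sd, "ci_low": self.ci_low, "ci_high": self.ci_high,
            "delta_low": self.delta_low, "delta_high": self.delta_high,
            "direction": self.direction,
        }


@dataclass
class ReversalReport:
    """Sign change of %SD between two life-cycle stages for one trait."""

    trait: str
    stage_pair: tuple
    pct_sd_pair: tuple
    reversed: bool


# ---------------------------------------------------------------------------
def percent_sd(mean_F: float, mean_M: float) -> float:
    """Percent sexual dimorphism, ``100 * (mean_F - mean_M) / mean_M``.

    Positive values indicate female-biased expression.
    """
    if abs(mean_M) < MEAN_M_FLOOR:
        raise ValueError("percent_sd undefined: mean_M is (numerically) zero")
    return 100.0 * (mean_F - mean_M) / mean_M


def percent_sd_ci(bound_F: float, bound_M: float) -> float:
    """One side of the propagated %SD interval: sqrt(bound_F^2 + bound_M^2).

    Applied once with the two lower 95% bounds of the sex-specific predicted
    means and once with the two upper bounds.
    """
    if not (np.isfinite(bound_F) and np.isfinite(bound_M)):
        raise ValueError("bounds must be finite")
    return float(math.hypot(bound_F, bound_M))


def percent_sd_delta_ci(
    mean_F: float,
    mean_M: float,
    var_F: float,
    var_M: float,
    cov_FM: float = 0.0,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Delta-method Wald interval for %SD on the response scale.

    ``var_*``/``cov_FM`` are variances/covariance of the two predicted means
    (response scale). The gradient of R = 100 (muF - muM)/muM is
    (100/muM, -100 muF/muM^2).
    """
    if abs(mean_M) < MEAN_M_FLOOR:
        raise ValueError("delta CI undefined: mean_M is (numerically) zero")
    gF = 100.0 / mean_M
    gM = -100.0 * mean_F / mean_M**2
    var = gF * gF * var_F + gM * gM * var_M + 2 * gF * gM * cov_FM
    half = norm.ppf(1 - alpha / 2) * math.sqrt(max(var, 0.0))
    r = percent_sd(mean_F, mean_M)
    return r - half, r + half


def _direction(pct: float, lo: float, hi: float) -> str:
    if lo > 0 and pct > 0:
        return "female-biased"
    if hi < 0 and pct < 0:
        return "male-biased"
    return "none"


# ---------------------------------------------------------------------------
def derive_traits(obs: pd.DataFrame) -> pd.DataFrame:
    """Append derived trait observations to a long observation table.

    Adds, where the component traits exist for an individual/stage:

    - ``total_flower_number`` = inflorescence_number * inflorescence_length
      (inflorescence length being a per-flower surrogate, the product
      estimates total flowers);
    - ``proportion_flowering_stems`` = flowering_stem_number / stem_number
      (flowering individuals only; zero stems yields a missing value);
    - ``total_biomass`` = vegetative_biomass + reproductive_biomass.

    Expects columns ``ind_id, stage, trait, value``; other columns are
    carried through. Returns a new DataFrame with the derived rows appended.
    """
    idx = ["ind_id", "stage"]
    carried = [c for c in obs.columns if c not in ("trait", "value", "kind")]
    wide = obs.pivot_table(index=idx, columns="trait", values="value",
                           aggfunc="first")
    meta = obs[carried].drop_duplicates(idx).set_index(idx)

    new_rows = []

    def emit(name: str, series: pd.Series, kind: str):
        series = series.dropna()
        if series.empty:
            return
        df = series.rename("value").reset_index()
        df["trait"] = name
        df["kind"] = kind
        df = df.join(meta.drop(columns=[c for c in meta.columns if c in df],
                               errors="ignore"),
                     on=idx)
        new_rows.append(df)

    cols = set(wide.columns)
    if {"inflorescence_number", "inflorescence_length"} <= cols:
        emit("total_flower_number",
             wide["inflorescence_number"] * wide["inflorescence_length"],
             "continuous")
    if {"flowering_stem_number", "stem_number"} <= cols:
        stems = wide["stem_number"]
        zero = stems == 0
        if zero.any():
            warnings.warn(
                f"{int(zero.sum())} individual-stages with zero stems; "
                "proportion_flowering_stems emitted as missing"
            )
        prop = wide["flowering_stem_number"] / stems.where(~zero)
        emit("proportion_flowering_stems", prop, "continuous")
    if {"vegetative_biomass", "reproductive_biomass"} <= cols:
        emit("total_biomass",
             wide["vegetative_biomass"] + wide["reproductive_biomass"],
             "continuous")

    if not new_rows:
        return obs.copy()
    add = pd.concat(new_rows, ignore_index=True).reindex(columns=obs.columns)
    return pd.concat([obs, add], ignore_index=True)


# ---------------------------------------------------------------------------
def estimate_from_means(
    trait: str,
    stage: str,
    scope: str,
    group: str,
    pm_F,
    pm_M,
    cov_link: float = 0.0,
) -> DimorphismEstimate | None:
    """Build a DimorphismEstimate from two PredictedMean objects.

    ``cov_link`` is the link-scale covariance between the two predicted
    means; response-scale variances for the delta interval are obtained by
    the inverse-link derivative at each estimate.
    """
    if abs(pm_M.estimate) < MEAN_M_FLOOR:
        warnings.warn(
            f"{trait}/{stage}/{group}: male predicted mean ~0; %SD undefined"
        )
        return None
    pct = percent_sd(pm_F.estimate, pm_M.estimate)
    lo = percent_sd_ci(pm_F.ci_low, pm_M.ci_low)
    hi = percent_sd_ci(pm_F.ci_high, pm_M.ci_high)
    # response-scale delta variances via the chain rule through the link
    dF = _inv_link_deriv(pm_F)
    dM = _inv_link_deriv(pm_M)
    dlo, dhi = percent_sd_delta_ci(
        pm_F.estimate, pm_M.estimate,
        (dF * pm_F.link_se) ** 2, (dM * pm_M.link_se) ** 2,
        dF * dM * cov_link,
    )
    return DimorphismEstimate(
        trait=trait, stage=stage, scope=scope, group=group,
        mean_F=pm_F.estimate, mean_M=pm_M.estimate, pct_sd=pct,
        ci_low=lo, ci_high=hi, direction=_direction(pct, dlo, dhi),
        delta_low=dlo, delta_high=dhi,
    )


def _inv_link_deriv(pm) -> float:
    """d mu / d eta at the estimate, from the stored link/response pair."""
    # derivative recovered numerically from the back-transform around eta
    eps = 1e-6
    # stored fields are enough: mu = inv(eta); use central difference via CI
    # anchors is unstable, so rely on common links analytically
    eta, mu = pm.link_estimate, pm.estimate
    if abs(mu - eta) < 1e-12:  # identity link
        return 1.0
    if mu > 0 and abs(math.log(max(mu, 1e-300)) - eta) < 1e-8:  # log link
        return mu
    # logistic link
    return mu * (1 - mu)


def dimorphism_table(models: dict, scope_groups: dict | None = None) -> list:
    """One DimorphismEstimate per trait x stage x scope from fitted models.

    ``models`` maps ``(trait, stage, scope)`` to objects exposing
    ``sex_means(group)`` -> ``(pm_F, pm_M, cov_link)`` per group (see
    :class:`dimorph.traitmodels.TraitModelResults`). ``scope_groups``
    optionally maps scope name -> list of group labels (default: the
    model's own groups).
    """
    out = []
    for (trait, stage, scope), model in sorted(models.items()):
        groups = (scope_groups or {}).get(scope) or model.groups()
        for g in groups:
            try:
                pm_F, pm_M, cov = model.sex_means(g)
            except KeyError:
                warnings.warn(f"{trait}/{stage}/{scope}/{g}: missing sex; skipped")
                continue
            est = estimate_from_means(trait, stage, scope, g, pm_F, pm_M, cov)
            if est is not None:
                out.append(est)
    return out


def detect_reversals(estimates: list, stage_order: list | None = None) -> list:
    """Flag traits whose %SD changes sign between stages with both CIs
    excluding zero (delta intervals gate significance)."""
    order = stage_order or ["wk2", "wk4", "wk8", "harvest"]
    by_trait: dict[str, list[DimorphismEstimate]] = {}
    for e in estimates:
        by_trait.setdefault(e.trait, []).append(e)
    reports = []
    for trait, ests in sorted(by_trait.items()):
        ests = sorted(ests, key=lambda e: order.index(e.stage)
                      if e.stage in order else 99)
        for i in range(len(ests)):
            for j in range(i + 1, len(ests)):
                a, b = ests[i], ests[j]
                if a.stage == b.stage or (a.scope, a.group) != (b.scope, b.group):
                    continue
                sig_a = a.delta_low > 0 or a.delta_high < 0
                sig_b = b.delta_low > 0 or b.delta_high < 0
                flipped = a.pct_sd * b.pct_sd < 0
                reports.append(ReversalReport(
                    trait=trait, stage_pair=(a.stage, b.stage),
                    pct_sd_pair=(a.pct_sd, b.pct_sd),
                    reversed=bool(flipped and sig_a and sig_b),
                ))
    return reports


def estimates_to_frame(estimates: list) -> pd.DataFrame:
    """Tidy export: trait, stage, scope, means, %SD, both interval kinds."""
    return pd.DataFrame([e.as_dict() for e in estimates])
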