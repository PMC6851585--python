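"""Synthetic study-design generator.

Emulates a range-wide common-garden study of a dioecious, wind-pollinated
annual: ~30 source populations (two chromosome races split along a west-east
cline), 15 open-pollinated maternal families per population, ~4 seedlings
per family (48-64 per population after germination failure), female-biased
population sex ratios (0.54-0.68), and quantitative traits of Gaussian,
count and binary kind measured at four occasions (week 2, week 4, week 8,
harvest) with sex x stage interactions and sex-differential bioclimatic
slopes.

Every generated trait has a closed-form true percent sexual dimorphism per
stage (stored in the scenario truth table), so downstream estimators can be
checked by parameter recovery. The 19 bioclimatic covariates are produced
from three latent climate axes (mean temperature, temperature range,
precipitation) plus noise, so that the variable-reduction step has a known
recoverable structure; temperature variables use the WorldClim v1.4 integer
convention (deg C x 10).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

__all__ = [
    "PopulationRecord",
    "IndividualRecord",
    "TraitEffects",
    "Scenario",
    "generate_populations",
    "generate_individuals",
    "generate_traits",
    "study_default_scenario",
    "populations_frame",
    "individuals_frame",
]

STAGES = ["wk2", "wk4", "wk8", "harvest"]

#: loading groups of the 19 bioclim variables on the three latent axes
_BIO_AXES = {
    "temp_mean": ["bio1", "bio5", "bio6", "bio8", "bio9", "bio10", "bio11"],
    "temp_range": ["bio2", "bio3", "bio4", "bio7"],
    "precip": ["bio12", "bio13", "bio14", "bio15", "bio16", "bio17", "bio18", "bio19"],
}
#: (centre, scale) per variable on its native WorldClim scale
_BIO_BASE = {
    "bio1": (185.0, 15.0), "bio5": (330.0, 12.0), "bio6": (40.0, 25.0),
    "bio8": (200.0, 30.0), "bio9": (150.0, 40.0), "bio10": (265.0, 10.0),
    "bio11": (95.0, 22.0),
    "bio2": (130.0, 10.0), "bio3": (45.0, 4.0), "bio4": (7200.0, 600.0),
    "bio7": (290.0, 18.0),
    "bio12": (1250.0, 150.0), "bio13": (160.0, 25.0), "bio14": (60.0, 15.0),
    "bio15": (20.0, 5.0), "bio16": (400.0, 60.0), "bio17": (210.0, 45.0),
    "bio18": (330.0, 50.0), "bio19": (280.0, 60.0),
}
_TEMPERATURE_VARS = _BIO_AXES["temp_mean"] + _BIO_AXES["temp_range"]

DENSITY_RANGE = (0.04, 122.4)
SEX_RATIO_RANGE = (0.54, 0.68)
POP_SIZE_RANGE = (10, 2_000_000)


@dataclass
class PopulationRecord:
    """One source population: race, geography, demography, climate."""

    pop_id: str
    race: str  # "XY" or "XY1Y2"
    latitude: float
    longitude: float
    elevation: float
    pop_size: int
    density: float  # plants per m^2
    sex_ratio: float  # females / (females + males)
    bioclim: dict = field(default_factory=dict)

    def __post_init__(self):
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ValueError("sex_ratio must be in [0, 1]")
        if self.density <= 0:
            raise ValueError("density must be positive")
        if self.pop_size < 1:
            raise ValueError("pop_size must be >= 1")
        if self.bioclim and len(self.bioclim) != 19:
            raise ValueError("bioclim must contain exactly 19 variables")


@dataclass
class IndividualRecord:
    """One seedling: identity, family (maternal parent), sex, block."""

    ind_id: str
    pop_id: str
    family_id: str
    sex: str  # "F", "M" or "U" (never flowered; cannot be sexed)
    block: str
    true_sex: str = ""  # latent sex driving trait generation

    def __post_init__(self):
        if not self.true_sex:
            self.true_sex = self.sex


@dataclass
class TraitEffects:
    """Link-scale generative effects for one trait.

    The linear predictor for individual i at stage s is::

        eta = intercept + stage[s] + female*(beta_sex + sex_stage[s])
              + race_effect*(race == XY1Y2)
              + climate_slope[sex] * z(bio1)
              + u_pop + u_family + u_individual  (+ residual if gaussian)

    where z(bio1) is the standardized annual-mean-temperature covariate of
    the source population. True %SD per stage follows in closed form with
    random effects at zero, climate at its mean, and the race factor
    averaged on the link scale (the same conditioning the model-based
    predicted means use).
    """

    family: str  # gaussian | poisson | binomial
    stages: list
    intercept: float
    beta_sex: float = 0.0
    stage_effects: dict = field(default_factory=dict)
    sex_stage: dict = field(default_factory=dict)
    beta_race: float = 0.0
    climate_slope_F: float = 0.0
    climate_slope_M: float = 0.0
    sd_population: float = 0.0
    sd_family: float = 0.0
    sd_individual: float = 0.0
    sd_residual: float = 0.0
    reproductive: bool = False

    def __post_init__(self):
        for sd in (self.sd_population, self.sd_family, self.sd_individual,
                   self.sd_residual):
            if sd < 0:
                raise ValueError("standard deviations must be >= 0")
        if self.family not in ("gaussian", "poisson", "binomial"):
            raise ValueError(f"unsupported family {self.family!r}")

    # -- closed-form truth ------------------------------------------------
    def _inv_link(self, eta):
        if self.family == "gaussian":
            return eta
        if self.family == "poisson":
            return np.exp(eta)
        return 1.0 / (1.0 + np.exp(-eta))

    def linpred(self, sex, stage, race_avg=0.5, climate_z=0.0):
        eta = self.intercept + self.stage_effects.get(stage, 0.0)
        eta += self.beta_race * race_avg
        if sex == "F":
            eta += self.beta_sex + self.sex_stage.get(stage, 0.0)
            eta += self.climate_slope_F * climate_z
        else:
            eta += self.climate_slope_M * climate_z
        return eta

    def true_pct_sd(self, stage: str) -> float:
        mu_F = self._inv_link(self.linpred("F", stage))
        mu_M = self._inv_link(self.linpred("M", stage))
        return 100.0 * (mu_F - mu_M) / mu_M


def sex_effect_for_pct_sd(pct: float, family: str, eta_M: float) -> float:
    """Link-scale female offset giving a target %SD at male predictor eta_M."""
    ratio = 1.0 + pct / 100.0
    if ratio <= 0:
        raise ValueError("target %SD must exceed -100")
    if family == "gaussian":
        return eta_M * (ratio - 1.0)
    if family == "poisson":
        return float(np.log(ratio))
    if family == "binomial":
        p_m = 1.0 / (1.0 + np.exp(-eta_M))
        p_f = p_m * ratio
        if not 0 < p_f < 1:
            raise ValueError("target %SD infeasible on the probability scale")
        return float(np.log(p_f / (1 - p_f)) - eta_M)
    raise ValueError(f"unsupported family {family!r}")


@dataclass
class Scenario:
    """A complete generative configuration."""

    n_pops: int = 30
    races: tuple = ("XY", "XY1Y2")
    n_families: int = 15
    n_per_family: int = 4
    germination: float = 0.995
    cline_strength: float = 1.0
    p_unsexed: float = 0.02
    n_blocks: int = 4
    traits: dict = field(default_factory=dict)

    def truth_table(self) -> pd.DataFrame:
        """Closed-form true %SD per trait and stage."""
        rows = [
            {"trait": name, "stage": s, "true_pct_sd": eff.true_pct_sd(s)}
            for name, eff in self.traits.items()
            for s in eff.stages
        ]
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["races"] = list(self.races)
        return d


# ---------------------------------------------------------------------------
def generate_populations(
    n_pops: int = 30,
    races: tuple = ("XY", "XY1Y2"),
    seed: int = 0,
    cline_strength: float = 1.0,
) -> list:
    """Sample source populations along a west-east geographic cline.

    Bioclim variables are linear in three latent climate axes (which are in
    turn linear in the coordinates, scaled by ``cline_strength``) plus
    independent noise, so they are correlated in blocks; demography is drawn
    within the study's field-observed ranges.
    """
    if n_pops < 2:
        raise ValueError("need at least 2 populations")
    rng = np.random.default_rng(seed)
    order = np.argsort(rng.uniform(size=n_pops))
    lon = np.sort(rng.uniform(-97.5, -77.5, n_pops))[order]
    lat = rng.uniform(29.5, 36.5, n_pops)
    elev = np.exp(rng.uniform(np.log(5), np.log(350), n_pops))

    lon_z = (lon - lon.mean()) / (lon.std() + 1e-12)
    lat_z = (lat - lat.mean()) / (lat.std() + 1e-12)
    c = cline_strength
    noise_sd = np.sqrt(max(1.0 - min(c, 1.0) ** 2 * 0.64, 0.05))
    latents = {
        "temp_mean": c * (-0.7 * lat_z + 0.3 * lon_z) + noise_sd * rng.normal(size=n_pops),
        "temp_range": c * (-0.6 * lon_z - 0.3 * lat_z) + noise_sd * rng.normal(size=n_pops),
        "precip": c * (0.7 * lon_z - 0.2 * lat_z) + noise_sd * rng.normal(size=n_pops),
    }

    bio = {}
    for axis, names in _BIO_AXES.items():
        for j, name in enumerate(names):
            centre, scale = _BIO_BASE[name]
            loading = 0.95 - 0.08 * (j % 4)
            vals = centre + scale * (loading * latents[axis]
                                     + np.sqrt(1 - loading**2) * rng.normal(size=n_pops))
            if name in _TEMPERATURE_VARS:
                vals = np.rint(vals)
            bio[name] = vals

    # races split along the cline: western half one karyotype, eastern the other
    race_of = np.empty(n_pops, dtype=object)
    west = np.argsort(lon)
    half = n_pops // 2
    race_of[west[:half]] = races[0]
    race_of[west[half:]] = races[-1] if len(races) > 1 else races[0]

    density = np.exp(rng.uniform(np.log(DENSITY_RANGE[0]),
                                 np.log(DENSITY_RANGE[1]), n_pops))
    pop_size = np.exp(rng.uniform(np.log(POP_SIZE_RANGE[0]),
                                  np.log(POP_SIZE_RANGE[1]), n_pops)).astype(int)
    sex_ratio = rng.uniform(*SEX_RATIO_RANGE, n_pops)

    pops = []
    for i in range(n_pops):
        pops.append(PopulationRecord(
            pop_id=f"P{i + 1:02d}",
            race=str(race_of[i]),
            latitude=float(lat[i]),
            longitude=float(lon[i]),
            elevation=float(elev[i]),
            pop_size=int(max(pop_size[i], 1)),
            density=float(density[i]),
            sex_ratio=float(sex_ratio[i]),
            bioclim={k: float(bio[k][i]) for k in sorted(_BIO_BASE,
                                                         key=lambda s: int(s[3:]))},
        ))
    return pops


def generate_individuals(
    pops: list,
    n_families: int = 15,
    n_per_family: int = 4,
    seed: int = 0,
    germination: float = 0.995,
    sex_ratio: float | None = None,
    p_unsexed: float = 0.0,
    n_blocks: int = 4,
) -> list:
    """Sample seedlings: maternal families nested in populations.

    Family sizes are Binomial(n_per_family, germination) truncated at 1, so
    per-population totals fall in the study's planted range. Sex is
    Bernoulli(population sex ratio) (overridable via ``sex_ratio``); when a
    family of two or more ends single-sex, one individual is flipped so both
    sexes are represented wherever feasible. With probability ``p_unsexed``
    an individual never flowers: its recorded sex is "U" and it receives no
    reproductive observations downstream (its latent sex still drives
    vegetative trait generation).
    """
    if not pops:
        raise ValueError("population list is empty")
    if n_families < 1:
        raise ValueError("need at least one family per population")
    rng = np.random.default_rng(seed)
    inds = []
    counter = 0
    for pop in pops:
        ratio = pop.sex_ratio if sex_ratio is None else sex_ratio
        for f in range(n_families):
            fam_id = f"{pop.pop_id}_F{f + 1:02d}"
            size = max(int(rng.binomial(n_per_family, germination)), 1)
            sexes = np.where(rng.uniform(size=size) < ratio, "F", "M")
            if size >= 2 and len(set(sexes)) == 1 and 0.0 < ratio < 1.0:
                sexes[rng.integers(size)] = "M" if sexes[0] == "F" else "F"
            for s in sexes:
                counter += 1
                obs_sex = "U" if rng.uniform() < p_unsexed else str(s)
                inds.append(IndividualRecord(
                    ind_id=f"I{counter:05d}",
                    pop_id=pop.pop_id,
                    family_id=fam_id,
                    sex=obs_sex,
                    block=f"B{rng.integers(n_blocks) + 1}",
                    true_sex=str(s),
                ))
    return inds


def generate_traits(
    inds: list,
    pops: list,
    scenario: Scenario,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw the long observation table for every trait/stage in ``scenario``.

    Returns columns ``ind_id, pop_id, family_id, sex, block, stage, trait,
    value, kind``. Gaussian values with positive-support interpretation
    (sizes, biomass) are generated with mean/SD ratios that make negative
    draws essentially impossible and are floored at zero. Unsexed
    individuals receive no reproductive traits.
    """
    if not inds:
        raise ValueError("individual list is empty")
    rng = np.random.default_rng(seed)
    pop_ix = {p.pop_id: i for i, p in enumerate(pops)}
    bio1 = np.array([p.bioclim.get("bio1", 0.0) for p in pops])
    bio1_z = (bio1 - bio1.mean()) / (bio1.std() + 1e-12)

    ind_pop = np.array([pop_ix[i.pop_id] for i in inds])
    fams, fam_codes = np.unique([i.family_id for i in inds], return_inverse=True)
    is_f = np.array([i.true_sex == "F" for i in inds])
    is_xy1y2 = np.array([pops[pop_ix[i.pop_id]].race == "XY1Y2" for i in inds])
    unsexed = np.array([i.sex == "U" for i in inds])
    n = len(inds)

    frames = []
    for name, eff in scenario.traits.items():
        u_pop = eff.sd_population * rng.normal(size=len(pops))
        u_fam = eff.sd_family * rng.normal(size=len(fams))
        u_ind = eff.sd_individual * rng.normal(size=n)
        keep = ~unsexed if eff.reproductive else np.ones(n, dtype=bool)
        for stage in eff.stages:
            if stage not in STAGES:
                raise ValueError(f"unknown stage {stage!r}")
            eta = (eff.intercept + eff.stage_effects.get(stage, 0.0)
                   + np.where(is_f, eff.beta_sex + eff.sex_stage.get(stage, 0.0), 0.0)
                   + eff.beta_race * is_xy1y2
                   + np.where(is_f, eff.climate_slope_F, eff.climate_slope_M)
                   * bio1_z[ind_pop]
                   + u_pop[ind_pop] + u_fam[fam_codes] + u_ind)
            if eff.family == "gaussian":
                vals = eta + eff.sd_residual * rng.normal(size=n)
                vals = np.maximum(vals, 0.0) if eff.intercept > 0 else vals
                kind = "continuous"
            elif eff.family == "poisson":
                vals = rng.poisson(np.exp(np.clip(eta, -30, 30))).astype(float)
                kind = "count"
            else:
                p = 1.0 / (1.0 + np.exp(-eta))
                vals = rng.binomial(1, p).astype(float)
                kind = "binary"
            if eff.reproductive and eff.family == "binomial":
                # never-flowering individuals are observed not flowering
                keep_stage = np.ones(n, dtype=bool)
                vals = np.where(unsexed, 0.0, vals)
            else:
                keep_stage = keep
            frames.append(pd.DataFrame({
                "ind_id": [i.ind_id for i, k in zip(inds, keep_stage) if k],
                "pop_id": [i.pop_id for i, k in zip(inds, keep_stage) if k],
                "family_id": [i.family_id for i, k in zip(inds, keep_stage) if k],
                "sex": [i.sex for i, k in zip(inds, keep_stage) if k],
                "block": [i.block for i, k in zip(inds, keep_stage) if k],
                "stage": stage,
                "trait": name,
                "value": vals[keep_stage],
                "kind": kind,
            }))
    out = pd.concat(frames, ignore_index=True)
    return out


# ---------------------------------------------------------------------------
def study_default_scenario(
    pct_sd_height=(0.0, -16.1, 9.4),
    sd_population: float = 0.04,
    sd_family: float = 0.03,
) -> Scenario:
    """The default study-like scenario.

    Trait battery and stage profiles mirror the common-garden design this
    package emulates: height with a male-biased peak-flowering stage and a
    female-biased maturity stage (``pct_sd_height`` per stage), female-biased
    leaf number/size and vegetative biomass at maturity, strongly
    female-biased flowering probability at peak flowering, and a reversal
    in inflorescence number. Random-effect SDs are on the link scale
    (relative scale for log links).
    """
    tr = {}
    h0 = 18.0  # cm at wk2
    h_wk4, h_wk8 = 50.0, 62.0
    tr["height"] = TraitEffects(
        family="gaussian", stages=["wk2", "wk4", "wk8"], intercept=h0,
        stage_effects={"wk4": h_wk4 - h0, "wk8": h_wk8 - h0},
        beta_sex=h0 * pct_sd_height[0] / 100.0,
        sex_stage={
            "wk4": h_wk4 * pct_sd_height[1] / 100.0 - h0 * pct_sd_height[0] / 100.0,
            "wk8": h_wk8 * pct_sd_height[2] / 100.0 - h0 * pct_sd_height[0] / 100.0,
        },
        climate_slope_F=0.0, climate_slope_M=1.5,
        sd_population=h_wk4 * sd_population, sd_family=h_wk4 * sd_family,
        sd_individual=0.0, sd_residual=6.0,
    )
    tr["leaf_number"] = TraitEffects(
        family="poisson", stages=["wk2", "wk4", "wk8"], intercept=np.log(8.0),
        stage_effects={"wk4": np.log(14 / 8), "wk8": np.log(22 / 8)},
        sex_stage={"wk8": np.log(1.158)},
        sd_population=sd_population, sd_family=sd_family,
    )
    tr["leaf_size"] = TraitEffects(
        family="gaussian", stages=["wk2", "wk4", "wk8"], intercept=3.0,
        stage_effects={"wk4": 1.5, "wk8": 2.5},
        sex_stage={"wk8": 5.5 * 0.073},
        sd_population=5.5 * sd_population, sd_family=5.5 * sd_family,
        sd_residual=0.8,
    )
    tr["stem_number"] = TraitEffects(
        family="poisson", stages=["wk4", "wk8"], intercept=np.log(4.0),
        stage_effects={"wk8": np.log(6 / 4)},
        sex_stage={"wk4": np.log(0.85)},
        sd_population=sd_population, sd_family=sd_family, reproductive=False,
    )
    tr["flowering"] = TraitEffects(
        family="binomial", stages=["wk4"], intercept=_logit(0.30),
        beta_sex=sex_effect_for_pct_sd(163.2, "binomial", _logit(0.30)),
        sd_population=2 * sd_population, sd_family=2 * sd_family,
        reproductive=True,
    )
    tr["inflorescence_number"] = TraitEffects(
        family="poisson", stages=["wk4", "wk8"], intercept=np.log(5.0),
        stage_effects={"wk8": np.log(12 / 5)},
        sex_stage={"wk4": np.log(1 - 0.186), "wk8": np.log(1 + 0.737)},
        sd_population=sd_population, sd_family=sd_family, reproductive=True,
    )
    tr["inflorescence_length"] = TraitEffects(
        family="gaussian", stages=["wk4", "wk8"], intercept=60.0,
        stage_effects={"wk8": 25.0},
        sex_stage={"wk4": -60.0 * 0.12, "wk8": -85.0 * 0.15},
        sd_population=70 * sd_population, sd_family=70 * sd_family,
        sd_residual=9.0, reproductive=True,
    )
    tr["vegetative_biomass"] = TraitEffects(
        family="gaussian", stages=["harvest"], intercept=1.6,
        beta_sex=1.6 * 0.452,
        sd_population=1.6 * sd_population * 2, sd_family=1.6 * sd_family * 2,
        sd_residual=0.35,
    )
    tr["reproductive_biomass"] = TraitEffects(
        family="gaussian", stages=["harvest"], intercept=0.9,
        beta_sex=0.9 * 0.25,
        sd_population=0.9 * sd_population * 2, sd_family=0.9 * sd_family * 2,
        sd_residual=0.2, reproductive=True,
    )
    return Scenario(traits=tr)


def _logit(p: float) -> float:
    return float(np.log(p / (1 - p)))


# ---------------------------------------------------------------------------
def populations_frame(pops: list) -> pd.DataFrame:
    rows = []
    for p in pops:
        row = {
            "pop_id": p.pop_id, "race": p.race, "lat": p.latitude,
            "lon": p.longitude, "elev": p.elevation, "pop_size": p.pop_size,
            "density": p.density, "sex_ratio": p.sex_ratio,
        }
        row.update(p.bioclim)
        rows.append(row)
    return pd.DataFrame(rows)


def individuals_frame(inds: list) -> pd.DataFrame:
    return pd.DataFrame([
        {"ind_id": i.ind_id, "pop_id": i.pop_id, "family_id": i.family_id,
         "sex": i.sex, "block": i.block}
        for i in inds
    ])
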