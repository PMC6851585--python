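"""End-to-end orchestration: simulate -> analyze -> recover.

Each run writes tidy CSV outputs plus a JSON manifest (config hash, seeds,
input digests, per-stage status, output checksums) so any run can be
reproduced from its manifest. Exclusions (unsexed individuals, missing
cells) are counted and reported, never silently dropped.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .correlations import (bootstrap_sex_difference, correlations_frame,
                           dimorphism_vs_intersex, partial_matrix,
                           population_trait_means, spearman_matrix)
from .dimorphism import (detect_reversals, dimorphism_table, derive_traits,
                         estimates_to_frame)
from .gradients import (CATEGORY_PREDICTORS, fit_gradient_models, funnel_summary,
                        reduce_bioclim)
from .simulate import (Scenario, TraitEffects, generate_individuals,
                       generate_populations, generate_traits,
                       individuals_frame, populations_frame,
                       study_default_scenario)
from .traitmodels import stagewise_models

OBS_COLUMNS = ["ind_id", "pop_id", "family_id", "sex", "block", "stage",
               "trait", "value", "kind"]
POP_COLUMNS = ["pop_id", "race", "lat", "lon", "elev", "pop_size", "density",
               "sex_ratio"] + [f"bio{i}" for i in range(1, 20)]


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _write_manifest(out_dir: Path, stages: dict, seeds: dict, config_text: str):
    out_dir = Path(out_dir)
    outputs = {
        p.name: _sha256(p)
        for p in sorted(out_dir.iterdir())
        if p.is_file() and p.name != "manifest.json"
    }
    manifest = {
        "package_version": __version__,
        "created": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "config_sha256": hashlib.sha256(config_text.encode()).hexdigest(),
        "seeds": seeds,
        "stages": stages,
        "outputs": outputs,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


# ---------------------------------------------------------------------------
def _pyify(obj):
    """Recursively convert numpy scalars so YAML stays plain."""
    if isinstance(obj, dict):
        return {k: _pyify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_pyify(v) for v in obj]
    if isinstance(obj, np.floating):
        return float(obj)
    if isinstance(obj, np.integer):
        return int(obj)
    return obj


def scenario_to_yaml(scenario: Scenario) -> str:
    return yaml.safe_dump(_pyify(scenario.to_dict()), sort_keys=False)


def scenario_from_yaml(text: str) -> Scenario:
    raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ValueError("scenario config must be a mapping")
    traits = {}
    for name, t in (raw.pop("traits", {}) or {}).items():
        unknown = set(t) - set(TraitEffects.__dataclass_fields__)
        if unknown:
            raise ValueError(
                f"scenario trait {name!r}: unknown keys {sorted(unknown)}")
        traits[name] = TraitEffects(**t)
    unknown = set(raw) - set(Scenario.__dataclass_fields__)
    if unknown:
        raise ValueError(f"scenario: unknown keys {sorted(unknown)}")
    if "races" in raw:
        raw["races"] = tuple(raw["races"])
    return Scenario(traits=traits, **raw)


# ---------------------------------------------------------------------------
def simulate_run(out_dir, scenario: Scenario | None = None, seed: int = 0) -> dict:
    """Generate a full synthetic dataset and write it to ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    scenario = scenario or study_default_scenario()
    pops = generate_populations(scenario.n_pops, scenario.races, seed=seed,
                                cline_strength=scenario.cline_strength)
    inds = generate_individuals(
        pops, scenario.n_families, scenario.n_per_family, seed=seed + 1,
        germination=scenario.germination, p_unsexed=scenario.p_unsexed,
        n_blocks=scenario.n_blocks,
    )
    obs = generate_traits(inds, pops, scenario, seed=seed + 2)

    populations_frame(pops).to_csv(out_dir / "populations.csv", index=False)
    obs[OBS_COLUMNS].to_csv(out_dir / "observations.csv", index=False)
    scenario.truth_table().to_csv(out_dir / "truth.csv", index=False)
    config_text = scenario_to_yaml(scenario)
    (out_dir / "scenario.yaml").write_text(config_text)
    manifest = _write_manifest(
        out_dir, {"simulate": "ok"},
        {"populations": seed, "individuals": seed + 1, "traits": seed + 2},
        config_text,
    )
    return manifest


def load_data(data_dir) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read and validate the observation and population tables."""
    data_dir = Path(data_dir)
    obs = pd.read_csv(data_dir / "observations.csv")
    pops = pd.read_csv(data_dir / "populations.csv")
    missing = [c for c in OBS_COLUMNS if c not in obs.columns]
    if missing:
        raise ValueError(f"observations.csv missing columns: {missing}")
    missing = [c for c in POP_COLUMNS if c not in pops.columns]
    if missing:
        raise ValueError(f"populations.csv missing columns: {missing}")
    bad_sex = set(obs["sex"]) - {"F", "M", "U"}
    if bad_sex:
        raise ValueError(f"observations.csv: unknown sex codes {sorted(bad_sex)}")
    orphan = set(obs["pop_id"]) - set(pops["pop_id"])
    if orphan:
        raise ValueError(f"observations reference unknown populations {sorted(orphan)}")
    return obs, pops


# ---------------------------------------------------------------------------
def analyze_run(
    data_dir,
    out_dir,
    traits=None,
    stages=("wk4", "wk8", "harvest"),
    bootstrap_pairs: int = 6,
    seed: int = 0,
    fast: bool = False,
) -> dict:
    """Full analysis bundle on a dataset directory.

    Runs trait models -> dimorphism -> gradients -> correlations and writes
    tidy CSVs plus a text report. ``fast`` restricts the battery (no type-2
    ANOVA and fewer bootstrap pairs) for smoke runs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    obs, pops = load_data(data_dir)
    status: dict = {}

    n_unsexed = int((obs["sex"] == "U").sum())
    obs_sexed = obs[obs["sex"].isin(["F", "M"])].copy()
    exclusions = {
        "unsexed_observations": n_unsexed,
        "unsexed_individuals": int(
            obs.loc[obs["sex"] == "U", "ind_id"].nunique()),
    }

    obs_sexed = derive_traits(obs_sexed)
    obs_sexed = obs_sexed.merge(pops[["pop_id", "race"]], on="pop_id", how="left")
    obs_sexed = obs_sexed[obs_sexed["stage"].isin(stages)]
    status["derive_traits"] = "ok"

    models = stagewise_models(
        obs_sexed, traits=traits,
        scopes=("overall", "race", "population"),
        anova=not fast,
    )
    n_nonconv = sum(1 for m in models.values() if not m.converged)
    status["trait_models"] = f"ok ({len(models)} fits, {n_nonconv} non-converged)"

    estimates = dimorphism_table(models)
    est_df = estimates_to_frame(estimates)
    est_df.to_csv(out_dir / "dimorphism.csv", index=False)
    overall = [e for e in estimates
               if e.scope == "overall" and e.stage != "pooled"]
    reversals = detect_reversals(overall)
    pd.DataFrame([
        {"trait": r.trait, "stage_a": r.stage_pair[0], "stage_b": r.stage_pair[1],
         "pct_sd_a": r.pct_sd_pair[0], "pct_sd_b": r.pct_sd_pair[1],
         "reversed": r.reversed}
        for r in reversals
    ]).to_csv(out_dir / "reversals.csv", index=False)
    status["dimorphism"] = f"ok ({len(estimates)} estimates)"

    # gradients on population-level %SD
    pops_ix = pops.set_index("pop_id")
    red = reduce_bioclim(pops)
    grad_rows = []
    pop_est = est_df[est_df["scope"] == "population"]
    for (trait, stage), grp in pop_est.groupby(["trait", "stage"]):
        y = grp.set_index("group")["pct_sd"]
        for category in ("demographic", "geographic", "bioclimatic"):
            order = (red.selected if category == "bioclimatic"
                     else CATEGORY_PREDICTORS[category])
            try:
                gm = fit_gradient_models(y, pops_ix, category, order=order,
                                         response=(trait, stage))
            except ValueError as e:
                warnings.warn(f"gradients {trait}/{stage}/{category}: {e}")
                continue
            grad_rows.append({
                "trait": trait, "stage": stage, "category": category,
                "predictors": ";".join(gm.predictors), "r2": gm.r_squared,
                "p": gm.p_value, "shapiro_p": gm.shapiro_p, "n": gm.n,
                "equation": gm.equation(),
            })
        fun = funnel_summary(y, pops_ix["density"], seed=seed)
        grad_rows.append({
            "trait": trait, "stage": stage, "category": "funnel",
            "predictors": "density", "r2": np.nan, "p": fun["heterogeneity_p"],
            "shapiro_p": np.nan, "n": fun["n"],
            "equation": f"heterogeneity_rs={fun['heterogeneity_rs']:.3f}",
        })
    pd.DataFrame(grad_rows).to_csv(out_dir / "gradients.csv", index=False)
    status["gradients"] = f"ok ({len(grad_rows)} rows; bioclim={red.selected})"

    # correlations per stage on population predicted means
    corr_entries = []
    boot_rows = []
    intersex_all = []
    rng = np.random.default_rng(seed)
    for stage in [s for s in stages if s != "harvest"]:
        try:
            mat = population_trait_means(models, stage)
        except ValueError:
            continue
        raw_entries = spearman_matrix(mat, stage=stage)
        corr_entries += raw_entries
        try:
            corr_entries += partial_matrix(mat, stage=stage)
        except (ValueError, np.linalg.LinAlgError) as e:
            warnings.warn(f"partial correlations at {stage}: {e}")
        intersex_all += [e for e in raw_entries if e.context == "intersex"]
        traits_here = sorted({t for t, _ in mat.columns})
        pairs = [(a, b) for i, a in enumerate(traits_here)
                 for b in traits_here[i + 1:]]
        if fast:
            pairs = pairs[:bootstrap_pairs]
        sub = min(25, len(mat))
        for a, b in pairs:
            bc = bootstrap_sex_difference(
                mat, (a, b), n_boot=1000, subsample=sub,
                seed=int(rng.integers(2**31 - 1)),
            )
            boot_rows.append({
                "stage": stage, "trait_a": a, "trait_b": b,
                "r_F": bc.r_F, "r_M": bc.r_M,
                "ci_F_low": bc.ci_F[0], "ci_F_high": bc.ci_F[1],
                "ci_M_low": bc.ci_M[0], "ci_M_high": bc.ci_M[1],
                "significant": bc.significant, "diff_p": bc.diff_p,
            })
    correlations_frame(corr_entries).to_csv(out_dir / "correlations.csv",
                                            index=False)
    pd.DataFrame(boot_rows).to_csv(out_dir / "bootstrap.csv", index=False)
    status["correlations"] = f"ok ({len(corr_entries)} entries)"

    assoc = None
    try:
        assoc = dimorphism_vs_intersex(overall, intersex_all)
    except ValueError as e:
        warnings.warn(f"|%SD|-intersex association: {e}")

    report = [
        f"dimorph v{__version__} analysis report",
        f"observations: {len(obs)} rows, {obs['ind_id'].nunique()} individuals, "
        f"{len(pops)} populations",
        f"exclusions: {exclusions}",
        f"bioclim reduction: {red.selected} (PC congruence {red.pc_check:.3f})",
        "",
        "stage status:",
    ] + [f"  {k}: {v}" for k, v in status.items()]
    if assoc is not None:
        report.append(
            f"|%SD| vs intersex correlation: r_s = {assoc.r_s:.3f}, "
            f"P = {assoc.p_value:.4f}")
    sig_rev = [r for r in reversals if r.reversed]
    report.append(f"significant temporal reversals: "
                  f"{[(r.trait, r.stage_pair) for r in sig_rev] or 'none'}")
    (out_dir / "report.txt").write_text("\n".join(report) + "\n")

    manifest = _write_manifest(out_dir, status, {"analysis": seed},
                               json.dumps(sorted(map(str, models))))
    manifest["exclusions"] = exclusions
    return manifest


# ---------------------------------------------------------------------------
def recovery_run(
    n_replicates: int = 10,
    seed: int = 0,
    true_pct_sd: float = 25.0,
    n_pops: int = 30,
    out_path=None,
) -> dict:
    """Repeated simulate+estimate for a single Gaussian trait scenario.

    Reports bias, RMSE and delta-interval coverage of the %SD estimator
    under the default 30-population design. Used by the acceptance harness.
    """
    if n_replicates < 2:
        raise ValueError("need at least 2 replicates")
    from .dimorphism import estimate_from_means
    from .traitmodels import ModelSpec, fit_trait_model

    errors, covered = [], []
    for r in range(n_replicates):
        est = _single_trait_estimate(true_pct_sd, seed + 1000 * r, n_pops)
        errors.append(est.pct_sd - true_pct_sd)
        covered.append(est.delta_low <= true_pct_sd <= est.delta_high)
    out = {
        "true_pct_sd": true_pct_sd,
        "n_replicates": n_replicates,
        "bias": float(np.mean(errors)),
        "rmse": float(np.sqrt(np.mean(np.square(errors)))),
        "coverage": float(np.mean(covered)),
    }
    if out_path:
        Path(out_path).write_text(json.dumps(out, indent=2))
    return out


def _single_trait_estimate(true_pct_sd: float, seed: int, n_pops: int = 30,
                           stage: str = "wk4"):
    """Simulate one Gaussian trait and estimate overall %SD at one stage."""
    from .dimorphism import estimate_from_means
    from .traitmodels import ModelSpec, fit_trait_model

    base = 50.0
    scen = Scenario(n_pops=n_pops, traits={
        "trait": TraitEffects(
            family="gaussian", stages=[stage], intercept=base,
            beta_sex=base * true_pct_sd / 100.0,
            sd_population=2.0, sd_family=1.5, sd_residual=6.0,
        )
    })
    pops = generate_populations(scen.n_pops, scen.races, seed=seed)
    inds = generate_individuals(pops, scen.n_families, scen.n_per_family,
                                seed=seed + 1, germination=scen.germination)
    obs = generate_traits(inds, pops, scen, seed=seed + 2)
    spec = ModelSpec(trait="trait", stages=[stage], fixed_terms=["sex"],
                     random_terms=["family_id", "pop_id"], family="gaussian")
    res = fit_trait_model(obs, spec, anova=False)
    pm_F, pm_M, cov = res.sex_means()
    return estimate_from_means("trait", stage, "overall", "overall",
                               pm_F, pm_M, cov)
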