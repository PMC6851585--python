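"""Synthetic study-design generator: structure, determinism, closed-form truth."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dimorph.simulate import (Scenario, TraitEffects, generate_individuals,
                              generate_populations, generate_traits,
                              individuals_frame, populations_frame,
                              sex_effect_for_pct_sd, study_default_scenario)


class TestPopulations:
    def test_race_split_and_count(self):
        pops = generate_populations(30, ("XY", "XY1Y2"), seed=1)
        assert len(pops) == 30
        races = pd.Series([p.race for p in pops]).value_counts()
        assert races["XY"] == 15 and races["XY1Y2"] == 15

    def test_seed_determinism(self):
        a = populations_frame(generate_populations(2, seed=7))
        b = populations_frame(generate_populations(2, seed=7))
        pd.testing.assert_frame_equal(a, b)

    def test_too_few_pops_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            generate_populations(1, seed=0)

    def test_bioclim_structure_and_demographic_ranges(self):
        pops = generate_populations(30, seed=3)
        for p in pops:
            assert len(p.bioclim) == 19
            assert 0.04 <= p.density <= 122.4
            assert 0.54 <= p.sex_ratio <= 0.68
            # temperature variables on the WorldClim integer scale
            assert p.bioclim["bio1"] == int(p.bioclim["bio1"])
        pf = populations_frame(pops)
        # block correlation: two variables of the same latent axis correlate
        r_same = stats.spearmanr(pf.bio1, pf.bio10)[0]
        assert abs(r_same) > 0.5

    def test_cline_links_climate_to_longitude(self):
        pf = populations_frame(generate_populations(30, seed=5,
                                                    cline_strength=1.0))
        r, p = stats.spearmanr(pf.bio12, pf.lon)
        assert p < 0.01  # precipitation axis loads on longitude

    def test_zero_cline_gives_null_association(self):
        """With cline_strength=0 the bio1-longitude correlation is null:
        significant at ~5% across replicates."""
        hits = 0
        n_rep = 50
        for r in range(n_rep):
            pf = populations_frame(
                generate_populations(30, seed=2000 + r, cline_strength=0.0))
            hits += stats.spearmanr(pf.bio1, pf.lon)[1] < 0.05
        assert hits / n_rep <= 0.16  # binomial 99% band around 0.05


class TestIndividuals:
    def test_family_structure(self):
        pops = generate_populations(2, seed=1)
        inds = generate_individuals(pops[:1], n_families=15, n_per_family=4,
                                    seed=3)
        df = individuals_frame(inds)
        assert len(df) <= 60
        assert df.family_id.nunique() == 15
        assert (df.groupby("family_id").size() >= 1).all()

    def test_population_totals_within_planted_range(self):
        pops = generate_populations(30, seed=2)
        inds = generate_individuals(pops, seed=4)
        sizes = individuals_frame(inds).groupby("pop_id").size()
        assert sizes.between(48, 64).all()
        assert 55 <= sizes.mean() <= 60.5

    def test_both_sexes_per_family_when_feasible(self):
        pops = generate_populations(4, seed=5)
        inds = generate_individuals(pops, seed=6)
        df = individuals_frame(inds)
        df = df[df.sex.isin(["F", "M"])]
        multi = df.groupby("family_id").filter(lambda g: len(g) >= 2)
        n_single_sex = (multi.groupby("family_id").sex.nunique() == 1).sum()
        assert n_single_sex == 0

    def test_degenerate_sex_ratio(self):
        pops = generate_populations(2, seed=1)
        inds = generate_individuals(pops, seed=2, sex_ratio=1.0)
        assert all(i.true_sex == "F" for i in inds)

    def test_sex_ratio_concentration(self):
        # large families so the both-sexes repair never triggers and the
        # female fraction concentrates at the Bernoulli rate
        pops = generate_populations(2, seed=1)
        inds = generate_individuals(pops, n_families=25, n_per_family=200,
                                    seed=9, germination=1.0, sex_ratio=0.6)
        assert len(inds) == 10_000
        frac = np.mean([i.true_sex == "F" for i in inds])
        assert 0.59 <= frac <= 0.61

    def test_empty_population_list_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            generate_individuals([], seed=0)


class TestTraits:
    def test_noise_free_gaussian_limit(self):
        scen = Scenario(n_pops=2, traits={
            "t": TraitEffects(family="gaussian", stages=["wk4"],
                              intercept=5.0, beta_sex=0.0)
        })
        pops = generate_populations(2, seed=1)
        inds = generate_individuals(pops, seed=2)
        obs = generate_traits(inds, pops, scen, seed=3)
        means = obs.groupby("sex").value.mean()
        assert means["F"] == means["M"] == 5.0

    def test_poisson_mean_recovery(self):
        scen = Scenario(traits={
            "t": TraitEffects(family="poisson", stages=["wk4"],
                              intercept=np.log(5.0))
        })
        pops = generate_populations(30, seed=1)
        inds = generate_individuals(pops, n_families=100, seed=2)
        obs = generate_traits(inds, pops, scen, seed=3)
        n = len(obs)
        assert n > 5000
        se = np.sqrt(5.0 / n)
        assert abs(obs.value.mean() - 5.0) < 3 * se

    def test_count_and_binary_supports(self, small_dataset):
        obs, _ = small_dataset
        counts = obs[obs.kind == "count"].value
        assert (counts >= 0).all() and np.allclose(counts, counts.round())

    def test_seed_determinism(self, small_scenario):
        pops = generate_populations(4, seed=1)
        inds = generate_individuals(pops, seed=2)
        a = generate_traits(inds, pops, small_scenario, seed=5)
        b = generate_traits(inds, pops, small_scenario, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_unsexed_receive_no_reproductive_traits(self):
        scen = study_default_scenario()
        scen = Scenario(n_pops=4, p_unsexed=0.3, traits=scen.traits)
        pops = generate_populations(4, seed=1)
        inds = generate_individuals(pops, seed=2, p_unsexed=0.3)
        obs = generate_traits(inds, pops, scen, seed=3)
        repro = {n for n, e in scen.traits.items() if e.reproductive
                 and e.family != "binomial"}
        assert (obs.sex == "U").any()
        assert not obs[(obs.sex == "U") & obs.trait.isin(repro)].shape[0]

    def test_family_variance_component_recovered(self):
        sd_fam = 0.8
        scen = Scenario(traits={
            "t": TraitEffects(family="gaussian", stages=["wk4"],
                              intercept=10.0, sd_family=sd_fam,
                              sd_residual=0.5)
        })
        pops = generate_populations(10, seed=1)
        inds = generate_individuals(pops, n_families=60, n_per_family=8,
                                    seed=2, germination=1.0)
        obs = generate_traits(inds, pops, scen, seed=3)
        fam_means = obs.groupby("family_id").value.mean()
        m = obs.groupby("family_id").size().mean()
        est = fam_means.var(ddof=1) - 0.25 / m
        assert est == pytest.approx(sd_fam**2, rel=0.2)


class TestTruth:
    def test_default_scenario_truth_matches_height_profile(self):
        truth = study_default_scenario().truth_table().set_index(
            ["trait", "stage"]).true_pct_sd
        assert truth[("height", "wk4")] == pytest.approx(-16.1, abs=1e-9)
        assert truth[("height", "wk8")] == pytest.approx(9.4, abs=1e-9)
        assert truth[("flowering", "wk4")] == pytest.approx(163.2, abs=1e-9)

    @pytest.mark.parametrize("family,eta_M", [
        ("gaussian", 40.0), ("poisson", np.log(6.0)), ("binomial", -0.5)])
    def test_sex_effect_solver_round_trips(self, family, eta_M):
        for target in (-20.0, 5.0, 60.0):
            eff = TraitEffects(family=family, stages=["wk4"], intercept=eta_M,
                               beta_sex=sex_effect_for_pct_sd(target, family,
                                                              eta_M))
            assert eff.true_pct_sd("wk4") == pytest.approx(target, abs=1e-9)

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError, match=">= 0"):
            TraitEffects(family="gaussian", stages=["wk4"], intercept=1.0,
                         sd_family=-0.1)

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError, match="unsupported family"):
            TraitEffects(family="negbin", stages=["wk4"], intercept=1.0)
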