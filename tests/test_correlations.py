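"""Spearman matrices, partial correlations, and the subsample bootstrap."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dimorph.correlations import (CorrelationEntry, bootstrap_sex_difference,
                                  dimorphism_vs_intersex, partial_matrix,
                                  partial_spearman, population_trait_means,
                                  spearman_matrix)
from dimorph.dimorphism import DimorphismEstimate


def _matrix(cols: dict) -> pd.DataFrame:
    df = pd.DataFrame(cols)
    df.columns = pd.MultiIndex.from_tuples(df.columns)
    df.index = [f"P{i:02d}" for i in range(len(df))]
    return df


@pytest.fixture
def random_matrix():
    rng = np.random.default_rng(0)
    return _matrix({(t, s): rng.normal(size=30)
                    for t in ("a", "b", "c") for s in "FM"})


class TestSpearmanMatrix:
    @pytest.mark.parametrize("x,y,expected", [
        ([1, 2, 3, 4, 5], [2, 4, 6, 8, 10], 1.0),
        ([1, 2, 3, 4, 5], [10, 8, 6, 4, 2], -1.0),
        ([1, 2, 3, 5, 4], [1, 2, 3, 4, 5], 0.9),
    ])
    def test_known_rank_correlations(self, x, y, expected):
        mat = _matrix({("a", "F"): x, ("b", "F"): y,
                       ("a", "M"): x, ("b", "M"): y})
        entries = {(e.trait_a, e.trait_b, e.context): e.r_s
                   for e in spearman_matrix(mat)}
        assert entries[("a", "b", "female")] == pytest.approx(expected)

    def test_intersex_entries_same_trait(self, random_matrix):
        entries = spearman_matrix(random_matrix)
        inter = [e for e in entries if e.context == "intersex"]
        assert {e.trait_a for e in inter} == {"a", "b", "c"}
        assert all(e.trait_a == e.trait_b for e in inter)

    def test_sign_convention(self, random_matrix):
        base = {(e.trait_a, e.trait_b): e.r_s
                for e in spearman_matrix(random_matrix)
                if e.context == "female"}
        neg = random_matrix.copy()
        neg[("b", "F")] = -neg[("b", "F")]
        flipped = {(e.trait_a, e.trait_b): e.r_s
                   for e in spearman_matrix(neg) if e.context == "female"}
        assert flipped[("a", "b")] == pytest.approx(-base[("a", "b")])
        assert flipped[("a", "c")] == pytest.approx(base[("a", "c")])

    def test_too_few_populations(self, random_matrix):
        with pytest.raises(ValueError, match=">=4"):
            spearman_matrix(random_matrix.iloc[:3])

    def test_constant_trait_flagged(self, random_matrix):
        m = random_matrix.copy()
        m[("a", "F")] = 1.0
        with pytest.warns(UserWarning, match="constant"):
            entries = spearman_matrix(m)
        vals = [e for e in entries if e.trait_a == "a" and e.context == "female"]
        assert all(np.isnan(e.r_s) for e in vals)


class TestPartialSpearman:
    def test_empty_controls_equals_raw(self, random_matrix):
        e = partial_spearman(random_matrix, ("a", "b"), [], "female")
        raw = stats.spearmanr(random_matrix[("a", "F")],
                              random_matrix[("b", "F")])[0]
        assert e.r_s == pytest.approx(raw, abs=1e-12)
        assert not e.partial

    def test_confounder_removed(self):
        # noise must be non-negligible: with near-deterministic monotone
        # dependence the rank transform leaves a discretization artefact
        # that biases any rank-based partial correlation (the reference
        # implementations show the same behaviour)
        raws, parts = [], []
        for s in range(20):
            rng = np.random.default_rng(300 + s)
            z = rng.normal(size=100)
            cols = {}
            for sex in "FM":
                cols[("x", sex)] = 2 * z + 0.5 * rng.normal(size=100)
                cols[("y", sex)] = -1.5 * z + 0.5 * rng.normal(size=100)
                cols[("z", sex)] = z
            mat = _matrix(cols)
            raws.append(partial_spearman(mat, ("x", "y"), [], "female").r_s)
            parts.append(partial_spearman(mat, ("x", "y"), ["z"],
                                          "female").r_s)
        assert np.median(np.abs(raws)) > 0.8
        # the confounder-driven association vanishes after conditioning
        assert np.median(np.abs(parts)) < 0.1
        assert np.max(np.abs(parts)) < 0.35

    def test_dual_routes_agree(self, random_matrix):
        for pair in (("a", "b"), ("a", "c"), ("b", "c")):
            r1 = partial_spearman(random_matrix, pair, ["a", "b", "c"][
                :0] or [t for t in "abc" if t not in pair], "male",
                method="residual").r_s
            r2 = partial_spearman(random_matrix, pair,
                                  [t for t in "abc" if t not in pair], "male",
                                  method="precision").r_s
            assert r1 == pytest.approx(r2, abs=1e-8)

    def test_matches_pingouin_oracle(self, random_matrix):
        pingouin = pytest.importorskip("pingouin")
        df = pd.DataFrame({
            "x": random_matrix[("a", "F")], "y": random_matrix[("b", "F")],
            "z": random_matrix[("c", "F")]})
        ref = pingouin.partial_corr(df, x="x", y="y", covar="z",
                                    method="spearman")
        ours = partial_spearman(random_matrix, ("a", "b"), ["c"], "female")
        assert ours.r_s == pytest.approx(float(ref["r"].iloc[0]), abs=1e-8)

    def test_intersex_controls_are_cross_sex_averages(self):
        rng = np.random.default_rng(4)
        cols = {(t, s): rng.normal(size=40) for t in ("a", "b")
                for s in "FM"}
        mat = _matrix(cols)
        e = partial_spearman(mat, ("a", "a"), ["b"], "intersex")
        # independent manual computation
        ra = stats.rankdata(mat[("a", "F")])
        rb = stats.rankdata(mat[("a", "M")])
        ctrl = stats.rankdata(mat[[("b", "F"), ("b", "M")]].mean(axis=1))
        Z = np.column_stack([np.ones(40), ctrl])
        ex = ra - Z @ np.linalg.lstsq(Z, ra, rcond=None)[0]
        ey = rb - Z @ np.linalg.lstsq(Z, rb, rcond=None)[0]
        manual = ex @ ey / np.sqrt((ex @ ex) * (ey @ ey))
        assert e.r_s == pytest.approx(manual, abs=1e-10)

    def test_insufficient_populations(self, random_matrix):
        with pytest.raises(ValueError, match="controls"):
            partial_spearman(random_matrix.iloc[:4], ("a", "b"), ["c"],
                             "female")


class TestBootstrap:
    def test_identical_sexes_not_significant(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=30), rng.normal(size=30)
        mat = _matrix({("a", "F"): x, ("b", "F"): y,
                       ("a", "M"): x, ("b", "M"): y})
        bc = bootstrap_sex_difference(mat, ("a", "b"), seed=1)
        assert bc.ci_F == bc.ci_M
        assert not bc.significant

    def test_seed_reproducibility_byte_identical(self, random_matrix):
        a = bootstrap_sex_difference(random_matrix, ("a", "b"), seed=7)
        b = bootstrap_sex_difference(random_matrix, ("a", "b"), seed=7)
        assert a == b

    def test_subsample_larger_than_populations_rejected(self, random_matrix):
        with pytest.raises(ValueError, match="exceeds"):
            bootstrap_sex_difference(random_matrix, ("a", "b"), subsample=31)

    def test_opposite_correlations_detected(self):
        rng = np.random.default_rng(6)
        cols = {}
        for s, rho in (("F", 0.9), ("M", -0.9)):
            xy = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], 30)
            cols[("a", s)], cols[("b", s)] = xy[:, 0], xy[:, 1]
        mat = _matrix(cols)
        bc = bootstrap_sex_difference(mat, ("a", "b"), seed=2)
        assert bc.significant
        assert bc.r_F > 0 > bc.r_M


class TestAssembly:
    def test_population_trait_means_shape(self, small_dataset):
        from dimorph.traitmodels import stagewise_models
        obs, _ = small_dataset
        models = stagewise_models(obs, traits=["height", "leaf_number"],
                                  anova=False, scopes=("population",))
        mat = population_trait_means(models, "wk4")
        assert mat.shape == (8, 4)  # 8 pops x (2 traits x 2 sexes)
        assert {t for t, _ in mat.columns} == {"height", "leaf_number"}

    def test_noise_free_means_recovered_exactly(self):
        """With all generator SDs at zero the predicted population means
        equal the closed-form means."""
        from dimorph.simulate import (Scenario, TraitEffects,
                                      generate_individuals,
                                      generate_populations, generate_traits)
        from dimorph.traitmodels import stagewise_models
        scen = Scenario(n_pops=4, traits={
            "t": TraitEffects(family="gaussian", stages=["wk4"],
                              intercept=10.0, beta_sex=2.0)})
        pops = generate_populations(4, seed=1)
        inds = generate_individuals(pops, seed=2)
        obs = generate_traits(inds, pops, scen, seed=3)
        obs["race"] = "XY"
        models = stagewise_models(obs, anova=False, scopes=("population",),
                                  families={"t": "gaussian"})
        mat = population_trait_means(models, "wk4")
        np.testing.assert_allclose(mat[("t", "F")], 12.0, atol=1e-6)
        np.testing.assert_allclose(mat[("t", "M")], 10.0, atol=1e-6)


class TestDimorphismVsIntersex:
    def _estimates(self, pct_values):
        return [DimorphismEstimate(
            trait=f"t{i}", stage="wk4", scope="overall", group="overall",
            mean_F=1, mean_M=1, pct_sd=p, ci_low=0, ci_high=0, direction="")
            for i, p in enumerate(pct_values)]

    def _intersex(self, r_values):
        return [CorrelationEntry(f"t{i}", f"t{i}", "intersex", r, 0.5,
                                 stage="wk4")
                for i, r in enumerate(r_values)]

    def test_monotone_association_is_one(self):
        ests = self._estimates([1, 2, 3, 4, 5])
        inter = self._intersex([0.1, 0.2, 0.3, 0.4, 0.5])
        e = dimorphism_vs_intersex(ests, inter)
        assert e.r_s == pytest.approx(1.0)

    def test_unmatched_pairs_rejected(self):
        with pytest.raises(ValueError, match=">=4"):
            dimorphism_vs_intersex(self._estimates([1, 2]),
                                   self._intersex([0.1, 0.2]))
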