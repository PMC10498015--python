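import numpy as np
import pandas as pd
import pytest

from phtmap.errors import AliasedEffectsError, FitError
from phtmap.varcomp import (
    RandomEffectsModel,
    VarianceComponents,
    blup_adjusted_means,
    heritability,
    trait_correlations,
)


def one_way(y, g, r):
    """Balanced one-way frame: g genotypes x r replicates."""
    return pd.DataFrame(
        {
            "value": y,
            "genotype_id": [f"g{i:03d}" for i in np.repeat(np.arange(g), r)],
            "round_time_id": "rt0",
            "container_id": "c0",
        }
    )


def anova_components(y, g, r):
    """Method-of-moments closed form for the balanced one-way design."""
    ym = y.reshape(g, r)
    ybar = ym.mean(axis=1)
    grand = y.mean()
    msb = r * np.sum((ybar - grand) ** 2) / (g - 1)
    msw = np.sum((ym - ybar[:, None]) ** 2) / (g * (r - 1))
    return (msb - msw) / r, msw, ybar, grand


class TestHeritability:
    def test_arithmetic(self):
        assert heritability(VarianceComponents(2, 1, 0.5, 1.5)) == pytest.approx(0.4)
        assert heritability(VarianceComponents(0, 1, 1, 1)) == 0.0
        assert heritability(VarianceComponents(0, 0, 0, 0)) == 0.0

    def test_negative_component_rejected(self):
        with pytest.raises(ValueError):
            heritability(VarianceComponents(-1, 0, 0, 1))


class TestRemlBalanced:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_anova_closed_form(self, seed):
        """On a balanced one-way design, REML equals the ANOVA estimator
        whenever the latter is non-negative."""
        rng = np.random.default_rng(seed)
        g, r = 40, 4
        y = np.repeat(rng.normal(0, 1.0, g), r) + rng.normal(0, 0.8, g * r)
        sg, se, *_ = anova_components(y, g, r)
        assert sg > 0  # generated well inside the interior
        fit = RandomEffectsModel(one_way(y, g, r)).fit()
        assert fit.varcomps.sigma2_genotype == pytest.approx(sg, rel=1e-6)
        assert fit.varcomps.sigma2_residual == pytest.approx(se, rel=1e-6)
        assert fit.varcomps.sigma2_round_time == 0.0
        assert fit.varcomps.sigma2_container == 0.0

    def test_blup_shrinkage_closed_form(self):
        rng = np.random.default_rng(11)
        g, r = 30, 5
        y = np.repeat(rng.normal(0, 1.2, g), r) + rng.normal(0, 1.0, g * r)
        sg, se, ybar, grand = anova_components(y, g, r)
        fit = RandomEffectsModel(one_way(y, g, r)).fit()
        lam = r * sg / (r * sg + se)
        np.testing.assert_allclose(fit.blups.to_numpy(), lam * (ybar - grand), rtol=1e-5)
        # shrinkage: predicted deviations never exceed the raw ones
        assert np.all(np.abs(fit.blups.to_numpy()) <= np.abs(ybar - grand) + 1e-12)
        assert abs(fit.blups.mean()) < 1e-6 * fit.blups.std()
        np.testing.assert_allclose(
            blup_adjusted_means(fit).to_numpy(), fit.mu + fit.blups.to_numpy()
        )

    def test_constant_data_all_zero(self):
        df = one_way(np.full(20, 5.0), 10, 2)
        fit = RandomEffectsModel(df).fit()
        assert fit.mu == 5.0
        assert fit.varcomps.total() == 0.0
        assert (fit.blups == 0).all()
        assert (blup_adjusted_means(fit) == 5.0).all()
        assert fit.h2 == 0.0

    def test_permutation_invariance(self):
        rng = np.random.default_rng(4)
        g, r = 20, 3
        y = np.repeat(rng.normal(0, 1, g), r) + rng.normal(0, 1, g * r)
        df = one_way(y, g, r)
        fit1 = RandomEffectsModel(df).fit()
        fit2 = RandomEffectsModel(df.sample(frac=1, random_state=0)).fit()
        assert fit1.mu == pytest.approx(fit2.mu, rel=1e-8)
        assert fit1.varcomps.sigma2_genotype == pytest.approx(
            fit2.varcomps.sigma2_genotype, rel=1e-5
        )
        pd.testing.assert_series_equal(fit1.blups, fit2.blups, rtol=1e-5)


class TestRemlMultiFactor:
    def _simulate(self, rng, n_g=60, r=4, sg=1.0, srt=0.4, sc=0.3, se=0.5):
        n = n_g * r
        geno = np.repeat(np.arange(n_g), r)
        rt = rng.integers(0, 6, n)
        cont = rng.integers(0, 8, n)
        y = (
            rng.normal(0, np.sqrt(sg), n_g)[geno]
            + rng.normal(0, np.sqrt(srt), 6)[rt]
            + rng.normal(0, np.sqrt(sc), 8)[cont]
            + rng.normal(0, np.sqrt(se), n)
        )
        return pd.DataFrame(
            {
                "value": y,
                "genotype_id": [f"g{i:03d}" for i in geno],
                "round_time_id": [f"rt{i}" for i in rt],
                "container_id": [f"c{i}" for i in cont],
            }
        )

    def test_components_recovered_in_expectation(self):
        """Average over a few fits lands near the generating components."""
        rng = np.random.default_rng(123)
        h2 = []
        for _ in range(8):
            fit = RandomEffectsModel(self._simulate(rng)).fit()
            h2.append(fit.h2)
        # truth: 1.0 / (1.0 + 0.4 + 0.3 + 0.5)
        assert np.mean(h2) == pytest.approx(1.0 / 2.2, abs=0.08)

    def test_aliased_factor_rejected(self):
        rng = np.random.default_rng(9)
        g, r = 10, 3
        geno = np.repeat(np.arange(g), r)
        df = pd.DataFrame(
            {
                "value": rng.normal(0, 1, g * r),
                "genotype_id": [f"g{i}" for i in geno],
                "round_time_id": "rt0",
                "container_id": [f"c{i}" for i in geno],  # same partition as genotype
            }
        )
        with pytest.raises(AliasedEffectsError):
            RandomEffectsModel(df)

    def test_too_few_replicates_rejected(self):
        df = pd.DataFrame(
            {
                "value": [1.0, 2.0, 3.0],
                "genotype_id": ["a", "b", "c"],
                "round_time_id": "rt0",
                "container_id": "c0",
            }
        )
        with pytest.raises(FitError):
            RandomEffectsModel(df)


class TestTraitCorrelations:
    def test_self_and_exact_linear(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, 20)
        df = pd.DataFrame({"a": x, "b": 2 * x + 3, "c": rng.normal(0, 1, 20)})
        r, p = trait_correlations(df)
        assert r.loc["a", "a"] == 1.0
        assert r.loc["a", "b"] == pytest.approx(1.0)
        assert p.loc["a", "b"] < 1e-10
        assert r.loc["a", "c"] == r.loc["c", "a"]  # symmetric

    def test_zero_variance_trait_flagged(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0], "b": [5.0, 5.0, 5.0, 5.0]})
        r, _ = trait_correlations(df)
        assert np.isnan(r.loc["a", "b"])
        assert r.loc["b", "b"] == 1.0
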