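import numpy as np
import pandas as pd
import pytest
from scipy import stats

from phtmap.errors import FitError, GenotypeInputError
from phtmap.gwas import (
    GenotypeMatrix,
    KinshipMatrix,
    MixedModelScan,
    clump,
    filter_snps,
    impute_mean,
    kinship,
    local_ld,
    qq_lambda,
    qtls_from_clumps,
    significant_snps,
)


def make_G(dosages, positions=None, chroms=None):
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    positions = np.arange(m) * 1000 + 1 if positions is None else positions
    chroms = ["1"] * m if chroms is None else chroms
    snps = pd.DataFrame(
        {"snp_id": [f"s{j}" for j in range(m)], "chrom": chroms, "pos": positions}
    )
    return GenotypeMatrix([f"a{i:03d}" for i in range(n)], snps, dosages)


class TestFilterImpute:
    def test_monomorphic_removed(self):
        G = make_G(np.zeros((10, 2)))
        G.dosages[:, 1] = [0, 1, 2, 1, 0, 1, 2, 1, 0, 1]
        out = filter_snps(G, maf_min=0.05, miss_max=0.1)
        assert list(out.snps["snp_id"]) == ["s1"]

    def test_missingness_strict_boundary(self):
        dos = np.tile([0.0, 2.0], (100, 1))
        dos[:50, :] = 0.0  # maf 0.25 both columns... make informative
        dos = np.column_stack([np.r_[np.zeros(50), np.full(50, 2.0)]] * 2)
        dos[:9, 0] = np.nan  # 9% missing: kept
        dos[:10, 1] = np.nan  # 10% missing: removed (strict <)
        out = filter_snps(make_G(dos), maf_min=0.05, miss_max=0.1)
        assert list(out.snps["snp_id"]) == ["s0"]

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(0)
        dos = rng.binomial(2, rng.uniform(0.01, 0.5, 200), size=(50, 200)).astype(float)
        dos[rng.random(dos.shape) < 0.08] = np.nan
        G = make_G(dos)
        kept = set(filter_snps(G, 0.05, 0.1).snps["snp_id"])
        expected = set()
        for j in range(200):
            col = dos[:, j]
            obs = col[~np.isnan(col)]
            p = obs.mean() / 2
            maf = min(p, 1 - p)
            miss = np.isnan(col).mean()
            if maf > 0.05 and miss < 0.1:
                expected.add(f"s{j}")
        assert kept == expected

    def test_impute_mean_values(self):
        G = make_G(np.array([[0.0], [2.0], [np.nan]]))
        out = impute_mean(G)
        assert out.dosages[2, 0] == pytest.approx(1.0)

    def test_impute_identity_and_mean_preserving(self):
        rng = np.random.default_rng(1)
        dos = rng.binomial(2, 0.4, (30, 20)).astype(float)
        G = make_G(dos.copy())
        np.testing.assert_array_equal(impute_mean(G).dosages, dos)
        dos[rng.random(dos.shape) < 0.2] = np.nan
        G2 = make_G(dos)
        before = np.nanmean(dos, axis=0)
        after = impute_mean(G2).dosages.mean(axis=0)
        np.testing.assert_allclose(before, after, rtol=1e-12)

    def test_all_missing_snp_rejected(self):
        G = make_G(np.full((5, 1), np.nan))
        with pytest.raises(GenotypeInputError, match="all-missing"):
            impute_mean(G)


class TestKinship:
    def test_identical_accessions(self):
        rng = np.random.default_rng(2)
        base = rng.binomial(2, 0.4, 50).astype(float)
        dos = np.vstack([base, base, rng.binomial(2, 0.4, 50)])
        for method in ("vanraden", "ibs"):
            K = kinship(make_G(dos), method)
            assert K.values[0, 1] == pytest.approx(K.values[0, 0])

    def test_vanraden_psd(self):
        rng = np.random.default_rng(3)
        dos = rng.binomial(2, 0.3, (40, 100)).astype(float)
        K = kinship(make_G(dos), "vanraden")
        assert np.linalg.eigvalsh(K.values).min() >= -1e-8

    def test_ibs_complementary_homozygotes(self):
        dos = np.vstack([np.zeros(20), np.full(20, 2.0)])
        K = kinship(make_G(dos), "ibs")
        assert K.values[0, 1] == pytest.approx(0.0)

    def test_zero_variance_set_rejected(self):
        with pytest.raises(GenotypeInputError, match="zero-variance"):
            kinship(make_G(np.zeros((5, 4))), "vanraden")


class TestScan:
    def test_identity_kinship_equals_ols(self):
        """With K = I the mixed-model scan is ordinary regression."""
        rng = np.random.default_rng(4)
        n, m = 80, 150
        dos = rng.binomial(2, 0.3, (n, m)).astype(float)
        G = make_G(dos)
        y = pd.Series(rng.normal(0, 1, n), index=G.accessions)
        K = KinshipMatrix(G.accessions, np.eye(n))
        res = MixedModelScan(y, G, K).fit()
        for j in rng.choice(m, 25, replace=False):
            p_ols = stats.linregress(dos[:, j], y.to_numpy()).pvalue
            d = abs(np.log10(p_ols) - np.log10(res.table["p"].iloc[j]))
            assert d < 1e-6

    def test_constant_phenotype_rejected(self):
        G = make_G(np.random.default_rng(0).binomial(2, 0.4, (20, 5)).astype(float))
        y = pd.Series(1.0, index=G.accessions)
        with pytest.raises(FitError, match="constant"):
            MixedModelScan(y, G, KinshipMatrix(G.accessions, np.eye(20)))

    def test_non_psd_kinship_rejected(self):
        rng = np.random.default_rng(1)
        G = make_G(rng.binomial(2, 0.4, (20, 5)).astype(float))
        y = pd.Series(rng.normal(0, 1, 20), index=G.accessions)
        K = KinshipMatrix(G.accessions, -np.eye(20))
        with pytest.raises(FitError, match="positive semidefinite"):
            MixedModelScan(y, G, K).fit()


class TestQqLambda:
    def test_uniform_grid_near_one(self):
        n = 10_000
        p = (np.arange(1, n + 1) - 0.5) / n
        _, lam = qq_lambda(p)
        assert 0.98 <= lam <= 1.02

    def test_halving_inflates(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(0.01, 1, 500)
        _, lam1 = qq_lambda(p)
        _, lam2 = qq_lambda(p / 2)
        assert lam2 > lam1

    def test_single_median_p(self):
        _, lam = qq_lambda([0.5])
        assert lam == pytest.approx(1.0)


class TestSignificance:
    def test_threshold_boundary(self):
        tab = pd.DataFrame(
            {
                "snp_id": ["a", "b", "c"],
                "chrom": "1",
                "pos": [1, 2, 3],
                "p": [1e-5, 1e-3, 1e-4],
            }
        )
        from phtmap.gwas import ScanResults

        res = ScanResults(table=tab, sigma_g2=1, sigma_e2=1, delta=1)
        kept = significant_snps(res, 4)
        assert set(kept["snp_id"]) == {"a", "c"}  # 1e-4 exactly is retained


def brute_force_clump(df, window_bp):
    """Independent greedy reference implementation."""
    remaining = df.sort_values(["p", "chrom", "pos", "snp_id"]).to_dict("records")
    out = []
    while remaining:
        idx = remaining[0]
        members = [
            r
            for r in remaining
            if r["chrom"] == idx["chrom"] and abs(r["pos"] - idx["pos"]) <= window_bp
        ]
        out.append((idx["snp_id"], sorted(m["snp_id"] for m in members)))
        member_ids = {m["snp_id"] for m in members}
        remaining = [r for r in remaining if r["snp_id"] not in member_ids]
    return out


class TestClumping:
    def test_worked_three_snp_case(self):
        df = pd.DataFrame(
            {
                "snp_id": ["x", "y", "z"],
                "chrom": "1",
                "pos": [100_000, 180_000, 600_000],
                "p": [1e-6, 1e-5, 1e-5],
            }
        )
        clumps = clump(df, window_kb=243)
        got = {c.index_snp: set(c.members["snp_id"]) for c in clumps}
        assert got == {"x": {"x", "y"}, "y": {"z"}} or got == {"x": {"x", "y"}, "z": {"z"}}
        qtls = qtls_from_clumps(clumps, min_snps=2)
        assert len(qtls) == 1
        assert (qtls[0].start, qtls[0].end, qtls[0].peak) == (100_000, 180_000, 100_000)

    def test_singleton(self):
        df = pd.DataFrame({"snp_id": ["x"], "chrom": "2", "pos": [5], "p": [1e-9]})
        clumps = clump(df, window_kb=100)
        assert len(clumps) == 1 and clumps[0].n_members == 1
        assert qtls_from_clumps(clumps) == []

    def test_empty(self):
        df = pd.DataFrame(columns=["snp_id", "chrom", "pos", "p"])
        assert clump(df, window_kb=100) == []

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        m = rng.integers(5, 40)
        df = pd.DataFrame(
            {
                "snp_id": [f"s{j}" for j in range(m)],
                "chrom": rng.choice(["1", "2"], m),
                "pos": rng.integers(1, 2_000_000, m),
                "p": 10.0 ** rng.uniform(-12, -4, m),
            }
        )
        window_kb = float(rng.integers(50, 400))
        got = [
            (c.index_snp, sorted(c.members["snp_id"]))
            for c in clump(df, window_kb=window_kb)
        ]
        assert got == brute_force_clump(df, window_kb * 1000)

    def test_partition_property(self):
        rng = np.random.default_rng(77)
        m = 60
        df = pd.DataFrame(
            {
                "snp_id": [f"s{j}" for j in range(m)],
                "chrom": rng.choice(["1", "2", "3"], m),
                "pos": rng.integers(1, 3_000_000, m),
                "p": 10.0 ** rng.uniform(-10, -4, m),
            }
        )
        clumps = clump(df, window_kb=150)
        assigned = [s for c in clumps for s in c.members["snp_id"]]
        assert sorted(assigned) == sorted(df["snp_id"])  # exactly one clump each
        for c in clumps:
            assert set(c.members["chrom"]) == {c.chrom}  # never crosses chromosomes


class TestLocalLd:
    def test_duplicated_and_orthogonal_columns(self):
        rng = np.random.default_rng(8)
        x = rng.binomial(2, 0.5, 60).astype(float)
        ortho = rng.normal(0, 1, 60)
        ortho -= ortho @ (x - x.mean()) / ((x - x.mean()) @ (x - x.mean())) * (x - x.mean())
        dos = np.column_stack([x, x, ortho - ortho.min()])
        G = make_G(dos, positions=[100, 200, 300])
        ld = local_ld(G, "1", center=200, flank=500)
        assert ld.r2.iloc[0, 1] == pytest.approx(1.0)
        assert ld.r2.iloc[0, 2] == pytest.approx(0.0, abs=1e-10)

    def test_matches_double_loop_oracle_and_flip_invariance(self):
        rng = np.random.default_rng(9)
        dos = rng.binomial(2, rng.uniform(0.1, 0.5, 30), size=(50, 30)).astype(float)
        G = make_G(dos, positions=np.arange(30) * 100 + 1)
        ld = local_ld(G, "1", center=1500, flank=10_000)
        m = ld.r2.shape[0]
        for i in range(m):
            for j in range(m):
                r = np.corrcoef(dos[:, i], dos[:, j])[0, 1]
                assert ld.r2.iloc[i, j] == pytest.approx(r * r, abs=1e-10)
        flipped = make_G(2.0 - dos, positions=np.arange(30) * 100 + 1)
        ld2 = local_ld(flipped, "1", center=1500, flank=10_000)
        np.testing.assert_allclose(ld.r2.to_numpy(), ld2.r2.to_numpy(), atol=1e-10)

    def test_zero_variance_snp_flagged(self):
        dos = np.column_stack([np.zeros(20), np.random.default_rng(0).binomial(2, 0.5, 20)])
        ld = local_ld(make_G(dos.astype(float)), "1", center=500, flank=5000)
        assert np.isnan(ld.r2.iloc[0, 1])
        assert ld.r2.iloc[0, 0] == 1.0  # diagonal stays defined
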