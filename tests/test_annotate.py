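import math

import numpy as np
import pandas as pd
import pytest

from phtmap.annotate import (
    GeneModel,
    enrich,
    flag_candidates,
    genes_linked,
    link_genes_across_qtls,
    read_gff3_genes,
)
from phtmap.errors import PhtmapError
from phtmap.gwas import LdMatrix


def make_ld(snp_ids, positions, r2, chrom="1"):
    df = pd.DataFrame(r2, index=snp_ids, columns=snp_ids)
    pos = pd.Series(positions, index=snp_ids)
    return LdMatrix(chrom, df, pos)


@pytest.fixture
def simple_region():
    # s_sig is the significant SNP; s_in sits inside the gene body
    r2 = np.array([[1.0, 0.45], [0.45, 1.0]])
    return make_ld(["s_sig", "s_in"], [50_000, 11_000], r2)


class TestGenesLinked:
    def test_gene_with_linked_snp_included(self, simple_region):
        gene = GeneModel("g1", "1", 10_000, 12_000)
        assert genes_linked([gene], simple_region, ["s_sig"]) == ["g1"]

    def test_boundary_r2_excluded(self):
        r2 = np.array([[1.0, 0.30], [0.30, 1.0]])
        ld = make_ld(["s_sig", "s_in"], [50_000, 11_000], r2)
        gene = GeneModel("g1", "1", 10_000, 12_000)
        assert genes_linked([gene], ld, ["s_sig"]) == []  # strictly > 0.3

    def test_gene_without_snps_excluded(self, simple_region):
        gene = GeneModel("empty", "1", 200_000, 201_000)
        assert genes_linked([gene], simple_region, ["s_sig"]) == []

    def test_other_chromosome_skipped(self, simple_region):
        gene = GeneModel("g2", "2", 10_000, 12_000)
        assert genes_linked([gene], simple_region, ["s_sig"]) == []

    def test_monotone_in_r2_threshold(self, simple_region):
        gene = GeneModel("g1", "1", 10_000, 12_000)
        low = set(genes_linked([gene], simple_region, ["s_sig"], r2_min=0.1))
        high = set(genes_linked([gene], simple_region, ["s_sig"], r2_min=0.6))
        assert high <= low

    def test_dedup_across_regions(self, simple_region):
        gene = GeneModel("g1", "1", 10_000, 12_000)
        out = link_genes_across_qtls([gene], [simple_region, simple_region], ["s_sig"])
        assert out == ["g1"]

    def test_significant_snp_itself_inside_gene(self):
        # a significant SNP inside the gene trivially has r2 = 1 with itself
        r2 = np.array([[1.0]])
        ld = make_ld(["s_sig"], [11_000], r2)
        gene = GeneModel("g1", "1", 10_000, 12_000)
        assert genes_linked([gene], ld, ["s_sig"]) == ["g1"]


class TestEnrich:
    def _mapping(self, assignments):
        return pd.DataFrame(
            [{"gene_id": g, "term_id": t} for g, terms in assignments.items() for t in terms]
        )

    def test_worked_hypergeometric_example(self):
        N, K, n, k = 1000, 20, 10, 2
        background = [f"g{i}" for i in range(N)]
        query = background[:n]
        assignments = {g: ["T"] for g in background[: k]}  # 2 term genes in query
        assignments.update({g: ["T"] for g in background[n: n + (K - k)]})
        table = enrich(query, background, self._mapping(assignments))
        row = table.set_index("term_id").loc["T"]
        assert row["fold"] == pytest.approx((k / n) / (K / N))
        assert row["fold"] == pytest.approx(10.0)
        # independent tail sum with exact combinatorics
        p_exact = sum(
            math.comb(K, i) * math.comb(N - K, n - i) for i in range(k, min(n, K) + 1)
        ) / math.comb(N, n)
        assert row["p"] == pytest.approx(p_exact, rel=1e-10)

    def test_zero_overlap(self):
        background = [f"g{i}" for i in range(50)]
        mapping = self._mapping({background[-1]: ["T"]})
        table = enrich(background[:5], background, mapping)
        row = table.set_index("term_id").loc["T"]
        assert row["k"] == 0 and row["fold"] == 0.0 and row["p"] == 1.0

    def test_query_equals_background(self):
        background = [f"g{i}" for i in range(30)]
        mapping = self._mapping({g: ["A"] for g in background[:7]})
        table = enrich(background, background, mapping)
        row = table.set_index("term_id").loc["A"]
        assert row["fold"] == pytest.approx(1.0) and row["p"] == pytest.approx(1.0)

    def test_stray_query_gene_named(self):
        with pytest.raises(PhtmapError, match="ghost"):
            enrich(["ghost"], ["g1", "g2"], self._mapping({"g1": ["T"]}))

    def test_gene_order_invariance(self):
        rng = np.random.default_rng(0)
        background = [f"g{i}" for i in range(100)]
        mapping = self._mapping({g: ["T"] for g in rng.choice(background, 25, replace=False)})
        query = list(rng.choice(background, 12, replace=False))
        t1 = enrich(query, background, mapping)
        t2 = enrich(query[::-1], list(reversed(background)), mapping)
        pd.testing.assert_frame_equal(t1, t2)

    def test_fdr_is_bh_adjusted(self):
        background = [f"g{i}" for i in range(60)]
        mapping = self._mapping(
            {g: ["A"] for g in background[:10]} | {g: ["B"] for g in background[10:40]}
        )
        table = enrich(background[:10], background, mapping)
        assert (table["fdr"] >= table["p"] - 1e-15).all()


class TestFlags:
    def test_deg_threshold(self):
        deg = pd.DataFrame(
            {"gene_id": ["g1", "g2", "g3"], "fold": [2.5, 1.5, -3.0]}
        )
        out = flag_candidates(["g1", "g2", "g3", "g4"], deg_table=deg).set_index("gene_id")
        assert out.loc["g1", "deg_status"] == "up"
        assert out.loc["g2", "deg_status"] == "none"  # below the 2-fold gate
        assert out.loc["g3", "deg_status"] == "down"
        assert out.loc["g4", "deg_status"] == "none"

    def test_no_evidence_tables(self):
        out = flag_candidates(["g1", "g2"])
        assert list(out["gene_id"]) == ["g1", "g2"]
        assert (out["deg_status"] == "none").all()
        assert (~out["chloroplast"]).all()

    def test_chloroplast_flag(self):
        cc = pd.DataFrame({"gene_id": ["g1"], "term_id": ["GO:0009507"]})
        out = flag_candidates(["g1", "g2"], go_cc_mapping=cc).set_index("gene_id")
        assert bool(out.loc["g1", "chloroplast"]) and not bool(out.loc["g2", "chloroplast"])


class TestGff3:
    def test_gene_features_parsed(self, tmp_path):
        gff = tmp_path / "g.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "1\tsrc\tgene\t100\t500\t.\t+\t.\tID=geneA\n"
            "1\tsrc\tmRNA\t100\t500\t.\t+\t.\tID=t1;Parent=geneA\n"
            "2\tsrc\tgene\t900\t1200\t.\t-\t.\tID=geneB\n"
        )
        genes = read_gff3_genes(str(gff))
        assert [(g.gene_id, g.chromosome, g.start, g.end) for g in genes] == [
            ("geneA", "1", 100, 500),
            ("geneB", "2", 900, 1200),
        ]
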