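"""From QTLs to genes: LD-based linkage, GO over-representation, evidence flags.

A gene is *linked* to the mapping results when it contains at least one SNP
whose LD (r2) with a significant GWAS SNP exceeds a threshold (0.3 by
default), computed within a +/-500 kb window around each QTL peak.  Linked
genes are tested for Gene Ontology term over-representation against a
user-supplied gene -> term annotation with a one-sided hypergeometric test
and Benjamini-Hochberg FDR control, and can be cross-referenced with
differential-expression and curation tables to flag candidates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import PhtmapError
from .gwas import LdMatrix

__all__ = [
    "GeneModel",
    "read_gff3_genes",
    "read_term_mapping",
    "genes_linked",
    "link_genes_across_qtls",
    "enrich",
    "flag_candidates",
]

logger = logging.getLogger(__name__)

#: GO cellular-component term for chloroplast, used by the candidate flags.
CHLOROPLAST_GO = "GO:0009507"


@dataclass(frozen=True)
class GeneModel:
    """One annotated gene: 1-based inclusive coordinates, start <= end."""

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise PhtmapError(f"gene {self.gene_id}: start {self.start} > end {self.end}")

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end


def read_gff3_genes(path: str) -> list[GeneModel]:
    """Extract ``gene`` features from a GFF3 file; other types are ignored."""
    import gffutils

    db = gffutils.create_db(
        path, dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes = []
    for feat in db.features_of_type("gene"):
        gid = feat.attributes.get("ID", [feat.id])[0]
        genes.append(GeneModel(str(gid), str(feat.seqid), int(feat.start), int(feat.end),
                               feat.strand or "+"))
    return genes


def read_term_mapping(path: str) -> pd.DataFrame:
    """Two-column gene -> term TSV (GAF-like); extra columns are ignored."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"gene_id", "term_id"}.issubset(df.columns):
        df = pd.read_csv(path, sep="\t", header=None, dtype=str)
        df = df.iloc[:, :2]
        df.columns = ["gene_id", "term_id"]
    return df[[c for c in ("gene_id", "term_id", "term_name") if c in df.columns]]


def genes_linked(
    genes: list[GeneModel],
    ld: LdMatrix,
    significant_snp_ids,
    r2_min: float = 0.3,
) -> list[str]:
    """Genes containing >= 1 SNP in LD (r2 strictly above ``r2_min``) with
    >= 1 significant SNP, within one local-LD region.

    Genes on other chromosomes, or genes containing no SNP of the region,
    never qualify; the former are logged and skipped silently.
    """
    sig = [s for s in significant_snp_ids if s in ld.r2.index]
    if not sig or ld.r2.empty:
        return []
    r2_to_sig = ld.r2[sig].max(axis=1)  # best LD of each region SNP to any significant SNP
    pos = ld.positions
    linked = []
    for gene in genes:
        if gene.chromosome != ld.chrom:
            logger.debug("gene %s on chromosome %s outside LD region (%s); skipped",
                         gene.gene_id, gene.chromosome, ld.chrom)
            continue
        in_gene = pos[(pos >= gene.start) & (pos <= gene.end)].index
        if len(in_gene) == 0:
            continue
        if float(r2_to_sig.loc[in_gene].max()) > r2_min:
            linked.append(gene.gene_id)
    return linked


def link_genes_across_qtls(
    genes: list[GeneModel],
    ld_regions: list[LdMatrix],
    significant_snp_ids,
    r2_min: float = 0.3,
) -> list[str]:
    """Union of linked genes over all QTL LD regions, deduplicated, in
    first-seen order."""
    seen: dict[str, None] = {}
    for ld in ld_regions:
        for gid in genes_linked(genes, ld, significant_snp_ids, r2_min):
            seen.setdefault(gid, None)
    return list(seen)


# ---------------------------------------------------------------------------
# GO over-representation


def enrich(
    query_genes,
    background_genes,
    mapping: pd.DataFrame,
    term_names: dict[str, str] | None = None,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of annotation terms.

    For a term annotating K of the N background genes, of which k fall in
    the size-n query, ``p = P[X >= k]`` for X hypergeometric(N, K, n) and
    ``fold = (k/n) / (K/N)``.  Terms absent from the background (K = 0)
    are skipped; p-values are BH-adjusted across the tested terms.

    Returns a DataFrame sorted by p with columns
    ``term_id, term_name, k, n, K, N, fold, p, fdr``.
    """
    query = list(dict.fromkeys(str(g) for g in query_genes))
    background = set(str(g) for g in background_genes)
    stray = [g for g in query if g not in background]
    if stray:
        raise PhtmapError(f"query genes absent from background: {stray}")
    ann = mapping[mapping["gene_id"].astype(str).isin(background)]
    names = dict(term_names or {})
    if "term_name" in ann.columns:
        names.update(dict(zip(ann["term_id"], ann["term_name"].fillna(""))))
    by_term = ann.groupby("term_id")["gene_id"].apply(lambda s: set(s.astype(str)))
    N = len(background)
    n = len(query)
    qset = set(query)
    rows = []
    for term_id, term_genes in by_term.items():
        K = len(term_genes)
        if K == 0:
            continue
        k = len(term_genes & qset)
        fold = (k / n) / (K / N) if n > 0 else 0.0
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if k > 0 else 1.0
        rows.append({"term_id": term_id, "term_name": names.get(term_id, ""),
                     "k": k, "n": n, "K": K, "N": N, "fold": fold, "p": min(p, 1.0)})
    out = pd.DataFrame(rows, columns=["term_id", "term_name", "k", "n", "K", "N", "fold", "p"])
    if len(out):
        out["fdr"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
        out = out.sort_values(["p", "term_id"], kind="stable").reset_index(drop=True)
    else:
        out["fdr"] = pd.Series(dtype=float)
    return out


# ---------------------------------------------------------------------------
# candidate flags


def flag_candidates(
    gene_ids,
    deg_table: pd.DataFrame | None = None,
    go_cc_mapping: pd.DataFrame | None = None,
    curation_table: pd.DataFrame | None = None,
    fold_threshold: float = 2.0,
    chloroplast_term: str = CHLOROPLAST_GO,
) -> pd.DataFrame:
    """Join optional evidence tables onto a linked-gene list.

    ``deg_table`` needs ``gene_id`` plus either ``fold`` (signed or with a
    ``direction`` column) or ``log2fc``; a gene is flagged up/down only
    when its absolute fold change strictly exceeds ``fold_threshold``.
    ``go_cc_mapping`` is a gene -> GO cellular-component table; genes
    annotated to the chloroplast term are flagged.  ``curation_table``
    contributes a free-text ``function_note``.
    """
    gene_ids = [str(g) for g in gene_ids]
    out = pd.DataFrame({"gene_id": gene_ids})
    out["deg_status"] = "none"
    out["chloroplast"] = False
    out["function_note"] = ""

    if deg_table is not None and len(deg_table):
        deg = deg_table.copy()
        deg["gene_id"] = deg["gene_id"].astype(str)
        if "fold" in deg.columns:
            fold = deg["fold"].astype(float)
        elif "log2fc" in deg.columns:
            fold = np.sign(deg["log2fc"].astype(float)) * 2.0 ** deg["log2fc"].abs().astype(float)
        else:
            raise PhtmapError("DEG table needs a 'fold' or 'log2fc' column")
        if "direction" in deg.columns:
            direction = deg["direction"].astype(str).str.lower()
        else:
            direction = pd.Series(np.where(fold >= 0, "up", "down"), index=deg.index)
        status = np.where(fold.abs() > fold_threshold, direction, "none")
        deg_status = pd.Series(status, index=deg["gene_id"])
        deg_status = deg_status[~deg_status.index.duplicated()]
        out["deg_status"] = out["gene_id"].map(deg_status).fillna("none")

    if go_cc_mapping is not None and len(go_cc_mapping):
        chloro = set(
            go_cc_mapping.loc[
                go_cc_mapping["term_id"].astype(str) == chloroplast_term, "gene_id"
            ].astype(str)
        )
        out["chloroplast"] = out["gene_id"].isin(chloro)

    if curation_table is not None and len(curation_table):
        cur = curation_table.copy()
        cur["gene_id"] = cur["gene_id"].astype(str)
        note_col = "function_note" if "function_note" in cur.columns else cur.columns[1]
        notes = pd.Series(cur[note_col].astype(str).values, index=cur["gene_id"])
        notes = notes[~notes.index.duplicated()]
        out["function_note"] = out["gene_id"].map(notes).fillna("")

    return out
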