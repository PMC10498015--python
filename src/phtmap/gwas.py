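"""Kinship-corrected genome-wide association scan and QTL definition.

The scan follows the efficient mixed-model approximation: variance
components of ``y = mu + g + e`` with ``g ~ N(0, s2_g K)`` are estimated
once under the no-SNP null (restricted likelihood over the spectral
decomposition of the kinship matrix K), the phenotype and design are
whitened by the fitted covariance, and each SNP is then tested with a
generalized-least-squares slope test.  Significant SNPs are grouped into
QTLs by greedy, p-value-ranked clumping within distance (optionally LD)
windows; clumps with fewer than two significant SNPs are discarded as
likely false positives.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import FitError, GenotypeInputError

__all__ = [
    "GenotypeMatrix",
    "KinshipMatrix",
    "LdMatrix",
    "Clump",
    "Qtl",
    "filter_snps",
    "impute_mean",
    "kinship",
    "MixedModelScan",
    "ScanResults",
    "qq_lambda",
    "significant_snps",
    "clump",
    "qtls_from_clumps",
    "local_ld",
]

SNP_COLUMNS = ["snp_id", "chrom", "pos"]

#: Median of the 1-df chi-square distribution, the QQ-inflation reference.
CHI2_MEDIAN = float(stats.chi2.ppf(0.5, df=1))


@dataclass
class GenotypeMatrix:
    """Biallelic dosages (0/1/2, NaN = missing) for accessions x SNPs."""

    accessions: list[str]
    snps: pd.DataFrame  # columns snp_id, chrom, pos (1-based bp)
    dosages: np.ndarray  # (n_accessions, n_snps) float

    def __post_init__(self) -> None:
        self.snps = self.snps.reset_index(drop=True)
        if self.dosages.shape != (len(self.accessions), len(self.snps)):
            raise GenotypeInputError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.accessions)} accessions x {len(self.snps)} SNPs"
            )
        missing = set(SNP_COLUMNS) - set(self.snps.columns)
        if missing:
            raise GenotypeInputError(f"SNP map lacks columns: {sorted(missing)}")

    @property
    def n_accessions(self) -> int:
        return len(self.accessions)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def maf(self) -> np.ndarray:
        """Per-SNP minor-allele frequency from non-missing calls."""
        with np.errstate(invalid="ignore"):
            p = np.nanmean(self.dosages, axis=0) / 2.0
        return np.minimum(p, 1.0 - p)

    def missing_fraction(self) -> np.ndarray:
        return np.mean(np.isnan(self.dosages), axis=0)

    def subset_snps(self, mask: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            accessions=list(self.accessions),
            snps=self.snps.loc[np.asarray(mask)].reset_index(drop=True),
            dosages=self.dosages[:, np.asarray(mask)],
        )

    def subset_accessions(self, keep: list[str]) -> "GenotypeMatrix":
        idx = [self.accessions.index(a) for a in keep]
        return GenotypeMatrix(list(keep), self.snps.copy(), self.dosages[idx])


@dataclass
class KinshipMatrix:
    accessions: list[str]
    values: np.ndarray
    method: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.accessions, columns=self.accessions)


def filter_snps(G: GenotypeMatrix, maf_min: float = 0.05, miss_max: float = 0.1) -> GenotypeMatrix:
    """Keep SNPs with MAF strictly above ``maf_min`` and missingness strictly
    below ``miss_max``; SNP order is preserved."""
    keep = (G.maf() > maf_min) & (G.missing_fraction() < miss_max)
    return G.subset_snps(keep)


def impute_mean(G: GenotypeMatrix) -> GenotypeMatrix:
    """Replace missing dosages with the per-SNP mean of the observed calls."""
    dos = G.dosages.copy()
    nan_mask = np.isnan(dos)
    if nan_mask.all(axis=0).any():
        bad = G.snps.loc[nan_mask.all(axis=0), "snp_id"].tolist()
        raise GenotypeInputError(f"all-missing SNPs cannot be mean-imputed: {bad}")
    if nan_mask.any():
        col_means = np.nanmean(dos, axis=0)
        dos[nan_mask] = np.broadcast_to(col_means, dos.shape)[nan_mask]
    return GenotypeMatrix(list(G.accessions), G.snps.copy(), dos)


def kinship(G: GenotypeMatrix, method: str = "vanraden") -> KinshipMatrix:
    """Marker-based relatedness matrix.

    ``vanraden``: centred cross-product of dosages scaled by
    ``2 * sum p(1-p)`` (a genomic relationship matrix).  ``ibs``: mean
    allele-sharing proportion, ``1 - |d_i - d_j| / 2`` averaged over SNPs.
    Requires an imputed (missing-free) matrix with >= 2 SNPs.
    """
    dos = G.dosages
    if np.isnan(dos).any():
        raise GenotypeInputError("kinship requires an imputed (missing-free) matrix")
    if G.n_snps < 2:
        raise GenotypeInputError("kinship requires >= 2 SNPs")
    if method == "vanraden":
        p = dos.mean(axis=0) / 2.0
        denom = 2.0 * np.sum(p * (1.0 - p))
        if denom <= 0:
            raise GenotypeInputError("zero-variance SNP set: cannot scale kinship")
        W = dos - 2.0 * p
        K = (W @ W.T) / denom
    elif method == "ibs":
        n = G.n_accessions
        K = np.empty((n, n))
        for i in range(n):
            K[i] = 1.0 - np.mean(np.abs(dos - dos[i]), axis=1) / 2.0
    else:
        raise ValueError(f"unknown kinship method: {method!r}")
    return KinshipMatrix(list(G.accessions), K, method)


# ---------------------------------------------------------------------------
# EMMAX-style scan


class MixedModelScan:
    """Single-SNP mixed-model association scan.

    Parameters
    ----------
    y : Series
        Phenotype (genotype adjusted means), indexed by accession.
    G : GenotypeMatrix
        Imputed dosages; accessions are intersected with ``y``.
    K : KinshipMatrix
        Relatedness matrix on (a superset of) the same accessions.
    covariates : DataFrame, optional
        Fixed covariates indexed by accession.
    """

    def __init__(
        self,
        y: pd.Series,
        G: GenotypeMatrix,
        K: KinshipMatrix,
        covariates: pd.DataFrame | None = None,
    ):
        common = [a for a in G.accessions if a in set(y.index) & set(K.accessions)]
        if len(common) < 10:
            raise FitError(f"only {len(common)} accessions shared between y, G and K")
        self.G = G.subset_accessions(common) if common != G.accessions else G
        kf = K.to_frame().loc[common, common]
        self.K = kf.to_numpy()
        self.y = y.loc[common].to_numpy(dtype=float)
        self.accessions = common
        if np.ptp(self.y) <= 0:
            raise FitError("constant phenotype")
        X = [np.ones(len(common))]
        if covariates is not None:
            X.extend(covariates.loc[common].to_numpy(dtype=float).T)
        self.X = np.column_stack(X)

    def fit(self) -> "ScanResults":
        n, p = self.X.shape
        s, U = np.linalg.eigh((self.K + self.K.T) / 2.0)
        if s[0] < -1e-6 * max(1.0, s[-1]):
            raise FitError(f"kinship matrix not positive semidefinite (min eig {s[0]:.3g})")
        s = np.maximum(s, 0.0)
        yr = U.T @ self.y
        Xr = U.T @ self.X

        def neg_restricted_ll(log_delta: float) -> float:
            delta = np.exp(log_delta)
            w = 1.0 / (s + delta)
            Xw = Xr * w[:, None]
            XtWX = Xr.T @ Xw
            try:
                beta = np.linalg.solve(XtWX, Xw.T @ yr)
            except np.linalg.LinAlgError:
                return np.inf
            r = yr - Xr @ beta
            rss = float(r @ (w * r))
            if rss <= 0:
                return np.inf
            dof = n - p
            sign, logdet_XtWX = np.linalg.slogdet(XtWX)
            if sign <= 0:
                return np.inf
            return (
                dof * np.log(rss / dof)
                - np.sum(np.log(w))
                + logdet_XtWX
            )

        grid = np.linspace(-10.0, 10.0, 41)
        vals = [neg_restricted_ll(g) for g in grid]
        i = int(np.argmin(vals))
        lo, hi = grid[max(i - 1, 0)], grid[min(i + 1, len(grid) - 1)]
        res = optimize.minimize_scalar(
            neg_restricted_ll, bounds=(lo, hi), method="bounded", options={"xatol": 1e-8}
        )
        log_delta = float(res.x) if res.fun <= vals[i] else float(grid[i])
        delta = float(np.exp(log_delta))

        w = 1.0 / (s + delta)
        Xw = Xr * w[:, None]
        beta0 = np.linalg.solve(Xr.T @ Xw, Xw.T @ yr)
        r = yr - Xr @ beta0
        sigma_g2 = float(r @ (w * r)) / (n - p)
        sigma_e2 = delta * sigma_g2

        # whiten once, then vectorized GLS slope tests
        sw = np.sqrt(w)
        yt = sw * yr
        Xt = Xr * sw[:, None]
        Gt = (U.T @ self.G.dosages) * sw[:, None]
        # residualize on the fixed design
        Q, _ = np.linalg.qr(Xt)
        yt_r = yt - Q @ (Q.T @ yt)
        Gt_r = Gt - Q @ (Q.T @ Gt)
        gg = np.einsum("ij,ij->j", Gt_r, Gt_r)
        gy = Gt_r.T @ yt_r
        dof = n - p - 1
        with np.errstate(divide="ignore", invalid="ignore"):
            beta = gy / gg
            rss = float(yt_r @ yt_r) - beta * gy
            sigma2 = rss / dof
            se = np.sqrt(sigma2 / gg)
            tstat = beta / se
        pvals = 2.0 * stats.t.sf(np.abs(tstat), dof)
        degenerate = ~np.isfinite(tstat)
        beta = np.where(degenerate, np.nan, beta)
        se = np.where(degenerate, np.nan, se)
        pvals = np.where(degenerate, np.nan, pvals)
        pvals = np.clip(pvals, np.finfo(float).tiny, 1.0)
        pvals[degenerate] = np.nan

        table = self.G.snps.copy()
        table["maf"] = self.G.maf()
        table["beta"] = beta
        table["se"] = se
        table["p"] = pvals
        table["n_used"] = n
        return ScanResults(
            table=table,
            sigma_g2=sigma_g2,
            sigma_e2=sigma_e2,
            delta=delta,
            accessions=list(self.accessions),
        )


@dataclass
class ScanResults:
    """Per-SNP effects and p-values from a mixed-model scan."""

    table: pd.DataFrame
    sigma_g2: float
    sigma_e2: float
    delta: float
    accessions: list[str] = field(default_factory=list)

    @property
    def pseudo_h2(self) -> float:
        """Marker-based variance share under the null model."""
        return self.sigma_g2 / (self.sigma_g2 + self.sigma_e2)

    def lambda_gc(self) -> float:
        p = self.table["p"].dropna().to_numpy()
        return qq_lambda(p)[1]

    def qq_data(self) -> pd.DataFrame:
        return qq_lambda(self.table["p"].dropna().to_numpy())[0]

    def significant(self, neglog10_threshold: float = 4.0) -> pd.DataFrame:
        return significant_snps(self, neglog10_threshold)

    def summary(self) -> str:
        lam = self.lambda_gc()
        return "\n".join(
            [
                "Mixed-model association scan (EMMAX approximation)",
                f"  accessions        : {len(self.accessions)}",
                f"  SNPs tested       : {len(self.table)}",
                f"  s2 polygenic      : {self.sigma_g2:.6g}",
                f"  s2 residual       : {self.sigma_e2:.6g}",
                f"  pseudo-h2 (null)  : {self.pseudo_h2:.3f}",
                f"  inflation lambda  : {lam:.3f}",
            ]
        )

    def plot_qq(self, ax=None):
        import matplotlib.pyplot as plt

        qq = self.qq_data()
        if ax is None:
            _, ax = plt.subplots()
        ax.scatter(qq["expected"], qq["observed"], s=4, color="k")
        m = float(qq["expected"].max())
        ax.plot([0, m], [0, m], color="red", lw=1)
        ax.set_xlabel("expected -log10 p")
        ax.set_ylabel("observed -log10 p")
        ax.set_title(f"QQ (lambda = {self.lambda_gc():.3f})")
        return ax

    def plot_manhattan(self, neglog10_threshold: float = 4.0, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(9, 3))
        offset = 0.0
        ticks, labels = [], []
        for i, (chrom, grp) in enumerate(self.table.groupby("chrom", sort=True)):
            x = grp["pos"].to_numpy() + offset
            ax.scatter(x, -np.log10(grp["p"]), s=3,
                       color="steelblue" if i % 2 == 0 else "darkorange")
            ticks.append(offset + grp["pos"].mean())
            labels.append(str(chrom))
            offset += grp["pos"].max() + 1
        ax.axhline(neglog10_threshold, color="red", lw=1)
        ax.set_xticks(ticks, labels)
        ax.set_xlabel("chromosome")
        ax.set_ylabel("-log10 p")
        return ax


def qq_lambda(p_values) -> tuple[pd.DataFrame, float]:
    """QQ quantile pairs and the genomic-inflation factor.

    Lambda is the median of the 1-df chi-square quantiles of the observed
    p-values divided by the chi-square median (0.4549...).
    """
    p = np.asarray(p_values, dtype=float)
    p = p[np.isfinite(p)]
    if p.size < 1:
        raise ValueError("no finite p-values")
    chi = stats.chi2.isf(p, df=1)
    lam = float(np.median(chi) / CHI2_MEDIAN)
    obs = np.sort(-np.log10(p))[::-1]
    n = p.size
    exp = -np.log10((np.arange(1, n + 1) - 0.5) / n)
    pairs = pd.DataFrame({"expected": exp, "observed": obs})
    return pairs, lam


def significant_snps(scan: ScanResults, neglog10_threshold: float = 4.0) -> pd.DataFrame:
    """SNPs at or above the -log10 p threshold (boundary included)."""
    tab = scan.table
    with np.errstate(divide="ignore"):
        keep = -np.log10(tab["p"].to_numpy(dtype=float)) >= neglog10_threshold
    keep &= np.isfinite(tab["p"].to_numpy(dtype=float))
    return tab.loc[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# clumping / QTLs / LD


@dataclass
class Clump:
    index_snp: str
    chrom: str
    peak_pos: int
    peak_p: float
    members: pd.DataFrame  # rows of the significant table assigned here

    @property
    def n_members(self) -> int:
        return len(self.members)


@dataclass
class Qtl:
    qtl_id: str
    chrom: str
    start: int
    end: int
    peak: int
    members: list[str]

    @property
    def n_significant(self) -> int:
        return len(self.members)


def _r2_vector(dosages: np.ndarray, index_col: int) -> np.ndarray:
    x = dosages[:, index_col]
    xc = x - x.mean()
    D = dosages - dosages.mean(axis=0)
    num = D.T @ xc
    den = np.sqrt((D * D).sum(axis=0) * float(xc @ xc))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = num / den
    return r * r


def clump(
    significant: pd.DataFrame,
    window_kb: float,
    r2_min: float | None = None,
    G: GenotypeMatrix | None = None,
) -> list[Clump]:
    """Greedy p-value-ranked clumping of significant SNPs.

    The smallest-p unassigned SNP becomes an index; every unassigned
    significant SNP on the same chromosome within ``window_kb`` kilobases
    of it (and, when ``r2_min`` is set, in LD r2 >= r2_min with it) joins
    its clump.  Repeats until all SNPs are assigned.  Ties in p are broken
    by position, then snp_id, for determinism.
    """
    if r2_min is not None and G is None:
        raise ValueError("r2_min requires the genotype matrix G")
    if len(significant) == 0:
        return []
    df = significant.sort_values(["p", "chrom", "pos", "snp_id"], kind="stable").reset_index(drop=True)
    window_bp = float(window_kb) * 1000.0
    assigned = np.zeros(len(df), dtype=bool)
    clumps: list[Clump] = []
    col_of = {}
    if G is not None:
        col_of = {sid: j for j, sid in enumerate(G.snps["snp_id"])}
    for i in range(len(df)):
        if assigned[i]:
            continue
        idx_row = df.iloc[i]
        mask = (
            ~assigned
            & (df["chrom"] == idx_row["chrom"]).to_numpy()
            & (np.abs(df["pos"].to_numpy(dtype=float) - float(idx_row["pos"])) <= window_bp)
        )
        if r2_min is not None:
            r2 = _r2_vector(G.dosages, col_of[idx_row["snp_id"]])
            snp_r2 = np.array([r2[col_of[s]] for s in df["snp_id"]])
            mask &= (snp_r2 >= r2_min) | (df["snp_id"] == idx_row["snp_id"]).to_numpy()
        members = df.loc[mask].sort_values(["pos", "snp_id"]).reset_index(drop=True)
        assigned |= mask
        clumps.append(
            Clump(
                index_snp=str(idx_row["snp_id"]),
                chrom=str(idx_row["chrom"]),
                peak_pos=int(idx_row["pos"]),
                peak_p=float(idx_row["p"]),
                members=members,
            )
        )
    return clumps


def qtls_from_clumps(clumps: list[Clump], min_snps: int = 2) -> list[Qtl]:
    """Promote clumps with >= ``min_snps`` members to QTL records."""
    qtls = []
    for c in clumps:
        if c.n_members < min_snps:
            continue
        positions = c.members["pos"].astype(int)
        qtls.append(
            Qtl(
                qtl_id=f"qtl-{c.chrom}-{c.peak_pos}",
                chrom=c.chrom,
                start=int(positions.min()),
                end=int(positions.max()),
                peak=c.peak_pos,
                members=[str(s) for s in c.members["snp_id"]],
            )
        )
    return qtls


def qtls_to_frame(qtls: list[Qtl]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "qtl_id": q.qtl_id,
                "chrom": q.chrom,
                "start": q.start,
                "end": q.end,
                "peak": q.peak,
                "n_significant": q.n_significant,
                "members": ";".join(q.members),
            }
            for q in qtls
        ],
        columns=["qtl_id", "chrom", "start", "end", "peak", "n_significant", "members"],
    )


@dataclass
class LdMatrix:
    """Pairwise r2 among the SNPs of one genomic window."""

    chrom: str
    r2: pd.DataFrame  # square, indexed by snp_id
    positions: pd.Series  # snp_id -> bp

    @property
    def snp_ids(self) -> list[str]:
        return list(self.r2.index)


def local_ld(
    G: GenotypeMatrix,
    chromosome: str,
    center: int,
    flank: int = 500_000,
) -> LdMatrix:
    """r2 between every SNP pair within ``center +/- flank`` on a chromosome.

    r2 is the squared Pearson correlation of the (imputed) dosage vectors.
    SNPs with zero dosage variance get NaN entries (undefined LD) but keep
    a unit diagonal.
    """
    snps = G.snps
    mask = (snps["chrom"].astype(str) == str(chromosome)) & (
        (snps["pos"] >= center - flank) & (snps["pos"] <= center + flank)
    )
    sub = G.subset_snps(mask.to_numpy())
    dos = sub.dosages
    if np.isnan(dos).any():
        raise GenotypeInputError("local_ld requires imputed dosages")
    ids = list(sub.snps["snp_id"].astype(str))
    if len(ids) == 0:
        return LdMatrix(str(chromosome), pd.DataFrame(), pd.Series(dtype=int))
    D = dos - dos.mean(axis=0)
    norms = np.sqrt((D * D).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        C = (D.T @ D) / np.outer(norms, norms)
    r2 = C * C
    np.fill_diagonal(r2, 1.0)
    r2_df = pd.DataFrame(r2, index=ids, columns=ids)
    pos = pd.Series(sub.snps["pos"].to_numpy(dtype=int), index=ids, name="pos")
    return LdMatrix(str(chromosome), r2_df, pos)
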