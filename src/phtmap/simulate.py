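"""Truth-known synthetic data for every pipeline stage.

The generator emulates the structure of a rice photosynthetic-heat-
tolerance screen: LD-structured biallelic genotypes for a panel of
accessions, a handful of causal loci acting on the thermal-curve
breakpoint, a replicated measurement design (plants nested in growth
containers of 48, measured in round x time batches), and noisy piecewise-
linear Fv/Fm ramps over 25-55 degC.  Everything is deterministic given the
seed, with one pseudo-random stream per logical component (genotypes,
design, effects, noise) so parts can be regenerated independently.

What it does *not* emulate: coalescent demography, strong population
structure (beyond an optional two-subpopulation split used in calibration
tests), epistasis, or instrument-level artifacts.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .curves import FluorescenceCurve, FluorescencePoint, SampleMeta
from .errors import PhtmapError
from .gwas import GenotypeMatrix

__all__ = [
    "SimConfig",
    "TruthBundle",
    "simulate_genotypes",
    "simulate_thermal_population",
    "expected_h2",
    "write_fixture_bundle",
    "PRESETS",
]


@dataclass
class SimConfig:
    """Generator settings; the defaults are the study-like conditions.

    Variance targets are on the breakpoint trait (degC^2); ``h2`` implied
    by the defaults is 0.6.  Slope baselines and the physiological Fv/Fm
    ceiling follow values typical of rice ramp screens.
    """

    seed: int = 0
    # panel / design
    n_accessions: int = 150
    n_plants_per_accession: int = 4
    plants_per_container: int = 48
    samples_per_round: int = 110
    # genome
    n_chromosomes: int = 2
    n_snps: int = 2000
    snp_spacing_bp: int = 10_000
    ld_decay_bp: float = 150_000.0
    n_founders: int = 16
    maf_range: tuple[float, float] = (0.05, 0.5)
    missing_rate: float = 0.01
    # genetics of the breakpoint trait
    n_causal: int = 3
    causal_maf_min: float = 0.15
    sigma2_g: float = 0.3
    sigma2_rt: float = 0.08
    sigma2_c: float = 0.05
    sigma2_e: float = 0.07
    # thermal-curve baselines; m2 is kept shallow enough that the
    # two-segment truth stays non-negative over the ramp for typical
    # breakpoints, so the physiological floor rarely truncates curves
    baseline_psi: float = 48.0
    baseline_m1: float = -0.005
    baseline_m2: float = -0.095
    baseline_fvfm25: float = 0.80
    m1_sd: float = 0.0005
    m2_sd: float = 0.008
    m2_psi_coupling: float = 0.0
    measurement_noise_sd: float = 0.02
    fvfm_ceiling: float = 0.85
    ramp: tuple[float, float, float] = (25.0, 55.0, 1.0)  # start, stop, step

    def ramp_grid(self) -> np.ndarray:
        start, stop, step = self.ramp
        return np.arange(start, stop + step / 2, step)

    def validate(self) -> None:
        for name in ("sigma2_g", "sigma2_rt", "sigma2_c", "sigma2_e"):
            if getattr(self, name) < 0:
                raise PhtmapError(f"{name} must be >= 0")
        if self.n_snps < self.n_chromosomes:
            raise PhtmapError("n_snps must be >= n_chromosomes")
        if self.sigma2_g > 0 and self.n_causal == 0:
            raise PhtmapError("sigma2_g > 0 requires at least one causal SNP")


def expected_h2(config: SimConfig) -> float:
    """Closed-form heritability implied by the configured variances."""
    total = config.sigma2_g + config.sigma2_rt + config.sigma2_c + config.sigma2_e
    if total == 0:
        raise PhtmapError("all variance components are zero")
    return config.sigma2_g / total


@dataclass
class TruthBundle:
    """Ground truth saved alongside a simulated dataset."""

    causal_snps: list[str]
    causal_effects: list[float]
    genetic_values: pd.Series  # accession -> breakpoint genetic value
    plant_truth: pd.DataFrame  # sample_id, psi, m1, m2, fvfm25
    expected_h2: float
    n_clipped_points: int = 0

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "causal_snps": self.causal_snps,
                    "causal_effects": self.causal_effects,
                    "genetic_values": self.genetic_values.to_dict(),
                    "plant_truth": self.plant_truth.to_dict(orient="list"),
                    "expected_h2": self.expected_h2,
                    "n_clipped_points": self.n_clipped_points,
                },
                fh,
                indent=2,
            )


def _streams(seed: int) -> dict[str, np.random.Generator]:
    names = ("genotypes", "design", "effects", "noise")
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def simulate_genotypes(config: SimConfig, rng: np.random.Generator | None = None) -> GenotypeMatrix:
    """LD-structured genotypes by Markov haplotype copying from founders.

    Per chromosome, founder haplotypes are themselves generated as Markov
    chains along the SNP map: at inter-SNP distance d an allele persists
    from the previous site with probability ``exp(-d / ld_decay_bp)`` and
    is otherwise redrawn at that site's frequency (inside ``maf_range``),
    so the founder pool carries block-like LD on the decay scale.  Each
    accession haplotype then copies a founder, switching to a random
    founder between adjacent SNPs with probability
    ``1 - exp(-d / ld_decay_bp)``.  Two independent haplotypes per
    accession give dosages in {0, 1, 2}.  In the limits, a zero decay
    scale yields independent SNPs and an infinite one yields constant
    founders copied whole, i.e. perfect local LD.
    """
    config.validate()
    if rng is None:
        rng = _streams(config.seed)["genotypes"]
    n_acc = config.n_accessions
    per_chrom = np.full(config.n_chromosomes, config.n_snps // config.n_chromosomes)
    per_chrom[: config.n_snps % config.n_chromosomes] += 1
    snp_rows = []
    dosage_blocks = []
    for ci, n_c in enumerate(per_chrom, start=1):
        gaps = rng.uniform(0.5, 1.5, size=n_c) * config.snp_spacing_bp
        pos = np.cumsum(gaps).astype(int) + 1
        freqs = rng.uniform(*config.maf_range, size=n_c)
        if config.ld_decay_bp > 0:
            stay_p = np.exp(-np.diff(pos) / config.ld_decay_bp)
        else:
            stay_p = np.zeros(n_c - 1)
        switch_p = 1.0 - stay_p
        # founder pool with internal block LD: alleles persist along the
        # chromosome on the same decay scale, else are redrawn at the
        # site frequency
        founders = np.empty((config.n_founders, n_c), dtype=np.int8)
        founders[:, 0] = rng.random(config.n_founders) < freqs[0]
        fresh = rng.random((config.n_founders, n_c)) < freqs
        persist = rng.random((config.n_founders, n_c - 1)) < stay_p
        for j in range(1, n_c):
            founders[:, j] = np.where(persist[:, j - 1], founders[:, j - 1], fresh[:, j])
        dos = np.zeros((n_acc, n_c))
        for _hap in range(2):
            idx = rng.integers(0, config.n_founders, size=n_acc)
            hap = np.empty((n_acc, n_c), dtype=np.int8)
            hap[:, 0] = founders[idx, 0]
            switches = rng.random((n_acc, n_c - 1)) < switch_p
            new_idx = rng.integers(0, config.n_founders, size=(n_acc, n_c - 1))
            for j in range(1, n_c):
                idx = np.where(switches[:, j - 1], new_idx[:, j - 1], idx)
                hap[:, j] = founders[idx, j]
            dos += hap
        if config.missing_rate > 0:
            miss = rng.random(dos.shape) < config.missing_rate
            dos = np.where(miss, np.nan, dos)
        dosage_blocks.append(dos)
        for j in range(n_c):
            snp_rows.append({"snp_id": f"snp_{ci}_{pos[j]}", "chrom": str(ci), "pos": int(pos[j])})
    accessions = [f"acc{i:04d}" for i in range(n_acc)]
    return GenotypeMatrix(accessions, pd.DataFrame(snp_rows), np.hstack(dosage_blocks))


def _assign_design(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Randomized plant -> container and plant -> measurement batch map."""
    rows = []
    for i in range(config.n_accessions):
        for r in range(config.n_plants_per_accession):
            rows.append({"sample_id": f"acc{i:04d}_p{r}", "genotype_id": f"acc{i:04d}"})
    df = pd.DataFrame(rows)
    n = len(df)
    order = rng.permutation(n)
    container = np.empty(n, dtype=object)
    container[order] = [f"cont{j // config.plants_per_container:02d}" for j in range(n)]
    order2 = rng.permutation(n)
    batch = np.empty(n, dtype=int)
    batch[order2] = np.arange(n) // config.samples_per_round
    df["container_id"] = container
    df["round_id"] = [f"round{b // 2 + 1:02d}" for b in batch]
    df["time_slot"] = ["am" if b % 2 == 0 else "pm" for b in batch]
    df["species"] = "sim"
    return df


def simulate_thermal_population(
    config: SimConfig, G: GenotypeMatrix
) -> tuple[list[FluorescenceCurve], pd.DataFrame, TruthBundle]:
    """Simulate noisy Fv/Fm ramps for a replicated panel.

    Causal SNPs (drawn among those with MAF above ``causal_maf_min``)
    shift each accession's breakpoint; the genetic values are rescaled so
    their panel variance equals ``sigma2_g``.  Per plant, the breakpoint
    adds the round x time, container and residual draws; the piecewise-
    linear truth plus Gaussian measurement noise, clipped to the
    physiological ceiling, gives the observed ramp.
    """
    config.validate()
    streams = _streams(config.seed)
    rng_eff = streams["effects"]
    rng_noise = streams["noise"]
    design = _assign_design(config, streams["design"])

    # accession-level genetic values from causal dosages
    maf = G.maf()
    eligible = np.where(maf >= config.causal_maf_min)[0]
    if config.n_causal > 0 and config.sigma2_g > 0:
        if eligible.size < config.n_causal:
            raise PhtmapError("not enough common SNPs to place causal loci")
        causal_idx = np.sort(rng_eff.choice(eligible, size=config.n_causal, replace=False))
        effects = rng_eff.normal(0.0, 1.0, size=config.n_causal)
        dos = np.nan_to_num(G.dosages[:, causal_idx], nan=1.0)
        raw = (dos - dos.mean(axis=0)) @ effects
        sd = raw.std()
        if sd == 0:
            raise PhtmapError("causal loci carry no dosage variance")
        scale = np.sqrt(config.sigma2_g) / sd
        genetic = raw * scale
        effects = effects * scale
        causal_ids = [str(G.snps.loc[j, "snp_id"]) for j in causal_idx]
    else:
        genetic = np.zeros(G.n_accessions)
        effects = np.array([])
        causal_ids = []
    gvalues = pd.Series(genetic, index=G.accessions, name="genetic_value")

    rt_levels = sorted(set(zip(design["round_id"], design["time_slot"])))
    c_levels = sorted(set(design["container_id"]))
    rt_eff = dict(zip(rt_levels, rng_eff.normal(0, np.sqrt(config.sigma2_rt), len(rt_levels))))
    c_eff = dict(zip(c_levels, rng_eff.normal(0, np.sqrt(config.sigma2_c), len(c_levels))))

    grid = config.ramp_grid()
    t_lo, t_hi = grid.min() + 2.0, grid.max() - 2.0
    curves = []
    truth_rows = []
    n_clipped = 0
    for row in design.itertuples(index=False):
        resid = rng_noise.normal(0, np.sqrt(config.sigma2_e))
        psi = (
            config.baseline_psi
            + float(gvalues[row.genotype_id])
            + rt_eff[(row.round_id, row.time_slot)]
            + c_eff[row.container_id]
            + resid
        )
        psi = float(np.clip(psi, t_lo, t_hi))
        m1 = config.baseline_m1 + rng_noise.normal(0, config.m1_sd)
        m2 = (
            config.baseline_m2
            + config.m2_psi_coupling * (psi - config.baseline_psi)
            + rng_noise.normal(0, config.m2_sd)
        )
        truth = (
            config.baseline_fvfm25
            + m1 * (grid - grid[0])
            + (m2 - m1) * np.maximum(0.0, grid - psi)
        )
        noisy = truth + rng_noise.normal(0, config.measurement_noise_sd, size=grid.size)
        clipped = np.clip(noisy, 0.0, config.fvfm_ceiling)
        n_clipped += int(np.sum(clipped != noisy))
        meta = SampleMeta(
            sample_id=row.sample_id,
            genotype_id=row.genotype_id,
            species=row.species,
            round_id=row.round_id,
            time_slot=row.time_slot,
            container_id=row.container_id,
        )
        room = FluorescencePoint(
            None,
            1.0 - config.baseline_fvfm25,
            1.0,
            config.baseline_fvfm25,
        )
        pts = [room] + [
            FluorescencePoint(float(t), float(1.0 - v), 1.0, float(v))
            for t, v in zip(grid, clipped)
        ]
        curves.append(FluorescenceCurve(meta, pts))
        truth_rows.append(
            {"sample_id": row.sample_id, "psi": psi, "m1": m1, "m2": m2,
             "fvfm25": config.baseline_fvfm25}
        )
    total_var = config.sigma2_g + config.sigma2_rt + config.sigma2_c + config.sigma2_e
    truth = TruthBundle(
        causal_snps=causal_ids,
        causal_effects=[float(e) for e in effects],
        genetic_values=gvalues,
        plant_truth=pd.DataFrame(truth_rows),
        expected_h2=expected_h2(config) if total_var > 0 else 0.0,
        n_clipped_points=n_clipped,
    )
    sample_map = design[
        ["sample_id", "genotype_id", "species", "round_id", "time_slot", "container_id"]
    ].copy()
    return curves, sample_map, truth


# ---------------------------------------------------------------------------
# fixture bundles on disk


def _dummy_genes(config: SimConfig, G: GenotypeMatrix, truth: TruthBundle,
                 rng: np.random.Generator) -> pd.DataFrame:
    """Gene models tiled along the genome, one centred on each causal SNP."""
    genes = []
    causal_pos = G.snps.set_index("snp_id").loc[truth.causal_snps] if truth.causal_snps else None
    gi = 0
    for chrom, grp in G.snps.groupby("chrom", sort=True):
        span_end = int(grp["pos"].max())
        start = 1000
        while start < span_end:
            length = int(rng.integers(2000, 5000))
            genes.append({"gene_id": f"gene{gi:04d}", "chrom": str(chrom),
                          "start": start, "end": start + length, "strand": "+"})
            gi += 1
            start += int(rng.integers(30_000, 60_000))
    df = pd.DataFrame(genes)
    if causal_pos is not None:
        for sid, row in causal_pos.iterrows():
            df.loc[len(df)] = {"gene_id": f"gene_causal_{sid}", "chrom": str(row["chrom"]),
                               "start": max(1, int(row["pos"]) - 1500),
                               "end": int(row["pos"]) + 1500, "strand": "+"}
    return df.sort_values(["chrom", "start"]).reset_index(drop=True)


def _dummy_terms(genes: pd.DataFrame, truth: TruthBundle, rng: np.random.Generator) -> pd.DataFrame:
    """Random GO-like annotation with a heat-response term enriched near
    the causal loci."""
    terms = [f"GO:{9000000 + i}" for i in range(8)]
    heat_term = "GO:0009408"  # response to heat
    rows = []
    for gid in genes["gene_id"]:
        for t in rng.choice(terms, size=rng.integers(1, 4), replace=False):
            rows.append({"gene_id": gid, "term_id": str(t)})
        if gid.startswith("gene_causal") or rng.random() < 0.05:
            rows.append({"gene_id": gid, "term_id": heat_term})
    return pd.DataFrame(rows)


def write_fixture_bundle(config: SimConfig, outdir: str) -> dict:
    """Generate and write a complete fixture bundle; returns file paths."""
    from .curves import write_curves_long
    from .genio import write_vcf, write_dosage_tsv

    os.makedirs(outdir, exist_ok=True)
    G = simulate_genotypes(config)
    curves, sample_map, truth = simulate_thermal_population(config, G)
    rng = _streams(config.seed)["design"]
    genes = _dummy_genes(config, G, truth, rng)
    terms = _dummy_terms(genes, truth, rng)

    paths = {
        "curves": os.path.join(outdir, "curves.csv"),
        "sample_map": os.path.join(outdir, "sample_map.csv"),
        "vcf": os.path.join(outdir, "genotypes.vcf"),
        "dosages": os.path.join(outdir, "dosages.tsv"),
        "snp_map": os.path.join(outdir, "snp_map.tsv"),
        "gff3": os.path.join(outdir, "genes.gff3"),
        "gene2term": os.path.join(outdir, "gene2term.tsv"),
        "truth": os.path.join(outdir, "truth.json"),
        "config": os.path.join(outdir, "sim_config.json"),
    }
    write_curves_long(curves, paths["curves"])
    sample_map.to_csv(paths["sample_map"], index=False)
    write_vcf(G, paths["vcf"])
    write_dosage_tsv(G, paths["dosages"], paths["snp_map"])
    with open(paths["gff3"], "w") as fh:
        fh.write("##gff-version 3\n")
        for row in genes.itertuples(index=False):
            fh.write(
                f"{row.chrom}\tphtmap_sim\tgene\t{row.start}\t{row.end}\t.\t{row.strand}\t.\t"
                f"ID={row.gene_id}\n"
            )
    terms.to_csv(paths["gene2term"], sep="\t", index=False)
    truth.to_json(paths["truth"])
    with open(paths["config"], "w") as fh:
        json.dump(dataclasses.asdict(config), fh, indent=2)
    return paths


def _preset_small(seed: int) -> SimConfig:
    return SimConfig(
        seed=seed,
        n_accessions=40,
        n_plants_per_accession=2,
        plants_per_container=24,
        samples_per_round=20,
        n_chromosomes=2,
        n_snps=400,
        n_founders=12,
        n_causal=2,
    )


def _preset_default(seed: int) -> SimConfig:
    return SimConfig(seed=seed)


PRESETS = {"small": _preset_small, "default": _preset_default}
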