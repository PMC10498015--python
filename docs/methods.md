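# Methods

## The thermal-response model

Fv/Fm of dark-adapted leaf tissue declines with temperature in two regimes:
a slow, near-linear drift up to a critical temperature, then a rapid
collapse as PSII is damaged. We model each sample's ramp with a continuous
two-segment linear regression,

    y(T) = b0 + m1*T + (m2 - m1) * max(0, T - psi) + eps,

where `psi` is the breakpoint (reported as T_crit, °C), `m1` and `m2` the
slopes below and above it (Fv/Fm per °C, stored signed — negative means
decline), and `b0` the lower-segment intercept at 0 °C. Slope magnitudes,
when wanted for presentation, are taken at the reporting layer; the model
always carries signs.

**Estimation.** For a fixed `psi` the model is linear, so the profile RSS
over `psi` drives everything. The default fitter is the iterative
linearization classically used for broken-line models: at a working value
of `psi`, OLS is run on `{1, T, U, V}` with `U = (T - psi)+` and
`V = -1[T > psi]`, and `psi` is updated by `gamma_hat / betaU_hat` until
the update falls below 1e-4 °C (max 50 iterations). The iteration is
seeded from the best candidate on the observed-temperature midpoint grid.
Two safeguards route degenerate cases to `grid_breakpoint`, an exhaustive
profile-RSS scan at 0.01 °C resolution (ties broken toward the lower
breakpoint): failure to converge, and the rare event that a linearization
step hops into a basin worse than its own starting candidate. The grid
fitter doubles as an independent oracle in the tests.

**Admissibility.** Breakpoints are restricted to the interior of the ramp:
at least 1/30 of the predictor range (1 °C on the standard 25–55 °C grid)
away from each end, with at least three observations on each side. Curves
on which no interior breakpoint improves on a single straight line by more
than 1e-3 relative RSS are flagged `no_break`; their T_crit is reported as
missing rather than a boundary artifact. The delta-method standard error
of `psi` (from the working linear model at convergence) is attached when
available.

**T_50.** Following the screen's convention, the sample's maximum Fv/Fm is
its 25 °C reading. T_50 is predicted from an *inverse* segmented model —
temperature as response, Fv/Fm as covariate, breakpoint re-estimated in
Fv/Fm space — evaluated at half the maximum. On exact two-segment data the
inverse fit coincides with inverting the forward model (the tests assert
agreement within 0.05 °C); whether an inverse re-fit or a forward
inversion is "the" definition is genuinely open, and we chose the re-fit
because it is the procedure actually described for the screen. Curves
whose minimum stays above half-maximum return a reason string instead of a
number, as do constant curves.

## Quality control

Defaults: ≥ 10 valid ramp points, 25 °C Fv/Fm ≥ 0.5 (healthy dark-adapted
tissue sits near 0.8), no temperature gap > 2 °C. These gates are
conventions of this package, configurable per run; the underlying screens
do not publish theirs. QC is idempotent and every rejection is itemized in
a JSON report.

## Random-effects trait model

Each trait (T_crit, T_50, m1, m2; one model per trait, species fitted
separately) is decomposed as

    y = mu + u_rt[round x time] + u_c[container] + u_g[genotype] + e,

all random effects independent zero-mean Gaussians. REML estimates the
four variance components; the criterion is profiled over the residual
variance and optimized over the non-negative ratios `sigma_f^2 /
sigma_e^2` (a bracketed scalar search for one factor; L-BFGS-B plus a
Nelder-Mead polish for several), with all solves routed through the q×q
Woodbury identity (q = total random-effect levels), so a 600-plant panel
fits in under a second. Components may land on the zero boundary;
single-level factors are dropped and reported as zero variance; a factor
whose partition coincides with genotype raises an aliasing error rather
than silently splitting variance.

Genotype BLUPs come from the mixed-model equations at the REML estimates;
adjusted means are `mu + BLUP`. Broad-sense heritability uses the full
phenotypic denominator, H² = σ²_g / (σ²_g + σ²_rt + σ²_c + σ²_e) — the
per-plot alternative (dividing non-genetic variance by replicate number)
is deliberately not offered. The reported fit diagnostic `r2_fit` is the
squared correlation between conditional fitted values (mu plus all
predicted random effects) and the observations; this conditional-R²
convention is one reasonable reading of an otherwise undefined "model R²"
and may not match other software. On balanced one-way designs the REML
estimates equal the ANOVA method-of-moments closed forms whenever those
are non-negative (tested at 1e-6 relative).

## Association scan

The scan is the efficient mixed-model approximation: under the no-SNP null
`y = mu + g + e`, `g ~ N(0, sigma_g^2 K)`, the variance ratio is estimated
by restricted likelihood over the spectral decomposition of the kinship
matrix K (grid-bracketed 1-D search over log delta); the phenotype and
design are whitened once by the fitted covariance and every SNP gets a GLS
slope test with a two-sided t p-value (n − rank df). The variance ratio is
*not* re-estimated per SNP — the approximation trades a little exactness
for a vectorized scan. With K = I the whole scan reduces numerically to
per-SNP ordinary regression (tested to 1e-6 in −log₁₀ p).

Kinship options: `vanraden` (centred dosage cross-product scaled by
2·Σp(1−p)) and `ibs` (mean allele sharing). SNP filters follow the screens
this mirrors: MAF strictly > 0.05, missingness strictly < 0.1 (0.05 for the
denser-genotyped panel in the original work); missing dosages are
mean-imputed before kinship and scanning.

Significance uses −log₁₀ p ≥ 4 with the boundary *included* (a p of
exactly 1e-4 is kept); the threshold is deliberately permissive because
QQ-calibrated scans of polygenic thermal traits rarely clear genome-wide
Bonferroni. Clumping is greedy and p-value-ranked: the best unassigned
SNP indexes a clump and captures every unassigned significant SNP on its
chromosome within the window (243 kb default, matching average genome-wide
LD of an aus rice panel; 150 kb suits a typical *O. glaberrima* panel).
Distance-only windows are the default since the screens specify windows by
average LD without an r² cutoff; an optional `r2_min` reproduces strict
PLINK-style behaviour. Clumps with fewer than two significant SNPs are
discarded — singleton associations are too often false positives. Windows
and positions are 1-based closed intervals throughout.

Local LD is the squared Pearson correlation of dosage vectors for all SNP
pairs within ±500 kb of each QTL peak. Genes (GFF3 `gene` features, body
only, no flanks) qualify as linked when they contain at least one SNP with
r² strictly above 0.3 to at least one significant SNP. GO
over-representation is the exact one-sided hypergeometric tail against a
user-supplied gene→term mapping with BH-FDR at 0.05; the background
defaults to all annotated genes, since the original classifier's internal
background is not reproducible. Candidate flags join optional evidence
tables: differential expression (|fold| strictly > 2), a chloroplast
cellular-component annotation (GO:0009507), and free-text curation.

## Synthetic data

The generator emulates the structure of the real screens: ~150 accessions
× 4 plants; plants randomized into 48-plant growth containers and ~110-
sample measurement batches (round × time); 31-point 25–55 °C ramps with
N(0, 0.02) measurement noise clipped to the physiological range [0, 0.85].

Genotypes are built by Markov haplotype copying from a founder pool whose
haplotypes are themselves Markov allele-persistence chains on the
`ld_decay_bp` scale (default 150 kb), giving block-like LD that decays
with distance; with the default 10 kb SNP spacing, adjacent-SNP r² is
about 0.7. Both knobs collapse correctly in the limits: zero decay gives
independent SNPs, infinite decay gives constant founders copied whole
(perfect local LD). Three causal SNPs (MAF ≥ 0.15) act on the breakpoint;
their effects are rescaled so accession-level genetic variance hits its
target exactly.

Default variance targets for T_crit are σ²_g = 0.3, σ²_rt = 0.08,
σ²_c = 0.05, σ²_e = 0.07 (°C²) — H² = 0.6 with a total SD of 0.7 °C,
matching the moderate-to-high heritabilities such screens report. Curve
baselines are Fv/Fm(25) = 0.80, m1 = −0.005, ψ = 48.0 °C and m2 = −0.095.
The breakpoint baseline sits inside the range observed for *O. sativa*
accessions; the decline slope is kept shallow enough that the two-segment
truth stays non-negative over the ramp for typical breakpoints. A steeper
decline (published population means run to ≈ −0.13 to −0.15) would drive
the linear truth below zero before 55 °C, where the physiological floor
truncates the curve and biases breakpoint recovery by ~0.5 °C — the
two-segment generating model is only self-consistent with the shallower
slope. Any clipping that does occur is counted in the truth bundle.

What the generator does **not** emulate: coalescent demography, selection,
population-structure confounding (beyond the two-subpopulation construct
used in the calibration tests), epistasis, genotype-by-environment
interaction, or instrument artifacts (drift, spatial gradients on the
measurement plate). Passing tests therefore demonstrate correctness of the
estimators under the stated generative model, not robustness to every
pathology of real screens.

One pseudo-random stream per logical component (genotypes, design,
effects, noise) hangs off a single seed, so fixture bundles are
byte-reproducible and components can be regenerated independently.

## Numerical choices and edge cases

- Breakpoint iteration: tol 1e-4 °C, max 50 iterations, then grid
  fallback at 0.01 °C; candidate validity needs ≥ 3 points per side;
  fewer than 6 distinct predictor values is degenerate.
- REML ratios bounded below by 0; constant responses short-circuit to an
  all-zero decomposition with `mu` equal to the common value.
- Scan p-values are clipped into (0, 1]; zero-variance SNPs yield NaN
  effect rows rather than spurious hits; a kinship matrix with eigenvalues
  below −1e-6 (relative) is rejected.
- Clump ties in p are broken by position then SNP id, making output
  order-independent.
- The genomic-inflation factor λ is the median observed 1-df chi-square
  quantile over 0.4549. On an oligogenic synthetic trait the corrected
  scan can sit modestly below 1 (the kinship matrix absorbs part of the
  causal signal); the structured-null calibration tests pin λ to
  [0.9, 1.1] where the trait is genuinely polygenic/confounded.

## Problem sizes

The shipped tests and the acceptance script use: 500 noise-free and 200
noisy curves for breakpoint recovery; 50 replicates of 150 genotypes × 4
plants per heritability level; 10,000 null SNPs on 200 structured
accessions for calibration; 50 power replicates; 100 random clumping
configurations; and the full default synthetic pipeline (150 × 4 plants,
2,000 SNPs). These sizes give stable estimates while keeping a complete
run in the minutes range on a single CPU.
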