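"""Random-effects decomposition of replicated thermal traits.

Each trait measured on every plant is modelled with an intercept and three
crossed random intercepts,

    y = mu + u_rt[round x time] + u_c[container] + u_g[genotype] + e,

all effects independent Gaussians.  Restricted maximum likelihood (REML)
estimates the four variance components; genotype BLUPs from the mixed-model
equations, added to the population mean, give adjusted means that feed the
association scan.  Broad-sense heritability is the genotypic share of the
total variance, ``H2 = s2_g / (s2_g + s2_rt + s2_c + s2_e)``.

The REML criterion is profiled over the residual variance and optimized
over the ratios ``gamma_f = s2_f / s2_e`` (non-negative, zero allowed on
the boundary).  All linear algebra is routed through the q x q Woodbury
identity, where q is the total number of random-effect levels, so fits
stay fast for hundreds of genotypes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats, linalg

from .errors import AliasedEffectsError, FitError

__all__ = [
    "VarianceComponents",
    "RandomEffectsModel",
    "RandomEffectsResults",
    "heritability",
    "blup_adjusted_means",
    "trait_correlations",
]


@dataclass
class VarianceComponents:
    sigma2_genotype: float
    sigma2_round_time: float
    sigma2_container: float
    sigma2_residual: float

    def total(self) -> float:
        return (
            self.sigma2_genotype
            + self.sigma2_round_time
            + self.sigma2_container
            + self.sigma2_residual
        )

    def as_dict(self) -> dict:
        return {
            "sigma2_genotype": self.sigma2_genotype,
            "sigma2_round_time": self.sigma2_round_time,
            "sigma2_container": self.sigma2_container,
            "sigma2_residual": self.sigma2_residual,
        }


def heritability(varcomps: VarianceComponents) -> float:
    """Broad-sense heritability: genotypic variance over total variance."""
    vals = varcomps.as_dict()
    for name, v in vals.items():
        if v < 0:
            raise ValueError(f"negative variance component {name}: {v}")
    total = varcomps.total()
    if total == 0:
        return 0.0
    return varcomps.sigma2_genotype / total


# ---------------------------------------------------------------------------


def _one_hot(codes: np.ndarray, n_levels: int) -> np.ndarray:
    Z = np.zeros((codes.size, n_levels))
    Z[np.arange(codes.size), codes] = 1.0
    return Z


class RandomEffectsModel:
    """All-random-effects model for one replicated trait.

    Parameters
    ----------
    data : DataFrame
        One row per plant with columns ``value`` (the trait),
        ``genotype_id``, ``round_time_id`` and ``container_id``.  A factor
        with a single level is dropped (its variance is not identifiable
        and is reported as 0).
    """

    FACTORS = ("genotype_id", "round_time_id", "container_id")

    def __init__(self, data: pd.DataFrame, value_col: str = "value"):
        missing = {value_col, *self.FACTORS} - set(data.columns)
        if missing:
            raise FitError(f"data lacks columns: {sorted(missing)}")
        data = data.dropna(subset=[value_col]).reset_index(drop=True)
        if len(data) < 2:
            raise FitError("need at least 2 observations")
        self.data = data
        self.y = data[value_col].to_numpy(dtype=float)
        self.n = self.y.size

        self._codes: dict[str, np.ndarray] = {}
        self._levels: dict[str, np.ndarray] = {}
        for f in self.FACTORS:
            codes, levels = pd.factorize(data[f].astype(str), sort=True)
            self._codes[f] = codes
            self._levels[f] = levels
        geno_counts = pd.Series(self._codes["genotype_id"]).value_counts()
        if (geno_counts >= 2).sum() < 2:
            raise FitError("need >= 2 genotypes with >= 2 observations each")
        self._check_aliasing()
        # factors that actually carry more than one level enter the fit
        self.active = [f for f in self.FACTORS if len(self._levels[f]) > 1]

    def _check_aliasing(self) -> None:
        g = self._codes["genotype_id"]
        for f in ("round_time_id", "container_id"):
            c = self._codes[f]
            if len(self._levels[f]) < 2:
                continue
            # identical partitions: the level of one determines the other, both ways
            if (pd.Series(g).groupby(c).nunique().max() == 1
                    and pd.Series(c).groupby(g).nunique().max() == 1):
                raise AliasedEffectsError(
                    f"aliased random effects: {f} partitions samples identically to genotype"
                )

    # -- REML machinery ----------------------------------------------------

    def _design(self):
        blocks = [_one_hot(self._codes[f], len(self._levels[f])) for f in self.active]
        sizes = [b.shape[1] for b in blocks]
        Z = np.hstack(blocks) if blocks else np.zeros((self.n, 0))
        return Z, sizes

    def _profiled_neg2reml(self, gamma: np.ndarray, Z, sizes, ZtZ, Zty):
        n = self.n
        y = self.y
        d = np.repeat(np.maximum(gamma, 0.0), sizes)
        sd = np.sqrt(d)
        M = np.eye(Z.shape[1]) + (sd[:, None] * ZtZ) * sd[None, :]
        try:
            cf = linalg.cho_factor(M, lower=True)
        except linalg.LinAlgError:
            return np.inf, None
        logdet_M = 2.0 * np.sum(np.log(np.diag(cf[0])))
        ZtX = Z.sum(axis=0)  # X is the intercept column
        a_x = sd * ZtX
        a_y = sd * Zty
        sol_x = linalg.cho_solve(cf, a_x)
        sol_y = linalg.cho_solve(cf, a_y)
        xtvx = n - a_x @ sol_x
        xtvy = y.sum() - a_x @ sol_y
        ytvy = y @ y - a_y @ sol_y
        if xtvx <= 0:
            return np.inf, None
        beta = xtvy / xtvx
        rss_v = max(ytvy - xtvy * beta, 0.0)
        dof = n - 1
        if rss_v <= 0:
            return np.inf, None
        sigma_e2 = rss_v / dof
        crit = dof * np.log(sigma_e2) + logdet_M + np.log(xtvx)
        return crit, (beta, sigma_e2, cf, sd)

    def fit(self, tol: float = 1e-10) -> "RandomEffectsResults":
        y = self.y
        if np.ptp(y) <= 1e-14:  # exactly constant response
            return self._constant_fit(float(y[0]))
        Z, sizes = self._design()
        ZtZ = Z.T @ Z
        Zty = Z.T @ y
        k = len(self.active)

        def objective(g):
            return self._profiled_neg2reml(np.asarray(g, dtype=float), Z, sizes, ZtZ, Zty)[0]

        if k == 0:
            gamma_hat = np.zeros(0)
        elif k == 1:
            gamma_hat = np.array([_optimize_scalar(lambda g: objective([g]))])
        else:
            gamma_hat = _optimize_multi(objective, k)
        crit, aux = self._profiled_neg2reml(gamma_hat, Z, sizes, ZtZ, Zty)
        if aux is None:
            raise FitError("REML criterion not finite at the optimum")
        beta, sigma_e2, cf, sd = aux
        return self._results(gamma_hat, beta, sigma_e2, Z, sizes, ZtZ, Zty, cf, sd, crit)

    def _constant_fit(self, value: float) -> "RandomEffectsResults":
        genos = list(self._levels["genotype_id"])
        vc = VarianceComponents(0.0, 0.0, 0.0, 0.0)
        blups = pd.Series(0.0, index=pd.Index(genos, name="genotype_id"))
        return RandomEffectsResults(
            model=self, varcomps=vc, mu=value, blups=blups, h2=0.0,
            r2_fit=float("nan"), converged=True, neg2reml=float("nan"),
        )

    def _results(self, gamma, beta, sigma_e2, Z, sizes, ZtZ, Zty, cf, sd, crit):
        comps = dict.fromkeys(self.FACTORS, 0.0)
        for f, g in zip(self.active, gamma):
            comps[f] = float(max(g, 0.0) * sigma_e2)
        vc = VarianceComponents(
            sigma2_genotype=comps["genotype_id"],
            sigma2_round_time=comps["round_time_id"],
            sigma2_container=comps["container_id"],
            sigma2_residual=float(sigma_e2),
        )
        # BLUPs: u = D Z' V0^{-1} (y - mu) via the Woodbury factorization
        w = Zty - beta * Z.sum(axis=0)
        d = np.repeat(np.maximum(gamma, 0.0), sizes)
        zv = w - ZtZ @ (sd * linalg.cho_solve(cf, sd * w))
        u = d * zv
        fitted = beta + Z @ u
        resid_var = np.var(self.y)
        if resid_var > 0 and np.var(fitted) > 0:
            r2 = float(np.corrcoef(fitted, self.y)[0, 1] ** 2)
        else:
            r2 = float("nan")
        # slice genotype BLUPs out of the stacked vector
        offset = 0
        geno_blups = None
        for f, size in zip(self.active, sizes):
            if f == "genotype_id":
                geno_blups = u[offset: offset + size]
            offset += size
        genos = list(self._levels["genotype_id"])
        if geno_blups is None:
            geno_blups = np.zeros(len(genos))
        blups = pd.Series(geno_blups, index=pd.Index(genos, name="genotype_id"))
        h2 = heritability(vc)
        return RandomEffectsResults(
            model=self, varcomps=vc, mu=float(beta), blups=blups, h2=h2,
            r2_fit=r2, converged=True, neg2reml=float(crit),
        )


def _optimize_scalar(f, lo_exp: float = -8.0, hi_exp: float = 8.0):
    """Grid-bracketed 1-D REML-ratio optimization (EMMA style)."""
    grid = np.concatenate([[0.0], np.logspace(lo_exp, hi_exp, 65)])
    vals = np.array([f(g) for g in grid])
    i = int(np.nanargmin(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, grid.size - 1)]
    if hi <= lo:
        return float(grid[i])
    res = optimize.minimize_scalar(
        f, bounds=(lo, hi), method="bounded", options={"xatol": 1e-12}
    )
    return float(res.x) if res.fun <= vals[i] else float(grid[i])


def _optimize_multi(f, k: int) -> np.ndarray:
    # coarse log-grid screen picks the start; one bounded quasi-Newton run
    # plus a derivative-free polish reaches boundary optima accurately
    scales = (0.0, 0.03, 0.3, 3.0)
    starts = sorted(
        (np.full(k, s) for s in scales), key=lambda x0: f(x0)
    )[:1] + [np.full(k, 0.3)]
    best_x, best_val = None, np.inf
    for x0 in starts:
        res = optimize.minimize(
            f, x0, method="L-BFGS-B", bounds=[(0.0, None)] * k,
            options={"ftol": 1e-12, "gtol": 1e-8, "maxiter": 200},
        )
        if res.fun < best_val:
            best_val, best_x = res.fun, res.x
    res = optimize.minimize(
        f, best_x, method="Nelder-Mead",
        options={"xatol": 1e-9, "fatol": 1e-11, "maxiter": 1000},
    )
    if res.fun <= best_val:
        best_x = np.maximum(res.x, 0.0)
    return np.asarray(best_x, dtype=float)


@dataclass
class RandomEffectsResults:
    """REML estimates, genotype BLUPs and heritability for one trait."""

    model: RandomEffectsModel
    varcomps: VarianceComponents
    mu: float
    blups: pd.Series
    h2: float
    r2_fit: float
    converged: bool
    neg2reml: float

    @property
    def adjusted_means(self) -> pd.Series:
        """Population mean plus genotype BLUP, per genotype."""
        return (self.mu + self.blups).rename("adjusted_mean")

    def summary(self) -> str:
        vc = self.varcomps
        lines = [
            "Random-effects trait model (REML)",
            f"  n obs / genotypes : {self.model.n} / {len(self.blups)}",
            f"  population mean   : {self.mu:.6g}",
            f"  s2 genotype       : {vc.sigma2_genotype:.6g}",
            f"  s2 round x time   : {vc.sigma2_round_time:.6g}",
            f"  s2 container      : {vc.sigma2_container:.6g}",
            f"  s2 residual       : {vc.sigma2_residual:.6g}",
            f"  H2 (broad sense)  : {self.h2:.4f}",
            f"  conditional R2    : {self.r2_fit:.4f}",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "varcomps": self.varcomps.as_dict(),
            "mu": self.mu,
            "h2": self.h2,
            "r2_fit": self.r2_fit,
        }


def blup_adjusted_means(fit: RandomEffectsResults) -> pd.Series:
    """Adjusted mean (mu + BLUP) per genotype from a fitted model."""
    return fit.adjusted_means


def trait_correlations(adjusted_means: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise-complete Pearson correlations between trait adjusted means.

    Parameters
    ----------
    adjusted_means : DataFrame
        Genotypes in rows, traits in columns.

    Returns
    -------
    (r, p) : pair of DataFrames
        Symmetric correlation matrix with unit diagonal and two-sided
        p-values from the t transform.  A zero-variance trait yields NaN
        against every other trait (undefined correlation).
    """
    cols = list(adjusted_means.columns)
    k = len(cols)
    r = pd.DataFrame(np.eye(k), index=cols, columns=cols)
    p = pd.DataFrame(np.full((k, k), np.nan), index=cols, columns=cols)
    np.fill_diagonal(p.values, 0.0)
    for i in range(k):
        for j in range(i + 1, k):
            pair = adjusted_means[[cols[i], cols[j]]].dropna()
            if len(pair) < 3:
                r.iloc[i, j] = r.iloc[j, i] = np.nan
                continue
            x, yv = pair.iloc[:, 0].to_numpy(), pair.iloc[:, 1].to_numpy()
            if np.ptp(x) == 0 or np.ptp(yv) == 0:
                r.iloc[i, j] = r.iloc[j, i] = np.nan
                continue
            rr, pp = stats.pearsonr(x, yv)
            r.iloc[i, j] = r.iloc[j, i] = rr
            p.iloc[i, j] = p.iloc[j, i] = pp
    return r, p
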