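"""Two-segment continuous linear regression with an estimated breakpoint.

The thermal-tolerance traits come from the model

    y = b0 + m1 * t + (m2 - m1) * max(0, t - psi) + eps

fitted to the Fv/Fm-temperature ramp of one sample:  ``psi`` is the
breakpoint temperature (T_crit), ``m1`` and ``m2`` the slopes below and
above it.  The maximum-likelihood breakpoint is found by iterative
linearization: at a working value of psi, ordinary least squares is run on
the design ``{1, t, U, V}`` with ``U = (t - psi)+`` and ``V = -1[t > psi]``,
and psi is updated by ``gamma_hat / betaU_hat`` (the ratio of the V and U
coefficients) until the update is below tolerance.  An exhaustive
grid search over candidate breakpoints (`grid_breakpoint`) provides both
the fallback when the iteration diverges and an independent brute-force
oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import FitError

__all__ = ["SegmentedModel", "SegmentedFit", "grid_breakpoint"]

#: Minimum points required on each side of an admissible breakpoint.
MIN_SIDE = 3

#: Relative RSS improvement below which the data are declared break-free.
NO_BREAK_REL_TOL = 1e-3


@dataclass
class SegmentedFit:
    """Results of a segmented fit.

    Attributes
    ----------
    psi : float
        Estimated breakpoint, in the units of the predictor.
    m1, m2 : float
        Slopes below and above the breakpoint (signed; negative for a
        declining response).
    b0 : float
        Intercept of the lower segment at predictor 0.
    rss : float
        Residual sum of squares at the estimate.
    n_iter : int
        Linearization iterations used (0 for a pure grid fit).
    converged : bool
        Whether the iteration met its tolerance (grid fits count as
        converged).
    no_break : bool
        True when no interior breakpoint improves on a single straight
        line by more than a relative tolerance; psi/m2 are then not
        interpretable.
    se_psi : float or None
        Delta-method standard error of psi, when computable.
    method : str
        "iterative" or "grid".
    nobs : int
    """

    psi: float
    m1: float
    m2: float
    b0: float
    rss: float
    n_iter: int
    converged: bool
    no_break: bool = False
    se_psi: float | None = None
    method: str = "iterative"
    nobs: int = 0

    def predict(self, t) -> np.ndarray:
        """Piecewise-linear prediction; continuous at the breakpoint."""
        t = np.asarray(t, dtype=float)
        return self.b0 + self.m1 * t + (self.m2 - self.m1) * np.maximum(0.0, t - self.psi)

    @property
    def params(self) -> dict:
        return {"psi": self.psi, "m1": self.m1, "m2": self.m2, "b0": self.b0}

    def summary(self) -> str:
        lines = [
            "Segmented regression (two continuous linear segments)",
            f"  n obs      : {self.nobs}",
            f"  breakpoint : {self.psi:.4f}"
            + (f" (se {self.se_psi:.4f})" if self.se_psi is not None else ""),
            f"  slope m1   : {self.m1:.6f}",
            f"  slope m2   : {self.m2:.6f}",
            f"  intercept  : {self.b0:.6f}",
            f"  rss        : {self.rss:.6g}",
            f"  method     : {self.method}, {self.n_iter} iter, "
            + ("converged" if self.converged else "not converged"),
        ]
        if self.no_break:
            lines.append("  flagged    : no-break (single line fits as well)")
        return "\n".join(lines)


def _validate(x: np.ndarray, y: np.ndarray, min_points: int) -> None:
    if x.ndim != 1 or y.ndim != 1 or x.size != y.size:
        raise FitError("x and y must be 1-D arrays of equal length")
    if x.size < min_points:
        raise FitError(f"need >= {min_points} points, got {x.size}")
    if not np.all(np.isfinite(x)) or not np.all(np.isfinite(y)):
        raise FitError("non-finite values in input")


def _admissible_range(x: np.ndarray, delta: float | None) -> tuple[float, float]:
    """Interval of breakpoints with delta clearance and MIN_SIDE support."""
    if np.unique(x).size < 2 * MIN_SIDE:
        raise FitError("degenerate segmentation: too few distinct predictor values")
    lo_delta = x.min() + (delta if delta is not None else 0.0)
    hi_delta = x.max() - (delta if delta is not None else 0.0)
    xs = np.sort(x)
    lo_sup = xs[MIN_SIDE - 1]  # smallest psi with 3 points at or below
    hi_sup = xs[-MIN_SIDE]
    lo = max(lo_delta, lo_sup)
    hi = min(hi_delta, hi_sup)
    if lo > hi:
        raise FitError("degenerate segmentation: no admissible breakpoint")
    return lo, hi


def _conditional_ls(x: np.ndarray, y: np.ndarray, psi: float):
    """OLS of y on {1, x, (x-psi)+} at a fixed breakpoint."""
    u = np.maximum(0.0, x - psi)
    X = np.column_stack([np.ones_like(x), x, u])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return beta, float(resid @ resid)


def _line_rss(x: np.ndarray, y: np.ndarray) -> float:
    X = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


def _candidate_rss(x: np.ndarray, y: np.ndarray, psis: np.ndarray) -> np.ndarray:
    """Vectorized conditional RSS over an array of candidate breakpoints."""
    n = x.size
    U = np.maximum(0.0, x[None, :] - psis[:, None])  # (m, n)
    s1 = float(n)
    sx = float(x.sum())
    sxx = float(x @ x)
    sy = float(y.sum())
    sxy = float(x @ y)
    syy = float(y @ y)
    su = U.sum(axis=1)
    sxu = U @ x
    suu = np.einsum("ij,ij->i", U, U)
    suy = U @ y
    m = psis.size
    G = np.empty((m, 3, 3))
    G[:, 0, 0] = s1
    G[:, 0, 1] = G[:, 1, 0] = sx
    G[:, 0, 2] = G[:, 2, 0] = su
    G[:, 1, 1] = sxx
    G[:, 1, 2] = G[:, 2, 1] = sxu
    G[:, 2, 2] = suu
    rhs = np.empty((m, 3))
    rhs[:, 0] = sy
    rhs[:, 1] = sxy
    rhs[:, 2] = suy
    rss = np.full(m, np.inf)
    # solve all well-conditioned systems at once, fall back per-candidate
    try:
        beta = np.linalg.solve(G, rhs[..., None])[..., 0]
        rss = syy - np.einsum("ij,ij->i", beta, rhs)
    except np.linalg.LinAlgError:
        for i in range(m):
            try:
                b = np.linalg.solve(G[i], rhs[i])
                rss[i] = syy - b @ rhs[i]
            except np.linalg.LinAlgError:
                pass
    return np.maximum(rss, 0.0)


def _finalize(
    x: np.ndarray,
    y: np.ndarray,
    psi: float,
    n_iter: int,
    converged: bool,
    method: str,
    se_psi: float | None = None,
) -> SegmentedFit:
    beta, rss = _conditional_ls(x, y, psi)
    b0, m1, du = float(beta[0]), float(beta[1]), float(beta[2])
    line = _line_rss(x, y)
    no_break = (line - rss) <= NO_BREAK_REL_TOL * max(line, np.finfo(float).tiny)
    return SegmentedFit(
        psi=float(psi),
        m1=m1,
        m2=m1 + du,
        b0=b0,
        rss=rss,
        n_iter=n_iter,
        converged=converged,
        no_break=no_break,
        se_psi=se_psi,
        method=method,
        nobs=x.size,
    )


def grid_breakpoint(
    x,
    y,
    resolution: float = 0.01,
    delta: float | None = None,
    min_points: int = 10,
) -> SegmentedFit:
    """Brute-force segmented fit: scan candidate breakpoints on a grid.

    Evaluates the conditional least-squares RSS at every breakpoint on a
    regular grid of the stated resolution within the admissible interval
    and returns the global minimizer (ties broken toward the lowest
    breakpoint).  Slower than the iterative fit but free of convergence
    concerns; used as its fallback and as an independent oracle.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    _validate(x, y, min_points)
    if delta is None:
        delta = (x.max() - x.min()) / 30.0
    lo, hi = _admissible_range(x, delta)
    n_cand = int(np.floor((hi - lo) / resolution)) + 1
    psis = lo + resolution * np.arange(n_cand)
    if psis[-1] < hi - 1e-12:
        psis = np.append(psis, hi)
    rss = _candidate_rss(x, y, psis)
    best = int(np.argmin(rss))  # argmin returns the first (lowest-psi) tie
    return _finalize(x, y, float(psis[best]), 0, True, "grid")


class SegmentedModel:
    """Two-segment broken-line model of a response against one predictor.

    Parameters
    ----------
    x, y : array-like
        Predictor (temperature, for the forward thermal model) and
        response (Fv/Fm), equal length, >= ``min_points`` values.
    delta : float, optional
        Exclusion zone at each end of the predictor range within which a
        breakpoint is not admissible.  Defaults to 1/30 of the predictor
        range, i.e. 1 degC on the standard 25-55 degC ramp.
    min_points : int
        Minimum number of observations.

    Examples
    --------
    >>> t = np.arange(25.0, 56.0)
    >>> y = 0.8 - 0.005 * (t - 25) - 0.146 * np.maximum(0, t - 46)
    >>> fit = SegmentedModel(t, y).fit()
    >>> round(fit.psi, 3)
    46.0
    """

    def __init__(self, x, y, delta: float | None = None, min_points: int = 10):
        self.x = np.asarray(x, dtype=float)
        self.y = np.asarray(y, dtype=float)
        _validate(self.x, self.y, min_points)
        if delta is None:
            delta = (self.x.max() - self.x.min()) / 30.0
        self.delta = float(delta)
        self.min_points = min_points
        self._range = _admissible_range(self.x, self.delta)

    # -- initialization ----------------------------------------------------

    def _initial_psi(self) -> tuple[float, float]:
        """Best candidate (and its RSS) from the observed-midpoint grid."""
        lo, hi = self._range
        xs = np.unique(self.x)
        mids = 0.5 * (xs[:-1] + xs[1:])
        cands = mids[(mids >= lo) & (mids <= hi)]
        if cands.size == 0:
            cands = np.array([0.5 * (lo + hi)])
        rss = _candidate_rss(self.x, self.y, cands)
        best = int(np.argmin(rss))
        return float(cands[best]), float(rss[best])

    # -- fitting -----------------------------------------------------------

    def fit(
        self,
        psi_init: float | str = "auto",
        tol: float = 1e-4,
        max_iter: int = 50,
        grid_resolution: float = 0.01,
    ) -> SegmentedFit:
        """Iteratively linearized fit with a grid-search fallback.

        ``psi_init="auto"`` seeds the iteration from the best of the
        observed-midpoint candidate grid.  If the iteration fails to
        converge in ``max_iter`` steps, or leaves the admissible interval
        irrecoverably, the exhaustive grid fit at ``grid_resolution`` is
        returned instead.
        """
        x, y = self.x, self.y
        lo, hi = self._range
        if psi_init == "auto":
            psi, init_rss = self._initial_psi()
        else:
            psi, init_rss = float(psi_init), np.inf
        psi = float(np.clip(psi, lo, hi))
        converged = False
        n_iter = 0
        se_psi = None
        for n_iter in range(1, max_iter + 1):
            u = np.maximum(0.0, x - psi)
            v = -(x > psi).astype(float)
            X = np.column_stack([np.ones_like(x), x, u, v])
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            beta_u, gamma = beta[2], beta[3]
            if abs(beta_u) < 1e-12:
                break  # slope change vanishing: linearization undefined
            step = gamma / beta_u
            new_psi = float(np.clip(psi + step, lo, hi))
            if abs(new_psi - psi) < tol:
                psi = new_psi
                converged = True
                # delta-method se of the breakpoint from the working model
                resid = y - X @ beta
                dof = x.size - 4
                if dof > 0:
                    sigma2 = float(resid @ resid) / dof
                    XtX_inv = np.linalg.pinv(X.T @ X)
                    var_gamma = sigma2 * XtX_inv[3, 3]
                    se_psi = float(np.sqrt(var_gamma) / abs(beta_u))
                break
            psi = new_psi
        if not converged:
            return grid_breakpoint(
                x, y, resolution=grid_resolution, delta=self.delta, min_points=self.min_points
            )
        fit = _finalize(x, y, psi, n_iter, True, "iterative", se_psi)
        # a linearization step can hop into a worse local basin than the
        # starting candidate; detect that and defer to the exhaustive search
        if fit.rss > init_rss * (1 + 1e-9) + 1e-12:
            return grid_breakpoint(
                x, y, resolution=grid_resolution, delta=self.delta, min_points=self.min_points
            )
        return fit


def psi_confint(fit: SegmentedFit, alpha: float = 0.05) -> tuple[float, float] | None:
    """Delta-method Wald interval for the breakpoint, if a se is available."""
    if fit.se_psi is None:
        return None
    z = stats.norm.ppf(1 - alpha / 2)
    return fit.psi - z * fit.se_psi, fit.psi + z * fit.se_psi
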