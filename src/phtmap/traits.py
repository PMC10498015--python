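"""Per-sample thermal-tolerance traits from fitted ramp curves.

Four traits summarize each sample's Fv/Fm-temperature response:

* ``t_crit`` — the breakpoint of the forward segmented model, where the
  decline of Fv/Fm switches from slow to rapid;
* ``m1`` / ``m2`` — the slopes below / above that breakpoint (Fv/Fm per
  degC, signed);
* ``t_50`` — the temperature at which Fv/Fm reaches 50% of its 25 degC
  maximum, predicted from an *inverse* segmented model (temperature
  regressed on Fv/Fm, with its own breakpoint in Fv/Fm space);
* ``fvfm_max`` — the 25 degC reading itself, the within-ramp maximum in
  healthy tissue.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .curves import FluorescenceCurve, GRID_TOL
from .errors import FitError
from .segmented import SegmentedModel, SegmentedFit

__all__ = ["ThermalTraits", "estimate_t50", "extract_traits"]


@dataclass
class ThermalTraits:
    sample_id: str
    t_crit: float | None
    t_50: float | None
    m1: float | None
    m2: float | None
    fvfm_max: float | None
    converged: bool
    reason: str = ""


def estimate_t50(
    temperatures,
    fvfm_values,
    start_temperature: float = 25.0,
) -> tuple[float | None, str]:
    """Temperature at which Fv/Fm is half its ramp-start maximum.

    The ramp-start (25 degC) Fv/Fm is taken as the sample's maximum.  An
    inverse segmented model — temperature as response, Fv/Fm as covariate,
    breakpoint re-estimated in Fv/Fm space — is fitted and used to predict
    the temperature at half that maximum.

    Returns ``(t50, "")`` on success, or ``(None, reason)`` when the curve
    never falls to half-maximum within the ramp or is too degenerate to
    invert.
    """
    t = np.asarray(temperatures, dtype=float)
    y = np.asarray(fvfm_values, dtype=float)
    at_start = np.abs(t - start_temperature) <= GRID_TOL
    if not at_start.any():
        return None, f"no {start_temperature:g} degC reading"
    y_max = float(y[at_start][0])
    half = 0.5 * y_max
    if np.ptp(y) <= 1e-12:
        return None, "degenerate inverse model"
    if float(y.min()) > half:
        return None, "half-max not reached"
    # inverse model: regress temperature on Fv/Fm, breakpoint in Fv/Fm space
    order = np.argsort(y, kind="stable")
    try:
        fit = SegmentedModel(y[order], t[order]).fit()
    except FitError:
        return None, "degenerate inverse model"
    return float(fit.predict(half)), ""


def _fit_curve(curve: FluorescenceCurve, start_temperature: float) -> ThermalTraits:
    sid = curve.meta.sample_id
    t, y = curve.ramp_arrays()
    fvfm_max = curve.fvfm_at(start_temperature)
    try:
        fit: SegmentedFit = SegmentedModel(t, y).fit()
    except FitError as exc:
        return ThermalTraits(sid, None, None, None, None, fvfm_max, False, str(exc))
    t50, t50_reason = estimate_t50(t, y, start_temperature)
    if fit.no_break:
        return ThermalTraits(sid, None, t50, fit.m1, None, fvfm_max, fit.converged,
                             "no-break" + (f"; t_50: {t50_reason}" if t50_reason else ""))
    reason = f"t_50: {t50_reason}" if t50_reason else ""
    return ThermalTraits(sid, fit.psi, t50, fit.m1, fit.m2, fvfm_max, fit.converged, reason)


def extract_traits(
    curves,
    start_temperature: float = 25.0,
) -> pd.DataFrame:
    """Fit every curve and tabulate its four thermal traits.

    Returns one row per sample with columns ``sample_id, t_crit, t_50,
    m1, m2, fvfm_max, converged, reason``.  Fit failures are recorded in
    ``reason`` with the affected traits absent; they are never fatal.
    """
    rows = []
    for curve in curves:
        tr = _fit_curve(curve, start_temperature)
        rows.append(
            {
                "sample_id": tr.sample_id,
                "t_crit": np.nan if tr.t_crit is None else tr.t_crit,
                "t_50": np.nan if tr.t_50 is None else tr.t_50,
                "m1": np.nan if tr.m1 is None else tr.m1,
                "m2": np.nan if tr.m2 is None else tr.m2,
                "fvfm_max": np.nan if tr.fvfm_max is None else tr.fvfm_max,
                "converged": tr.converged,
                "reason": tr.reason,
            }
        )
    cols = ["sample_id", "t_crit", "t_50", "m1", "m2", "fvfm_max", "converged", "reason"]
    return pd.DataFrame(rows, columns=cols)
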