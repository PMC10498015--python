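"""Reading, validation and quality control of Fv/Fm temperature-ramp curves.

A *curve* is the series of chlorophyll-fluorescence readings taken from one
leaf sample while the measurement surface is ramped from 25 to 55 degC in
1 degC steps.  Each reading records minimal fluorescence ``F_o`` (measuring
light only) and maximal fluorescence ``F_m`` (saturating pulse); the maximum
quantum efficiency of photosystem II is ``Fv/Fm = (F_m - F_o)/F_m``.  A
"room"-temperature reading taken before the ramp starts is retained for
reference but never enters model fits, because its temperature is not on the
controlled grid.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import CurveInputError, InvalidReadingError

__all__ = [
    "FluorescencePoint",
    "SampleMeta",
    "FluorescenceCurve",
    "QcReport",
    "compute_fvfm",
    "read_curve_table",
    "curves_from_frame",
    "curves_to_frame",
    "write_curves_long",
    "qc_curves",
]

#: Sentinel temperature label for the pre-ramp (dark-adapted) reading.
ROOM = "room"

#: Tolerance for deciding whether a parsed temperature sits on the 1 degC grid.
GRID_TOL = 0.01


def compute_fvfm(f_o: float, f_m: float) -> float:
    """Maximum quantum efficiency of PSII, ``(F_m - F_o) / F_m``.

    Parameters
    ----------
    f_o : float
        Minimal fluorescence under the measuring light, >= 0.
    f_m : float
        Maximal fluorescence under the saturating pulse, > 0.

    Returns
    -------
    float
        The dimensionless ratio, in [0, 1] whenever ``f_o <= f_m``.

    Raises
    ------
    InvalidReadingError
        If ``f_m <= 0``, ``f_o < 0``, or ``f_o > f_m`` — readings that a
        functioning instrument cannot produce on dark-adapted tissue.
    """
    if not (f_m > 0):
        raise InvalidReadingError(f"non-positive F_m reading: {f_m!r}")
    if f_o < 0:
        raise InvalidReadingError(f"negative F_o reading: {f_o!r}")
    if f_o > f_m:
        raise InvalidReadingError(f"F_o {f_o!r} exceeds F_m {f_m!r}")
    return (f_m - f_o) / f_m


@dataclass(frozen=True)
class FluorescencePoint:
    """One fluorescence reading at one ramp temperature.

    ``temperature`` is in degC; ``None`` marks the pre-ramp "room" reading.
    ``fvfm`` is ``None`` when the raw readings were invalid (the point is
    kept so the record of the measurement is complete, but it never enters
    a fit).
    """

    temperature: float | None
    f_o: float
    f_m: float
    fvfm: float | None = field(default=None)

    @classmethod
    def from_raw(cls, temperature: float | None, f_o: float, f_m: float) -> "FluorescencePoint":
        try:
            ratio = compute_fvfm(f_o, f_m)
        except InvalidReadingError:
            ratio = None
        return cls(temperature, f_o, f_m, ratio)

    @property
    def is_ramp(self) -> bool:
        return self.temperature is not None


@dataclass(frozen=True)
class SampleMeta:
    """Experimental-design labels for one plant sample.

    ``round_id`` and ``time_slot`` jointly index the measurement batch
    (their interaction is a random effect downstream); ``container_id`` is
    the growth container the plant came from.
    """

    sample_id: str
    genotype_id: str
    species: str = ""
    round_id: str = ""
    time_slot: str = ""
    container_id: str = ""

    @property
    def round_time_id(self) -> str:
        return f"{self.round_id}:{self.time_slot}"


@dataclass
class FluorescenceCurve:
    """One sample's ordered Fv/Fm-temperature series plus its metadata."""

    meta: SampleMeta
    points: list[FluorescencePoint]

    def __post_init__(self) -> None:
        ramp = [p for p in self.points if p.is_ramp]
        temps = [p.temperature for p in ramp]
        if any(t2 <= t1 for t1, t2 in zip(temps, temps[1:])):
            raise CurveInputError(
                f"sample {self.meta.sample_id!r}: ramp temperatures not strictly increasing"
            )

    @property
    def ramp_points(self) -> list[FluorescencePoint]:
        return [p for p in self.points if p.is_ramp]

    @property
    def room_point(self) -> FluorescencePoint | None:
        for p in self.points:
            if not p.is_ramp:
                return p
        return None

    def ramp_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """(temperatures, fvfm) for ramp points with a valid ratio."""
        pts = [p for p in self.ramp_points if p.fvfm is not None]
        t = np.array([p.temperature for p in pts], dtype=float)
        y = np.array([p.fvfm for p in pts], dtype=float)
        return t, y

    def fvfm_at(self, temperature: float, tol: float = GRID_TOL) -> float | None:
        for p in self.ramp_points:
            if abs(p.temperature - temperature) <= tol:
                return p.fvfm
        return None


# ---------------------------------------------------------------------------
# parsing


def _parse_temperature(label: object) -> float | None:
    """Parse a column header / cell into degC, or None for the room reading."""
    if isinstance(label, str) and label.strip().lower() == ROOM:
        return None
    try:
        value = float(label)  # type: ignore[arg-type]
    except (TypeError, ValueError):
        raise CurveInputError(f"malformed temperature label: {label!r}") from None
    if not math.isfinite(value):
        raise CurveInputError(f"malformed temperature label: {label!r}")
    return value


def _read_sample_map(sample_map: pd.DataFrame) -> dict[str, SampleMeta]:
    required = {"sample_id", "genotype_id"}
    missing = required - set(sample_map.columns)
    if missing:
        raise CurveInputError(f"sample map lacks columns: {sorted(missing)}")
    metas: dict[str, SampleMeta] = {}
    for row in sample_map.itertuples(index=False):
        sid = str(row.sample_id)
        if sid in metas:
            raise CurveInputError(f"duplicate sample_id in sample map: {sid!r}")
        metas[sid] = SampleMeta(
            sample_id=sid,
            genotype_id=str(row.genotype_id),
            species=str(getattr(row, "species", "")),
            round_id=str(getattr(row, "round_id", "")),
            time_slot=str(getattr(row, "time_slot", "")),
            container_id=str(getattr(row, "container_id", "")),
        )
    return metas


def curves_from_frame(readings: pd.DataFrame, sample_map: pd.DataFrame) -> list[FluorescenceCurve]:
    """Build curves from an in-memory readings table plus a sample map.

    The readings table may be *long* (columns ``sample_id, temperature,
    f_o, f_m``) or *wide* (``sample_id`` plus one Fv/Fm column per
    temperature step, e.g. ``room, 25, 26, ..., 55``).  Wide tables carry
    ratios only, so F_o/F_m are stored as ``fvfm`` and ``1.0``.
    """
    metas = _read_sample_map(sample_map)
    long_cols = {"sample_id", "temperature", "f_o", "f_m"}
    if long_cols.issubset(readings.columns):
        return _curves_from_long(readings, metas)
    if "sample_id" in readings.columns:
        return _curves_from_wide(readings, metas)
    raise CurveInputError(
        "readings table is neither long (sample_id/temperature/f_o/f_m) "
        "nor wide (sample_id + temperature columns)"
    )


def _require_meta(metas: dict[str, SampleMeta], sid: str) -> SampleMeta:
    if sid not in metas:
        raise CurveInputError(f"sample {sid!r} present in readings but absent from sample map")
    return metas[sid]


def _curves_from_long(readings: pd.DataFrame, metas: dict[str, SampleMeta]) -> list[FluorescenceCurve]:
    curves = []
    for sid, grp in readings.groupby("sample_id", sort=False):
        meta = _require_meta(metas, str(sid))
        pts = []
        for row in grp.itertuples(index=False):
            temp = _parse_temperature(row.temperature)
            pts.append(FluorescencePoint.from_raw(temp, float(row.f_o), float(row.f_m)))
        room = [p for p in pts if not p.is_ramp]
        ramp = sorted((p for p in pts if p.is_ramp), key=lambda p: p.temperature)
        curves.append(FluorescenceCurve(meta, room + ramp))
    return curves


def _curves_from_wide(readings: pd.DataFrame, metas: dict[str, SampleMeta]) -> list[FluorescenceCurve]:
    temp_cols = [(c, _parse_temperature(c)) for c in readings.columns if c != "sample_id"]
    if readings["sample_id"].duplicated().any():
        dupes = readings.loc[readings["sample_id"].duplicated(), "sample_id"].tolist()
        raise CurveInputError(f"duplicate sample_id rows in wide table: {dupes}")
    curves = []
    for _, row in readings.iterrows():
        meta = _require_meta(metas, str(row["sample_id"]))
        pts = []
        for col, temp in temp_cols:
            value = row[col]
            if pd.isna(value):
                continue
            ratio = float(value)
            # wide layout carries the ratio only; store it with F_m = 1
            pts.append(FluorescencePoint(temp, 1.0 - ratio, 1.0, ratio))
        room = [p for p in pts if not p.is_ramp]
        ramp = sorted((p for p in pts if p.is_ramp), key=lambda p: p.temperature)
        curves.append(FluorescenceCurve(meta, room + ramp))
    return curves


def read_curve_table(path: str, sample_map_path: str, sep: str = ",") -> list[FluorescenceCurve]:
    """Read a readings table (long or wide) and its sample map from disk."""
    readings = pd.read_csv(path, sep=sep)
    sample_map = pd.read_csv(sample_map_path, sep=sep)
    return curves_from_frame(readings, sample_map)


def curves_to_frame(curves: Iterable[FluorescenceCurve]) -> pd.DataFrame:
    """Serialize curves to the canonical long layout (room rows labelled 'room')."""
    rows = []
    for c in curves:
        for p in c.points:
            rows.append(
                {
                    "sample_id": c.meta.sample_id,
                    "temperature": ROOM if p.temperature is None else p.temperature,
                    "f_o": p.f_o,
                    "f_m": p.f_m,
                }
            )
    return pd.DataFrame(rows, columns=["sample_id", "temperature", "f_o", "f_m"])


def write_curves_long(curves: Iterable[FluorescenceCurve], path: str) -> None:
    curves_to_frame(curves).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# quality control


@dataclass
class QcReport:
    """Outcome of curve-level quality control."""

    n_input: int
    n_kept: int
    rejections: list[dict]
    params: dict

    @property
    def empty_output(self) -> bool:
        return self.n_kept == 0

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "n_input": self.n_input,
                    "n_kept": self.n_kept,
                    "empty_output": self.empty_output,
                    "params": self.params,
                    "rejections": self.rejections,
                },
                fh,
                indent=2,
            )


def qc_curves(
    curves: Sequence[FluorescenceCurve],
    min_points: int = 10,
    min_initial_fvfm: float = 0.5,
    max_gap: float = 2.0,
    start_temperature: float = 25.0,
) -> tuple[list[FluorescenceCurve], QcReport]:
    """Gate curves on ramp completeness and a healthy starting Fv/Fm.

    A curve is rejected when it has fewer than ``min_points`` valid ramp
    points, when its reading at ``start_temperature`` (the ramp start,
    where Fv/Fm is maximal in healthy dark-adapted tissue) is missing or
    below ``min_initial_fvfm``, or when consecutive ramp temperatures are
    more than ``max_gap`` degC apart.
    """
    kept: list[FluorescenceCurve] = []
    rejections: list[dict] = []
    for curve in curves:
        t, y = curve.ramp_arrays()
        reason = None
        if t.size < min_points:
            reason = f"too few ramp points ({t.size} < {min_points})"
        else:
            start = curve.fvfm_at(start_temperature)
            if start is None:
                reason = f"missing {start_temperature:g} degC reading"
            elif start < min_initial_fvfm:
                reason = f"low initial Fv/Fm ({start:.3f} < {min_initial_fvfm:g})"
            elif t.size > 1 and float(np.max(np.diff(t))) > max_gap:
                reason = f"ramp gap ({float(np.max(np.diff(t))):g} degC > {max_gap:g} degC)"
        if reason is None:
            kept.append(curve)
        else:
            rejections.append({"sample_id": curve.meta.sample_id, "reason": reason})
    report = QcReport(
        n_input=len(curves),
        n_kept=len(kept),
        rejections=rejections,
        params={
            "min_points": min_points,
            "min_initial_fvfm": min_initial_fvfm,
            "max_gap": max_gap,
            "start_temperature": start_temperature,
        },
    )
    return kept, report
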