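"""Data model and CSV I/O for grid campaigns and questionnaire surveys.

Two tabular inputs drive the pipeline:

* a *grid campaign* file: one row per flux-density reading on the canonical
  measurement grid around a household induction cooker, with the household's
  device covariates repeated on each row;
* a *questionnaire survey* file: one row per subject with self-reported
  geometry (and, for validation surveys, a paired measured exposure at
  iliac-crest height).

Units at the file boundary are questionnaire-natural (cm, W, uT); device
lengths are converted to meters exactly once at parse time because the dipole
models are dimensionally consistent in meters.  The CSV dialect is fixed:
comma-separated, UTF-8, decimal point, header row required.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from importlib import resources
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, RecordValidationError

CANONICAL_H_CM = (-20.0, -10.0, 0.0, 10.0, 20.0)
CANONICAL_D_CM = (0.0, 10.0, 20.0, 30.0)

GRID_COLUMNS = [
    "household_id",
    "h_cm",
    "d_cm",
    "b_ut",
    "wattage_w",
    "cookware_diameter_cm",
    "hob_offset_cm",
    "table_height_cm",
]

QUESTIONNAIRE_COLUMNS = [
    "subject_id",
    "stature_cm",
    "dh_center_cm",
    "d_edge_cm",
    "cookware_diameter_cm",
    "wattage_w",
    "measured_b_ut",
]

SUMMARY_COLUMNS = [
    "h_cm",
    "d_cm",
    "n",
    "mean_ut",
    "sd_ut",
    "gm_ut",
    "gsd",
    "q1_ut",
    "median_ut",
    "q3_ut",
]

_REL_TOL = 1e-9  # slack for invariants checked on rounded/printed values


@dataclass(frozen=True)
class GridMeasurement:
    """One wideband RMS flux-density reading (uT) at a grid position.

    ``h_cm`` is the signed height relative to the cooktop surface; ``d_cm``
    the horizontal distance from the cooktop edge.
    """

    household_id: str
    h_cm: float
    d_cm: float
    b_ut: float

    def __post_init__(self):
        if self.b_ut < 0:
            raise RecordValidationError(
                f"b_ut must be >= 0, got {self.b_ut} for household "
                f"{self.household_id!r}"
            )

    @property
    def is_canonical(self) -> bool:
        return self.h_cm in CANONICAL_H_CM and self.d_cm in CANONICAL_D_CM


@dataclass(frozen=True)
class HouseholdDevice:
    """Induction-cooker covariates for one household (lengths in meters)."""

    household_id: str
    wattage_w: float
    cookware_diameter_m: float
    hob_offset_m: float
    table_height_m: Optional[float] = None

    def __post_init__(self):
        if self.wattage_w <= 0:
            raise RecordValidationError(
                f"wattage_w must be positive, got {self.wattage_w}"
            )
        if not 0 < self.cookware_diameter_m < 0.5:
            raise RecordValidationError(
                "cookware_diameter_m must lie in (0, 0.5) m, got "
                f"{self.cookware_diameter_m}"
            )
        if self.hob_offset_m <= 0:
            raise RecordValidationError(
                f"hob_offset_m must be positive, got {self.hob_offset_m}"
            )


@dataclass(frozen=True)
class QuestionnaireResponse:
    """Self-reported variables for one subject.

    Optional fields are ``None`` when unanswered -- never zero-filled.  At
    least one of the two distance reports must be present.
    """

    subject_id: str
    stature_cm: float
    dh_center_cm: Optional[float] = None
    d_edge_cm: Optional[float] = None
    cookware_diameter_cm: Optional[float] = None
    wattage_w: Optional[float] = None
    measured_b_ut: Optional[float] = None

    def __post_init__(self):
        if self.stature_cm <= 0:
            raise RecordValidationError(
                f"stature_cm must be positive, got {self.stature_cm}"
            )
        if self.dh_center_cm is None and self.d_edge_cm is None:
            raise RecordValidationError(
                f"subject {self.subject_id!r}: at least one of dh_center_cm / "
                "d_edge_cm must be reported"
            )


@dataclass(frozen=True)
class GridSummary:
    """Summary statistics of flux density for one (h, d) grid cell.

    GM/GSD are the geometric mean and geometric standard deviation
    (exp of mean / SD of log values); they are NaN for cells containing a
    zero reading.  Quartiles follow the linear-interpolation (type-7) rule.
    """

    h_cm: float
    d_cm: float
    n: int
    mean_ut: float
    sd_ut: float
    gm_ut: float
    gsd: float
    q1_ut: float
    median_ut: float
    q3_ut: float

    def __post_init__(self):
        if math.isfinite(self.gm_ut):
            if self.gm_ut > self.mean_ut * (1 + _REL_TOL) + 1e-12:
                raise RecordValidationError(
                    f"cell (h={self.h_cm}, d={self.d_cm}): GM {self.gm_ut} "
                    f"exceeds arithmetic mean {self.mean_ut}"
                )
        if math.isfinite(self.gsd) and self.gsd < 1 - _REL_TOL:
            raise RecordValidationError(
                f"cell (h={self.h_cm}, d={self.d_cm}): GSD {self.gsd} < 1"
            )
        if not (
            self.q1_ut <= self.median_ut * (1 + _REL_TOL) + 1e-12
            and self.median_ut <= self.q3_ut * (1 + _REL_TOL) + 1e-12
        ):
            raise RecordValidationError(
                f"cell (h={self.h_cm}, d={self.d_cm}): quartiles out of order"
            )


def _optional(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    return float(value)


def _read_frame(path, required: Sequence[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file, expected a CSV header") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")
    return df


def read_grid_csv(path):
    """Parse a grid-campaign CSV.

    Returns ``(measurements, devices)`` with household covariates
    deduplicated by ``household_id``.  Raises :class:`FormatError` for schema
    problems and :class:`RecordValidationError` (citing the file row) for
    invalid values.
    """
    df = _read_frame(path, GRID_COLUMNS)
    measurements: list[GridMeasurement] = []
    devices: dict[str, HouseholdDevice] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        hid = str(row.household_id)
        b = float(row.b_ut)
        if b < 0:
            raise RecordValidationError(f"{path} row {i}: b_ut = {b} is negative")
        measurements.append(
            GridMeasurement(hid, float(row.h_cm), float(row.d_cm), b)
        )
        if hid not in devices:
            try:
                devices[hid] = HouseholdDevice(
                    household_id=hid,
                    wattage_w=float(row.wattage_w),
                    cookware_diameter_m=float(row.cookware_diameter_cm) / 100.0,
                    hob_offset_m=float(row.hob_offset_cm) / 100.0,
                    table_height_m=(
                        None
                        if _optional(row.table_height_cm) is None
                        else float(row.table_height_cm) / 100.0
                    ),
                )
            except RecordValidationError as exc:
                raise RecordValidationError(f"{path} row {i}: {exc}") from exc
    if measurements and not all(m.is_canonical for m in measurements):
        warnings.warn(
            f"{path}: grid contains non-canonical (h, d) positions; "
            "the canonical campaign grid is h in {-20,-10,0,10,20} cm, "
            "d in {0,10,20,30} cm",
            stacklevel=2,
        )
    return measurements, list(devices.values())


def write_grid_csv(path, measurements: Iterable[GridMeasurement],
                   devices: Iterable[HouseholdDevice]) -> None:
    """Write a grid-campaign CSV (inverse of :func:`read_grid_csv`)."""
    by_id = {d.household_id: d for d in devices}
    rows = []
    for m in measurements:
        dev = by_id[m.household_id]
        rows.append(
            {
                "household_id": m.household_id,
                "h_cm": m.h_cm,
                "d_cm": m.d_cm,
                "b_ut": m.b_ut,
                "wattage_w": dev.wattage_w,
                "cookware_diameter_cm": dev.cookware_diameter_m * 100.0,
                "hob_offset_cm": dev.hob_offset_m * 100.0,
                "table_height_cm": (
                    "" if dev.table_height_m is None else dev.table_height_m * 100.0
                ),
            }
        )
    pd.DataFrame(rows, columns=GRID_COLUMNS).to_csv(path, index=False)


def read_questionnaire_csv(path) -> list[QuestionnaireResponse]:
    """Parse a questionnaire-survey CSV; unanswered optionals become None."""
    required = ["subject_id", "stature_cm"]
    df = _read_frame(path, required)
    responses = []
    for i, row in enumerate(df.to_dict(orient="records"), start=2):
        try:
            responses.append(
                QuestionnaireResponse(
                    subject_id=str(row["subject_id"]),
                    stature_cm=float(row["stature_cm"]),
                    dh_center_cm=_optional(row.get("dh_center_cm")),
                    d_edge_cm=_optional(row.get("d_edge_cm")),
                    cookware_diameter_cm=_optional(row.get("cookware_diameter_cm")),
                    wattage_w=_optional(row.get("wattage_w")),
                    measured_b_ut=_optional(row.get("measured_b_ut")),
                )
            )
        except RecordValidationError as exc:
            raise RecordValidationError(f"{path} row {i}: {exc}") from exc
    return responses


def write_questionnaire_csv(path, responses: Iterable[QuestionnaireResponse]) -> None:
    rows = [
        {
            "subject_id": r.subject_id,
            "stature_cm": r.stature_cm,
            "dh_center_cm": r.dh_center_cm,
            "d_edge_cm": r.d_edge_cm,
            "cookware_diameter_cm": r.cookware_diameter_cm,
            "wattage_w": r.wattage_w,
            "measured_b_ut": r.measured_b_ut,
        }
        for r in responses
    ]
    pd.DataFrame(rows, columns=QUESTIONNAIRE_COLUMNS).to_csv(path, index=False)


def summarize_grid(measurements: Iterable[GridMeasurement]) -> list[GridSummary]:
    """Per-(h, d)-cell summary statistics in campaign-report layout.

    GM = exp(mean log b), GSD = exp(SD of log b) with the n-1 denominator;
    quartiles use numpy's default linear-interpolation (type-7) rule.  Cells
    containing a zero reading get NaN GM/GSD with a warning, since the log
    transform is undefined there.
    """
    cells: dict[tuple[float, float], list[float]] = {}
    for m in measurements:
        cells.setdefault((m.h_cm, m.d_cm), []).append(m.b_ut)
    out = []
    for (h, d) in sorted(cells, key=lambda hd: (-hd[0], hd[1])):
        vals = np.asarray(cells[(h, d)], dtype=float)
        n = len(vals)
        mean = float(vals.mean())
        sd = float(vals.std(ddof=1)) if n > 1 else 0.0
        if np.any(vals == 0):
            warnings.warn(
                f"cell (h={h}, d={d}) contains zero readings; "
                "GM/GSD undefined for this cell",
                stacklevel=2,
            )
            gm, gsd = math.nan, math.nan
        else:
            logs = np.log(vals)
            gm = float(np.exp(logs.mean()))
            gsd = float(np.exp(logs.std(ddof=1))) if n > 1 else 1.0
        q1, med, q3 = np.quantile(vals, [0.25, 0.5, 0.75])
        out.append(
            GridSummary(h, d, n, mean, sd, gm, gsd, float(q1), float(med), float(q3))
        )
    return out


def write_summary_csv(path, summaries: Iterable[GridSummary]) -> None:
    rows = [
        {c: getattr(s, c) for c in SUMMARY_COLUMNS}
        for s in summaries
    ]
    pd.DataFrame(rows, columns=SUMMARY_COLUMNS).to_csv(path, index=False)


def read_summary_csv(path) -> list[GridSummary]:
    df = _read_frame(path, SUMMARY_COLUMNS)
    return [
        GridSummary(
            h_cm=float(r.h_cm),
            d_cm=float(r.d_cm),
            n=int(r.n),
            mean_ut=float(r.mean_ut),
            sd_ut=float(r.sd_ut),
            gm_ut=float(r.gm_ut),
            gsd=float(r.gsd),
            q1_ut=float(r.q1_ut),
            median_ut=float(r.median_ut),
            q3_ut=float(r.q3_ut),
        )
        for r in df.itertuples(index=False)
    ]


def load_reference_grid_summary() -> list[GridSummary]:
    """The packaged 20-cell reference campaign summary (45 households/cell).

    Values are stored digit-for-digit as published for the Phase-1 campaign;
    they are shipped data, never recomputed.
    """
    ref = resources.files("cookfield") / "data/reference_grid_summary.csv"
    with resources.as_file(ref) as p:
        return read_summary_csv(p)
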