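"""Core EHR domain model: cohort tables, invariants, and delimited-text I/O.

A *cohort* is four aligned long-format tables:

``encounters``
    One row per ED-initiated hospital visit: opaque ``encounter_id``,
    demographics (sex, age, race), six comorbidity flags, and the visit's
    time bounds ``ed_arrival``/``discharge``.
``observations``
    Timestamped clinical measurements (vitals, labs, GCS, vasopressor
    infusion rates, ventilation flag) feeding SOFA sub-scores. One canonical
    unit per kind; no on-the-fly conversion.
``orders``
    Timestamped blood-culture and antibiotic order events.
``alerts``
    Timestamped predictive-model score events with a chart-viewed flag.
    An alert only counts as *fired* downstream when the score reaches the
    display threshold AND the chart was viewed.

All timestamps are ISO-8601 with explicit offset on disk and normalized to
UTC in memory, so lead-time arithmetic is timezone-safe. Encounter spans are
closed ``[ed_arrival, discharge]``; scoring-grid bins are half-open
``[t, t + step)``.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

SEXES = ("female", "male")
RACES = ("Asian", "Black", "Hispanic", "White", "Other")
COMORBIDITIES = (
    "diabetes",
    "hyperlipidemia",
    "chronic_kidney_disease",
    "cabg",
    "pvd",
    "stroke",
)
VASOPRESSORS = ("dopamine", "dobutamine", "epinephrine", "norepinephrine")

#: Physiologic plausibility bounds per observation kind (closed intervals,
#: canonical units). Rows outside these bounds are rejected at read time.
#: pf_ratio mmHg; platelets 10^3/uL; bilirubin mg/dL; map mmHg; gcs integer
#: 3-15; creatinine mg/dL; urine_output_24h mL/day; vasopressors ug/kg/min;
#: ventilated 0/1.
PLAUSIBILITY_BOUNDS: dict[str, tuple[float, float]] = {
    "pf_ratio": (1.0, 1000.0),
    "platelets": (0.0, 2000.0),
    "bilirubin": (0.0, 80.0),
    "map": (10.0, 300.0),
    "gcs": (3.0, 15.0),
    "creatinine": (0.0, 40.0),
    "urine_output_24h": (0.0, 20000.0),
    "dopamine": (0.0, 100.0),
    "dobutamine": (0.0, 100.0),
    "epinephrine": (0.0, 10.0),
    "norepinephrine": (0.0, 10.0),
    "ventilated": (0.0, 1.0),
}
OBSERVATION_KINDS = tuple(PLAUSIBILITY_BOUNDS)
ORDER_KINDS = ("blood_culture", "antibiotic")

ENCOUNTER_COLUMNS = [
    "encounter_id",
    "sex",
    "age_years",
    "race",
    *COMORBIDITIES,
    "ed_arrival",
    "discharge",
]
OBSERVATION_COLUMNS = ["encounter_id", "timestamp", "kind", "value"]
ORDER_COLUMNS = ["encounter_id", "timestamp", "kind"]
ALERT_COLUMNS = ["encounter_id", "timestamp", "model_score", "chart_viewed"]

TABLE_COLUMNS: dict[str, list[str]] = {
    "encounters": ENCOUNTER_COLUMNS,
    "observations": OBSERVATION_COLUMNS,
    "orders": ORDER_COLUMNS,
    "alerts": ALERT_COLUMNS,
}
TABLE_NAMES = tuple(TABLE_COLUMNS)

_TS_FORMAT = "%Y-%m-%dT%H:%M:%S+00:00"


class SchemaError(ValueError):
    """A table is missing a required column or is otherwise malformed."""


class ReferentialError(ValueError):
    """A child table references an encounter_id absent from encounters."""


@dataclasses.dataclass(frozen=True)
class GridSpec:
    """Scoring-grid specification: a fixed step anchored at each encounter's
    ED arrival (``origin=None``) or at an explicit origin timestamp.

    ``step_minutes`` must divide 60 so grid times stay on round clock marks.
    """

    step_minutes: int = 15
    origin: pd.Timestamp | None = None

    def __post_init__(self) -> None:
        if self.step_minutes <= 0 or 60 % self.step_minutes != 0:
            raise ValueError(
                f"step_minutes must be a positive divisor of 60, got {self.step_minutes}"
            )

    @property
    def step(self) -> pd.Timedelta:
        return pd.Timedelta(minutes=self.step_minutes)


@dataclasses.dataclass
class Cohort:
    """The four cohort tables plus per-row rejection diagnostics from read time."""

    encounters: pd.DataFrame
    observations: pd.DataFrame
    orders: pd.DataFrame
    alerts: pd.DataFrame
    rejections: pd.DataFrame = dataclasses.field(
        default_factory=lambda: _empty_rejections()
    )

    def __post_init__(self) -> None:
        for name in TABLE_NAMES:
            df = getattr(self, name)
            missing = [c for c in TABLE_COLUMNS[name] if c not in df.columns]
            if missing:
                raise SchemaError(f"{name}: missing column(s) {missing}")


def _empty_rejections() -> pd.DataFrame:
    return pd.DataFrame(columns=["table", "line", "encounter_id", "reason"])


def _empty_table(name: str) -> pd.DataFrame:
    df = pd.DataFrame(columns=TABLE_COLUMNS[name])
    for col in TABLE_COLUMNS[name]:
        if col in ("ed_arrival", "discharge", "timestamp"):
            df[col] = pd.Series(dtype="datetime64[ns, UTC]")
        elif col in ("age_years", "model_score"):
            df[col] = pd.Series(dtype="int64")
        elif col in COMORBIDITIES or col == "chart_viewed":
            df[col] = pd.Series(dtype="bool")
        elif col == "value":
            df[col] = pd.Series(dtype="float64")
        else:
            df[col] = pd.Series(dtype="object")
    return df


def _read_raw(path: Path | str, name: str) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"encounter_id": str}, encoding="utf-8")
    missing = [c for c in TABLE_COLUMNS[name] if c not in df.columns]
    if missing:
        raise SchemaError(f"{name}: missing column(s) {missing}")
    return df[TABLE_COLUMNS[name]].copy()


def _parse_timestamps(
    df: pd.DataFrame, cols: list[str], table: str, diagnostics: list[dict]
) -> pd.DataFrame:
    """Parse ISO-8601 timestamp columns to UTC; reject unparseable rows.

    ``line`` in the diagnostics is the 1-based physical line number in the
    source file (header is line 1).
    """
    bad = pd.Series(False, index=df.index)
    for col in cols:
        parsed = pd.to_datetime(df[col], utc=True, errors="coerce")
        newly_bad = parsed.isna() & df[col].notna() | df[col].isna()
        for idx in df.index[newly_bad & ~bad]:
            diagnostics.append(
                {
                    "table": table,
                    "line": int(idx) + 2,
                    "encounter_id": df.at[idx, "encounter_id"],
                    "reason": f"unparseable timestamp in column {col!r}: {df.at[idx, col]!r}",
                }
            )
        bad |= newly_bad
        df[col] = parsed
    return df[~bad].copy()


def _reject(
    df: pd.DataFrame,
    mask: pd.Series,
    table: str,
    reason_of,
    diagnostics: list[dict],
) -> pd.DataFrame:
    for idx in df.index[mask]:
        diagnostics.append(
            {
                "table": table,
                "line": int(idx) + 2,
                "encounter_id": df.at[idx, "encounter_id"],
                "reason": reason_of(df.loc[idx]),
            }
        )
    return df[~mask]


def _coerce_bool(series: pd.Series) -> pd.Series:
    mapping = {
        "true": True, "false": False, "1": True, "0": False,
        "True": True, "False": False,
    }
    if series.dtype == bool:
        return series
    return series.map(lambda v: mapping.get(str(v).strip(), bool(int(float(v)))))


def read_cohort(paths: Mapping[str, Path | str]) -> Cohort:
    """Read and validate the four cohort tables.

    Invariant-violating rows (out-of-bounds values, timestamps outside the
    encounter span, unknown categories, unparseable timestamps) are dropped
    and recorded one-per-row in ``Cohort.rejections`` with the source table,
    physical line number and reason. Structural problems raise instead:
    a missing column raises :class:`SchemaError`; a child row referencing an
    unknown ``encounter_id`` raises :class:`ReferentialError`.
    """
    diagnostics: list[dict] = []

    enc = _read_raw(paths["encounters"], "encounters")
    enc = _parse_timestamps(enc, ["ed_arrival", "discharge"], "encounters", diagnostics)
    enc = _reject(
        enc,
        enc["encounter_id"].duplicated(),
        "encounters",
        lambda r: f"duplicate encounter_id {r['encounter_id']!r}",
        diagnostics,
    )
    enc = _reject(
        enc,
        ~enc["sex"].isin(SEXES),
        "encounters",
        lambda r: f"unknown sex {r['sex']!r}",
        diagnostics,
    )
    enc = _reject(
        enc,
        ~enc["race"].isin(RACES),
        "encounters",
        lambda r: f"unknown race {r['race']!r}",
        diagnostics,
    )
    age = pd.to_numeric(enc["age_years"], errors="coerce")
    enc = _reject(
        enc,
        age.isna() | (age < 18),
        "encounters",
        lambda r: f"age_years must be an integer >= 18, got {r['age_years']!r}",
        diagnostics,
    )
    enc["age_years"] = enc["age_years"].astype(np.int64)
    enc = _reject(
        enc,
        enc["discharge"] < enc["ed_arrival"],
        "encounters",
        lambda r: "discharge precedes ed_arrival",
        diagnostics,
    )
    for flag in COMORBIDITIES:
        enc[flag] = _coerce_bool(enc[flag])
    enc = enc.reset_index(drop=True)

    bounds = enc.set_index("encounter_id")[["ed_arrival", "discharge"]]

    def check_children(df: pd.DataFrame, table: str) -> pd.DataFrame:
        orphans = sorted(set(df["encounter_id"]) - set(bounds.index))
        if orphans:
            raise ReferentialError(
                f"{table}: encounter_id(s) not present in encounters: {orphans[:10]}"
                + ("..." if len(orphans) > 10 else "")
            )
        arr = df["encounter_id"].map(bounds["ed_arrival"])
        dis = df["encounter_id"].map(bounds["discharge"])
        return _reject(
            df,
            (df["timestamp"] < arr) | (df["timestamp"] > dis),
            table,
            lambda r: "timestamp outside encounter bounds",
            diagnostics,
        )

    obs = _read_raw(paths["observations"], "observations")
    obs = _parse_timestamps(obs, ["timestamp"], "observations", diagnostics)
    obs = _reject(
        obs,
        ~obs["kind"].isin(OBSERVATION_KINDS),
        "observations",
        lambda r: f"unknown observation kind {r['kind']!r}",
        diagnostics,
    )
    obs["value"] = pd.to_numeric(obs["value"], errors="coerce")
    lo = obs["kind"].map({k: b[0] for k, b in PLAUSIBILITY_BOUNDS.items()})
    hi = obs["kind"].map({k: b[1] for k, b in PLAUSIBILITY_BOUNDS.items()})
    obs = _reject(
        obs,
        obs["value"].isna() | (obs["value"] < lo) | (obs["value"] > hi),
        "observations",
        lambda r: (
            f"value {r['value']!r} outside plausibility bounds "
            f"{PLAUSIBILITY_BOUNDS[r['kind']]} for kind {r['kind']!r}"
        ),
        diagnostics,
    )
    obs = check_children(obs, "observations").reset_index(drop=True)

    orders = _read_raw(paths["orders"], "orders")
    orders = _parse_timestamps(orders, ["timestamp"], "orders", diagnostics)
    orders = _reject(
        orders,
        ~orders["kind"].isin(ORDER_KINDS),
        "orders",
        lambda r: f"unknown order kind {r['kind']!r}",
        diagnostics,
    )
    orders = check_children(orders, "orders").reset_index(drop=True)

    alerts = _read_raw(paths["alerts"], "alerts")
    alerts = _parse_timestamps(alerts, ["timestamp"], "alerts", diagnostics)
    score = pd.to_numeric(alerts["model_score"], errors="coerce")
    alerts = _reject(
        alerts,
        score.isna() | (score < 0) | (score != score.round()),
        "alerts",
        lambda r: f"model_score must be a non-negative integer, got {r['model_score']!r}",
        diagnostics,
    )
    alerts["model_score"] = alerts["model_score"].astype(np.int64)
    alerts["chart_viewed"] = _coerce_bool(alerts["chart_viewed"])
    alerts = check_children(alerts, "alerts").reset_index(drop=True)

    rejections = (
        pd.DataFrame(diagnostics, columns=["table", "line", "encounter_id", "reason"])
        if diagnostics
        else _empty_rejections()
    )
    return Cohort(enc, obs, orders, alerts, rejections)


def write_cohort(cohort: Cohort, paths: Mapping[str, Path | str]) -> dict[str, Path]:
    """Write the four tables as UTF-8 comma-separated text.

    Timestamps are rendered ISO-8601 in UTC with an explicit ``+00:00``
    offset; boolean flags as 0/1. Column order is fixed so that
    ``read_cohort(write_cohort(x)) == x`` for any invariant-satisfying
    cohort.
    """
    written: dict[str, Path] = {}
    for name in TABLE_NAMES:
        df = getattr(cohort, name)[TABLE_COLUMNS[name]].copy()
        for col in df.columns:
            if col in ("ed_arrival", "discharge", "timestamp"):
                df[col] = pd.to_datetime(df[col], utc=True).dt.strftime(_TS_FORMAT)
            elif col in COMORBIDITIES or col == "chart_viewed":
                df[col] = df[col].astype(int)
        path = Path(paths[name])
        df.to_csv(path, index=False, encoding="utf-8")
        written[name] = path
    return written


def cohort_paths(directory: Path | str) -> dict[str, Path]:
    """Conventional file layout: one CSV per table inside ``directory``."""
    d = Path(directory)
    return {name: d / f"{name}.csv" for name in TABLE_NAMES}
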