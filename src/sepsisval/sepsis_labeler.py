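"""Sepsis-3 electronic phenotype: per-encounter labels and onset times.

An encounter is labeled septic when (a) its total SOFA score rises by >= 2
points over the baseline at some grid time, and (b) at least one blood
culture AND at least one antibiotic were ordered at any time during the
visit. Onset is the earliest grid time at which the 2-point rise is reached
(first crossing). Encounters crossing the SOFA threshold without both orders
are non-septic with ``orders_satisfied=False``.

Baseline modes
--------------
``first_score`` (default)
    Baseline is the total score at the encounter's first grid time — a
    within-encounter reference, appropriate when "changed by 2 or more
    points" is read relative to presentation.
``zero``
    Baseline 0, the consensus assumption for patients without known prior
    organ dysfunction. Under this mode an encounter whose very first grid
    score is already >= 2 has onset at the first grid time.
"""

from __future__ import annotations

import dataclasses
import logging

import pandas as pd

from .ehr_model import ORDER_KINDS

logger = logging.getLogger(__name__)

BASELINE_MODES = ("first_score", "zero")

LABEL_COLUMNS = [
    "encounter_id",
    "sepsis",
    "onset_time",
    "baseline_sofa",
    "onset_sofa",
    "orders_satisfied",
]


@dataclasses.dataclass(frozen=True)
class SepsisLabel:
    encounter_id: str
    sepsis: bool
    onset_time: pd.Timestamp | None
    baseline_sofa: int
    onset_sofa: int | None
    orders_satisfied: bool


def label_cohort(
    sofa_series: pd.DataFrame,
    orders: pd.DataFrame,
    baseline_mode: str = "first_score",
    encounters: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Label every encounter present in ``sofa_series``.

    Parameters
    ----------
    sofa_series
        Long-format SOFA table from :func:`~sepsisval.sofa_engine.compute_sofa_series`
        (requires ``encounter_id, grid_time, total``), one series per encounter.
    orders
        Order-event table; the blood-culture/antibiotic requirement is
        encounter-level (any time during the visit).
    baseline_mode
        See module docstring.
    encounters
        Optional encounter table; when given, every encounter must have a
        SOFA series (missing ids raise).

    Returns
    -------
    One row per encounter: ``sepsis`` flag, ``onset_time`` (NaT when not
    septic or never crossing), ``baseline_sofa``, ``onset_sofa`` (total at
    the first crossing; <NA> if none) and ``orders_satisfied``.
    """
    if baseline_mode not in BASELINE_MODES:
        raise ValueError(f"baseline_mode must be one of {BASELINE_MODES}")
    if sofa_series.duplicated(["encounter_id", "grid_time"]).any():
        dups = (
            sofa_series.loc[
                sofa_series.duplicated(["encounter_id", "grid_time"]), "encounter_id"
            ]
            .unique()
            .tolist()
        )
        raise ValueError(f"duplicate SOFA series rows for encounter(s): {dups[:10]}")

    s = sofa_series.sort_values(["encounter_id", "grid_time"], kind="stable")
    first = s.drop_duplicates("encounter_id", keep="first")
    enc_ids = sofa_series["encounter_id"].drop_duplicates()

    if encounters is not None:
        missing = sorted(set(encounters["encounter_id"]) - set(enc_ids))
        if missing:
            raise ValueError(
                f"encounters missing a SOFA series: {missing[:10]}"
                + ("..." if len(missing) > 10 else "")
            )

    if baseline_mode == "first_score":
        baseline = first.set_index("encounter_id")["total"]
    else:
        baseline = pd.Series(0, index=pd.Index(first["encounter_id"], name="encounter_id"))

    threshold = s["encounter_id"].map(baseline) + 2
    crossing = s[s["total"] >= threshold]
    onset = crossing.drop_duplicates("encounter_id", keep="first").set_index(
        "encounter_id"
    )

    wide = (
        orders.assign(flag=True)
        .pivot_table(index="encounter_id", columns="kind", values="flag", aggfunc="any")
        .reindex(columns=list(ORDER_KINDS), fill_value=False)
    )
    has_orders = wide.all(axis=1)

    labels = pd.DataFrame({"encounter_id": enc_ids}).reset_index(drop=True)
    labels["onset_time"] = labels["encounter_id"].map(onset["grid_time"])
    labels["baseline_sofa"] = labels["encounter_id"].map(baseline).astype(int)
    labels["onset_sofa"] = labels["encounter_id"].map(onset["total"]).astype("Int64")
    labels["orders_satisfied"] = (
        labels["encounter_id"].map(has_orders).eq(True).astype(bool)
    )
    labels["sepsis"] = labels["onset_time"].notna() & labels["orders_satisfied"]
    labels.loc[~labels["sepsis"], "onset_time"] = pd.NaT
    labels.loc[~labels["sepsis"], "onset_sofa"] = pd.NA
    labels["onset_time"] = pd.to_datetime(labels["onset_time"], utc=True)

    n = len(labels)
    k = int(labels["sepsis"].sum())
    logger.info("labeled %d encounters: %d septic (%.2f%%)", n, k, 100 * k / max(n, 1))
    return labels[LABEL_COLUMNS]


def detect_onset(
    sofa_series: pd.DataFrame,
    orders: pd.DataFrame,
    baseline_mode: str = "first_score",
) -> SepsisLabel:
    """Label a single encounter's SOFA series (always returns a label)."""
    if sofa_series.empty:
        raise ValueError("sofa_series is empty")
    ids = sofa_series["encounter_id"].unique()
    if len(ids) != 1:
        raise ValueError(f"expected a single encounter, got {len(ids)}")
    row = label_cohort(sofa_series, orders, baseline_mode=baseline_mode).iloc[0]
    onset = None if pd.isna(row["onset_time"]) else row["onset_time"]
    return SepsisLabel(
        encounter_id=row["encounter_id"],
        sepsis=bool(row["sepsis"]),
        onset_time=onset,
        baseline_sofa=int(row["baseline_sofa"]),
        onset_sofa=None if pd.isna(row["onset_sofa"]) else int(row["onset_sofa"]),
        orders_satisfied=bool(row["orders_satisfied"]),
    )


def write_labels(labels: pd.DataFrame, path) -> None:
    out = labels.copy()
    out["onset_time"] = pd.to_datetime(out["onset_time"], utc=True).dt.strftime(
        "%Y-%m-%dT%H:%M:%S+00:00"
    )
    out["sepsis"] = out["sepsis"].astype(int)
    out["orders_satisfied"] = out["orders_satisfied"].astype(int)
    out.to_csv(path, index=False, encoding="utf-8")


def read_labels(path) -> pd.DataFrame:
    labels = pd.read_csv(path, dtype={"encounter_id": str})
    labels["onset_time"] = pd.to_datetime(labels["onset_time"], utc=True)
    labels["sepsis"] = labels["sepsis"].astype(bool)
    labels["orders_satisfied"] = labels["orders_satisfied"].astype(bool)
    labels["onset_sofa"] = labels["onset_sofa"].astype("Int64")
    return labels[LABEL_COLUMNS]
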