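"""Sequential Organ Failure Assessment (SOFA) scoring on a fixed time grid.

Implements the six consensus organ sub-scores (respiration, coagulation,
liver, cardiovascular, CNS, renal; each 0-4) and the total score (0-24),
evaluated at every grid time of an encounter from raw timestamped
observations.

Threshold table (severity bins are left-closed on the worse side, i.e. a
value exactly on a printed cutoff takes the *less* severe score unless the
table says otherwise):

===============  =====  ==========  =========  ==================  =======
score            0      1           2          3                   4
===============  =====  ==========  =========  ==================  =======
PaO2/FiO2 mmHg   >=400  <400        <300       <200 + vent         <100 + vent
platelets e3/uL  >=150  <150        <100       <50                 <20
bilirubin mg/dL  <1.2   1.2-1.9     2.0-5.9    6.0-11.9            >=12
cardiovascular   MAP>=70 MAP<70     dop<=5 or  dop>5 or epi<=0.1   dop>15 or
                                    dobutamine or norepi<=0.1      epi>0.1 or
                                                                   norepi>0.1
GCS              15     13-14       10-12      6-9                 <6
creatinine mg/dL <1.2   1.2-1.9     2.0-3.4    3.5-4.9             >=5.0
urine mL/day     --     --          --         <500                <200
===============  =====  ==========  =========  ==================  =======

Respiratory scores 3-4 additionally require ventilatory support; an
unventilated PF ratio below 200 caps at 2. The renal score is the maximum
of the creatinine and urine-output pathways. Vasopressor doses are in
ug/kg/min; any dose, however small, engages the dose rules.

Missing-data policy: at each grid time a sub-score uses the most recent
observation within a configurable lookback (last observation carried
forward, default 24 h). An organ with no observation in the lookback scores
0 (assumed normal) and is flagged in the imputation mask — ED patients lack
many labs early, and scoring unmeasured organs as failing would label nearly
every encounter septic.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .ehr_model import GridSpec, VASOPRESSORS

ORGANS = ("respiration", "coagulation", "liver", "cardiovascular", "cns", "renal")

SOFA_COLUMNS = [
    "encounter_id",
    "grid_time",
    *ORGANS,
    "total",
    *(f"{o}_imputed" for o in ORGANS),
]


# -- vectorized sub-score kernels (NaN input means "no observation" -> 0) --

def _resp(pf: np.ndarray, vent: np.ndarray) -> np.ndarray:
    return np.select(
        [(pf < 100) & vent, (pf < 200) & vent, pf < 300, pf < 400],
        [4, 3, 2, 1],
        default=0,
    )


def _coag(platelets: np.ndarray) -> np.ndarray:
    return np.select(
        [platelets < 20, platelets < 50, platelets < 100, platelets < 150],
        [4, 3, 2, 1],
        default=0,
    )


def _liver(bilirubin: np.ndarray) -> np.ndarray:
    return np.select(
        [bilirubin >= 12, bilirubin >= 6, bilirubin >= 2, bilirubin >= 1.2],
        [4, 3, 2, 1],
        default=0,
    )


def _cardio(
    mean_ap: np.ndarray,
    dopamine: np.ndarray,
    dobutamine: np.ndarray,
    epinephrine: np.ndarray,
    norepinephrine: np.ndarray,
) -> np.ndarray:
    dop = np.nan_to_num(dopamine)
    dob = np.nan_to_num(dobutamine)
    epi = np.nan_to_num(epinephrine)
    nor = np.nan_to_num(norepinephrine)
    return np.select(
        [
            (dop > 15) | (epi > 0.1) | (nor > 0.1),
            (dop > 5) | ((epi > 0) & (epi <= 0.1)) | ((nor > 0) & (nor <= 0.1)),
            ((dop > 0) & (dop <= 5)) | (dob > 0),
            mean_ap < 70,
        ],
        [4, 3, 2, 1],
        default=0,
    )


def _cns(gcs: np.ndarray) -> np.ndarray:
    return np.select([gcs < 6, gcs <= 9, gcs <= 12, gcs <= 14], [4, 3, 2, 1], default=0)


def _renal(creatinine: np.ndarray, urine_24h: np.ndarray) -> np.ndarray:
    by_cr = np.select(
        [creatinine >= 5.0, creatinine >= 3.5, creatinine >= 2.0, creatinine >= 1.2],
        [4, 3, 2, 1],
        default=0,
    )
    by_urine = np.select([urine_24h < 200, urine_24h < 500], [4, 3], default=0)
    return np.maximum(by_cr, by_urine)


# -- scalar public operations with domain validation --

def score_respiration(pf_ratio: float, ventilated: bool) -> int:
    """Respiration sub-score from the PaO2/FiO2 ratio (mmHg) and support status."""
    if not pf_ratio > 0:
        raise ValueError(f"pf_ratio must be positive, got {pf_ratio}")
    return int(_resp(np.asarray([float(pf_ratio)]), np.asarray([bool(ventilated)]))[0])


def score_coagulation(platelets: float) -> int:
    """Coagulation sub-score from the platelet count (10^3/uL)."""
    if platelets < 0:
        raise ValueError(f"platelets must be non-negative, got {platelets}")
    return int(_coag(np.asarray([float(platelets)]))[0])


def score_liver(bilirubin: float) -> int:
    """Liver sub-score from total bilirubin (mg/dL)."""
    if bilirubin < 0:
        raise ValueError(f"bilirubin must be non-negative, got {bilirubin}")
    return int(_liver(np.asarray([float(bilirubin)]))[0])


def score_cardiovascular(
    mean_arterial_pressure: float, vasopressors: Mapping[str, float] | None = None
) -> int:
    """Cardiovascular sub-score from MAP (mmHg) and vasopressor doses (ug/kg/min).

    The result is the maximum over the applicable hypotension and
    drug-dose rules.
    """
    doses = dict.fromkeys(VASOPRESSORS, 0.0)
    for drug, dose in (vasopressors or {}).items():
        if drug not in doses:
            raise ValueError(f"unknown vasopressor {drug!r}")
        if dose < 0:
            raise ValueError(f"negative {drug} dose: {dose}")
        doses[drug] = float(dose)
    return int(
        _cardio(
            np.asarray([float(mean_arterial_pressure)]),
            *(np.asarray([doses[d]]) for d in VASOPRESSORS),
        )[0]
    )


def score_cns(gcs: int) -> int:
    """CNS sub-score from the Glasgow Coma Scale (3-15)."""
    if not 3 <= gcs <= 15:
        raise ValueError(f"gcs must be in [3, 15], got {gcs}")
    return int(_cns(np.asarray([float(gcs)]))[0])


def score_renal(creatinine: float, urine_output_24h: float | None = None) -> int:
    """Renal sub-score: max of the creatinine (mg/dL) and 24-h urine (mL) pathways."""
    if creatinine < 0:
        raise ValueError(f"creatinine must be non-negative, got {creatinine}")
    if urine_output_24h is not None and urine_output_24h < 0:
        raise ValueError(f"urine_output_24h must be non-negative, got {urine_output_24h}")
    urine = np.nan if urine_output_24h is None else float(urine_output_24h)
    return int(_renal(np.asarray([float(creatinine)]), np.asarray([urine]))[0])


def _build_grid(encounters: pd.DataFrame, grid: GridSpec) -> pd.DataFrame:
    """One row per (encounter, grid time); times step from each ED arrival
    through discharge: ``n_points = floor((discharge - arrival)/step) + 1``."""
    arrival = pd.to_datetime(encounters["ed_arrival"], utc=True)
    discharge = pd.to_datetime(encounters["discharge"], utc=True)
    n_points = ((discharge - arrival) // grid.step).to_numpy().astype(np.int64) + 1
    enc_idx = np.repeat(np.arange(len(encounters)), n_points)
    # offset within each encounter: 0..n_points-1
    starts = np.cumsum(n_points) - n_points
    step_idx = np.arange(n_points.sum()) - np.repeat(starts, n_points)
    arr64 = arrival.to_numpy(dtype="datetime64[ns]")  # UTC, tz dropped
    grid_time = arr64[enc_idx] + step_idx * grid.step.to_timedelta64()
    return pd.DataFrame(
        {
            "encounter_id": encounters["encounter_id"].to_numpy()[enc_idx],
            "grid_time": pd.DatetimeIndex(grid_time).tz_localize("UTC"),
        }
    )


def compute_sofa_series(
    observations: pd.DataFrame,
    encounters: pd.DataFrame,
    grid: GridSpec | None = None,
    carry_forward_hours: float = 24.0,
) -> pd.DataFrame:
    """Score every encounter at every grid time.

    Parameters
    ----------
    observations
        Long-format observation table (``encounter_id, timestamp, kind, value``).
    encounters
        Encounter table providing the time bounds; the returned series covers
        ``ed_arrival`` through ``discharge`` for each row, one point per grid
        step (a same-instant admission-discharge pair yields a single-point
        series).
    grid
        Grid specification; default 15-minute step anchored at each arrival.
    carry_forward_hours
        LOCF lookback. At each grid time the most recent observation of each
        kind within this window (inclusive of the grid instant) is used;
        beyond it the kind reverts to "unobserved".

    Returns
    -------
    DataFrame with one row per (encounter, grid time): the six organ
    sub-scores, their total, and per-organ imputation flags (True where no
    contributing observation was in the lookback and the organ defaulted
    to 0).
    """
    grid = grid or GridSpec()
    tolerance = pd.Timedelta(hours=carry_forward_hours)
    long = _build_grid(encounters, grid)

    order = np.argsort(long["grid_time"].to_numpy(), kind="stable")
    sorted_grid = long.iloc[order].reset_index(drop=True)

    kinds = [
        "pf_ratio", "ventilated", "platelets", "bilirubin", "map",
        *VASOPRESSORS, "gcs", "creatinine", "urine_output_24h",
    ]
    values: dict[str, np.ndarray] = {}
    for kind in kinds:
        obs_k = observations.loc[
            observations["kind"] == kind, ["encounter_id", "timestamp", "value"]
        ]
        if obs_k.empty:
            values[kind] = np.full(len(sorted_grid), np.nan)
            continue
        obs_k["timestamp"] = pd.to_datetime(obs_k["timestamp"], utc=True)
        obs_k = obs_k.sort_values("timestamp", kind="stable")
        merged = pd.merge_asof(
            sorted_grid,
            obs_k.rename(columns={"timestamp": "grid_time"}),
            on="grid_time",
            by="encounter_id",
            tolerance=tolerance,
            direction="backward",
        )
        values[kind] = merged["value"].to_numpy(dtype=float)

    vent = np.nan_to_num(values["ventilated"]) > 0
    out = sorted_grid
    out["respiration"] = _resp(values["pf_ratio"], vent)
    out["coagulation"] = _coag(values["platelets"])
    out["liver"] = _liver(values["bilirubin"])
    out["cardiovascular"] = _cardio(
        values["map"], *(values[d] for d in VASOPRESSORS)
    )
    out["cns"] = _cns(values["gcs"])
    out["renal"] = _renal(values["creatinine"], values["urine_output_24h"])
    out["total"] = sum(out[o] for o in ORGANS)

    out["respiration_imputed"] = np.isnan(values["pf_ratio"])
    out["coagulation_imputed"] = np.isnan(values["platelets"])
    out["liver_imputed"] = np.isnan(values["bilirubin"])
    out["cardiovascular_imputed"] = np.isnan(values["map"]) & np.all(
        [np.isnan(values[d]) for d in VASOPRESSORS], axis=0
    )
    out["cns_imputed"] = np.isnan(values["gcs"])
    out["renal_imputed"] = np.isnan(values["creatinine"]) & np.isnan(
        values["urine_output_24h"]
    )

    # restore encounter order as given, grid time ascending within encounter
    rank = {eid: i for i, eid in enumerate(encounters["encounter_id"])}
    out = out.sort_values(
        by=["encounter_id", "grid_time"],
        key=lambda s: s.map(rank) if s.name == "encounter_id" else s,
        kind="stable",
    ).reset_index(drop=True)
    return out[SOFA_COLUMNS]
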