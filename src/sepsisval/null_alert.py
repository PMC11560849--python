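"""Monte-Carlo random-alert baseline ("how good is an alarm that fires at
random at the same rate?") and the randomness adjustment of sensitivity.

The null mechanism, ``per_encounter`` mode (default): each encounter
independently receives one pseudo-alert with probability equal to the
observed alert prevalence, at a time uniform over its stay; the windowed
confusion matrix and metrics are then computed exactly as for the real
alert. ``per_interval`` mode instead fires each 15-minute interval
independently with the given probability and takes the first firing.

The adjustment subtracts the null sensitivity from the model sensitivity
(floored at zero): the part of the model's hit rate that a rate-matched
random alarm would already achieve is not credited to the model.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .alert_evaluation import METRIC_NAMES

MODES = ("per_encounter", "per_interval")


@dataclasses.dataclass(frozen=True)
class NullResult:
    n_reps: int
    seed: int
    mode: str
    window_hours: float | None
    alert_prevalence: float
    replicates: pd.DataFrame  # one row per replicate: the four metrics
    summary: pd.DataFrame  # mean/sd/q05/q50/q95 per metric

    def as_dict(self) -> dict:
        return {
            "n_reps": self.n_reps,
            "seed": self.seed,
            "mode": self.mode,
            "window_hours": self.window_hours,
            "alert_prevalence": self.alert_prevalence,
            "summary": {
                m: {k: (None if pd.isna(v) else float(v)) for k, v in row.items()}
                for m, row in self.summary.to_dict(orient="index").items()
            },
        }


def _metrics_row(tp, fp, fn, tn) -> dict:
    def ratio(k, n):
        return np.nan if n == 0 else k / n

    return {
        "sensitivity": ratio(tp, tp + fn),
        "specificity": ratio(tn, tn + fp),
        "ppv": ratio(tp, tp + fp),
        "npv": ratio(tn, tn + fn),
    }


def simulate_random_alerts(
    encounters: pd.DataFrame,
    labels: pd.DataFrame,
    alert_prevalence: float,
    n_reps: int = 500,
    seed: int = 0,
    window_hours: float | None = 6.0,
    mode: str = "per_encounter",
    step_minutes: int = 15,
) -> NullResult:
    """Distribution of diagnostic metrics under random alerting.

    Parameters
    ----------
    encounters, labels
        Cohort time bounds and sepsis labels (matched on ``encounter_id``).
    alert_prevalence
        Per-encounter firing probability (``per_encounter`` mode) or
        per-interval firing probability (``per_interval`` mode); in (0, 1].
    window_hours
        Forward window for the confusion matrix; ``None`` evaluates at
        encounter level (any alert in a septic encounter is a TP).
    n_reps, seed
        Number of replicates and RNG seed; results are deterministic given
        the seed.
    """
    if not 0 <= alert_prevalence <= 1:
        raise ValueError("alert_prevalence must be in [0, 1]")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")

    merged = labels.merge(
        encounters[["encounter_id", "ed_arrival", "discharge"]],
        on="encounter_id",
        how="left",
        validate="one_to_one",
    )
    if merged["ed_arrival"].isna().any():
        bad = merged.loc[merged["ed_arrival"].isna(), "encounter_id"].tolist()
        raise ValueError(f"labels without encounter rows: {bad[:10]}")

    los_min = (
        (merged["discharge"] - merged["ed_arrival"]).dt.total_seconds().to_numpy() / 60.0
    )
    onset_off = (
        (merged["onset_time"] - merged["ed_arrival"]).dt.total_seconds().to_numpy()
        / 60.0
    )  # NaN for non-septic encounters
    sepsis = merged["sepsis"].to_numpy(dtype=bool)
    n = len(merged)
    window_min = None if window_hours is None else window_hours * 60.0

    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n_reps):
        if alert_prevalence == 0:
            fire = np.zeros(n, dtype=bool)
            alert_off = np.zeros(n)
        elif mode == "per_encounter":
            fire = rng.random(n) < alert_prevalence
            alert_off = rng.random(n) * los_min
        else:
            n_intervals = np.floor(los_min / step_minutes).astype(np.int64) + 1
            first = rng.geometric(alert_prevalence, n)
            fire = first <= n_intervals
            alert_off = (first - 1) * float(step_minutes)
        if window_min is None:
            hit = sepsis
        else:
            with np.errstate(invalid="ignore"):
                hit = sepsis & (onset_off >= alert_off) & (
                    onset_off <= alert_off + window_min
                )
        tp = int(np.sum(fire & hit))
        fp = int(np.sum(fire & ~hit))
        fn = int(np.sum(~fire & sepsis))
        tn = int(np.sum(~fire & ~sepsis))
        rows.append(_metrics_row(tp, fp, fn, tn))

    reps = pd.DataFrame(rows, columns=list(METRIC_NAMES))
    summary = pd.DataFrame(
        {
            "mean": reps.mean(),
            "sd": reps.std(ddof=1),
            "q05": reps.quantile(0.05),
            "q50": reps.quantile(0.50),
            "q95": reps.quantile(0.95),
        }
    )
    return NullResult(
        n_reps=n_reps,
        seed=seed,
        mode=mode,
        window_hours=window_hours,
        alert_prevalence=alert_prevalence,
        replicates=reps,
        summary=summary,
    )


def adjust_for_randomness(model_sensitivity: float, null_sensitivity: float) -> float:
    """Model sensitivity minus the random-alert sensitivity, floored at 0."""
    for name, v in (("model", model_sensitivity), ("null", null_sensitivity)):
        if not 0 <= v <= 1:
            raise ValueError(f"{name} sensitivity must be in [0, 1], got {v}")
    return max(0.0, model_sensitivity - null_sensitivity)
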