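"""Diagnostic-accuracy evaluation of fired alerts against sepsis labels.

A raw alert event *fires* when its model score reaches the display threshold
(default 6) and the provider viewed the chart — both are required for the
interruptive advisory to appear. The first fired alert per encounter anchors
all downstream analyses.

Two confusion matrices are built over the same cohort:

windowed (default 6 h)
    An alerted encounter is a true positive only when sepsis onset falls
    inside the closed window ``[alert, alert + window]``. An alerted septic
    encounter whose onset falls *outside* the window is counted as a false
    positive — the alert, judged at its horizon, pointed at the wrong time —
    so the column margins are alerted vs not-alerted, and the "positive"
    margin is (onset-in-window) + (sepsis, never alerted).
encounter
    The window is dropped: any fired alert in a septic encounter is a true
    positive, regardless of order in time.

The two matrices share FN and TN by construction: both depend only on the
un-alerted encounters.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

DEFAULT_THRESHOLD = 6
DEFAULT_WINDOW_HOURS = 6.0

METRIC_NAMES = ("sensitivity", "specificity", "ppv", "npv")


@dataclasses.dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int
    analysis_mode: str  # "windowed" | "encounter"

    def __post_init__(self) -> None:
        for field in ("tp", "fp", "fn", "tn"):
            if getattr(self, field) < 0:
                raise ValueError(f"{field} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass(frozen=True)
class DiagnosticMetrics:
    """Point estimates (None where the defining denominator is zero) and
    optional Wilson score 95% intervals per metric."""

    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    ci: dict[str, tuple[float, float]] | None = None

    def as_dict(self) -> dict:
        d = {m: getattr(self, m) for m in METRIC_NAMES}
        if self.ci is not None:
            d["ci"] = {k: list(v) for k, v in self.ci.items()}
        return d


def extract_fired_alerts(
    alerts: pd.DataFrame, threshold: int = DEFAULT_THRESHOLD
) -> pd.Series:
    """Earliest fired-alert time per encounter.

    Fired means ``model_score >= threshold`` and ``chart_viewed``; events
    failing either test (sub-threshold scores, unviewed charts) are decoys
    and ignored. Encounters with no fired alert are absent from the result.
    """
    fired = alerts[
        (alerts["model_score"] >= threshold) & alerts["chart_viewed"].astype(bool)
    ]
    if fired.empty:
        return pd.Series(dtype="datetime64[ns, UTC]", name="alert_time").rename_axis(
            "encounter_id"
        )
    out = fired.groupby("encounter_id")["timestamp"].min()
    out.name = "alert_time"
    return out


def _join(first_alerts: pd.Series, labels: pd.DataFrame) -> pd.DataFrame:
    if labels["encounter_id"].duplicated().any():
        raise ValueError("labels contain duplicate encounter ids")
    unknown = sorted(set(first_alerts.index) - set(labels["encounter_id"]))
    if unknown:
        raise ValueError(
            f"fired alerts for encounters absent from labels: {unknown[:10]}"
        )
    joined = labels[["encounter_id", "sepsis", "onset_time"]].copy()
    joined["alert_time"] = pd.to_datetime(
        joined["encounter_id"].map(first_alerts), utc=True
    )
    return joined


def windowed_confusion(
    first_alerts: pd.Series,
    labels: pd.DataFrame,
    window_hours: float = DEFAULT_WINDOW_HOURS,
) -> ConfusionMatrix:
    """Confusion matrix for sepsis onset within ``window_hours`` after the alert.

    The window is one-sided forward and closed at both ends; an onset at
    exactly ``alert + window`` is a true positive. Alerted septic encounters
    with onset outside the window fall in FP (see module docstring).
    """
    if window_hours < 0:
        raise ValueError("window_hours must be non-negative")
    j = _join(first_alerts, labels)
    alerted = j["alert_time"].notna()
    window = pd.Timedelta(hours=window_hours)
    in_window = (
        j["sepsis"]
        & alerted
        & (j["onset_time"] >= j["alert_time"])
        & (j["onset_time"] <= j["alert_time"] + window)
    )
    tp = int((alerted & in_window).sum())
    fp = int((alerted & ~in_window).sum())
    fn = int((~alerted & j["sepsis"]).sum())
    tn = int((~alerted & ~j["sepsis"]).sum())
    return ConfusionMatrix(tp, fp, fn, tn, "windowed")


def encounter_confusion(first_alerts: pd.Series, labels: pd.DataFrame) -> ConfusionMatrix:
    """Confusion matrix over the entire hospital encounter (no time window)."""
    j = _join(first_alerts, labels)
    alerted = j["alert_time"].notna()
    tp = int((alerted & j["sepsis"]).sum())
    fp = int((alerted & ~j["sepsis"]).sum())
    fn = int((~alerted & j["sepsis"]).sum())
    tn = int((~alerted & ~j["sepsis"]).sum())
    return ConfusionMatrix(tp, fp, fn, tn, "encounter")


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else num / den


def diagnostic_metrics(
    cm: ConfusionMatrix, include_ci: bool = True, alpha: float = 0.05
) -> DiagnosticMetrics:
    """Sensitivity, specificity, PPV and NPV from a confusion matrix.

    A metric whose defining denominator is zero is reported as undefined
    (None), never as 0. Wilson score intervals at level ``1 - alpha`` are
    attached for each defined metric when ``include_ci``.
    """
    pairs = {
        "sensitivity": (cm.tp, cm.tp + cm.fn),
        "specificity": (cm.tn, cm.tn + cm.fp),
        "ppv": (cm.tp, cm.tp + cm.fp),
        "npv": (cm.tn, cm.tn + cm.fn),
    }
    estimates = {name: _ratio(k, n) for name, (k, n) in pairs.items()}
    ci = None
    if include_ci:
        ci = {}
        for name, (k, n) in pairs.items():
            if n > 0:
                lo, hi = proportion_confint(k, n, alpha=alpha, method="wilson")
                ci[name] = (float(lo), float(hi))
    return DiagnosticMetrics(**estimates, ci=ci)


def evaluate(
    alerts: pd.DataFrame,
    labels: pd.DataFrame,
    threshold: int = DEFAULT_THRESHOLD,
    window_hours: float = DEFAULT_WINDOW_HOURS,
) -> dict:
    """Full evaluation: both matrices and their metrics, as a JSON-ready dict.

    Asserts the structural identity that the windowed and encounter-level
    matrices share FN and TN (both count only un-alerted encounters).
    """
    first_alerts = extract_fired_alerts(alerts, threshold=threshold)
    cm_win = windowed_confusion(first_alerts, labels, window_hours=window_hours)
    cm_enc = encounter_confusion(first_alerts, labels)
    assert (cm_win.fn, cm_win.tn) == (cm_enc.fn, cm_enc.tn), (
        "windowed and encounter matrices must share FN/TN"
    )
    return {
        "threshold": threshold,
        "window_hours": window_hours,
        "n_encounters": int(len(labels)),
        "windowed": {
            "confusion": cm_win.as_dict(),
            "metrics": diagnostic_metrics(cm_win).as_dict(),
        },
        "encounter": {
            "confusion": cm_enc.as_dict(),
            "metrics": diagnostic_metrics(cm_enc).as_dict(),
        },
    }


def reconstruct_windowed_margins(
    n_encounters: int, n_alerted: int, n_sepsis: int, n_tp_encounter: int, n_tp_windowed: int
) -> dict:
    """Reconstruct the windowed matrix implied by published margin totals.

    Given cohort-level totals (encounters, alerted encounters, septic
    encounters, encounter-level true positives, windowed true positives),
    build a minimal cohort realizing them, run :func:`windowed_confusion`,
    and return its counts together with the implied "positive" margin
    (tp + fn). This validates the reclassification rule — alerted septic
    encounters with onset outside the window land in FP — against published
    margins using the production code path, not separate arithmetic.
    """
    n_out = n_tp_encounter - n_tp_windowed  # alerted septic, onset outside window
    n_fp_nonsep = n_alerted - n_tp_encounter  # alerted, never septic
    n_fn = n_sepsis - n_tp_encounter  # septic, never alerted
    n_tn = n_encounters - n_alerted - n_fn
    if min(n_out, n_fp_nonsep, n_fn, n_tn) < 0:
        raise ValueError("inconsistent margin totals")

    t0 = pd.Timestamp("2023-01-01T00:00:00+00:00")
    groups = [
        # (count, alerted, sepsis, onset offset hours from alert)
        (n_tp_windowed, True, True, 3.0),   # onset inside [alert, alert+6h]
        (n_out, True, True, -3.0),          # onset before alert -> outside window
        (n_fp_nonsep, True, False, np.nan),
        (n_fn, False, True, np.nan),
        (n_tn, False, False, np.nan),
    ]
    ids, sepsis, onset, alert = [], [], [], []
    counter = 0
    for count, has_alert, is_sep, off in groups:
        for _ in range(count):
            ids.append(f"m{counter}")
            counter += 1
            sepsis.append(is_sep)
            alert.append(t0 if has_alert else pd.NaT)
            if is_sep:
                base = t0 if has_alert else t0
                onset.append(base + pd.Timedelta(hours=off if has_alert else 1.0))
            else:
                onset.append(pd.NaT)
    labels = pd.DataFrame(
        {
            "encounter_id": ids,
            "sepsis": sepsis,
            "onset_time": pd.to_datetime(onset, utc=True),
        }
    )
    first_alerts = pd.Series(
        pd.to_datetime(alert, utc=True), index=pd.Index(ids, name="encounter_id"),
        name="alert_time",
    ).dropna()
    cm = windowed_confusion(first_alerts, labels, window_hours=DEFAULT_WINDOW_HOURS)
    return {
        "tp": cm.tp,
        "fp": cm.fp,
        "fn": cm.fn,
        "tn": cm.tn,
        "n_positive_margin": cm.tp + cm.fn,
        "n_negative_margin": cm.fp + cm.tn,
    }
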