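"""Lead-time analysis: how far in advance of sepsis onset does the alert fire?

Restricted to encounter-level true positives (a fired alert AND sepsis in
the same encounter). Lead time is signed, in minutes:

    lead = onset_time - first_alert_time

positive when the alert precedes onset (useful warning), negative when the
alert arrives after sepsis has already occurred. The "80% interval" is the
empirical 10th-90th percentile interval of the lead-time distribution
(numpy linear interpolation); ties at zero lead are counted with
"alert before or at onset".
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd


@dataclasses.dataclass(frozen=True)
class TimingSummary:
    n_tp: int
    lead_times_min: np.ndarray  # signed minutes, one per TP encounter
    median_lead_min: float  # NaN when n_tp == 0
    interval_80_min: tuple[float, float]  # empirical (p10, p90); NaN when empty
    n_alert_before_onset: int  # lead > 0
    n_alert_at_onset: int  # lead == 0
    n_alert_after_onset: int  # lead < 0
    fraction_alert_before_onset: float  # lead >= 0 (ties counted as before)
    fraction_alert_after_onset: float

    def as_dict(self) -> dict:
        def num(x):
            return None if pd.isna(x) else float(x)

        return {
            "n_tp": self.n_tp,
            "median_lead_min": num(self.median_lead_min),
            "interval_80_min": [num(v) for v in self.interval_80_min],
            "interval_80_definition": "empirical 10th-90th percentile of lead times",
            "n_alert_before_onset": self.n_alert_before_onset,
            "n_alert_at_onset": self.n_alert_at_onset,
            "n_alert_after_onset": self.n_alert_after_onset,
            "fraction_alert_before_onset": num(self.fraction_alert_before_onset),
            "fraction_alert_after_onset": num(self.fraction_alert_after_onset),
            "tie_rule": "zero lead counted with alert-before-onset",
        }


def compute_lead_times(first_alerts: pd.Series, labels: pd.DataFrame) -> TimingSummary:
    """Summarize signed lead times over encounter-level true positives.

    An empty true-positive set yields ``n_tp=0`` with NaN statistics, not an
    error.
    """
    j = labels[["encounter_id", "sepsis", "onset_time"]].copy()
    j["onset_time"] = pd.to_datetime(j["onset_time"], utc=True)
    j["alert_time"] = pd.to_datetime(j["encounter_id"].map(first_alerts), utc=True)
    tp = j[j["sepsis"] & j["alert_time"].notna() & j["onset_time"].notna()]
    leads = (
        (tp["onset_time"] - tp["alert_time"]).dt.total_seconds().to_numpy() / 60.0
    )
    n = len(leads)
    if n == 0:
        return TimingSummary(
            n_tp=0,
            lead_times_min=leads,
            median_lead_min=float("nan"),
            interval_80_min=(float("nan"), float("nan")),
            n_alert_before_onset=0,
            n_alert_at_onset=0,
            n_alert_after_onset=0,
            fraction_alert_before_onset=float("nan"),
            fraction_alert_after_onset=float("nan"),
        )
    p10, p90 = np.percentile(leads, [10, 90], method="linear")
    return TimingSummary(
        n_tp=n,
        lead_times_min=leads,
        median_lead_min=float(np.median(leads)),
        interval_80_min=(float(p10), float(p90)),
        n_alert_before_onset=int(np.sum(leads > 0)),
        n_alert_at_onset=int(np.sum(leads == 0)),
        n_alert_after_onset=int(np.sum(leads < 0)),
        fraction_alert_before_onset=float(np.mean(leads >= 0)),
        fraction_alert_after_onset=float(np.mean(leads < 0)),
    )


def lead_time_histogram(
    lead_times_min: np.ndarray, bin_minutes: int = 15
) -> pd.DataFrame:
    """Binned lead-time counts (half-open bins ``[left, right)``), suitable
    for plotting or CSV export."""
    if len(lead_times_min) == 0:
        return pd.DataFrame(columns=["bin_left_min", "bin_right_min", "count"])
    lo = np.floor(lead_times_min.min() / bin_minutes) * bin_minutes
    hi = np.floor(lead_times_min.max() / bin_minutes) * bin_minutes + bin_minutes
    edges = np.arange(lo, hi + bin_minutes, bin_minutes)
    counts, _ = np.histogram(lead_times_min, bins=edges)
    return pd.DataFrame(
        {
            "bin_left_min": edges[:-1].astype(float),
            "bin_right_min": edges[1:].astype(float),
            "count": counts.astype(int),
        }
    )
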