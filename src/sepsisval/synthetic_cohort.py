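"""Synthetic ED cohort generator with planted sepsis-onset and alert structure.

The generator emulates a large two-site county emergency-department cohort:
~3.7% of encounters meet the Sepsis-3 electronic phenotype, ~4.9% receive a
fired predictive-model alert, and the joint alert/onset structure is
parameterized by ``p_alert_given_sepsis`` plus a signed lead-time
distribution. The alert rate among non-septic encounters is solved from the
marginal alert prevalence, so the configured marginals and the one
window-conditional rate jointly pin the whole 2x2-plus-timing structure.

Construction guarantees (what the round-trip tests rely on):

* For every septic encounter the observation trajectory is a piecewise-
  constant "step" profile — normal baseline values at arrival, a platelet
  drop crossing two severity bins exactly at the planted onset grid time —
  so the SOFA engine's first 2-point rise lands exactly on the planted
  onset. Blood-culture and antibiotic orders are always present.
* Non-septic encounters never accumulate a 2-point SOFA rise: they are flat
  or carry a single 1-point wobble, even when they receive noise orders or
  decoy alert events.
* Everything is drawn from one seeded generator: identical seed + config
  give byte-identical output files.

Default lead-time structure is a two-sided mixture: about half of alerted
septic encounters are alerted only *after* onset, a quarter within the
6-hour useful window before onset, and the rest too early — mirroring the
timing structure reported for a production sepsis advisory.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .alert_evaluation import ConfusionMatrix
from .ehr_model import COMORBIDITIES, Cohort, GridSpec

#: Demographic marginals emulating a predominantly Hispanic and Black county
#: ED population (row proportions of the emulated cohort).
DEFAULT_DEMOGRAPHICS: dict = {
    "sex": {"female": 0.4536, "male": 0.5464},
    "age_band": {"18-44": 0.4551, "45-64": 0.3816, "65+": 0.1633},
    "race": {
        "Asian": 0.0095,
        "Black": 0.3005,
        "Hispanic": 0.5546,
        "White": 0.1027,
        "Other": 0.0327,
    },
    "comorbidities": {
        "diabetes": 0.2304,
        "hyperlipidemia": 0.2465,
        "chronic_kidney_disease": 0.0124,
        "cabg": 0.0271,
        "pvd": 0.0263,
        "stroke": 0.0292,
    },
}

_AGE_RANGES = {"18-44": (18, 44), "45-64": (45, 64), "65+": (65, 95)}

LEAD_FAMILIES = ("point_mass", "uniform", "two_sided_mixture")


class ConfigurationError(ValueError):
    """Scenario parameters are jointly infeasible."""


class GenerationError(ValueError):
    """A planted event fell outside its encounter bounds."""


@dataclasses.dataclass(frozen=True)
class LeadTimeDistribution:
    """Signed alert-to-onset lead time (minutes; positive = alert first).

    Families:

    ``point_mass``: every lead equals ``params['minutes']``.
    ``uniform``: leads uniform on ``[params['low'], params['high']]``.
    ``two_sided_mixture`` (default): with probability ``p_within`` a lead
    inside the useful forward window (uniform on ``within``), with
    ``p_after`` a negative lead (alert after onset, uniform on ``after``),
    otherwise a too-early lead (uniform on ``late``). Component bounds are
    placed strictly inside/outside the 6-h window so planted confusion
    counts are exact, and the default ranges reproduce a ~0-minute median
    with an 80% spread of roughly -400 to +720 minutes.
    """

    family: str = "two_sided_mixture"
    params: Mapping[str, object] = dataclasses.field(
        default_factory=lambda: {
            "p_within": 550 / 2253,
            "p_after": 1126 / 2253,
            "within": (5, 355),
            "after": (-402, -5),
            "late": (365, 720),
        }
    )

    def __post_init__(self) -> None:
        if self.family not in LEAD_FAMILIES:
            raise ValueError(f"family must be one of {LEAD_FAMILIES}")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """Draw ``n`` whole-minute leads."""
        p = self.params
        if self.family == "point_mass":
            return np.full(n, int(p["minutes"]))
        if self.family == "uniform":
            return rng.integers(int(p["low"]), int(p["high"]) + 1, size=n)
        u = rng.random(n)
        p_within, p_after = float(p["p_within"]), float(p["p_after"])
        if p_within + p_after > 1 + 1e-12:
            raise ConfigurationError("p_within + p_after must be <= 1")
        within = rng.integers(p["within"][0], p["within"][1] + 1, size=n)
        after = rng.integers(p["after"][0], p["after"][1] + 1, size=n)
        late = rng.integers(p["late"][0], p["late"][1] + 1, size=n)
        return np.where(u < p_within, within, np.where(u < p_within + p_after, after, late))


@dataclasses.dataclass(frozen=True)
class ScenarioConfig:
    """Full description of one synthetic scenario.

    Defaults are the emulated study conditions: 3.7% sepsis prevalence,
    4.9% fired-alert prevalence, P(alert | sepsis) = 2253/5433, and the
    two-sided lead-time mixture described in
    :class:`LeadTimeDistribution`.
    """

    n_encounters: int = 14600
    sepsis_prevalence: float = 0.037
    alert_prevalence: float = 0.049
    p_alert_given_sepsis: float = 2253 / 5433
    lead_time: LeadTimeDistribution = dataclasses.field(
        default_factory=LeadTimeDistribution
    )
    window_hours: float = 6.0
    demographics: Mapping = dataclasses.field(
        default_factory=lambda: DEFAULT_DEMOGRAPHICS
    )
    seed: int = 0
    step_minutes: int = 15
    #: fraction of non-septic encounters receiving noise blood-culture +
    #: antibiotic orders (order presence alone must not create sepsis labels)
    order_noise_fraction: float = 0.10
    #: fraction of encounters receiving a decoy alert event (sub-threshold
    #: score or unviewed chart) that downstream code must ignore
    decoy_alert_fraction: float = 0.15
    #: fraction of non-septic encounters with a single 1-point SOFA wobble
    wobble_fraction: float = 0.20
    #: length-of-stay lognormal: median minutes and log-scale sigma
    los_median_minutes: float = 480.0
    los_sigma: float = 0.75
    #: planted onsets occur on the grid between these offsets from arrival
    onset_min_minutes: int = 720
    onset_max_minutes: int = 2160
    start: str = "2023-01-01T00:00:00+00:00"
    span_days: int = 365

    def __post_init__(self) -> None:
        if self.n_encounters <= 0:
            raise ConfigurationError("n_encounters must be positive")
        for name in ("sepsis_prevalence", "alert_prevalence", "p_alert_given_sepsis"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        for group, probs in self.demographics.items():
            if group == "comorbidities":
                continue
            total = sum(probs.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigurationError(
                    f"demographics[{group!r}] proportions sum to {total}, not 1"
                )
        # joint feasibility: alerted septic mass cannot exceed the alert margin
        joint = self.p_alert_given_sepsis * self.sepsis_prevalence
        if joint > self.alert_prevalence + 1e-12:
            raise ConfigurationError(
                "infeasible joint structure: p_alert_given_sepsis * sepsis_prevalence "
                f"= {joint:.4f} exceeds alert_prevalence = {self.alert_prevalence:.4f}"
            )
        if self.sepsis_prevalence < 1 and self.nonsepsis_alert_rate > 1:
            raise ConfigurationError(
                "infeasible joint structure: implied non-sepsis alert rate exceeds 1"
            )

    @property
    def nonsepsis_alert_rate(self) -> float:
        """Alert rate among non-septic encounters solved from the margins."""
        if self.sepsis_prevalence >= 1:
            return 0.0
        return (
            self.alert_prevalence
            - self.p_alert_given_sepsis * self.sepsis_prevalence
        ) / (1 - self.sepsis_prevalence)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["lead_time"] = {
            "family": self.lead_time.family,
            "params": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in self.lead_time.params.items()
            },
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path, encoding="utf-8") as fh:
            d = yaml.safe_load(fh)
        if "lead_time" in d:
            lt = d["lead_time"]
            params = {
                k: (tuple(v) if isinstance(v, list) else v)
                for k, v in lt.get("params", {}).items()
            }
            d["lead_time"] = LeadTimeDistribution(family=lt["family"], params=params)
        return cls(**d)


def _sample_categorical(
    rng: np.random.Generator, probs: Mapping[str, float], n: int
) -> np.ndarray:
    cats = list(probs)
    p = np.asarray([probs[c] for c in cats], dtype=float)
    p = p / p.sum()
    return rng.choice(cats, size=n, p=p)


def plant_skeleton(config: ScenarioConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw encounters and the ground-truth sepsis/alert skeleton.

    Returns ``(encounters, truth)`` where ``truth`` has one row per
    encounter: ``sepsis`` flag, planted ``onset_time`` (NaT when not septic)
    and planted fired ``alert_time`` (NaT when not alerted). Deterministic
    given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_encounters
    step = config.step_minutes

    sepsis = rng.random(n) < config.sepsis_prevalence
    alerted = np.where(
        sepsis,
        rng.random(n) < config.p_alert_given_sepsis,
        rng.random(n) < config.nonsepsis_alert_rate,
    )

    sex = _sample_categorical(rng, config.demographics["sex"], n)
    band = _sample_categorical(rng, config.demographics["age_band"], n)
    age = np.empty(n, dtype=np.int64)
    for b, (lo, hi) in _AGE_RANGES.items():
        mask = band == b
        age[mask] = rng.integers(lo, hi + 1, size=int(mask.sum()))
    race = _sample_categorical(rng, config.demographics["race"], n)
    comorb = {
        flag: rng.random(n) < p
        for flag, p in config.demographics["comorbidities"].items()
    }

    start = pd.Timestamp(config.start)
    arrival_min = rng.integers(0, config.span_days * 1440, size=n)
    los_min = np.maximum(
        np.round(
            np.exp(
                np.log(config.los_median_minutes)
                + config.los_sigma * rng.standard_normal(n)
            )
        ),
        120,
    ).astype(np.int64)

    onset_off = np.full(n, -1, dtype=np.int64)
    k_sep = int(sepsis.sum())
    onset_off[sepsis] = (
        rng.integers(
            config.onset_min_minutes // step,
            config.onset_max_minutes // step + 1,
            size=k_sep,
        )
        * step
    )

    lead = np.zeros(n, dtype=np.int64)
    sep_alert = sepsis & alerted
    lead[sep_alert] = config.lead_time.sample(rng, int(sep_alert.sum()))
    alert_off = np.full(n, -1, dtype=np.int64)
    alert_off[sep_alert] = onset_off[sep_alert] - lead[sep_alert]
    if (alert_off[sep_alert] < 0).any():
        raise GenerationError(
            "a planted lead time pushed an alert before ED arrival; raise "
            "onset_min_minutes or narrow the lead-time distribution"
        )

    # stays must contain every planted event (plus one grid step of slack)
    need = np.zeros(n, dtype=np.int64)
    need[sepsis] = onset_off[sepsis] + int(max(402, config.window_hours * 60)) + 60
    need[sep_alert] = np.maximum(need[sep_alert], alert_off[sep_alert] + step)
    los_min = np.maximum(los_min, need)

    ns_alert = ~sepsis & alerted
    alert_off[ns_alert] = rng.integers(0, los_min[ns_alert])

    ids = np.array([f"e{i:06d}" for i in range(n)])
    arrival = start + pd.to_timedelta(arrival_min, unit="m")
    discharge = arrival + pd.to_timedelta(los_min, unit="m")

    encounters = pd.DataFrame(
        {
            "encounter_id": ids,
            "sex": sex,
            "age_years": age,
            "race": race,
            **{flag: comorb[flag] for flag in COMORBIDITIES},
            "ed_arrival": arrival,
            "discharge": discharge,
        }
    )
    truth = pd.DataFrame(
        {
            "encounter_id": ids,
            "sepsis": sepsis,
            "onset_time": pd.Series(arrival + pd.to_timedelta(onset_off, unit="m")).where(
                sepsis, pd.NaT
            ),
            "alert_time": pd.Series(arrival + pd.to_timedelta(alert_off, unit="m")).where(
                alert_off >= 0, pd.NaT
            ),
        }
    )
    return encounters, truth


def synthesize_observations(
    truth: pd.DataFrame,
    encounters: pd.DataFrame,
    config: ScenarioConfig,
    seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Emit observations and orders realizing the planted skeleton.

    Every encounter gets normal baseline vitals/labs at arrival (all organ
    sub-scores 0). Septic encounters get a platelet step at the planted
    onset (coagulation 0 -> 2, so the first 2-point total rise is exactly
    there) and both required orders; a configurable fraction of non-septic
    encounters get noise orders and/or a single 1-point MAP wobble that can
    never reach a 2-point rise.
    """
    rng = np.random.default_rng(seed)
    enc = encounters.reset_index(drop=True)
    tr = truth.set_index("encounter_id").loc[enc["encounter_id"]].reset_index()
    n = len(enc)
    arrival = pd.to_datetime(enc["ed_arrival"], utc=True)
    discharge = pd.to_datetime(enc["discharge"], utc=True)
    los_min = ((discharge - arrival).dt.total_seconds() / 60).to_numpy().astype(np.int64)

    sepsis = tr["sepsis"].to_numpy(dtype=bool)
    onset = pd.to_datetime(tr["onset_time"], utc=True)
    if ((onset < arrival) | (onset > discharge)).any():
        raise GenerationError("planted onset outside encounter bounds")

    frames = []

    def emit(ids, times, kind, values):
        frames.append(
            pd.DataFrame(
                {
                    "encounter_id": ids,
                    "timestamp": times,
                    "kind": kind,
                    "value": values,
                }
            )
        )

    ids = enc["encounter_id"].to_numpy()
    baseline = {
        "platelets": rng.uniform(200, 350, n).round(0),
        "bilirubin": rng.uniform(0.2, 1.0, n).round(2),
        "map": rng.uniform(75, 100, n).round(0),
        "gcs": np.full(n, 15.0),
        "creatinine": rng.uniform(0.5, 1.1, n).round(2),
        "pf_ratio": rng.uniform(420, 500, n).round(0),
    }
    for kind, vals in baseline.items():
        emit(ids, arrival.to_numpy(), kind, vals)

    # sepsis step: platelets cross two severity bins exactly at onset
    emit(
        ids[sepsis],
        onset[sepsis].to_numpy(),
        "platelets",
        rng.uniform(55, 95, int(sepsis.sum())).round(0),
    )

    # single-point wobble on some non-septic encounters (MAP < 70: +1 only)
    can_wobble = ~sepsis & (los_min >= 2 * config.step_minutes)
    wobble = can_wobble & (rng.random(n) < config.wobble_fraction)
    n_wob = int(wobble.sum())
    if n_wob:
        max_steps = np.maximum(los_min[wobble] // config.step_minutes, 1)
        at = rng.integers(1, max_steps + 1) * config.step_minutes
        emit(
            ids[wobble],
            (arrival[wobble] + pd.to_timedelta(at, unit="m")).to_numpy(),
            "map",
            rng.uniform(55, 68, n_wob).round(0),
        )

    observations = (
        pd.concat([f for f in frames if not f.empty] or frames[:1], ignore_index=True)
        .sort_values(["encounter_id", "timestamp", "kind"], kind="stable")
        .reset_index(drop=True)
    )
    observations["timestamp"] = pd.to_datetime(observations["timestamp"], utc=True)

    # orders: always both kinds for septic encounters, noise for some others
    order_frames = []
    onset_min = ((onset - arrival).dt.total_seconds() / 60).to_numpy()
    for kind, lo, hi in (("blood_culture", -60, 120), ("antibiotic", -30, 180)):
        off = np.clip(
            onset_min[sepsis] + rng.integers(lo, hi + 1, int(sepsis.sum())),
            0,
            los_min[sepsis],
        )
        order_frames.append(
            pd.DataFrame(
                {
                    "encounter_id": ids[sepsis],
                    "timestamp": (
                        arrival[sepsis] + pd.to_timedelta(off, unit="m")
                    ).to_numpy(),
                    "kind": kind,
                }
            )
        )
    noise = ~sepsis & (rng.random(n) < config.order_noise_fraction)
    n_noise = int(noise.sum())
    for kind in ("blood_culture", "antibiotic"):
        off = rng.integers(0, los_min[noise] + 1)
        order_frames.append(
            pd.DataFrame(
                {
                    "encounter_id": ids[noise],
                    "timestamp": (
                        arrival[noise] + pd.to_timedelta(off, unit="m")
                    ).to_numpy(),
                    "kind": kind,
                }
            )
        )
    orders = (
        pd.concat(
            [f for f in order_frames if not f.empty] or order_frames[:1],
            ignore_index=True,
        )
        .sort_values(["encounter_id", "timestamp", "kind"], kind="stable")
        .reset_index(drop=True)
    )
    orders["timestamp"] = pd.to_datetime(orders["timestamp"], utc=True)
    return observations, orders


def synthesize_alerts(
    truth: pd.DataFrame,
    encounters: pd.DataFrame,
    config: ScenarioConfig,
    seed: int,
) -> pd.DataFrame:
    """Emit alert events: one fired event (score >= 6, chart viewed) at each
    planted alert time, plus decoy events (sub-threshold score, or unviewed
    chart) that downstream extraction must ignore."""
    rng = np.random.default_rng(seed)
    enc = encounters.reset_index(drop=True)
    tr = truth.set_index("encounter_id").loc[enc["encounter_id"]].reset_index()
    n = len(enc)
    arrival = pd.to_datetime(enc["ed_arrival"], utc=True)
    discharge = pd.to_datetime(enc["discharge"], utc=True)
    los_min = ((discharge - arrival).dt.total_seconds() / 60).to_numpy().astype(np.int64)
    ids = enc["encounter_id"].to_numpy()

    alert_time = pd.to_datetime(tr["alert_time"], utc=True)
    has_alert = alert_time.notna().to_numpy()
    if ((alert_time < arrival) | (alert_time > discharge)).any():
        raise GenerationError("planted alert outside encounter bounds")

    frames = [
        pd.DataFrame(
            {
                "encounter_id": ids[has_alert],
                "timestamp": alert_time[has_alert].to_numpy(),
                "model_score": rng.integers(6, 13, int(has_alert.sum())),
                "chart_viewed": True,
            }
        )
    ]
    decoy = rng.random(n) < config.decoy_alert_fraction
    n_dec = int(decoy.sum())
    if n_dec:
        off = rng.integers(0, los_min[decoy] + 1)
        unviewed = rng.random(n_dec) < 0.5
        score = np.where(unviewed, rng.integers(6, 13, n_dec), rng.integers(0, 6, n_dec))
        frames.append(
            pd.DataFrame(
                {
                    "encounter_id": ids[decoy],
                    "timestamp": (arrival[decoy] + pd.to_timedelta(off, unit="m")).to_numpy(),
                    "model_score": score,
                    "chart_viewed": ~unviewed,
                }
            )
        )
    alerts = (
        pd.concat([f for f in frames if not f.empty] or frames[:1], ignore_index=True)
        .sort_values(["encounter_id", "timestamp", "model_score"], kind="stable")
        .reset_index(drop=True)
    )
    alerts["timestamp"] = pd.to_datetime(alerts["timestamp"], utc=True)
    alerts["model_score"] = alerts["model_score"].astype(np.int64)
    alerts["chart_viewed"] = alerts["chart_viewed"].astype(bool)
    return alerts


def generate_cohort(config: ScenarioConfig) -> tuple[Cohort, pd.DataFrame]:
    """Plant the skeleton and synthesize all four cohort tables.

    Sub-stage seeds are derived as ``config.seed``, ``+1``, ``+2`` so each
    stage is independently reproducible.
    """
    encounters, truth = plant_skeleton(config)
    observations, orders = synthesize_observations(
        truth, encounters, config, seed=config.seed + 1
    )
    alerts = synthesize_alerts(truth, encounters, config, seed=config.seed + 2)
    return Cohort(encounters, observations, orders, alerts), truth


def grid_spec(config: ScenarioConfig) -> GridSpec:
    return GridSpec(step_minutes=config.step_minutes)


def planted_confusion(
    truth: pd.DataFrame, window_hours: float = 6.0
) -> ConfusionMatrix:
    """Ground-truth windowed confusion matrix implied by the planted skeleton
    (the oracle the full pipeline must reproduce)."""
    alerted = truth["alert_time"].notna()
    lead = (truth["onset_time"] - truth["alert_time"]).dt.total_seconds() / 60.0
    in_window = truth["sepsis"] & alerted & (lead >= 0) & (lead <= window_hours * 60)
    tp = int((alerted & in_window).sum())
    fp = int((alerted & ~in_window).sum())
    fn = int((~alerted & truth["sepsis"]).sum())
    tn = int((~alerted & ~truth["sepsis"]).sum())
    return ConfusionMatrix(tp, fp, fn, tn, "windowed")


def planted_encounter_confusion(truth: pd.DataFrame) -> ConfusionMatrix:
    """Ground-truth encounter-level confusion matrix."""
    alerted = truth["alert_time"].notna()
    tp = int((alerted & truth["sepsis"]).sum())
    fp = int((alerted & ~truth["sepsis"]).sum())
    fn = int((~alerted & truth["sepsis"]).sum())
    tn = int((~alerted & ~truth["sepsis"]).sum())
    return ConfusionMatrix(tp, fp, fn, tn, "encounter")


def write_ground_truth(truth: pd.DataFrame, path) -> None:
    out = truth.copy()
    for col in ("onset_time", "alert_time"):
        out[col] = pd.to_datetime(out[col], utc=True).dt.strftime(
            "%Y-%m-%dT%H:%M:%S+00:00"
        )
    out["sepsis"] = out["sepsis"].astype(int)
    out.to_csv(path, index=False, encoding="utf-8")


def read_ground_truth(path) -> pd.DataFrame:
    truth = pd.read_csv(path, dtype={"encounter_id": str})
    truth["sepsis"] = truth["sepsis"].astype(bool)
    for col in ("onset_time", "alert_time"):
        truth[col] = pd.to_datetime(truth[col], utc=True)
    return truth
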