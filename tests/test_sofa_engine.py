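"""SOFA sub-scores against an independent lookup oracle, LOCF behaviour,
grid alignment, and monotonicity/bounds properties."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from sepsisval import sofa_engine
from sepsisval.ehr_model import GridSpec


# -- independent oracle: threshold-counting re-derivation of the consensus
#    table, deliberately structured unlike the production np.select kernels --

def oracle_resp(pf, vent):
    s = sum(pf < t for t in (400, 300, 200, 100))
    return s if vent else min(s, 2)


def oracle_coag(platelets):
    return sum(platelets < t for t in (150, 100, 50, 20))


def oracle_liver(bilirubin):
    return sum(bilirubin >= t for t in (1.2, 2.0, 6.0, 12.0))


def oracle_cns(gcs):
    return sum(gcs <= t for t in (14, 12, 9, 5))


def oracle_renal(creatinine, urine=None):
    by_cr = sum(creatinine >= t for t in (1.2, 2.0, 3.5, 5.0))
    by_ur = 0 if urine is None else (4 if urine < 200 else 3 if urine < 500 else 0)
    return max(by_cr, by_ur)


def oracle_cardio(mean_ap, dop=0.0, dob=0.0, epi=0.0, nor=0.0):
    candidates = [0]
    if mean_ap < 70:
        candidates.append(1)
    if 0 < dop <= 5 or dob > 0:
        candidates.append(2)
    if dop > 5 or 0 < epi <= 0.1 or 0 < nor <= 0.1:
        candidates.append(3)
    if dop > 15 or epi > 0.1 or nor > 0.1:
        candidates.append(4)
    return max(candidates)


@pytest.mark.parametrize(
    "pf,vent,expected",
    [(500, False, 0), (399.9, False, 1), (150, True, 3), (150, False, 2), (90, True, 4), (90, False, 2)],
)
def test_respiration_support_requirement(pf, vent, expected):
    assert sofa_engine.score_respiration(pf, vent) == expected
    assert oracle_resp(pf, vent) == expected


@pytest.mark.parametrize(
    "fn,oracle,value,expected",
    [
        (sofa_engine.score_coagulation, oracle_coag, 160, 0),
        (sofa_engine.score_coagulation, oracle_coag, 100, 1),  # left-closed bin
        (sofa_engine.score_coagulation, oracle_coag, 99.9, 2),
        (sofa_engine.score_coagulation, oracle_coag, 15, 4),
        (sofa_engine.score_liver, oracle_liver, 1.0, 0),
        (sofa_engine.score_liver, oracle_liver, 1.2, 1),
        (sofa_engine.score_liver, oracle_liver, 13.0, 4),
        (sofa_engine.score_cns, oracle_cns, 15, 0),
        (sofa_engine.score_cns, oracle_cns, 13, 1),
        (sofa_engine.score_cns, oracle_cns, 3, 4),
    ],
)
def test_single_input_subscores_match_lookup_oracle(fn, oracle, value, expected):
    assert fn(value) == expected == oracle(value)


def test_renal_takes_worse_of_creatinine_and_urine_pathways():
    assert sofa_engine.score_renal(1.0, 150) == 4 == oracle_renal(1.0, 150)
    assert sofa_engine.score_renal(1.0, 450) == 3
    assert sofa_engine.score_renal(3.6, 2000) == 3
    assert sofa_engine.score_renal(1.0) == 0


@pytest.mark.parametrize(
    "mean_ap,doses,expected",
    [
        (80, {}, 0),
        (65, {}, 1),
        (80, {"dopamine": 3}, 2),
        (80, {"dobutamine": 0.01}, 2),
        (80, {"norepinephrine": 0.05}, 3),
        (60, {"norepinephrine": 0.2}, 4),  # dose rule dominates MAP rule
        (80, {"dopamine": 20}, 4),
    ],
)
def test_cardiovascular_dose_rules(mean_ap, doses, expected):
    assert sofa_engine.score_cardiovascular(mean_ap, doses) == expected
    assert oracle_cardio(mean_ap, **{k[:3]: v for k, v in doses.items()}) == expected


def test_domain_errors():
    with pytest.raises(ValueError):
        sofa_engine.score_respiration(0, True)
    with pytest.raises(ValueError):
        sofa_engine.score_cns(16)
    with pytest.raises(ValueError):
        sofa_engine.score_cardiovascular(70, {"norepinephrine": -0.1})


@given(
    pf=st.floats(1, 600),
    vent=st.booleans(),
    platelets=st.floats(0, 400),
    bilirubin=st.floats(0, 30),
    mean_ap=st.floats(20, 130),
    nor=st.floats(0, 1),
    gcs=st.integers(3, 15),
    creatinine=st.floats(0, 12),
    urine=st.floats(0, 4000),
)
def test_subscores_match_oracle_and_worsening_never_lowers_score(
    pf, vent, platelets, bilirubin, mean_ap, nor, gcs, creatinine, urine
):
    scores = {
        "respiration": sofa_engine.score_respiration(pf, vent),
        "coagulation": sofa_engine.score_coagulation(platelets),
        "liver": sofa_engine.score_liver(bilirubin),
        "cardiovascular": sofa_engine.score_cardiovascular(mean_ap, {"norepinephrine": nor}),
        "cns": sofa_engine.score_cns(gcs),
        "renal": sofa_engine.score_renal(creatinine, urine),
    }
    oracle = {
        "respiration": oracle_resp(pf, vent),
        "coagulation": oracle_coag(platelets),
        "liver": oracle_liver(bilirubin),
        "cardiovascular": oracle_cardio(mean_ap, nor=nor),
        "cns": oracle_cns(gcs),
        "renal": oracle_renal(creatinine, urine),
    }
    assert scores == oracle
    assert all(0 <= s <= 4 for s in scores.values())
    assert 0 <= sum(scores.values()) <= 24

    worse = {
        "respiration": sofa_engine.score_respiration(max(pf / 2, 1), vent),
        "coagulation": sofa_engine.score_coagulation(platelets / 2),
        "liver": sofa_engine.score_liver(bilirubin * 2),
        "cardiovascular": sofa_engine.score_cardiovascular(
            mean_ap / 2, {"norepinephrine": nor * 2}
        ),
        "cns": sofa_engine.score_cns(max(gcs - 2, 3)),
        "renal": sofa_engine.score_renal(creatinine * 2, urine / 2),
    }
    for organ in scores:
        assert worse[organ] >= scores[organ]


def _one_encounter(los_hours=6):
    return pd.DataFrame(
        {
            "encounter_id": ["e1"],
            "ed_arrival": pd.to_datetime(["2023-02-01T00:00:00+00:00"], utc=True),
            "discharge": pd.to_datetime(["2023-02-01T00:00:00+00:00"], utc=True)
            + pd.Timedelta(hours=los_hours),
        }
    )


def test_no_observations_scores_zero_everywhere_and_flags_imputation():
    enc = _one_encounter()
    obs = pd.DataFrame(columns=["encounter_id", "timestamp", "kind", "value"])
    series = sofa_engine.compute_sofa_series(obs, enc)
    assert (series["total"] == 0).all()
    for organ in sofa_engine.ORGANS:
        assert series[f"{organ}_imputed"].all()


def test_locf_carries_until_lookback_expiry_then_reverts_to_default():
    enc = _one_encounter(los_hours=8)
    obs = pd.DataFrame(
        {
            "encounter_id": ["e1"],
            "timestamp": pd.to_datetime(["2023-02-01T00:00:00+00:00"], utc=True),
            "kind": ["platelets"],
            "value": [40.0],
        }
    )
    series = sofa_engine.compute_sofa_series(obs, enc, carry_forward_hours=3.0)
    within = series["grid_time"] <= pd.Timestamp("2023-02-01T03:00:00+00:00")
    assert (series.loc[within, "coagulation"] == 3).all()
    assert (series.loc[~within, "coagulation"] == 0).all()
    assert (~series.loc[within, "coagulation_imputed"]).all()
    assert series.loc[~within, "coagulation_imputed"].all()


@pytest.mark.parametrize("los_minutes,expected_points", [(0, 1), (14, 1), (15, 2), (100, 7)])
def test_grid_alignment(los_minutes, expected_points):
    enc = _one_encounter(los_hours=los_minutes / 60)
    obs = pd.DataFrame(columns=["encounter_id", "timestamp", "kind", "value"])
    series = sofa_engine.compute_sofa_series(obs, enc)
    assert len(series) == expected_points
    assert series["grid_time"].iloc[0] == enc["ed_arrival"].iloc[0]


def test_total_equals_sum_of_subscores_and_recompute_is_identical(study_cohort):
    cohort, _, series, _, _ = study_cohort
    assert (series["total"] == series[list(sofa_engine.ORGANS)].sum(axis=1)).all()
    assert series["total"].between(0, 24).all()
    for organ in sofa_engine.ORGANS:
        assert series[organ].between(0, 4).all()
    again = sofa_engine.compute_sofa_series(cohort.observations, cohort.encounters)
    pd.testing.assert_frame_equal(series, again)


def test_grid_length_matches_formula_on_generated_cohort(study_cohort):
    cohort, _, series, _, _ = study_cohort
    step = GridSpec().step
    expected = (
        (cohort.encounters["discharge"] - cohort.encounters["ed_arrival"]) // step + 1
    )
    counts = series.groupby("encounter_id", sort=False).size()
    assert (
        counts.loc[cohort.encounters["encounter_id"]].to_numpy()
        == expected.to_numpy()
    ).all()
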