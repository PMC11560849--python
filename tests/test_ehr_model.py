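"""Cohort I/O: schema checks, per-row rejection diagnostics, round trips."""

import pandas as pd
import pytest

from sepsisval import ehr_model, synthetic_cohort as sc


def _write_tables(tmp_path, **overrides):
    """A tiny valid cohort on disk, with optional raw-text table overrides."""
    defaults = {
        "encounters": (
            "encounter_id,sex,age_years,race,diabetes,hyperlipidemia,"
            "chronic_kidney_disease,cabg,pvd,stroke,ed_arrival,discharge\n"
            "e1,female,40,Black,0,0,0,0,0,0,"
            "2023-01-01T00:00:00+00:00,2023-01-02T00:00:00+00:00\n"
        ),
        "observations": "encounter_id,timestamp,kind,value\n",
        "orders": "encounter_id,timestamp,kind\n",
        "alerts": "encounter_id,timestamp,model_score,chart_viewed\n",
    }
    defaults.update(overrides)
    paths = ehr_model.cohort_paths(tmp_path)
    for name, text in defaults.items():
        paths[name].write_text(text, encoding="utf-8")
    return paths


def test_empty_child_tables_give_valid_cohort_with_empty_series(tmp_path):
    cohort = ehr_model.read_cohort(_write_tables(tmp_path))
    assert len(cohort.encounters) == 1
    assert cohort.observations.empty and cohort.orders.empty and cohort.alerts.empty
    assert cohort.rejections.empty


def test_out_of_bounds_gcs_rejected_with_diagnostic(tmp_path):
    paths = _write_tables(
        tmp_path,
        observations=(
            "encounter_id,timestamp,kind,value\n"
            "e1,2023-01-01T01:00:00+00:00,gcs,17\n"
            "e1,2023-01-01T01:00:00+00:00,gcs,12\n"
        ),
    )
    cohort = ehr_model.read_cohort(paths)
    assert len(cohort.observations) == 1
    assert len(cohort.rejections) == 1
    row = cohort.rejections.iloc[0]
    assert row["table"] == "observations" and row["line"] == 2
    assert "gcs" in row["reason"] and "bounds" in row["reason"]


def test_rejected_plus_accepted_rows_equals_input_rows(tmp_path):
    obs_rows = [
        "e1,2023-01-01T01:00:00+00:00,gcs,17",  # bound violation
        "e1,not-a-time,platelets,100",  # bad timestamp
        "e1,2023-01-05T00:00:00+00:00,platelets,100",  # outside encounter
        "e1,2023-01-01T02:00:00+00:00,platelets,100",  # valid
        "e1,2023-01-01T03:00:00+00:00,sodium,140",  # unknown kind
    ]
    paths = _write_tables(
        tmp_path,
        observations="encounter_id,timestamp,kind,value\n" + "\n".join(obs_rows) + "\n",
    )
    cohort = ehr_model.read_cohort(paths)
    assert len(cohort.observations) + len(cohort.rejections) == len(obs_rows)
    assert len(cohort.observations) == 1


def test_unparseable_timestamp_diagnostic_carries_line_number(tmp_path):
    paths = _write_tables(
        tmp_path,
        orders=(
            "encounter_id,timestamp,kind\n"
            "e1,2023-01-01T01:00:00+00:00,antibiotic\n"
            "e1,banana,blood_culture\n"
        ),
    )
    cohort = ehr_model.read_cohort(paths)
    assert len(cohort.orders) == 1
    assert cohort.rejections.iloc[0]["line"] == 3
    assert "timestamp" in cohort.rejections.iloc[0]["reason"]


def test_missing_column_raises_schema_error_naming_column(tmp_path):
    paths = _write_tables(tmp_path, alerts="encounter_id,timestamp,model_score\n")
    with pytest.raises(ehr_model.SchemaError, match="chart_viewed"):
        ehr_model.read_cohort(paths)


def test_orphan_encounter_id_raises_referential_error(tmp_path):
    paths = _write_tables(
        tmp_path,
        orders="encounter_id,timestamp,kind\nghost,2023-01-01T01:00:00+00:00,antibiotic\n",
    )
    with pytest.raises(ehr_model.ReferentialError, match="ghost"):
        ehr_model.read_cohort(paths)


def test_underage_encounter_rejected(tmp_path):
    paths = _write_tables(
        tmp_path,
        encounters=(
            "encounter_id,sex,age_years,race,diabetes,hyperlipidemia,"
            "chronic_kidney_disease,cabg,pvd,stroke,ed_arrival,discharge\n"
            "e1,female,17,Black,0,0,0,0,0,0,"
            "2023-01-01T00:00:00+00:00,2023-01-02T00:00:00+00:00\n"
        ),
    )
    cohort = ehr_model.read_cohort(paths)
    assert cohort.encounters.empty
    assert "age" in cohort.rejections.iloc[0]["reason"]


@pytest.mark.parametrize("seed", [0, 7, 42])
def test_write_read_round_trip_identity(tmp_path, seed):
    """read_cohort(write_cohort(x)) == x on generated invariant-satisfying cohorts."""
    cohort, _ = sc.generate_cohort(sc.ScenarioConfig(n_encounters=150, seed=seed))
    paths = ehr_model.cohort_paths(tmp_path)
    ehr_model.write_cohort(cohort, paths)
    back = ehr_model.read_cohort(paths)
    assert back.rejections.empty
    for name in ehr_model.TABLE_NAMES:
        pd.testing.assert_frame_equal(
            getattr(cohort, name).reset_index(drop=True),
            getattr(back, name).reset_index(drop=True),
            check_dtype=False,
        )


def test_non_ascii_encounter_id_survives_round_trip(tmp_path):
    cohort, _ = sc.generate_cohort(sc.ScenarioConfig(n_encounters=5, seed=1))
    exotic = "enc-åßœ-普通"
    for name in ehr_model.TABLE_NAMES:
        table = getattr(cohort, name)
        table.loc[table["encounter_id"] == "e000000", "encounter_id"] = exotic
    paths = ehr_model.cohort_paths(tmp_path)
    ehr_model.write_cohort(cohort, paths)
    back = ehr_model.read_cohort(paths)
    assert exotic in set(back.encounters["encounter_id"])


def test_empty_cohort_writes_header_only_files(tmp_path):
    empty = ehr_model.Cohort(
        *(ehr_model._empty_table(n) for n in ehr_model.TABLE_NAMES)
    )
    paths = ehr_model.write_cohort(empty, ehr_model.cohort_paths(tmp_path))
    for name, path in paths.items():
        lines = path.read_text().strip().splitlines()
        assert lines == [",".join(ehr_model.TABLE_COLUMNS[name])]
    back = ehr_model.read_cohort(paths)
    assert all(getattr(back, n).empty for n in ehr_model.TABLE_NAMES)


@pytest.mark.parametrize("step", [0, -15, 7, 45])
def test_grid_spec_rejects_steps_not_dividing_hour(step):
    with pytest.raises(ValueError):
        ehr_model.GridSpec(step_minutes=step)
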