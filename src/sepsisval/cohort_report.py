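"""Cohort characteristics stratified by sepsis status, with chi-square tests.

Produces the standard "Table 1"-style demographics/comorbidity table: for
each categorical variable, counts by sepsis status with *row* percentages
(percent of that category's encounters that are / are not septic), and a
chi-square test of independence between the variable and the sepsis label.

Tests: Pearson chi-square without continuity correction for tables larger
than 2x2; for 2x2 tables the Yates correction is off by default and
config-exposed. A likelihood-ratio (G-test) variant is available for
multi-level variables. Age is banded 18-44 / 45-64 / 65+.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .ehr_model import COMORBIDITIES

AGE_BANDS = ("18-44", "45-64", "65+")

DEFAULT_VARIABLES = ("sex", "age_band", "race", *COMORBIDITIES)


def band_age(age_years: pd.Series) -> pd.Series:
    """Band adult ages into 18-44 / 45-64 / 65+."""
    return pd.cut(
        age_years,
        bins=[18, 45, 65, np.inf],
        right=False,
        labels=list(AGE_BANDS),
    ).astype(object)


def chi2_independence(
    table: np.ndarray | pd.DataFrame,
    correction: bool = False,
    method: str = "pearson",
) -> tuple[float, int, float]:
    """Chi-square (or likelihood-ratio) test of independence on a
    contingency table of counts. Returns (statistic, dof, p_value)."""
    if method not in ("pearson", "log-likelihood"):
        raise ValueError("method must be 'pearson' or 'log-likelihood'")
    res = stats.chi2_contingency(
        np.asarray(table),
        correction=correction,
        lambda_=None if method == "pearson" else "log-likelihood",
    )
    return float(res.statistic), int(res.dof), float(res.pvalue)


def characteristics_table(
    encounters: pd.DataFrame,
    labels: pd.DataFrame,
    variables: tuple[str, ...] = DEFAULT_VARIABLES,
    correction_2x2: bool = False,
    multilevel_method: str = "pearson",
) -> pd.DataFrame:
    """Per-variable stratified counts, row percentages, and chi-square tests.

    Returns a long DataFrame with one row per (variable, category):
    ``n_no_sepsis, pct_no_sepsis, n_sepsis, pct_sepsis`` (row percentages)
    and the variable-level ``chi2, dof, p_value`` repeated on each of its
    rows. A variable with a zero *expected* cell is reported with NaN test
    results and a warning instead of a test.
    """
    df = encounters.merge(
        labels[["encounter_id", "sepsis"]], on="encounter_id", validate="one_to_one"
    )
    df["age_band"] = band_age(df["age_years"])

    out_rows = []
    for var in variables:
        if var in COMORBIDITIES:
            cats = df[var].astype(bool).map({True: "yes", False: "no"})
            display_categories = ["yes"]  # convention: report flag carriers
        else:
            cats = df[var]
            display_categories = sorted(cats.dropna().unique().tolist())
        ct = pd.crosstab(cats, df["sepsis"]).reindex(columns=[False, True], fill_value=0)

        stat, dof, p = np.nan, 0, np.nan
        if ct.shape[0] >= 2 and ct.values.sum() > 0:
            expected = stats.contingency.expected_freq(ct.values)
            if (expected == 0).any():
                warnings.warn(
                    f"variable {var!r}: zero expected cell count, test skipped",
                    stacklevel=2,
                )
            else:
                is_2x2 = ct.shape == (2, 2)
                stat, dof, p = chi2_independence(
                    ct.values,
                    correction=correction_2x2 if is_2x2 else False,
                    method="pearson" if is_2x2 else multilevel_method,
                )

        for cat in display_categories:
            if cat not in ct.index:
                continue
            n_no, n_yes = int(ct.loc[cat, False]), int(ct.loc[cat, True])
            row_n = n_no + n_yes
            out_rows.append(
                {
                    "variable": var,
                    "category": cat,
                    "n_no_sepsis": n_no,
                    "pct_no_sepsis": 100.0 * n_no / row_n if row_n else np.nan,
                    "n_sepsis": n_yes,
                    "pct_sepsis": 100.0 * n_yes / row_n if row_n else np.nan,
                    "chi2": stat,
                    "dof": dof,
                    "p_value": p,
                }
            )
    return pd.DataFrame(out_rows)


def render_text_table(table: pd.DataFrame) -> str:
    """Plain-text rendering of :func:`characteristics_table` output."""
    lines = [
        f"{'variable':<24}{'category':<12}{'no sepsis':>16}{'sepsis':>16}{'p':>10}"
    ]
    last_var = None
    for _, r in table.iterrows():
        p = "" if pd.isna(r["p_value"]) else (
            "<.01" if r["p_value"] < 0.01 else f"{r['p_value']:.2f}"
        )
        show_p = p if r["variable"] != last_var else ""
        lines.append(
            f"{r['variable'] if r['variable'] != last_var else '':<24}"
            f"{str(r['category']):<12}"
            f"{r['n_no_sepsis']:>9} ({r['pct_no_sepsis']:4.1f}%)"
            f"{r['n_sepsis']:>9} ({r['pct_sepsis']:4.1f}%)"
            f"{show_p:>10}"
        )
        last_var = r["variable"]
    return "\n".join(lines)
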