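"""Cohort characteristics stratified by sepsis status.

Demographics and comorbidity flags with row percentages and chi-square
tests of independence against the sepsis label. Writes
results/characteristics.csv and prints the rendered table.
"""

import argparse
from pathlib import Path

from sepsisval import cohort_report, ehr_model, sepsis_labeler

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--cohort-dir", type=Path, default=Path("results/cohort"))
parser.add_argument("--labels", type=Path, default=Path("results/labels.csv"))
parser.add_argument("--out", type=Path, default=Path("results/characteristics.csv"))
args = parser.parse_args()

cohort = ehr_model.read_cohort(ehr_model.cohort_paths(args.cohort_dir))
labels = sepsis_labeler.read_labels(args.labels)
table = cohort_report.characteristics_table(cohort.encounters, labels)
table.to_csv(args.out, index=False)
print(cohort_report.render_text_table(table))
print(f"-> {args.out}")
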