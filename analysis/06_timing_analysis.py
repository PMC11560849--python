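"""Lead-time analysis over encounter-level true positives.

Signed lead = onset - first fired alert (positive: alert first). Writes
results/timing.json and a 15-minute-binned histogram CSV.
"""

import argparse
import json
from pathlib import Path

from sepsisval import alert_evaluation, ehr_model, sepsis_labeler, timing_analysis

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--cohort-dir", type=Path, default=Path("results/cohort"))
parser.add_argument("--labels", type=Path, default=Path("results/labels.csv"))
parser.add_argument("--out", type=Path, default=Path("results/timing.json"))
parser.add_argument(
    "--histogram", type=Path, default=Path("results/lead_time_histogram.csv")
)
args = parser.parse_args()

cohort = ehr_model.read_cohort(ehr_model.cohort_paths(args.cohort_dir))
labels = sepsis_labeler.read_labels(args.labels)
first = alert_evaluation.extract_fired_alerts(cohort.alerts)
summary = timing_analysis.compute_lead_times(first, labels)

args.out.write_text(json.dumps(summary.as_dict(), indent=2))
timing_analysis.lead_time_histogram(summary.lead_times_min).to_csv(
    args.histogram, index=False
)

lo, hi = summary.interval_80_min
print(f"{summary.n_tp} encounter-level true positives")
print(f"  median lead {summary.median_lead_min:.0f} min; 80% interval [{lo:.0f}, {hi:.0f}] min")
print(
    f"  alert at/before onset: {100 * summary.fraction_alert_before_onset:.1f}%  "
    f"after onset: {100 * summary.fraction_alert_after_onset:.1f}%"
)
print(f"-> {args.out}, {args.histogram}")
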