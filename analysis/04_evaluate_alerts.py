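"""Diagnostic accuracy of the fired alerts.

Extracts fired alerts (score >= 6, chart viewed), builds the 6-hour-window
and whole-encounter confusion matrices, and writes results/metrics.json with
sensitivity / specificity / PPV / NPV and Wilson 95% intervals.
"""

import argparse
import json
from pathlib import Path

from sepsisval import alert_evaluation, ehr_model, sepsis_labeler

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--cohort-dir", type=Path, default=Path("results/cohort"))
parser.add_argument("--labels", type=Path, default=Path("results/labels.csv"))
parser.add_argument("--out", type=Path, default=Path("results/metrics.json"))
parser.add_argument("--window-hours", type=float, default=6.0)
parser.add_argument("--threshold", type=int, default=6)
args = parser.parse_args()

cohort = ehr_model.read_cohort(ehr_model.cohort_paths(args.cohort_dir))
labels = sepsis_labeler.read_labels(args.labels)
result = alert_evaluation.evaluate(
    cohort.alerts, labels, threshold=args.threshold, window_hours=args.window_hours
)
args.out.write_text(json.dumps(result, indent=2))

for mode in ("windowed", "encounter"):
    cm = result[mode]["confusion"]
    m = result[mode]["metrics"]
    print(
        f"{mode:>9}: tp={cm['tp']} fp={cm['fp']} fn={cm['fn']} tn={cm['tn']}  "
        f"sens {100 * m['sensitivity']:.1f}% spec {100 * m['specificity']:.1f}% "
        f"ppv {100 * m['ppv']:.1f}% npv {100 * m['npv']:.1f}%"
    )
print(f"-> {args.out}")
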