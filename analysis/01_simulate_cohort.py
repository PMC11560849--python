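"""Generate the synthetic validation cohort.

Plants a seeded ED cohort at the emulated study conditions — ~3.7% sepsis
prevalence, ~4.9% fired-alert prevalence, P(alert | sepsis) ~ 0.41 and the
two-sided lead-time mixture — and writes the four cohort tables plus the
ground-truth skeleton under results/cohort/.
"""

import argparse
from pathlib import Path

from sepsisval import ehr_model, synthetic_cohort as sc

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--n", type=int, default=14_600, help="cohort size")
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--out-dir", type=Path, default=Path("results/cohort"))
args = parser.parse_args()

config = sc.ScenarioConfig(n_encounters=args.n, seed=args.seed)
cohort, truth = sc.generate_cohort(config)

args.out_dir.mkdir(parents=True, exist_ok=True)
ehr_model.write_cohort(cohort, ehr_model.cohort_paths(args.out_dir))
sc.write_ground_truth(truth, args.out_dir / "ground_truth.csv")
config.to_yaml(args.out_dir / "scenario.yaml")

n_sep = int(truth["sepsis"].sum())
n_alert = int(truth["alert_time"].notna().sum())
print(f"wrote {args.n} encounters to {args.out_dir}")
print(f"  planted septic : {n_sep} ({100 * n_sep / args.n:.2f}%)")
print(f"  planted alerted: {n_alert} ({100 * n_alert / args.n:.2f}%)")
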