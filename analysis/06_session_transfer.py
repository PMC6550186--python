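#!/usr/bin/env python
"""Do repeated same-day assessments help, and does detection transfer to
another day?

Trains population models on either the first (pre-medication) session
only or on all six day-1 sessions, and tests the held-out subject's
clips from day 1 or from the day-2 follow-up visit (where sensors were
re-applied, simulated as a random fixed rotation of each sensor frame).
Reports per-condition AUROC and paired tests on the per-subject change.
"""

import argparse
import json
from pathlib import Path

import pdwear as pw
from pdwear.evaluation import session_experiment


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--symptom", default="bradykinesia",
                    choices=["tremor", "bradykinesia"])
    ap.add_argument("--out", default="results/session_transfer.json")
    args = ap.parse_args()

    config = pw.CohortConfig(n_subjects=10, tasks=pw.DEFAULT_TASKS[:3],
                             n_sessions_day1=6, include_day2=True,
                             n_day2_subjects=8, locations=("hand",),
                             task_duration_s=20.0, brady_prev_mean=0.55,
                             rng_seed=args.seed)
    recordings, annotations = pw.simulate_cohort(config)
    out = session_experiment(recordings, annotations, config, args.symptom,
                             seed=args.seed)

    payload = {"results": {k: r.to_dict() for k, r in out["results"].items()},
               "comparisons": out["comparisons"]}
    path = Path(args.out)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True))

    print(f"{args.symptom} detection, day-1 training:")
    for name, res in sorted(out["results"].items()):
        print(f"  {name:22s} AUROC {res.mean_auroc:.3f} "
              f"(n={res.n_subjects_evaluated})")
    for name, cmp_ in out["comparisons"].items():
        if cmp_["mean_diff"] is None:
            continue
        print(f"  {name}: change {cmp_['mean_diff']:+.3f} "
              f"(p={cmp_['p']:.3f}, n={cmp_['n_pairs']})")
    print(f"wrote {path}")


if __name__ == "__main__":
    main()
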