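#!/usr/bin/env python
"""How many training subjects does a population model need?

On a 19-subject heterogeneous cohort (subject-specific tremor frequency,
propensity and movement scale; moderate effect size), random-forest
models are trained on random subsets of 3..15 subjects and evaluated on
the left-out subjects, repeated per size. Expected AUROC should rise
with the training-pool size and then flatten.
"""

import argparse
import json
from pathlib import Path

import numpy as np

import pdwear as pw
import pdwear.features as feat
from pdwear.evaluation import learning_curve_experiment


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--sizes", type=int, nargs="+",
                    default=[3, 5, 7, 10, 15])
    ap.add_argument("--repeats", type=int, default=25)
    ap.add_argument("--out", default="results/learning_curve.json")
    args = ap.parse_args()

    config = pw.CohortConfig(n_subjects=19, tasks=pw.DEFAULT_TASKS[:3],
                             n_sessions_day1=1, include_day2=False,
                             locations=("hand",), task_duration_s=30.0,
                             tremor_amp_scale=0.03, tremor_mod_depth=0.12,
                             noise_acc_g=0.02, rng_seed=args.seed)
    recordings, annotations = pw.simulate_cohort(config)
    dominant = {s.subject_id: s.dominant_side
                for s in pw.cohort_subjects(config)}
    clips = pw.assemble_dataset(recordings, annotations, "hand",
                                dominant_side=dominant)
    table = feat.extract_features_table(clips, "tremor")
    out = learning_curve_experiment(
        feat.feature_matrix(table), table["label"].to_numpy(int),
        table["subject"].to_numpy(), sizes=args.sizes,
        n_repeats=args.repeats, seed=args.seed)

    payload = {str(s): r.to_dict() for s, r in out.items()}
    path = Path(args.out)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True))

    print("expected AUROC on a new subject vs training-pool size "
          f"({args.repeats} repeats):")
    for size, res in sorted(out.items()):
        m = np.mean(res.extras["per_repeat_mean"])
        print(f"  {size:3d} subjects: {m:.3f} "
              f"(95% CI {res.ci_low:.3f}-{res.ci_high:.3f})")
    print(f"wrote {path}")


if __name__ == "__main__":
    main()
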