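#!/usr/bin/env python
"""Preprocess a simulated cohort into labeled 5-s clips and extract the
56-feature representation for the dominant-side hand sensor.

Reads the cohort written by 01_simulate_cohort.py (or simulates a fresh
one), segments each recording into 5-s clips with 50% overlap, applies
the symptom-specific filtering and writes one feature table per symptom,
plus the feature manifest.
"""

import argparse
from pathlib import Path

import pdwear as pw
import pdwear.features as feat


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--cohort", default="results/cohort")
    ap.add_argument("--out", default="results/features")
    args = ap.parse_args()

    cohort_dir = Path(args.cohort)
    if cohort_dir.exists():
        recordings, annotations, config = pw.read_cohort(cohort_dir)
        print(f"loaded cohort from {cohort_dir}")
    else:
        config = pw.CohortConfig(n_subjects=8, tasks=pw.DEFAULT_TASKS[:6],
                                 n_sessions_day1=2, n_day2_subjects=6,
                                 task_duration_s=15.0, rng_seed=args.seed)
        recordings, annotations = pw.simulate_cohort(config)
        print("simulated a fresh cohort")

    dominant = {s.subject_id: s.dominant_side
                for s in pw.cohort_subjects(config)}
    clips = pw.assemble_dataset(recordings, annotations, "hand",
                                dominant_side=dominant)
    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)
    (out / "feature_manifest.json").write_text(feat.feature_manifest(["hand"]))
    for symptom in ("bradykinesia", "tremor"):
        table = feat.extract_features_table(clips, symptom)
        path = out / f"features_{symptom}.csv"
        table.to_csv(path, index=False)
        print(f"  {symptom}: {len(table)} clips x "
              f"{table.shape[1] - len(feat.META_COLUMNS)} features "
              f"(positives {table['label'].mean():.1%}) -> {path}")


if __name__ == "__main__":
    main()
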