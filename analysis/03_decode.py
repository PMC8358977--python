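#!/usr/bin/env python
"""Per-subject decoding: 5-fold cross-validated AUC for CNN and SVM.

For every subject, trains one fresh model per fold (never shared across
subjects) on the clean epochs and scores the held-out fold; reports the five
fold AUCs with mean and SD per subject and model, against the binomial
chance thresholds (58% at alpha=.05, 68% at alpha=1e-4 for n=100).

Reads results/epochs/, writes results/decoding/report.csv and stats.json.
"""

import json
from pathlib import Path

from rhythmdecode.cnn import TrainConfig
from rhythmdecode.evaluation import cohort_report, run_cv
from rhythmdecode.io import load_epochs

ROOT = Path(__file__).resolve().parent.parent / "results"
CV_SEED = 11
CNN_CONFIG = TrainConfig(n_epochs=12)  # shortened sessions need fewer passes


def main() -> None:
    out = ROOT / "decoding"
    out.mkdir(parents=True, exist_ok=True)
    summaries = []
    for path in sorted((ROOT / "epochs").glob("S*_epochs.h5")):
        sid = path.name.split("_")[0]
        epochs = load_epochs(path)
        for model in ("cnn", "svm"):
            s = run_cv(model, epochs, k=5, seed=CV_SEED, condition="clean",
                       subject_id=sid, cnn_config=CNN_CONFIG)
            summaries.append(s)
            print(f"{sid} {model}: mean AUC {s.mean_auc:.3f} (SD {s.sd_auc:.3f})")
    table, stats = cohort_report(summaries)
    table.to_csv(out / "report.csv", index=False)
    with open(out / "stats.json", "w") as fh:
        json.dump(stats, fh, indent=2, default=float)
    for key, grp in stats["groups"].items():
        print(f"{key}: cohort mean AUC {grp['mean_auc']:.3f} (SD {grp['sd_auc']:.3f})")
    print(f"significance thresholds (n=100): {stats['thresholds']}")


if __name__ == "__main__":
    main()
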