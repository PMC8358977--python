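#!/usr/bin/env python
"""Final cohort figures and summary table.

Combines the decoding and robustness tables into per-subject AUC plots with
fold-SD bars, the significance thresholds, and a clean-vs-noisy comparison
per model. Writes results/report/summary.csv and two PNG figures.
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from rhythmdecode.evaluation import significance_threshold

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    out = ROOT / "report"
    out.mkdir(parents=True, exist_ok=True)
    decoding = pd.read_csv(ROOT / "decoding" / "report.csv")
    robustness = pd.read_csv(ROOT / "robustness" / "robustness.csv")

    thr05 = significance_threshold(100, 0.05).threshold_pct / 100
    thr1e4 = significance_threshold(100, 1e-4).threshold_pct / 100

    fig, axes = plt.subplots(1, 2, figsize=(11, 4), sharey=True)
    for ax, model in zip(axes, ("cnn", "svm")):
        grp = decoding[decoding.model == model]
        ax.errorbar(range(len(grp)), grp["mean_auc"], yerr=grp["sd_auc"],
                    fmt="o", capsize=3)
        ax.axhline(thr05, ls=":", color="gray", label="p=0.05")
        ax.axhline(thr1e4, ls="--", color="gray", label="p=1e-4")
        ax.axhline(grp["mean_auc"].mean(), ls="-", color="C1", label="cohort mean")
        ax.set_title(f"{model.upper()} (clean epochs)")
        ax.set_xlabel("subject")
        ax.set_ylim(0.3, 1.05)
    axes[0].set_ylabel("5-fold mean AUC")
    axes[1].legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(out / "per_subject_auc.png", dpi=150)

    fig2, ax = plt.subplots(figsize=(5, 4))
    for i, model in enumerate(("cnn", "svm")):
        grp = robustness[robustness.model == model]
        ax.scatter([i - 0.15] * len(grp), grp["clean_auc"], label=None, color="C0")
        ax.scatter([i + 0.15] * len(grp), grp["all_epochs_auc"], color="C3")
        for _, row in grp.iterrows():
            ax.plot([i - 0.15, i + 0.15], [row.clean_auc, row.all_epochs_auc],
                    color="gray", lw=0.5)
    ax.set_xticks([0, 1], ["CNN", "SVM"])
    ax.set_ylabel("mean AUC (blue=clean, red=all epochs)")
    ax.set_title("Robustness to retained noisy epochs")
    fig2.tight_layout()
    fig2.savefig(out / "robustness.png", dpi=150)

    summary = robustness.groupby("model").agg(
        clean=("clean_auc", "mean"), noisy=("all_epochs_auc", "mean"),
        degradation=("degradation", "mean"),
    ).round(4)
    summary.to_csv(out / "summary.csv")
    print(summary.to_string())
    print(f"figures and summary written to {out}")


if __name__ == "__main__":
    main()
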