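#!/usr/bin/env python
"""Preprocess every archived session into labelled 2-s epochs.

Runs the fixed chain (0.5-45 Hz zero-phase band-pass, drop channels 61-64,
downsample to 100 Hz, joint per-subject bad-channel detection and
interpolation, average re-reference, 2-s stimulus-locked epoching,
improbable-epoch masking) and reports, per subject, how many channels were
repaired and what fraction of epochs the improbability criterion masked -
expected to bracket one quarter at the default artifact conditions.

Reads results/cohort/, writes one epoch container per subject to
results/epochs/.
"""

import json
from pathlib import Path

from rhythmdecode.io import load_recording, save_epochs
from rhythmdecode.preprocess import PreprocessConfig, preprocess_subject

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cfg = PreprocessConfig()
    out = ROOT / "epochs"
    out.mkdir(parents=True, exist_ok=True)
    summary = {}
    subjects = sorted({p.name.split("_")[0] for p in (ROOT / "cohort").glob("S*_*.h5")})
    for sid in subjects:
        recordings = {
            label: load_recording(ROOT / "cohort" / f"{sid}_{label}.h5")
            for label in ("drum", "syllable")
        }
        epochs, info = preprocess_subject(recordings, cfg)
        save_epochs(epochs, out / f"{sid}_epochs.h5", provenance={"subject": sid})
        summary[sid] = info
        flagged = info["drum"]["flagged_channels"]
        rates = {k: round(v["rejection_rate"], 3) for k, v in info.items()}
        print(f"{sid}: {epochs.n_epochs} epochs, {len(flagged)} channels interpolated, "
              f"rejection {rates}")
    with open(out / "preprocess_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=float)


if __name__ == "__main__":
    main()
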