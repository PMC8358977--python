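#!/usr/bin/env python
"""Generate the synthetic study cohort and archive it to disk.

Ten subjects, each with one drumbeat and one syllable session at the default
noise and artifact conditions (2 Hz stimulation, 64-channel net at 1000 Hz,
subject-specific SNR around 0.6, ~8 transient artifacts per minute, two bad
channels). Sessions are shortened to 160 stimulus repetitions (80 s) so the
whole analysis runs on a laptop; per-time-unit conditions are unchanged.

Writes one HDF5 container + TSV event sidecar per session under
results/cohort/, plus the ground-truth artifact manifests.
"""

import json
from pathlib import Path

from rhythmdecode.io import save_recording, write_events_tsv
from rhythmdecode.simulate import GeneratorConfig, iter_cohort

OUT = Path(__file__).resolve().parent.parent / "results" / "cohort"
N_SUBJECTS = 10
CONFIG = GeneratorConfig(n_repetitions=160, rng_seed=123)


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    manifests = {}
    for subject in iter_cohort(N_SUBJECTS, CONFIG):
        for label, rec in subject.recordings.items():
            stem = OUT / f"{subject.subject_id}_{label}"
            save_recording(rec, f"{stem}.h5", provenance={"seed": CONFIG.rng_seed})
            write_events_tsv(rec, f"{stem}_events.tsv")
        manifests[subject.subject_id] = {
            "snr": subject.snr,
            "site": subject.site,
            "artifacts": subject.manifests,
        }
        print(f"{subject.subject_id}: snr={subject.snr:.2f} site={subject.site}")
    with open(OUT / "ground_truth.json", "w") as fh:
        json.dump(manifests, fh, indent=2, default=float)
    print(f"wrote {N_SUBJECTS} subjects ({2 * N_SUBJECTS} sessions) to {OUT}")


if __name__ == "__main__":
    main()
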