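# rhythmdecode

Per-subject decoding of which rhythmic auditory stimulus an infant heard —
a repeated syllable or a drumbeat, both presented at 2 Hz — from 60-channel
EEG. The package implements the full analysis as a tested, reusable
pipeline: a synthetic-EEG cohort generator (so every stage is exercisable
without real infant data), the preprocessing chain from continuous
recording to labelled 2-second epochs, two within-subject classifiers (a
compact convolutional network on raw epochs and a band-power + PCA + linear
SVM), cross-validated ROC-AUC evaluation with exact binomial significance
thresholds, and the robustness-to-noise comparison between the two models.

## Who this is for

Developmental-EEG and BCI researchers who want a self-contained, seeded
reference implementation of within-subject rhythmic-stimulus decoding:
every stage is a plain function over explicit containers (`Recording`,
`EpochSet`), every stochastic draw derives from one master seed, and the
statistical structure of the data is generated, so ground truth is known.

## The analysis

**Preprocessing** (per subject): zero-phase 0.5–45 Hz band-pass → drop
unused channels 61–64 → downsample 1000 → 100 Hz → automated bad-channel
detection (per-channel excess kurtosis and a kernel-density improbability
score, flagged at |z| > 2 across channels) with nearest-neighbour
interpolation → average re-reference → non-overlapping 2-s epochs cut to
stimulus onset (4 beats per epoch) → improbable-epoch masking (epochs kept,
flagged), which masks roughly a quarter of epochs at the default artifact
conditions.

**CNN** (one network per subject, 53,129 trainable parameters): temporal
1×4 convolution (12 filters, no activation) → spatio-temporal 60×4
convolution (12 filters, ELU) → 1×4 max-pool → flatten (576) → dropout 0.3
→ dense 32 (ELU) → sigmoid. Input is the raw 60×200 epoch min-max scaled to
[−1, 1]; training is Adam (lr 10⁻³, β₁ 0.9, β₂ 0.999, ε 10⁻⁷) on
class-weighted binary cross-entropy, batch 32, 25 passes (or early stopping
on validation AUC, patience 6). Implemented in plain numpy with analytic
backprop — no deep-learning framework required.

**SVM**: per epoch and channel, power in δ (1–4 Hz), θ (4–8 Hz) and
α (8–12 Hz) from a Hann periodogram → 180 features → log, z-score, PCA to
30 components (fit per training fold) → linear-kernel SVM; signed decision
values feed the ROC.

**Evaluation**: shuffled 5-fold cross-validation, AUC per fold via the
Mann–Whitney formulation (AUC = P(score⁺ > score⁻), ties ½); per-subject
mean ± SD over folds; decoding significance against the exact binomial
chance threshold (for n = 100 trials: accuracy > 58% ⇒ p < 0.05,
> 68% ⇒ p < 10⁻⁴); robustness = rerunning the identical protocol with the
masked noisy epochs retained; site comparison by rank-sum test.

## Worked example

The `analysis/` scripts run the whole study on a 10-subject synthetic
cohort (80 s sessions; per-time-unit noise and artifact conditions are the
generator defaults — see `docs/methods.md`):

```bash
python analysis/01_simulate.py     # cohort -> results/cohort/
python analysis/02_preprocess.py   # epochs -> results/epochs/
python analysis/03_decode.py       # 5-fold AUC per subject and model
python analysis/04_robustness.py   # clean vs all-epochs comparison
python analysis/05_report.py       # summary table + figures
```

`02_preprocess.py` prints, per subject, the interpolated-channel count and
the fraction of epochs masked as improbable, e.g.

```
S001: 80 epochs, 2 channels interpolated, rejection {'drum': 0.2, 'syllable': 0.25}
```

— both injected bad channels were found, and ~20–25% of epochs were masked.
`04_robustness.py` ends with the study's key contrast:

```
cnn: mean degradation -0.0283
svm: mean degradation +0.0842
mean epoch rejection rate: 24.9%
```

Retaining the noisy quarter of the data costs the band-power SVM about
0.08 AUC on average, while the CNN is essentially unaffected — the CNN is
the more noise-robust model, although the SVM is competitive on clean data.
`05_report.py` writes the per-subject AUC figure (with fold-SD bars and the
58%/68% significance lines) and `results/report/summary.csv`:

```
        clean   noisy  degradation
cnn    0.9196  0.9479      -0.0283
svm    0.7703  0.6861       0.0842
```

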