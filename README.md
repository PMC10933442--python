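# arousalscore

Automatic scoring and per-sleep-stage classification of EEG **arousal
intensity** from polysomnography.

Cortical arousals — abrupt EEG shifts to higher frequency lasting ≥ 3 s after
≥ 10 s of stable sleep — fragment sleep, but the standard arousal index
ignores how *strong* each arousal is. This package scores every annotated
arousal by the mean peak-to-peak amplitude of the C3 and C4 EEG channels
within the event,

    A = ½ [ ptp(C3) + ptp(C4) ]   over [onset, onset + duration),

quantile-bins the scores into intensity levels 1–4 (with stable-sleep "sham"
control windows as level 0), extracts a 136-dimensional feature vector per
event (132 Daubechies-4 wavelet statistics over C3/4, O1/2, F3/4 and chin
EMG, plus band power spectral intensity, average power, RMS, and the DFA
scaling exponent α on C3/4 — every feature normalized by its pre-arousal
value), and trains one optimized classifier per sleep stage (REM, N1, N2,
N3): SMOTE balancing, recursive feature elimination with 5-fold CV over two
classifier families (random forest, LightGBM), and TPE hyperparameter search
with successive-halving pruning. Reports give per-level sensitivity,
specificity, PPV, NPV and one-vs-rest AUROC per stage, with cross-stage
average and pooled total rows.

It is aimed at sleep researchers who have EDF recordings with hypnograms and
scorer arousal annotations, and at anyone who needs a reproducible,
fully-automated alternative to visual arousal-intensity scaling. Because
clinical PSG datasets are rarely redistributable, the package includes a
synthetic polysomnography generator with known ground-truth intensity
strata, so the entire pipeline is testable at desk scale.

## Worked example

```python
from arousalscore import (
    ArousalIntensityModel, PipelineConfig, SyntheticConfig, TrainConfig,
    run_pipeline,
)

cfg = PipelineConfig(
    synthetic=SyntheticConfig(n_recordings=8, duration=2700.0),
    train=TrainConfig(n_trials=10),
    seed=1,
)
results = run_pipeline(cfg, "out/")
print(results.summary())
```

This simulates eight 45-minute recordings (≈ 190 arousals plus ≈ 95 sham
windows), scores them, extracts features, trains the four stage models, and
prints (abridged):

```
Arousal intensity classification — per-sleep-stage models
events: 221 train / 56 test (seed 1)

Stage  Classifier          #Features  CV acc
REM    random_forest      5          1.0000
N1     random_forest      5          1.0000
N2     random_forest      36         0.9885
N3     random_forest      36         1.0000

Stage  Level  Sens%   Spec%   PPV%    NPV%    AUROC%  n
N2     0      100.00 100.00 100.00 100.00 100.00 10
N2     2       80.00 100.00 100.00  95.65  98.18 5
...
Avg    0      100.00 100.00 100.00 100.00 100.00 21
Total          98.21  99.66  98.39  99.71  99.85 56
```

Reading it: each row is one intensity level's one-vs-rest performance on the
held-out 20% of events within one sleep stage; `Avg` rows average a level
across the stages whose test set contains it, and `Total` pools every
prediction. Here level-0 sensitivity 100% means every sham (non-arousal)
window was recognized; the synthetic amplitude strata are well separated, so
near-ceiling numbers are expected — see `docs/methods.md` for what this does
and does not demonstrate about clinical data.

The same pipeline runs on real data from a directory of
`<name>.edf` + `<name>_hypnogram.csv` + `<name>_events.csv` files via
`PipelineConfig(data_dir=...)`, or from the shell:

```sh
arousalscore run-all --config pipeline.yaml --out out/ --seed 1
```

with subcommands `simulate`, `score`, `extract-features`, `train`,
`evaluate` for the individual stages.

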