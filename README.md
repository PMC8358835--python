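# scsga

Sparse Granger-causality analysis for multichannel time series (EEG-style
recordings), built around four coefficient estimators for the lagged
multivariate autoregression of each channel:

- **l2** — ordinary least squares (closed form, minimum-norm on singular
  systems);
- **lasso** — squared loss + L1 penalty, cyclic coordinate descent;
- **lapps** — L1 fitting loss + L1/2 penalty, solved by a linearized ADMM
  alternating half-thresholding and soft-thresholding proximal steps
  (robust to amplitude outliers);
- **scsga** — the lapps objective on a design whose predictor blocks are
  scaled by the Pearson correlation between each predictor channel and the
  target channel, so sensor similarity acts as a prior on which causal
  edges may enter.

Per-target coefficient vectors are repacked into an `m x m x s` tensor,
collapsed over lags into a nonnegative directed network, vectorized
(off-diagonal raster, optionally per frequency band), and classified with
an L2-regularized logistic regression, a ridge classifier, or a linear
SVM under repeated stratified k-fold cross-validation.

A simulation module generates stable sparse VAR datasets with known
causal support, optional outlier contamination, and multi-class labels,
so the whole pipeline is testable without any external recordings.

## Library quick start

```python
from scsga.simulate import EASY_REGIME, make_dataset
from scsga.pipeline import PipelineConfig, run_pipeline

ds = make_dataset(EASY_REGIME)
cfg = PipelineConfig.from_dict(dict(
    s=2, solver="scsga", lam=0.1, backend="logistic_l2",
    folds=5, repeats=10, seed=1, out_dir="scsga_out",
))
report = run_pipeline(cfg, trials=list(ds.trials), labels=ds.labels)
print(report.to_text())
```

## CLI

```sh
# synthetic labeled dataset (CSV trials + ground-truth JSON)
scsga simulate --m 8 --n 400 --classes 3 --trials-per-class 40 \
    --seed 20240101 --out data/

# per-trial causality networks (edge-list TSV)
scsga fit --config config.yaml --out networks/

# cross-validate a saved features CSV
scsga classify --features out/features.csv --backend ridge \
    --repeats 100 --seed 1 --out report.json

# full pipeline from a YAML config
scsga run --config config.yaml
```

A config file mirrors `PipelineConfig` (unknown keys are rejected):

```yaml
trials: [data/trial_0000.csv, data/trial_0001.csv]
labels: [0, 1]
srate: 200.0
s: 3
solver: scsga
lam: 0.1
bands:
  - {name: gamma, lo: 31, hi: 50}
evaluation: cv
folds: 5
repeats: 100
seed: 1
out_dir: out/
```

Band decomposition uses a 4th-order Butterworth band-pass applied
forward-backward (zero phase). Signals are mean-centered per channel
before design construction; the lag model carries no intercept.

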