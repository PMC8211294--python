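# soyield

Genotype-by-environment yield prediction for soybean multi-environment
trials, built around two recurrent sequence regressors — a **stacked LSTM**
and a **temporal-attention LSTM** — that map a growing season of daily
weather, plus a reduced pedigree representation, to plot yield.

## Who this is for

Plant-breeding and quantitative-genetics groups who have genotype × location
× year performance records (the Uniform-Soybean-Tests style of data: yield
in bu/acre, maturity group MG 0–8, parentage but no molecular markers) and
matched daily weather, and who want both *prediction* across environments
and *interpretability* — which phases of the season drive the prediction.

## The model

Each record carries a weather sequence `x^<1..Tx>` (7 variables per
time-step: ADNI, AP, ARH, MDNI, MaxSur, MinSur, AvgSur), downsampled from
the 214-day season (April 1 – October 31) to weekly (Tx = 30), biweekly
(Tx = 15) or monthly (Tx = 7) steps over the first 210 days, keeping each
variable's sense (mean of averages, max of maxima, min of minima; mean
precipitation). Two stacked LSTM layers (hidden size h in both, dropout 0.2
after each) encode the sequence into annotations `a^<t>`:

* **Stacked LSTM** — the final annotation `a^<Tx>` summarizes the sequence.
* **Temporal attention** — a shared linear scorer gives `e^<t> = w·a^<t> + b`,
  attention weights `α^<t> = softmax(e)^<t>`, and the context
  `c = Σ_t α^<t> a^<t>` replaces `a^<Tx>`. The profile `α` is the
  interpretability readout.

The summary passes through a 2-unit linear "context" layer, is concatenated
with the scaled MG and genotype-cluster scalars (which are also appended to
every input step), and a linear unit outputs the scaled yield. With h = 128
and Tx = 30 the MG+cluster variants have exactly **202,503** (stacked) and
**202,632** (attention) trainable parameters under the single-bias LSTM
convention 4h(d + h + 1) per layer.

Genotype clusters come from pedigree: Wright's numerator relationship
matrix A by the tabular method, normalized to a correlation matrix
`C_ij = A_ij/√(A_ii A_jj)`, then K-means on the correlation-profile rows
(hard assignment, inertia-minimizing, K = 20 by default at full scale).

Training follows a fixed protocol: random 80/10/10 record split, all
features and the target min-max scaled to (−1, 1) on the training split,
Adam (lr 0.001) on MSE, fixed epoch budget, metrics (RMSE, MAE, R²)
reported in bu/acre after inverting the target scaling, repeated runs
giving mean ± population SD. A greedy forward search ranks the 7 weather
variables; SVR-RBF (ε = 0.1, C = 1) and LASSO (α = 10⁻⁶) are the classical
baselines. The forward/backward passes are implemented in NumPy (float64),
so CPU runs are bit-reproducible.

Because the coordinated-trial datasets are not redistributable, the package
ships a synthetic trial generator (`soyield.synthetic`) that emulates the
full schema with a *planted* yield mechanism — family (cluster) effects,
MG × latitude adaptation, a time-windowed weather effect, Gaussian noise —
so every stage is testable against ground truth.

## Worked example

```python
from soyield import *
from soyield.experiments import oracle_r2

cfg = SyntheticConfig(seed=1)                 # desk-scale planted study
bundle = generate_trial_bundle(cfg)

C = to_correlation(build_relationship_matrix(bundle.pedigree))
clusters = kmeans_cluster(C, 5, seed=1)

tr, va, te = split_records(len(bundle.records), seed=1)
data, scaler, y_scaler = assemble_inputs(bundle.records, bundle.weather,
                                         clusters.labels, granularity="weekly",
                                         train_idx=tr)
model = build_temporal_attention(
    ModelSpec(variant="attention", tx=30, input_dim=9, hidden=8), seed=1)
train_model(model, data.subset(tr),
            TrainConfig(epochs=200, batch_size=256, seed=1), val=data.subset(va))

m = evaluate(model, data.subset(te), y_scaler)
profiles = extract_profiles(model, data)
score = localization_score(profiles, (18, 24))
```

Output:

```
1520 records, 200 genotypes, 10 locations x 4 years
K-means inertia at K=5: 277.97
test RMSE 2.620 bu/acre, MAE 2.089 bu/acre, R^2 0.694
generative-oracle R^2: 0.839
attention mass in planted window (steps 18-24): 0.292 (density ratio 1.35)
```

Reading it: the pedigree clustering recovers the 5 planted families; the
attention model explains 69% of held-out yield variance where a regression
on the *true* generating features tops out at 84%; and the attention
profile concentrates 29% of its mass on the 7 weekly steps (of 30) carrying
the planted weather effect — 1.35× the per-step density elsewhere, the
localization signature of the pod-set/seed-fill window.

The same pipeline is scriptable from the shell:

```bash
soyield synth --out data/ --seed 1
soyield cluster --pedigree data/pedigree.csv --k 5 --seed 1 --out clusters.csv
soyield train --data data/ --model attention --granularity weekly --k 5 \
              --hidden 8 --epochs 200 --repeats 3 --seed 1 --out run/
soyield attend --data data/ --k 5 --out fig/
soyield describe --variant attention       # per-layer parameter table
```

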