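# Methods

## Scope

`soyield` implements a yield-prediction pipeline for soybean
multi-environment trials: pedigree-derived genotype clustering, weather
downsampling and scaling, two recurrent sequence regressors (stacked LSTM
and temporal attention) with maturity-group/cluster augmentation, a
training/evaluation protocol with repeated runs, greedy forward selection
over weather variables, classical baselines, and attention-based
interpretability. Everything is exercised end to end on a built-in
synthetic trial generator with known ground truth.

## Synthetic trial generator

The generator emulates the schema of coordinated public variety trials:
`records.csv` (genotype, location, year, MG 0–8, yield in bu/acre),
`pedigree.csv` (individual/parent1/parent2, `NA` = unknown) and
`weather.csv` (per location-year, 214 days × 7 variables).

**Pedigree.** Founders are split into `n_clusters` families; each
generation adds `crosses_per_generation` within-family crosses with parents
drawn from earlier generations. Families are therefore mutually unrelated
blocks — the structure K-means on the correlation matrix should recover,
which makes "cluster ID helps prediction" testable by construction.

**Weather.** Daily surface temperature follows a latitude-dependent
seasonal sinusoid (level 12 − 0.35·(lat − 40) °C, amplitude 12 °C, peaking
mid-July) plus AR(1) noise (ρ = 0.7, σ = 3 °C); max/min temperatures add and
subtract positive exponential spreads, so MinSur ≤ AvgSur ≤ MaxSur holds on
every day by construction. Irradiance follows the same seasonal shape with
ADNI a random fraction of MDNI (hence ADNI ≤ MDNI); precipitation is a
Bernoulli–exponential mixture (≥ 0); relative humidity an AR(1) level
clipped to [0, 100]. Real weather has spatial correlation between
locations, weather fronts, and heavy-tailed extremes that this model does
not attempt; tests passing on it validate the pipeline mechanics and the
planted-signal recovery, not meteorological realism.

**Yield model.** For genotype g at location l in year y:

    yield = base_yield + cluster_effect[family(g)]
          − mg_adapt_penalty · (MG_g − MG_opt(lat_l))²
          + Σ_v β_v · z_v(l, y) + Normal(0, noise_sd)

with MG_opt linear from MG 8 at 30° N to MG 0 at 50° N. `z_v` is the mean
of variable v over the effect window (default days 120–168, the
pod-set/seed-fill phase), **centered within location** and standardized
across location-years. The centering is deliberate: the raw window mean is
dominated by latitude, a static covariate readable from any time-step (or
from MG itself), so an uncentered effect would plant a geography proxy
rather than a temporal signal. With the anomaly definition, the planted
signal is year-to-year weather variation that exists only inside the
window, which is what a temporal-localization diagnostic should probe.
Genotypes are planted at locations within ±1 MG of local adaptation, each
year with probability 0.85 — the density of testing is a free knob, not a
calibration claim.

**Defaults.** 20 founders, 3 generations × 60 crosses (200 lines), 5
families, 10 locations at latitudes 32–48° N, 4 years (~1,500 records);
`cluster_effect_sd` 4 bu/acre, `mg_adapt_penalty` 2 bu/acre per MG²,
β(MinSur) = 3 bu/acre per SD, base 45 bu/acre. `noise_sd` = 2.1 bu/acre is
calibrated once so that a linear regression on the true generating features
(the "generative oracle") attains R² ≈ 0.8 on held-out records — the
signal-to-noise regime the recovery experiments are defined at. The whole
bundle is a deterministic function of the config seed (files are
byte-identical across runs).

## Pedigree relatedness and clustering

Relatedness is Wright's numerator relationship matrix via the tabular
method: A_ii = 1 + ½A_{p1,p2}, A_ij = ½(A_{j,p1} + A_{j,p2}), unknown
parents contributing zero (treated as unrelated, non-inbred founders). The
matrix is then diagonal-normalized to a correlation matrix. K-means
(k-means++, n_init = 10, fixed seed) runs on the rows of the correlation
matrix — each genotype represented by its correlation profile — because
K-means needs vectors, not a similarity matrix. An organization-label
override is available for datasets where grouping by developing program is
preferred; the K-means path is the default. Marker-based G matrices are out
of scope (the motivating datasets lack genotyping).

## Weather preparation

Downsampling uses the first 210 days for the non-daily granularities
(weekly 30 × 7-day, biweekly 15 × 14-day, monthly 7 × 30-day windows) and
preserves each variable's sense: window mean for ADNI, ARH, AvgSur; window
max for MDNI, MaxSur; window min for MinSur; window *mean* for
precipitation by default (window total behind `ap_total=True`, retained
because both are defensible). Daily granularity passes all 214 rows
through; Tx = 214 is this package's convention for it.

Scaling is per-feature min-max to (−1, 1), fitted on the training split
only; a constant feature maps to 0; test values outside the training range
legitimately leave [−1, 1] (no clipping). The target yield is scaled the
same way because evaluation inverts the scaling back to bu/acre. MG and
cluster ID enter as scalar ordinals — not one-hot — both appended to every
time-step (9-dim input) and concatenated before the prediction head; this
"both places" injection is the variant that the parameter totals pin down.

## Architectures

Both models share the encoder: LSTM(d→h) → dropout(0.2) → LSTM(h→h) →
dropout(0.2), hidden sizes equal in both layers. The stacked variant takes
the last annotation; the attention variant scores every annotation with a
shared linear map (h→1, with bias), softmax-normalizes over time
(max-subtraction stabilized) and takes the weighted sum as context. The
scorer form is derived from parameter accounting: the attention model has
exactly h + 1 = 129 more parameters than the stacked one at h = 128, which
uniquely identifies a linear scorer with bias. No decoder LSTM — the task
is many-to-one. The context layer and the output unit are linear.

Parameter counting uses the single-bias LSTM convention, 4h(d + h + 1) per
layer; under it the two Tx = 30 MG+cluster reference models total 202,503
and 202,632 trainable parameters (also available in closed form in
`expected_param_count`).

Initialization: Glorot-uniform input/dense kernels, orthogonal recurrent
kernels (per-gate QR with sign correction), zero biases, all from a seeded
generator. Dropout applies only between layers (not on recurrent
connections) and only in training mode; inference is deterministic.

The implementation is plain NumPy in float64, with hand-derived
backpropagation through time verified against central finite differences
(`rtol 1e-4` elementwise on every parameter of small models of both
variants). Single-threaded CPU runs are bit-reproducible given seeds.

## Training and evaluation protocol

Records are split 80/10/10 at the record level by a seeded permutation.
Adam (lr 0.001, β = 0.9/0.999, ε = 1e-8) minimizes MSE on the scaled target
for a fixed number of epochs (no early stopping), batch size 512 at full
scale. RMSE, MAE and R² are computed after inverting the target scaling.
Repeated runs keep the split fixed and vary the initialization/training
seed (seed + repeat index); aggregate spread uses the *population*
standard deviation, recorded in the output metadata. `mae_percent` divides
MAE by a reference statistic (test mean or SD) × 100.

Greedy forward selection adds, at each stage, the remaining variable whose
addition minimizes the criterion RMSE; ties break by candidate order and a
stage failure preserves the partial trace. The default criterion is
validation RMSE (no test leakage); `test_rmse` is available to mirror
protocols that rank by test RMSE. Baselines (SVR-RBF ε = 0.1, C = 1; LASSO
α = 1e-6, 1000 iterations) receive the same scaled features flattened to
Tx·d + side dimensions and are evaluated identically, with hyperparameters
echoed in the result metadata.

## Interpretability

`extract_profiles` returns one normalized attention profile per record.
`stratify_profiles` buckets records by MG panel (default {1, 7}, the two
geo-climatically distinct panels) × actual-yield range (default:
within-panel quartiles, configurable breaks), reporting per-bucket mean
curves with inter-quartile bands and omitting buckets under a minimum count
(default 20). `localization_score` measures the mean attention mass inside
a time-step window and normalizes per step, so windows of different lengths
compare on density; a uniform profile scores ratio 1 for any window.

## Desk-scale experiment sizes

The recovery experiments run the full pipeline at sizes chosen for a
single-CPU laptop-class budget: ~1,500 records, weekly Tx = 30, hidden size
8 for the attention interpretability runs (200 epochs, batch 256) and
hidden 16 at monthly granularity for the paired with/without-MG+cluster
comparison (60 epochs, 3 repeats). The small hidden state is a deliberate
interpretability choice beyond cost: with limited memory the encoder cannot
losslessly carry the effect-window summary to the end of the season, so
in-window annotations stay the most informative and the attention profile
localizes on the planted window; large-capacity encoders instead shift
attention toward late steps whose annotations already integrate the signal
— the same readout caveat applies to attention profiles from any
high-capacity sequence model. A negative control (weather effect spread
over the whole season) across five seeds confirms the localization
diagnostic does not fire without planted temporal structure.

## Known limitations

* The weather generator has no spatial correlation across locations and no
  extreme-event structure; soil, management, irrigation and disease
  covariates are out of scope.
* Cluster and MG enter as ordinals; with many clusters a learned embedding
  would be preferable, but the ordinal encoding is what the reference
  parameter totals imply.
* The attention profile is a measure of where the *model* looks, not a
  causal statement about crop physiology; on real data it should be read as
  a hypothesis-generation tool.
* Greedy selection retrains one model per candidate per stage (28 trainings
  for 7 variables) and inherits the variance of small-model training; the
  tests quantify this on a toy with a single signal-bearing variable.
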