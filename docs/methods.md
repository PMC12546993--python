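# Methods

`microst` forecasts multivariate microbial abundance time series by combining
graph convolutions over a taxon co-occurrence network with temporal
convolutions and a deep recurrent branch. This note records the model, the
statistical procedures, the synthetic world the tests run in, and the design
choices that were genuinely open.

## Problem setting

The input is a taxa × samples abundance table whose columns are time-ordered
(e.g. daily 16S samples from one body site of one subject, collapsed to the
genus level). The task is to predict each taxon's abundance one or more steps
ahead. Taxon abundances are interdependent — ecological interactions couple
their trajectories — so a per-taxon univariate forecaster discards exactly
the structure that makes the problem tractable. The package therefore first
estimates an interaction graph from the data and then lets the forecaster
propagate information along it.

## Preprocessing

* Taxa that are all-zero are removed. Count tables are additionally filtered
  with the strict rule *total < `min_total` (default 10) OR prevalence <
  `min_prevalence` (default 5) samples ⇒ removed*; boundary taxa (exactly 10
  total, exactly 5 samples) are retained. Genus collapse sums rows sharing
  the taxonomy prefix up to the requested rank; OTUs unassigned at that rank
  are pooled into a single `unassigned at <rank>` row so per-sample mass is
  conserved rather than silently dropped.
* Each taxon is Z-scored, `(x − μᵢ)/σᵢ`, with the **population** (divisor-n)
  standard deviation; a constant taxon gets σ substituted to 1 so it maps to
  zeros instead of NaN. Parameters are fitted on the training time range only.
* The **change stream** is the first difference between adjacent time steps,
  zero-padded at t = 0 so both streams share one `(N, D, T)` shape. The first
  element is a convention (the pre-window value is unknown); zero is the
  neutral choice under Z-scoring.
* Sliding windows of width `W` (default 8) with an `H`-step target are split
  **chronologically** (default 80/20; 70/30 available via `train_fraction`).
  Random splits of overlapping windows would leak future values into
  training, so random mode exists but is not the default.

## Co-occurrence network

For every taxon pair: Spearman ρ (Pearson correlation of mid-ranks, average
ranks on ties), a two-sided permutation p-value, Benjamini–Hochberg control
over the D(D−1)/2 unique pair p-values, and removal of pairs with adjusted
p > α (default 0.05; exactly-α pairs survive, matching the strict "greater
than" removal rule). Decisions made here that the procedure itself does not
pin down:

* **Permutation estimator.** Monte Carlo mode (default, `n_perm = 1000`,
  seeded) uses the add-one estimator `(1 + count)/(1 + n_perm)`, which is
  never zero and is a valid p-value; exhaustive mode enumerates all `n!`
  permutations for `n ≤ 7` and returns the exact proportion — it is the
  oracle the Monte Carlo path is tested against.
* **BH scope.** Applied to the unique upper-triangle p-values, then mirrored:
  each pair is one hypothesis, not two.
* **Adjacency normalization.** The graph convolution uses
  `Â = D⁻¹ᐟ²(|A| + I)D⁻¹ᐟ²`: edge signs are kept in the exported adjacency
  but dropped for aggregation (mixing weights must be non-negative), and a
  self-loop is added before symmetric normalization so every degree is
  positive — standard graph-convolution practice.
* The model's `Â` comes from the thresholded network, not the raw ρ matrix.

## Forecaster

Input windows are `(B, N, T)`: batch, taxa (graph nodes), window length.

* **Temporal block.** Causal 1-D convolution along time (kernel `k = 3`,
  left-zero-padded so length is preserved and entry *t* sees only times ≤ t),
  with a gated output: the convolution produces `2C` channels split into a
  linear path `P` and gate `Q`, returning `P·σ(Q)`. The gating realizes
  "linear and non-linear activations" in one block.
* **Spatial block.** `lfs[b,c,i,t] = Σⱼ Â[i,j]·x[b,c,j,t]` — an Einstein
  contraction over the node axis — followed by a learned 1×1 channel mix and
  ReLU. This contraction is the only cross-node information path, which makes
  the full forward node-permutation equivariant (tested).
* **Stream.** Each stream stacks `n_blocks = 2` temporal–spatial–temporal
  sandwiches (`C = 16` channels) and reads out the last time step's features
  per node. Block count, width and order are not dictated by the method
  description; the sandwich follows the STGCN family layout.
* **Recurrent branch.** A five-layer LSTM over the time axis, one scalar
  input per node per step, hidden width equal to the window length (one unit
  per time step). It attaches to the abundance stream only by default; a
  config flag (`change_stream_lstm`) adds one to the change stream.
* **Variants.** `fusion` = both streams + recurrent branch; `stgcn2s` = the
  two streams only; `lstm` = the recurrent branch + head only (no graph, no
  change stream). Per-node features are concatenated and a fully connected
  head maps them to `H` standardized abundances per taxon.

Because `torch` is not available in the supported environment, the network
runs on a small in-package reverse-mode autodiff engine over numpy
(`microst.nn`). It is float64 and fully deterministic, so identical seeds
give bit-identical training runs; every layer is tested against brute-force
and numeric-gradient oracles.

## Training and evaluation

* Loss = mean absolute error (the selection metric), Adam, `lr = 1e-3`,
  batch 32, default 100 epochs, no early stopping. Validation MAE is
  computed every epoch and the weights of the **best** epoch are returned
  (best-MAE checkpointing subsumes early stopping).
* None of loss, optimizer, learning rate, batch size or epoch budget are
  pinned down by the method description; all are explicit config.
* MAE and sMAPE (bounded at 200%, with the 0/0 ⇒ 0 convention) are reported
  per horizon step and pooled, on the standardized scale and, by inverting
  the Z-score, on the original scale.
* Multi-step forecasts are **recursive**: each one-step prediction is
  appended to the window, the oldest step dropped, and the change stream
  recomputed, so the appended delta always equals the difference of
  consecutive window values. A direct multi-horizon head exists
  (`horizon > 1`) but recursion is the default protocol, with `H = 8` the
  conventional multi-step depth. Confidence bands are out of scope (no
  defined construction to implement).

## Synthetic world

The generator is a stable VAR(1): `x_t = c + (ρ_self·I + γA)x_{t−1} + ε_t`,
ε Gaussian, over a sparse signed symmetric interaction graph (edge weights
uniform on ±[0.3, 1]); stationarity (spectral radius < 1) is enforced, a
100-step burn-in discarded. Defaults — D = 20 taxa, T = 300 steps,
ρ_self = 0.55, γ = 0.12, σ_noise = 0.3 around baseline 5 — give a
moderately persistent, visibly graph-coupled daily-style series. Linear
dynamics are a deliberate choice over e.g. Lotka–Volterra: the best possible
one-step predictor is the conditional mean, whose MAE has the closed form
σ·√(2/π), so trained models are judged against an analytic floor rather
than another fitted model. An optional multinomial sampling layer converts
trajectories into fixed-depth integer count tables with synthetic
four-phylum taxonomy strings, making the table I/O, filtering and network
stages testable end to end.

What the generator does **not** emulate: compositional closure,
zero-inflation, over-dispersion, uneven sampling intervals, and nonlinear
ecology. A green forecast-quality test therefore establishes that the
implementation learns linear graph-coupled dynamics to near the analytic
floor — not that it matches published error levels on real sequencing data,
which depend on external datasets and hardware-bound stochastic training.

Noise-free fidelity tests use `burn_in = 0` with a perturbed initial state
(`x0_scale`): a stable noise-free VAR otherwise sits at its fixed point and
the series would be constant.

## Numerical choices and degenerate inputs

* σ = 0 taxa standardize to zeros (σ → 1 substitution).
* Constant vectors have undefined rank correlation: ρ is reported as 0 and
  p as 1, both flagged, rather than NaN.
* Permutation comparisons use `|ρ_perm| ≥ |ρ_obs| − 1e−12` to keep exact
  rank ties from being split by float noise.
* An empty post-threshold network is returned with a warning flag, not an
  error; `Â` is then the identity (self-loops only) and the forecaster
  degrades to per-taxon temporal modelling.
* Filtering that removes *all* taxa raises: an empty table is unusable
  downstream.

## Test-budget scaling

The stochastic acceptance checks run at the stated world size (D = 20,
T = 300, σ = 0.3) but with reduced epoch budgets chosen before thresholds
were measured — 50 epochs for forecast quality (convergence is observed in
fewer than 50 epochs), 15 epochs × 3 seeds for the ablation ordering — so
the whole suite fits a single-CPU time budget.

## Known limitations

* Recursive forecasting compounds one-step bias; no uncertainty is attached.
* The co-occurrence permutation test treats samples as exchangeable, which
  autocorrelated series violate; network edges on strongly autocorrelated
  data are anti-conservative. (This mirrors the standard field practice the
  package implements.)
* BIOM-HDF5 binary tables are not read; use TSV exports.
* The autodiff backend is CPU/numpy; it is sized for tens-to-hundreds of
  taxa, not thousands.
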