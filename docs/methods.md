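# Methods

This note documents the models implemented in `micos`, the choices made
where the design was genuinely open, and what the synthetic benchmarks do
and do not establish about real data.

## Ground-truth community model

Species abundances follow a generalized Lotka-Volterra (gLV) system with
optional third-order interaction terms:

    dx_i/dt = ( r_i + Σ_j a_ij x_j + Σ_{j≠i} Σ_{k≠i,j} b_ijk x_j x_k ) x_i

with `r_i` the intrinsic growth rate (1/h), `a_ij` pairwise interaction
coefficients (1/(h·OD)) and `b_ijk` third-order coefficients defined only
for `j ≠ i`, `k ∉ {i, j}` (all other tensor entries are exactly zero).
Self-limitation `a_ii < 0` is required: without it the multiplicative
dynamics admit finite-time blow-up.

`generate_ground_truth` draws `r ~ U(0.1, 0.8)`, off-diagonal
`a ~ N(mean, sd)` and `a_ii ~ U(lo, hi)`; third-order entries are i.i.d.
uniform on `±f·max|a|` with `f = 0.25` ("mild") or `0.50` ("moderate"),
optionally sparsified. All knobs are explicit keyword arguments.

**Stability of sampled parameter sets.** Unbiased off-diagonal draws
(`N(0, 0.4)`) routinely produce mutualistic feedback loops that diverge in
finite time once six or more species are combined. The benchmark therefore
draws predominantly competitive communities — off-diagonal `N(-0.15, 0.25)`,
diagonal `U(-2.0, -1.0)` — which keeps all assemblies bounded at realistic
optical densities (≲ 1 OD) while leaving both signs of interaction common.
Rare residual blow-ups at high richness are treated as what they are —
assemblies with no finite trajectory — and rejected with replacement when
building datasets.

Integration uses adaptive RK45 (`rtol 1e-6`, `atol 1e-9`) on the
present-species subsystem only, so absent species are exactly zero by
construction, with states clipped at zero after sampling. Serial passaging
divides the whole state by the dilution factor (default 20-fold every
24 h); samples that coincide with a passage report the pre-dilution state.
Observation noise is multiplicative log-normal (σ = 0.1 by default) on
abundances only, preserving exact zeros; the choice is a modeling decision —
plate-reader and sequencing-derived abundances have roughly constant
coefficient of variation — not a calibrated error model.

Initial abundance is an equal split over present species of
`0.0066 OD × richness`, echoing the standard inoculation density per
species in the experimental protocol this emulates.

## Community sampling designs

The training design enumerates all monocultures and all pairs, then adds
distinct random 3-, 5- and 6-member communities (defaults 100/100/99, giving
624 designs for a 25-species pool). Test designs are uniform over all
communities with richness at least a floor (default 10), drawn by sampling
the richness with probability proportional to the number of subsets of that
size. Duplicates are rejection-sampled with a hard attempt cap.

## Recurrent dynamics model

One LSTM unit maps the standardized community state at time t to time t+1:

    i_t = σ(W_ii x_t + b_ii + W_hi h_{t-1} + b_hi)
    f_t = σ(W_if x_t + b_if + W_hf h_{t-1} + b_hf)
    g_t = tanh(W_ig x_t + b_ig + W_hg h_{t-1} + b_hg)
    o_t = σ(W_io x_t + b_io + W_ho h_{t-1} + b_ho)
    c_t = f_t ⊙ c_{t-1} + i_t ⊙ g_t
    h_t = o_t ⊙ tanh(c_t)
    y_t = W_yo o_t + b_yo

Weights are shared across time steps; the output map reads the next state
off the **output gate** (not the hidden state), as in the architecture this
package implements. At inference the model runs free: `y_t` is fed back as
the next input, so every prediction is forecast from the state at time 0.

The implementation is plain numpy (float64) with hand-written reverse-mode
gradients, including the feedback path through `y_t`; gradient correctness
is pinned by central-finite-difference tests at 1e-5 relative tolerance.
Training is therefore CPU-only and bitwise reproducible given a seed.

**Teacher forcing.** During training, at each transition of each sequence
the observed standardized state replaces the fed-back prediction with
probability `teacher_forcing_prob` (per-step Bernoulli; default 0.5, never
specified upstream). Probability 1 reduces exactly to one-step-ahead
regression chained through the hidden state; probability 0 trains the pure
rollout.

**Feature scaling.** Each feature is standardized to zero mean and unit
variance *separately at every time point*, with the population (1/N)
variance convention and a 1e-8 floor for degenerate features. Statistics
come from training data only; a `normalize_all` toggle reproduces the
alternative of pooling hold-out data (reported upstream as making almost no
difference). Losses are computed on the standardized scale; all accuracy
metrics (squared Pearson correlation, "Pearson R²") are computed after
transforming back to original units.

**Model flavors.**
* *abundance*: state = species vector; trained with teacher forcing on all
  observed time points.
* *endpoint*: one LSTM transition from initial to final abundance plus a
  ReLU feed-forward head mapping the (standardized) endpoint abundance to
  the four metabolite concentrations (butyrate, lactate, acetate,
  succinate); abundance and metabolite MSE are weighted equally on
  standardized scales and all weights train simultaneously (end to end).
* *joint*: state = species ⊕ metabolites (29-dimensional for the full
  pool); the same unit propagates the concatenated vector so metabolite
  trajectories depend on both abundances and concentrations.

**Hyperparameters.** Adam with learning rates from {0.005, 0.001, 0.0001},
decayed ×0.25 every 25 epochs; L2 weight decay 1e-5; mini-batches of 10-20;
hidden width 2048 (abundance-only) or 4096 (joint) at full scale. The
scaled-down studies in this repository use hidden 32-256 and 80-400 epochs,
selected by hold-out performance during development — the architecture, not
the width, is the object under test. Weight initialization is uniform
fan-in (±1/√hidden), seed-controlled.

## Pairwise gLV fitting

`fit_glv` fits a pairwise-only gLV (third-order tensor forced to zero) by
trajectory least squares: fixed-step RK4 simulations from each table's
observed initial state are matched to the observations at all later sample
times. The optimizer is multistart `scipy.optimize.least_squares` (TRF,
finite-difference Jacobian) with diagonal entries bounded negative, seeded
by a log-derivative gradient-matching ridge regression
(`d log x_i/dt ≈ r_i + Σ_j a_ij x_j` on midpoint abundances). The
gradient-matching start makes one multistart usually sufficient; additional
starts perturb it multiplicatively. On noise-free self-generated 3-species
data the fit recovers all parameters to well under 1% (the acceptance
contract is 5%).

A discretized gLV baseline is also provided: the multiplicative map
`x_i(t+1) = x_i(t)(r_i + Σ_j a_ij x_j(t))` — implemented exactly as
written, with no "1 +" term, so its fixed points satisfy `r + Σ a x = 1` —
trained with the same Adam loop as the LSTM from zero-initialized
parameters, with features scaled to [0, 1] by per-timestep training maxima
and an optional feed-forward metabolite head applied to `x(t+1)`.

## Interpretation

**Local surrogate explanations.** `lime_explain` perturbs the binary
presence vector (the number of flipped bits is drawn uniformly so the
neighbourhood spans all Hamming distances), queries the model, and fits a
ridge surrogate (penalty 1.0) weighted by an exponential kernel
`exp(-d²/w²)` with width `0.75·√(pool size)` on the Hamming distance.
Coefficients are in target units. The perturbation/kernel/surrogate stack
is implemented here directly. Explanations are aggregated into networks by
the median weight across communities, gated to targets whose
cross-validated R² exceeds 0.5, and thresholded at 5 mM for metabolite
targets or 0.2 for species targets after normalizing by the target
species' own self-impact.

**Gradient sensitivity.** With weights frozen, one reverse pass through the
free-running rollout yields ∂(output a at step t)/∂(input b at time 0)
exactly; derivatives are chain-ruled back to original units via the scaler
standard deviations. Agreement with central finite differences at 1e-4
relative is part of the acceptance suite.

**Prediction-sensitivity statistics.** Hold-out accuracy versus training
fraction uses repeated subsampling (default 30 repeats of 50-100% in 10%
steps) with k-fold cross-validation (default 20) and pooled out-of-fold
predictions. The pairwise sensitivity statistic is

    100/N² · Σ_i Σ_{j≠i} (R²_ij − R²_i)/R²_i

with `R²_i` computed over communities initially containing species i and
`R²_ij` over those containing both. The normalizer is N² exactly as
defined, although the sum has N(N−1) terms; a flag switches to the term
count. Pairs whose subsets are empty or too small for a defined
correlation are skipped with a warning — synthetic datasets, unlike the
761-community experimental set, do not guarantee populated subsets.

## Community design

`enumerate_designs` streams all subsets above a richness floor (never
materialized; counts are binomial sums, cross-checked by full enumeration
on small pools). The *distributed* panel runs k-means (k-means++ with 10
restarts, fixed seed) in the predicted 4-metabolite space and takes the
nearest distinct design per centroid. The *corner* panel applies two-level
tail binning — the 5% lowest lactate then 5% lowest/highest butyrate of
those, and symmetrically anchored on butyrate; within each of the four
corners the same pattern on acetate/succinate yields 16 sub-corners — then
picks one seed-random design per sub-corner plus four more maximizing
Hamming distance to the chosen set (greedy sequential max-min, ties broken
lexicographically; an exhaustive variant exists for small candidate sets).
Each binning step keeps at least `per_subcorner` rows: the procedure was
designed for tables of tens of millions of predictions, where a 5%-of-5%
cascade still leaves hundreds of candidates, and the count floor is what
makes it well-defined on the 10⁵-row tables used here. Corner
classification assigns each community to the nearest class centroid in
measured metabolite space and reports misclassification against inter-class
centroid distance.

## Trajectory clustering

Communities are embedded as flattened metabolite trajectories (4 metabolites
× T time points) and clustered by divisive cutting of the minimum spanning
tree of the complete Euclidean graph: repeatedly remove the largest
remaining edge whose removal leaves every component at least
`min_cluster_size` (default 5) strong, until the requested number of
clusters (default 6) exists; inadmissible edges are logged. Ties are broken
by smallest index pair, making the procedure deterministic. The elbow
diagnostic reports the mean intracluster distance — implemented as the
size-weighted mean of within-cluster average pairwise distances, with an
unweighted option, since the quantity is not otherwise pinned down — over a
(cluster count × minimum size) grid, with the elbow taken at the maximum
second difference. Design rules per cluster come from an unpruned CART tree
(Gini, feature order fixed to pool order, fixed random state) on presence
bits: the conjunction of conditions on the path to the cluster's majority
leaf, with rule coverage and deviating communities reported.

## Scaled-down benchmark

The in-silico comparison of the recurrent model against the pairwise gLV
refit runs on a 10-species pool: training on 10 monocultures + 45 pairs +
60 triples + 35 quadruples (150 communities, mirroring the low-richness
training design), testing on 300 distinct communities of richness ≥ 6,
sampled every 8 h over 48 h, noise-free. The augmentation experiment adds
100 communities of richness ≥ 5 to training. Problem sizes were chosen so
the full comparison runs in a few CPU-minutes.

What the benchmark shows at this scale: (i) under pairwise-only truth both
model families reach high and similar hold-out accuracy; (ii) augmenting
training with higher-richness communities substantially repairs the
recurrent model's richness-extrapolation bias under third-order truth.

What it does not show: a *superiority* of the recurrent model over the
pairwise refit under third-order perturbations. With a zero-mean uniform
third-order tensor, the refit pairwise model absorbs most of the aggregate
third-order effect into effective pairwise coefficients (it outperforms
even the true pairwise part of the generator), and the recurrent model's
extrapolation error from low-richness training is of the same size as the
refit's model-class error. The corresponding ordering test is kept and
currently fails; the robust orderings at this scale are the similarity
under pairwise truth, the degradation of the pairwise refit when fitted to
third-order data relative to pairwise data, and the augmentation gain.

More generally, the synthetic generator produces smooth, noise-controlled,
perfectly observed dynamics from a known model family. Passing these tests
establishes correctness of the algorithms and the expected orderings under
the stated conditions — not predictive performance on experimental
communities, where measurement error, unmodeled environmental drift and
compositional noise dominate.

## Numerical conventions and degenerate inputs

* Pearson R² requires ≥ 3 points and non-constant vectors; constant input
  is an error, never silently 0 or 1.
* Scaler σ floored at 1e-8; transform of a constant feature is 0.
* Simulator states are clipped at 0 after sampling; the batch RK4 used in
  fitting clips to [0, 1e3] so bad parameter draws yield large finite
  residuals rather than overflow.
* All stochastic operations are pure functions of an integer seed; a run
  seed fans out to named component seeds through `SeedRegistry` (CRC-backed,
  stable across processes).
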