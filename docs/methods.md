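# Methods

This note records the statistical model behind `trainstates`, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical choices that matter for reproducing results.

## Study frame

All statistics assume a two-sex, five-group design: sedentary controls plus
groups trained for 1, 2, 4 or 8 weeks, with every tissue × ome dataset
measured on its own set of samples. Controls are a single shared group per
sex; no time-matched controls are modelled, so every timewise contrast is
"trained at week *t* versus sedentary, within sex".

## Differential model

Each feature is fit with a cell-means model over the observed sex × group
cells. The residual variance is pooled across all cells (df = samples −
cells) and shrunk towards a common prior variance estimated from all
features of the dataset:

* prior df `d0` defaults to 4 and is configurable; `d0 = 0` disables
  moderation and reproduces the classical pooled two-sample t exactly
  (this equivalence is a test);
* the prior variance `s0²` is the bias-corrected geometric-mean estimator
  `exp(mean(log s² − ψ(d/2) + log(d/2)) + ψ(d0/2) − log(d0/2))`, computed
  over features with positive residual variance;
* timewise p-values use a t reference with `d + d0` df, the training
  p-value an F reference with (number of trained cells, `d + d0`) df.

The training p-value is a joint F-test of the null "no effect at any
sex × time" (null model: one mean per sex), rather than a combination of
the eight timewise p-values: it is the simplest test with exactly that
null, and it shares the moderated variance with the timewise statistics so
the two outputs cannot disagree about a feature's evidence.

One moderated Gaussian model is used for every ome after normalization
(counts → log2 counts-per-million + 0.5; continuous omes pass through).
Platform-specific pipelines (e.g. count GLMs) are deliberately out of
scope; the normalization constant 0.5 keeps zero counts finite and the CPM
scale keeps library-size effects out of the cell means.

BH selection runs within each tissue × ome dataset, because differential
counts are reported per dataset and the multiple-testing universe should
match the reporting unit. Features that are constant across all samples are
excluded from testing with a recorded reason rather than given p = 1.

Permutation validation permutes group labels within sex (or sex labels
within group), so cell sizes are preserved and the permuted statistic
targets exactly the labels whose information is being tested. The full
training-p + BH pipeline is re-run per permutation; the empirical p is the
plain fraction of permuted selection counts at least as large as observed.

## Joint-state mixture

Per time point, the sex pair of moderated z-scores follows a nine-state
mixture with a factorized density per state. Components per sex:

| component | distribution | constraint |
|---|---|---|
| null (0)  | N(0, 1) | fixed |
| up (+1)   | N(μ₊, σ₊²) | μ₊ ≥ 1, σ₊ ≥ 1 |
| down (−1) | N(μ₋, σ₋²) | μ₋ ≤ −1, σ₋ ≥ 1 |

The SD floor of 1 is physical: an alternative z-score is a true effect plus
unit sampling noise, so its marginal SD cannot fall below 1. The mean bound
of 1 is an identifiability choice: with fully free means the alternatives
can collapse onto the null and siphon weight from it (on pure-null data the
unconstrained MLE moves ~5% of the mass into near-zero alternatives). Both
bounds are implemented as an exact box-constrained M-step — the mean is
clipped into its half-space and the variance is computed around the clipped
mean — which is the constrained maximizer, so the EM log-likelihood remains
monotone. EM starts from π₀₀ = 0.8 (rest uniform), μ = ±3, σ = 1, stops at
relative tolerance 1e−8 or 500 iterations, and retries from up to three
seeded random re-initializations if a converged solution violates the sign
constraint (not observed in practice with the constrained M-step).

States are assigned independently per time point (argmax posterior; exact
ties resolve to the null state and are flagged); there is no Markov
coupling along the time course, because the graph's edges are observed
feature flows, not a transition model. Only features selected by the
training test with complete timewise statistics (all 8 sex × time cells)
enter state modelling; datasets contributing fewer than 10 such features
are skipped and logged. Posterior tables order the nine states
lexicographically over (f, m) ∈ {−1, 0, 1}².

## Graphs and summaries

Node counts (per time × state) and edge counts (consecutive-time flows,
with per-ome sub-counts) each conserve the clustered-feature total; these
invariants are property-tested. Top paths rank by member count with
lexicographic label tie-breaks. Trajectory curves standardize each feature
across **all** samples of its dataset (not per sex), so both sexes share
one standardized axis; zero-variance features are excluded with a warning.
The per-time state summary uses six categories — up-both, down-both,
female-only, male-only, opposite (f·m = −1), null — which partition the
nine states.

## Enrichment battery

* Over-representation: one-sided hypergeometric tail, pathways restricted
  to the universe, size filter 5–500 (configurable), BH across tested
  pathways, significance at 10% FDR by default. Driver genes are the
  query ∩ pathway overlap.
* Redundancy pruning walks records in ascending p order and drops a record
  whose driver-set **overlap coefficient** |A∩B|/min(|A|,|B|) with any
  retained record reaches 0.8. Similarity for the pathway network is
  **Jaccard** |A∩B|/|A∪B| with default threshold 0.375; both measures and
  thresholds are configurable since different analyses use 0.3 or 0.375.
* GSEA: weighted KS running sum (hit steps ∝ |score|^w, default w = 1;
  miss steps 1/(N−n)); ES is the extreme deviation; NES divides by the
  mean |permuted ES| of the same sign; p is the same-sign exceedance
  fraction over gene-label permutations with add-one smoothing (so p is
  never exactly 0 at finite n_perm). Leading edge: hits at or before
  (after, for negative ES) the extremum.
* Communities: seeded Louvain modularity maximization, resolution 1.0.
* Marker correlations: the cluster signature is the per-sample mean of the
  standardized member features; categories with ≥ 2 usable markers get a
  two-sided one-sample t on their Pearson r values with BH across
  categories; single-marker categories report r without a test; constant
  markers are dropped with a warning.

## Synthetic-data generator

The generator emulates the study frame with known truth. Defaults:

| parameter | default | rationale |
|---|---|---|
| n_per_group | 6 | a typical per-cell replicate count for such designs |
| frac_null | 0.9 | most features unaffected |
| noise_sd | 0.5 | residual SD on log2 scale typical of omics data |
| effect_size_scale | 0.7126 | see below |
| count dispersion | 0.1 | moderate NB overdispersion |
| library-size CV | 20% | log-normal library factors |

Non-null features draw one magnitude *m* ~ Exponential(effect_size_scale)
and a trajectory from a catalogue of the patterns of interest (sustained
up both sexes; male-first with late female convergence; male-only;
sustained down; early transient; opposite-sex), each cell's true log2FC
being ±m per the path's states. The exponential scale solves
P(m < log2 1.5) = 0.56 in closed form, so 56% of non-null features have
their maximum fold change inside (1/1.5, 1.5) — the "modest effects"
regime. Note that the *estimated* max |logFC| of selected features at
n = 6 is noise-inflated (each cell estimate has SE ≈ 0.29, and the max is
taken over 8 cells), so the band fraction computed from fitted statistics
is much smaller than the truth-level 56%; the acceptance script reports
both numbers.

What the generator does **not** emulate: inter-feature correlation,
batch/platform effects, missing values, heavy-tailed noise, and
feature-to-gene multiplicity. Passing tests therefore demonstrate
correctness of the machinery and calibration under the stated model, not
robustness to those real-data features.

## Problem sizes used in validation

The test suite and acceptance script validate at desk scale: FDR control
uses 25 studies of 10,000 features (90% null, n = 6 per cell); EM recovery
uses 5,000 z-pairs with a 20% spike at |μ| = 4 and a Bayes-optimal oracle
on the same draws; permutation validation uses 2,000 features with 50
label permutations. These sizes give Monte-Carlo standard errors small
enough for the stated tolerances while keeping a full run in seconds.

## Known limitations

* The moderated F's null reference is exact under the hierarchical
  variance model; when the true variances are identical across features the
  reference is mildly conservative (this is visible as a slightly sub-nominal
  mean FDP).
* State assignment treats the two sexes' z-scores as independent given the
  state; correlated noise between sexes would blur state posteriors.
* The similarity-network communities depend on the Louvain seed for
  near-degenerate partitions; the seed is fixed and recorded in the
  manifest.
* `run_pipeline` computes trajectories and marker tests for each tissue's
  largest path only; other clusters are available through the library API.
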