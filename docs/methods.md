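# Methods

This note documents the models, conventions and numerical choices behind
`evoconn`, in the order data flows through the pipeline.

## Connectivity construction

**Band-pass filtering.** ROI columns are filtered independently with a
2nd-order Butterworth band-pass applied forward and backward
(`scipy.signal.filtfilt`), which doubles the effective order and cancels
phase distortion. Column means are subtracted first, so constant
columns map to zero exactly. The default band is 0.01–0.1 Hz, the slow
fluctuation range conventionally analysed in resting-state studies; at
the default sampling interval of 3.0 s the Nyquist frequency is 1/6 Hz,
and bands reaching it are rejected. Series shorter than the filter's
padding requirement (15 samples for this order) raise an error rather
than returning unstable output.

**Correlation and Fisher z.** Connectivity is the Pearson correlation of
ROI column pairs; the diagonal is set to zero by convention because
self-connectivity carries no information downstream. Zero-variance
columns are reported by ROI name instead of silently producing NaNs.
The Fisher transform z = atanh(r) is applied with |r| clipped at
1 − 10⁻⁷, so perfectly correlated pairs map to a large finite value
(≈ 8.4) rather than infinity; the distortion is negligible at any |r|
encountered in practice and keeps all downstream features finite.

**Thresholding.** Two rules binarize the z matrix. *Absolute*: keep
pairs with z strictly above a cut (one-sided on signed z — a strongly
negative correlation is not an edge; ranking by |z| is available behind
a flag, off by default). *Proportional*: keep exactly
⌈d · N(N−1)/2⌉ pairs with the largest z, ties broken by (i, j)
lexicographic order so results are bit-reproducible. When the requested
density selects fewer than one pair the count still rounds up to a
single edge and a warning is emitted. Neither rule stated here is
canonical in the field; the package defaults to proportional
thresholding at d = 0.15 because it fixes the edge budget independently
of each subject's overall correlation level, and both rules are exposed.

## Graph measures

Seven node-level measures are computed per subject on one graph built
over the union of atlas ROIs and network nodes (164 nodes in the
standard configuration) from a single connectivity matrix; network-node
measures are read from that same graph rather than from
network-restricted subgraphs, keeping a single consistent topology.

Conventions for disconnected graphs keep all quantities finite without
graph-dependent imputation: the average path length from a node is the
mean over *reachable* nodes (0 for an isolated node), and efficiencies
count unreachable pairs as contributing 0 (1/∞). Betweenness divides
by the (N−1)(N−2)/2 node pairs excluding the index node, making it a
proportion in [0, 1]. Cost is defined node-wise as deg(v)/(N−1), the
natural per-ROI restriction of network density. Local efficiency of a
node is the mean inverse shortest-path distance within the subgraph
induced on its neighbours (0 for degree < 2). Betweenness is computed
with networkx's exact Brandes algorithm; the remaining measures are
vectorized over one all-pairs shortest-path computation
(`scipy.sparse.csgraph`). The test suite checks all seven measures
against an independently coded Floyd–Warshall + path-counting oracle,
exhaustively on every graph with up to 5 nodes and on random 6–8-node
graphs.

**Feature assembly.** The feature vector concatenates atlas-ROI
measures, network-node measures, and one global aggregate per measure.
The aggregate is the arithmetic mean over the 32 network nodes (a mean
over all 164 nodes is available via `global_over="all"`). With 132
ROIs, 32 network nodes and the global block this yields the
(132 + 32 + 1) × 7 = 1155 named features of the standard configuration.

## Classifier and training

The classifier is an MLP with layer sizes [k, 10, 10, 1]: tanh hidden
units, a logistic output, and 0/1 targets so the squared error of each
sample is bounded. Weights are initialized uniformly in [−0.5, 0.5]
from a seeded generator.

Training minimizes F(x) = eᵀe by Levenberg–Marquardt. The error
Jacobian J = ∂e/∂x is assembled from output sensitivities propagated
backward through the layers (computed in closed form for all samples at
once and verified against central finite differences to 10⁻⁴ relative
error). Each epoch solves (JᵀJ + μI)Δ = Jᵀe and accepts the step only
if F decreases; on acceptance μ is divided by 10, on rejection
multiplied by 10 and the step retried. Defaults follow the classical
Marquardt recipe: μ₀ = 10⁻³, μ_max = 10¹⁰, at most 100 epochs, gradient
tolerance 10⁻⁷ on ‖Jᵀe‖∞. Accepted steps never increase F, which the
tests assert on every training history. With ~231 parameters against
~126 training subjects the network interpolates its training set; the
honest performance estimate is therefore always cross-validated.

Evaluation is stratified k-fold cross-validation (10 folds by default,
so each fold is a 90/10 split; folds preserve the group proportions of
these small, near-balanced cohorts). Feature columns are standardized
with training-fold statistics only. Fold assignment, fold-level
initialization seeds and everything downstream derive from a single
seed, making every evaluation deterministic. Reported accuracy is the
fold mean; the pooled-prediction accuracy is also returned. A
single-split mode (one stratified 90/10 split, optionally repeated)
provides a cheaper fitness for search inner loops.

## Subset search

All five algorithms search subsets of fixed cardinality k, repairing
candidates back to k after variation (random drop/add of selected
bits), memoizing fitness by subset, and drawing all randomness from one
seeded generator per run. The fitness seed is fixed per run so cached
evaluations are consistent and elitism is well-defined. Best-so-far
histories are non-decreasing by construction for GA, SA, PSO and ACO.

* **GA** — population 20; Boltzmann roulette parent selection with
  pressure β = 8 on min–max-normalized fitness; 14 offspring per
  generation by crossover, the operator drawn uniformly from
  single-point, double-point and uniform on the binary mask; mutation
  applied to 30% of offspring, swapping each selected bit with
  probability 0.1; survivor truncation of parents + offspring to the
  population size. Truncation prefers *distinct* individuals (duplicates
  fill only leftover slots): without this the population collapses to
  copies of the incumbent within a few generations and recombination
  stalls, which measurably hurt recovery of planted features.
* **NSGA-II** — population 25, mutation 0.4/0.1, 14 offspring;
  objectives (maximize CV accuracy, minimize cardinality) with
  cardinality free in [1, k_max]; fast nondominated sorting, crowding
  distance, binary tournaments; returns the final first front and the
  best archived subset per cardinality.
* **ACO** — 10 ants; each samples k distinct features with probability
  ∝ τ^α η^β (α = β = 1), where the heuristic η is the per-feature
  Welch |t| between groups — the same prior information the statistical
  baseline uses; pheromone evaporates at 0.05 per iteration and the
  iteration-best ant deposits fitness/100 on its features.
* **SA** — swap neighbourhood (one selected for one unselected
  feature); improving moves always accepted, worsening moves with
  probability exp(−Δ/T); T starts at 10 and decays by 0.99 per
  iteration. At T = 0 the procedure degenerates to hill-climbing.
* **PSO** — 20 particles with continuous positions over all F features;
  inertia 0.72, cognitive and social coefficients 1.5; a particle
  decodes to the k features with the largest position values (ties to
  the lower index), a deterministic rank decoding that preserves the
  cardinality without sigmoid sampling noise.
* **t-test baseline** — Welch two-sample t per feature (scipy), subset
  = k smallest p-values, ties to the lower index; features with zero
  variance in both groups get p = 1 and rank last.

The default iteration budget is 200 (the searches on the benchmark
problems converge well before that; a 500-iteration variant is a config
change away). Accuracy-versus-k experiments derive one seed per
(algorithm, k) cell by hashing a master seed, so a whole experiment is
reproducible bit-for-bit from its configuration.

## Synthetic cohorts

The generators emulate the cohort geometry of the motivating study
design: two groups of 72 and 68 subjects by default, and time series of
140 timepoints at a 3.0 s sampling interval.

*Feature level*: all columns are Normal(0, noise_sd) in both groups;
informative columns are shifted by effect · noise_sd in group 1, so
`effect` is the standardized mean difference. *Time-series level*:
each subject is a multivariate Gaussian draw whose covariance is the
identity except for an equicorrelated ROI block (correlation ρ₀ in
group 0 and ρ₀ + Δρ in group 1); positive definiteness is checked
before sampling. Gaussian signals rather than realistic BOLD spectra
are deliberate — correlation structure is all the downstream stages
consume, and the band-pass step is still exercised. The generators do
not model hemodynamics, motion or physiological artifacts, spatial
autocorrelation, or site effects; tests passing on these cohorts
demonstrate that the machinery recovers known structure under clean
conditions, not that any accuracy level transfers to real imaging data.

Calibration checks: with effect = 0 the cross-validated accuracy over
20 seeded cohorts stays inside the exact binomial 95% interval around
50% (balanced 70/70 groups are used for this null so the majority-class
rate is exactly 50%), and the planted time-series contrast reproduces
Fisher-z sampling theory (difference within 2 SE of
atanh(ρ₀+Δρ) − atanh(ρ₀), SE ≈ (T−3)^{−1/2}).

## Benchmark protocol and problem sizes

The reference benchmark (`evoconn.benchmarks.ga_wrapper_benchmark`,
driven by `scripts/acceptance.py`) uses cohorts of 70 + 70 subjects
with 200 features, 10 informative at effect 1.5 — strongly separable as
a set (group Mahalanobis distance ≈ 4.7) while each single feature is
only moderately informative, so selection is non-trivial. The GA runs
50 generations with the operator constants above; its fitness is
10-fold CV accuracy with a shortened LM budget (20 epochs — training
has converged or stalled by then on these problems, so this changes
speed, not values), and the selected subset is re-evaluated with the
default training configuration on the same seeded folds. The reported
number is the mean over five master seeds. Reporting the wrapper's own
cross-validated accuracy follows standard wrapper-selection practice
and is optimistically biased relative to an outer, nested validation —
the ground truth lets the benchmark also report how many planted
features each run recovered (typically 2–4 of 10 at this budget).

Tests use smaller instances of the same machinery (toy subset spaces
small enough to enumerate exhaustively, graphs small enough for the
brute-force oracle) so the full suite runs in minutes on one CPU.

## Known limitations

* The search algorithms' printed constants follow one common reading of
  the standard EA templates (e.g. "crossover 14" as offspring per
  generation, Boltzmann β = 8 as selection pressure); other readings
  exist and would change trajectories, though not the interfaces.
* Graph measures are unweighted/binary only; weighted variants are out
  of scope.
* The wrapper fitness and the final report share fold assignments;
  nested cross-validation would remove the selection bias at roughly
  tenfold cost and is left to the caller (the pieces — independent
  seeds for `FitnessConfig` — are available).
* Levenberg–Marquardt stores the full Jacobian (samples × parameters);
  this is ideal at cohort scale but not for networks orders of
  magnitude larger.
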