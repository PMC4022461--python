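# Methods

This note documents the model, the synthetic cohort generator, the
numerical choices and the known limitations of `connstates`.

## Pipeline

**Consistency mask.** SC from tractography is sparse and variable across
subjects, so all statistics are computed over region pairs with streamline
count ≥ 1 in at least a fraction (default 0.8) of subjects. "Present"
means count ≥ 1; pairs exactly at the boundary are retained (the rule is
≥, not >). The mask is rejected as degenerate if any of the three focus
classes (PP, NN, PN) loses all its edges.

**Representative network.** Entrywise arithmetic mean of SC and of each
state's FC across subjects. Correlations are averaged directly by default;
a `fisher_z` option averages through arctanh instead. Whether group FC
should be averaged raw or z-transformed is genuinely open; raw averaging
is the default because it is the plain construction, and the option makes
the sensitivity checkable.

**Threshold grid.** Per state, thresholds are the empirical quantiles
0.00, 0.05, …, 0.90 of the FC (rest) or ΔFC (task) values over masked
edges. Quantile grids make states with different FC scales comparable;
the exact grid is configurable and results should be (and in tests are)
robust to it. Survival is strict (FC > φ). The 0-quantile threshold is
nudged one ulp below the minimum so the first grid point retains every
edge and reproduces the baseline exactly. Grid points leaving fewer than
`min_edges` (default 10) surviving edges are dropped; duplicated
thresholds from tied quantiles are deduplicated.

**Densities.** n_c(φ) is the fraction of structural weight (streamline
counts; or presence indicators in the unweighted variant) carried by
coupling class c among surviving edges. The baseline is the no-threshold
density over all masked edges, so Σ_c n_c = 1 at every φ and
Σ_c Δn_c = 0 identically. Masked pairs with no structural connection in a
given subject carry zero weight and therefore contribute nothing in either
variant. Internally a single descending-FC sort plus class-wise cumulative
sums give the whole sweep in O(E log E); tests verify exact agreement with
brute-force pair enumeration.

**State points and separations.** x = Δn_PN, y = Δn_PP − Δn_NN per
admissible φ; the state point is the unweighted mean over grid points
(no density weighting — a deliberate, simplest-choice average). Angular
separation between two states is the angle between their origin-anchored
state points, computed via atan2(|cross|, dot) in degrees. Points within
1e-12 of the origin make the angle undefined and raise rather than
returning an arbitrary value.

**Grouping.** argmin(θ_AM, θ_MR, θ_RA) maps to primary / secondary_RM /
secondary_RA. Exact ties are measure-zero for continuous data; they break
in that priority order with a logged warning, favoring the majority group.
The decision margin (second-smallest minus smallest angle) is reported per
subject.

**Triangle remapping.** The normalized triple (θ_RA, θ_AM, θ_MR)/Σθ and
its two cyclic permutations are mapped through barycentric coordinates of
a fixed equilateral triangle. The construction guarantees the two
properties the representation is used for: equal separations collapse to
the centroid (area 0, size encodes asymmetry), and cyclically permuting
the triple rotates but does not reshape the triangle (orientation encodes
rank order). Any embedding with these properties would serve; the
barycentric one is the simplest.

**Permutation null.** Region labels are reshuffled uniformly, preserving
class counts, with one shared relabeling per permutation for the whole
cohort (all subjects share one atlas, so per-subject permutations would
test a different hypothesis). The full density → state-point → separation
pipeline is rerun per permutation; the default statistic is the cohort
mean of (θ_RA + θ_AM + θ_MR)/3. The mask and threshold grids are
label-independent and are cached, which is what makes 99 permutations
cheap. The empirical p uses the add-one estimator
p = (1 + #{null ≥ observed}) / (1 + n_perm), so p is never 0 and is valid
at any permutation count ≥ 19. Permutations that orphan a focus class are
resampled (at most 10 retries, logged).

**Behavioral statistics.** δm is the signed deviation of a measure from
the pooled cohort mean; rel_m = m_A − m_M (a `normalize_rel` option
divides by (|m_A|+|m_M|)/2; raw is the default since no normalization is
canonical). Group comparisons are one-tailed Welch (unequal-variance)
two-sample t-tests on the magnitudes |δm| and |rel_m|, secondary (both
secondary groups pooled) > primary. Magnitudes are compared because the
hypothesis is about being an outlier, which is unsigned; Welch rather than
pooled-variance because the groups are markedly unequal in size (about
2:1) and there is no reason to assume equal variances.

## Synthetic cohort generator

The generator emulates the data structure the analysis consumes; its
defaults are the study conditions used throughout the tests.

* **Cohort**: 71 subjects, 200 regions, label fractions (P, N, O) =
  (0.3, 0.3, 0.4), archetype mixture (0.66, 0.23, 0.11).
* **Structure**: a shared backbone sampled per class-pair with probability
  0.2, weights ⌈lognormal(μ=1, σ=1)⌉ (heavy-tailed streamline counts);
  each subject keeps each backbone edge with probability 0.9 (weights
  jittered ±20% multiplicatively, floored at 1 and rounded) and gains
  spurious unit-weight edges with probability 0.01. Retention 0.9 makes
  the 80% consistency mask nontrivial: backbone edges pass it with high
  probability, spurious edges never do.
* **FC**: generated edgewise, FC_ij = base_c(state) + slope_c(state)
  · log(1+w_ij)·1[w>0] + N(0, 0.08), clipped to (−0.999, 0.999). FC is
  not simulated from time series: the pipeline consumes only the FC
  matrix, so time-series simulation would add cost without adding a
  testable property. Task states are generated directly as ΔFC, the
  quantity the pipeline thresholds.
* **Planted geometry.** No empirical effect sizes exist for the class
  enrichments, so the baselines are design choices, fixed once: at rest
  NN (0.37) > PP (0.35) ≫ PN (0.02) with other classes at 0.15 — strong
  within-network correlations, anticorrelation-like weak PN coupling; the
  attention-like deviation enriches PP and PN (0.19 each); the
  memory-like deviation enriches NN and PN; the rest-like deviation (the
  task state that secondary archetypes share with rest) enriches NN/PP
  and depletes PN. These place the three states of a primary subject at
  roughly 175°/70°/115° pairwise separations with the attention–memory
  angle clearly smallest, and give each secondary archetype a near-zero
  rest–task angle — recoverable but noisy at the subject level.
* **Behavior**: group-conditional normals. Primary is task-symmetric
  (d′ 2.0/2.0, CS 0.5/0.5, RT ≈ 0.72–0.75 s); secondary groups are RT
  outliers in opposite directions (≈ ±0.2 s) and have large
  attention-memory splits (d′ 2.6 vs 1.4, CS 0.7 vs 0.3). SDs: RT 0.08 s,
  CS 0.10, d′ 0.30. Reaction times are floored at 1 ms to keep them
  positive under extreme draws.
* A `structureless` switch equalizes all class baselines and slopes,
  removing every planted effect; it exists solely to calibrate the
  permutation null.
* **Determinism**: one spec seed feeds a `SeedSequence` whose spawned
  children drive labels, backbone and each subject, so cohorts (and the
  files `simulate` writes) are byte-reproducible.

What the generator does **not** emulate: spatial embedding and distance-
dependent connectivity, hemodynamics and autocorrelated BOLD noise,
indirect (polysynaptic) structure-function coupling, negative-tail FC
structure, and subject-level variation in the labeling itself. Passing
recovery tests therefore shows the pipeline is correct and sensitive under
the planted model, not that the scientific claims hold in new empirical
data.

## Problem sizes in tests and the acceptance script

Reduced scales were chosen to keep full runs fast while leaving each check
well-powered: density oracle on networks of ≤ 12 nodes (where brute force
is exact and cheap); quadrant recovery on a 40-subject, 200-region cohort
(noise in the representative network falls as 1/√subjects); grouping
recovery at the default 71 subjects; planted permutation null at
24 subjects × 100 regions × 99 permutations; null calibration at
8 subjects × 100 regions × 19 permutations × 50 replicates (19
permutations put the attainable p floor exactly at the 0.05 decision
threshold, giving a nominal 5% false-positive rate); behavioral power over
100 replicate 71-subject behavioral tables.

## Limitations

* Region labels are an input; mapping an atlas onto task-positive/negative
  masks is out of scope.
* No neuroimaging file formats: matrices arrive as CSV, labels as TSV.
* The grouping rule is the rank-order rule only; data-driven clustering of
  subjects is out of scope.
* The triangle embedding reproduces the qualitative properties (size ↔
  asymmetry, rotation ↔ rank order); its absolute coordinates are a
  convention, not comparable across software.
* Behavioral measures (d′, CS, RT) arrive precomputed; no signal-detection
  modeling of the underlying tasks.
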