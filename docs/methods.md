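# Methods

This note records the model, the numerical choices, the synthetic-data
generator, and default parameters, with the reasoning behind each.

## 1. Occupancy model

**Observable.** For each subject (one scan occasion per subject) the
element-wise occupancy is `Occ = 1 − BP_post / BP_baseline`. Baselines
must be strictly positive on the analysis mask; `compute_occupancy`
rejects non-positive baseline elements with a count of offenders.

**Mixture model.** Occupancy in cluster *j* at exposure `C_p` of drug
*d* is `Σ_k f_{j,k} · C_p/(C_p + K_i[d,k])`, where component sets are
declared per drug by a `ModelConfig` (the last component is never
displaceable; drug A's set must cover drug B's in size; every
displaceable component must be displaced by at least one drug). Named
structures: `M2a` (one lumped displaceable component) and `M3c` (drug A
displaces components 1–2, drug B only component 1).
`enumerate_configs()` returns the six admissible structures with
N ∈ {2,3,4} in which drug A displaces all displaceable components;
other shapes can be built directly with `ModelConfig`.

**Simplex reparameterization.** Fractions are mapped to the unit box by
cumulative ratios `v_k = (Σ_{q≤k} f_q)/(Σ_{q≤k+1} f_q)` with the
convention `v_k = 0` when the numerator and denominator both vanish;
the inverse is `f_k = Π_{q=k..N} v_q − Π_{q=k−1..N} v_q` with
`v_0 ≡ 0`, `v_N ≡ 1`. This is a bijection between the interior of the
simplex and the open unit box and maps any box point onto the simplex;
round-trip exactness (≤ 1e-12 over 3000 random points, N ∈ {2,3,4}) is
asserted in the acceptance suite.

## 2. Fitting: variable projection with an exact inner solver

The objective separates: given the global affinities, each cluster's
fraction fit is an independent simplex-constrained linear least-squares
problem `min_f ||A f − y||²`. We solve it *exactly* by enumerating all
`2^N − 1` faces of the simplex (N ≤ 4, so at most 15 KKT candidates):
on each face the equality-constrained minimizer has a closed form via a
pseudo-inverse of the reduced design, shared across all clusters, so
the solve is vectorized over clusters. The outer problem — at most four
log-affinities — is run through `scipy.optimize.least_squares` (trust
region reflective) with bounds `K_i ∈ [1e-3, 1e5]` exposure units and
within-drug ascending order enforced by a log-increment
parameterization (first parameter: log K_i of the highest-affinity
component; subsequent: non-negative log increments). This removes the
permutation ambiguity of component labels; a fit started from a
deliberately permuted point reaches the same canonical solution (unit
test).

Initialization places the affinities at geometric quantiles (0.2/0.8)
of each drug arm's exposure distribution and all fractions at the
uniform simplex point. Degenerate designs (an arm without at least two
distinct exposures for a drug with its own affinity parameters) are
rejected up front.

Confidence intervals for the affinities use the delta method on the
outer Jacobian at the optimum with `s² = SSR/(n − p)`.

**Solver validation.** The inner solver is checked against a dense
0.01-step grid search (a fully independent route). Two facts are
asserted: the exact solver's SSR never exceeds the grid optimum, and
the exact solution snapped to the grid is grid-optimal up to the a
priori quadratic snapping bound `λ_max(AᵀA)·||snap||²`. The distance
between the two argmins is reported but deliberately not used as the
equivalence criterion: near-flat SSR valleys (common when exposures
poorly separate two components) can hold two almost equally good
solutions more than one grid tick apart, which says nothing about
solver correctness.

## 3. Preprocessing

Baseline maps are optionally smoothed (Gaussian, FWHM in mm,
mask-normalized so values near the mask edge are unbiased), the
inter-subject minimum baseline is thresholded at BP_ND ≥ 0.1
(inclusive) to form the valid mask, occupancies are computed per
subject, and elements are grouped into 4×4×4-element blocks (64-fold
data reduction on a fully valid grid). Cluster occupancy is the mean
over member elements. These defaults (threshold 0.1, block 4³) match
the intended operating point of the method; both are configurable.

## 4. Model comparison and selection

Per configuration: SSR; MSE = SSR/n; least-squares AIC
`n ln(SSR/n) + 2p` with `p = (#affinities) + M·(N−1)` counting every
per-cluster free fraction; pairwise extra-sum-of-squares F-tests
between nested pairs (p-value 1 with a warning if the complex model
fits worse); percentage of fraction parameters at zero (overfit
indicator); leave-one-subject-per-arm cross-validation — all 8×4 = 32
(arm-A subject, arm-B subject) exclusion pairs for the default design —
scored as the median |f_cv − f_full| over folds, clusters and
components; and the median left–right regional asymmetry of the
component maps (overall flumazenil binding is hemispherically
symmetric, so strongly lateralized components indicate noise capture).

CV refits are *initialized* at the full-fit optimum. This is an
initialization choice only (the refit optimizes the fold's own
objective); it speeds the 32 refits up substantially and in practice
converges to the same optimum as a cold start on this smooth,
low-dimensional outer problem.

**Selection rule.** A configuration survives only if it significantly
improves (F-test, α = 0.05) on *every nested simpler* candidate; the
simplest candidate passes vacuously. Among survivors the best mean
rank across AIC, CV stability, zero-percentage and asymmetry wins,
ties breaking toward fewer components then fewer parameters. An
over-parameterized structure that wins its F-tests can still — and in
the replicated recovery experiment does — lose the rank stage on the
sanity checks. A stricter variant that also eliminated configurations
beaten by more-complex ones was evaluated and rejected: occasional
spurious F-tests (as expected at α = 0.05) then eliminated the true
structure, dropping recovery from 100% to 80% over 20 replicates.

## 5. Component maps, regions, gene correlation

Cluster fractions are projected to elements either by nearest
assignment (each element inherits its cluster's simplex exactly; used
for regional aggregation and conservation) or by trilinear
interpolation on the regular block lattice of cluster centers (hand
rolled because the lattice, clamping, missing-block fill via nearest
occupied block, and per-element renormalization back to the simplex
are all specific to this structure). Absolute maps are fraction ×
inter-subject mean baseline; in nearest mode the absolute component
maps sum to the mean baseline exactly (asserted to 1e-12).

Regional component means are correlated with *fractional* gene
expression (each gene divided by the summed expression of the
GABRA1/2/3/5 set per region; a heuristic warns if the input looks
log2-scaled). Pearson R with BH-FDR adjustment
(`statsmodels.stats.multitest`); constant vectors are flagged
undefined and excluded from the FDR family. Correlation sizes are
categorized at fixed cutoffs 0 / 0.3 / 0.5 / 0.7 / 0.9 (lack /
negligible / low / moderate / high / very high positive correlation),
inclusive at the upper bound.

## 6. Synthetic-data generator

The generator's defaults define the study conditions used throughout
testing: a mirror-symmetric Voronoi-region geometry (even-sized mirror
axis; each region present in both hemispheres with equal element
counts), smooth simplex fraction fields (softmax of mirrored smoothed
Gaussian fields, contrast 1.5), baseline BP_ND in 1–6, a 12-subject
design (8 on drug A, 4 on drug B) with log-spaced jittered exposures
over 0.1–120 (spanning roughly 0.1–10× every true affinity), true
affinities A: (1.0, 12.0) — a 12-fold within-drug separation — and
B: 1.5, additive Gaussian occupancy noise (SD 0.05), log-normal
baseline jitter (CV 23%), and gene expression linked positionally —
GABRA1→C1, GABRA2→C2, GABRA5→C3, with GABRA3 unlinked — via
multiplicative log-normal noise (noise 0 gives exact fractional
linkage). Post-drug maps are `baseline × (1 − occupancy)` so the
generative route matches the analysis observable definition exactly.

## 7. Validation experiment sizes

Chosen to finish comfortably on one CPU: parameter recovery on a 24³
grid (216 clusters of 64 elements, ~0.2 s per fit); the replicated
model-selection experiment on an 8³ grid (8 clusters, 20 replicates,
~1 min total including CV); the solver-vs-grid comparison on 20 random
small instances. Observed results: noiseless recovery exact to machine
precision; at noise SD 0.05, max affinity error ≈ 0.8% and median
fraction error ≈ 0.003; structure recovery 100%/20.

## 8. Limitations

- The inner face-enumeration solver is exponential in N and is
  intended for N ≤ 4 components (15 faces); the model family is capped
  there anyway.
- Affinity confidence intervals are asymptotic (delta method) and do
  not propagate uncertainty from the per-cluster fraction estimates.
- Trilinear projection renormalizes interpolated fractions per
  element, so linear-mode absolute maps conserve the baseline only
  approximately; nearest mode is exact and is what regional tables
  use.
- The F-test degrees of freedom count every per-cluster fraction as a
  free parameter; with many clusters the tests are effectively very
  liberal gates and the composite rank stage carries the real
  selection burden.
- One scan occasion per subject is assumed (occupancy per subject);
  repeated measures within subject are not modeled.
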