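# Methods

This note records the models, conventions and numerical choices behind
`attnet`, in the order the pipeline runs them.

## Motion quality control

Realignment traces carry six rigid-body parameters per frame: three
rotations (radians) then three translations (mm), the MCFLIRT `.par`
column order. Rotations are converted to millimetres as arc length on a
sphere of radius 50 mm (the Power convention); the radius is a parameter
of every function that uses it.

- **FD** at frame t is Σ|Δtranslation| + r·Σ|Δrotation| over the six
  parameters — length `n_frames − 1`. FD depends only on differentials,
  so it is invariant to constant offsets in any parameter, and it is
  monotone in the rotation radius.
- **Mean Motion** is the mean over frames of the Euclidean norm of the
  translation differential (the Van Dijk displacement index). The
  per-axis mean-of-absolute-differentials reading is also defensible from
  the usual verbal definitions; it is exposed as
  `mean_motion(trace, method="per_axis")` without endorsement. The norm
  was chosen because the displacement-index citation trail supports it.
- **Exclusion**: a subject is dropped when any converted parameter
  excursion exceeds 1.0 mm (strict) or Mean Motion exceeds 0.25 mm
  (strict). Excursion means max |value| of the mm-converted parameter
  relative to the realignment reference. Subjects, not frames, are
  excluded; no scrubbing is performed.
- The motion-vs-connectivity check reports Pearson (linear) and Spearman
  (rank) correlations; Spearman is the package's reading of a
  "non-linear" association check, which the convention leaves unnamed.

## Wavelet-correlation connectivity

Nuisance regression removes a per-frame confound matrix (motion
parameters, tissue signals, global signal — whatever the caller supplies)
plus an intercept from every node by least squares; residuals are exactly
orthogonal to the confound columns. Rank-deficient confound sets raise
with the collinear columns named. The 1/80 Hz high-pass of raw images is
treated as upstream preprocessing: inputs are assumed already filtered.

The MODWT is implemented as the standard pyramid recursion with circular
(periodic) boundary handling, using PyWavelets' `sym4` filter bank — the
Daubechies least-asymmetric length-8 filter customary in fMRI wavelet
work — rescaled by 1/√2 per the undecimated transform's definition. The
filter is configurable. Scale k isolates the octave
[2^(−k−1)/TR, 2^(−k)/TR]; scales {2, 3, 4} are the default, and at
TR = 2 s tile 0.015625–0.125 Hz. Note the dyadic formula assigns scale 2
the *highest* of the three octaves; band listings elsewhere sometimes
pair the labels in the opposite order, but the union band is the same
either way and the formula is taken as authoritative.

Detail series keep the input length (any length ≥ 2^(k+1) is accepted)
and are circularly advanced by the LA-filter phase shift
L_j/2 − 1, L_j = (2^j − 1)(L − 1) + 1, so that coefficients across scales
line up in time before the pointwise mean is taken. Boundary-affected
coefficients are retained. Connectivity entry (i, j) is |Pearson r|
between the scale-averaged series of nodes i and j; the matrix is
symmetric with NaN diagonal, and any zero-variance averaged series marks
its pairs undefined rather than guessing.

Because every node passes through the same linear filter, the population
cross-correlation structure of a multivariate time series survives the
transform — which is what lets the synthetic generator's planted effects
propagate to the connectivity stage with known ground truth.

## Binary graphs and topology metrics

`threshold_at_cost` keeps the K = round(c·N(N−1)/2) strongest entries
(round half away from zero; the handling of fractional K is a package
choice). Ties break by lexicographic node order, which makes edge sets
nest as cost grows. NaN entries ranked into the top K raise.

Efficiencies use the Latora–Marchiori conventions: disconnected pairs
contribute 0 (the 1/∞ limit), neighbour subgraphs with fewer than two
nodes contribute 0 to local efficiency. Distances come from BFS
(`scipy.sparse.csgraph`); betweenness is Brandes' algorithm (networkx)
normalized by (N−1)(N−2)/2 with endpoints excluded, matching the
"proportion of shortest paths" definition. All metrics are cross-checked
in the test suite against pure-Python brute-force oracles (all-pairs BFS;
explicit shortest-path enumeration for betweenness) on every labeled
graph with N ≤ 5, the full non-isomorphic atlas at N = 6, and 500 random
graphs with N ≤ 12, at 1e−10.

Null models: the random null rewires by degree-preserving double edge
swaps (target 10·K successful swaps, seeded; constrained graphs simply
randomize less), so the degree sequence is preserved exactly. The
regular null is a ring lattice with the same N and K — neighbour offsets
fill outward and leftover edges go to the lowest-index nodes
deterministically. A cost passes the small-world test when both strict
inequalities hold against the null values, the random side being an
ensemble mean (default 20 rewirings per cost; benchmark runs in the test
suite use 10 with a 0.05–0.50 step-0.05 grid to keep runtimes sensible).
The regime is the longest contiguous run of passing costs.

Two standing grid conventions: global-metric curves default to
0.10–0.50 step 0.01, hub and nodal averaging to 0.05–0.30 step 0.01.
Both are configurable, and group curve comparisons accept any grid.

Benchmark-graph behaviour worth knowing: pushing a *lattice-derived*
connectivity through a full cost grid adds random edges above the
lattice's native cost, which genuinely produces small-world graphs (a
lattice plus shortcuts is the Watts–Strogatz construction). The
per-graph statement "a ring lattice is not small-world" therefore holds
at the graph's own cost, where it coincides with its regular null and
the strict inequality fails; the benchmark tests evaluate it there.

The truncated power law P(k) ∝ k^(α−1) e^(−k/k_c) is fitted by maximum
likelihood with the distribution normalized over integer k ∈ [1, k_max]
(k_max defaults to the observed maximum; pass N−1 to normalize over the
graph-theoretic support). Optimization is Nelder–Mead on (α, log k_c)
from (1.5, log mean(k)); non-convergence and degenerate inputs
(zero-variance degrees) are flagged in the result, never raised. A
least-squares fit to the empirical log-CCDF, restricted to bins holding
at least five observations, is provided as an independent cross-check of
the MLE.

## Hub detection

Hub metrics (degree, betweenness) are averaged over the hub cost grid,
z-scored across nodes using the sample SD (n−1), and tested one-sided:
p = 1 − Φ(z), hub iff p < 0.05 strictly. Zero dispersion across nodes
yields no hubs with a degeneracy flag. By construction the expected hub
fraction under exchangeable node metrics is ~5%, which the test suite
verifies by simulation. Group-level hub tables are computed on the
group-mean connectivity matrix by default (one matrix per group); the
same functions accept per-subject matrices for vulnerability-style
analyses. Hub tables report degree-hubs, betweenness-hubs, and their
union and intersection.

## Network-based statistic

Edge-wise statistics are pooled-variance two-sample t values on the |r|
entries, df = n_a + n_b − 2 (the NBS-toolbox convention; the primary
threshold default of 3.5 corresponds to uncorrected p < 0.01 at the
44-subject design size). Zero pooled variance marks an edge undefined.
Components are maximal connected subgraphs of suprathreshold edges in a
single direction; the default contrast is one-directional (group A >
group B, i.e. reduced connectivity in patients), and the opposite
direction is a separate run. Extent is the edge count; node count is an
option since "component size" admits both readings.

Permutations relabel subjects while preserving group sizes, with no
exchangeability blocks. The FWE p of an observed component of extent k is
the plain proportion of permutations whose maximal extent is ≥ k; the
(b+1)/(m+1) variant is available as `add_one=True`. With n_perm below 20
the 0.05 level is unresolvable and the result carries a warning.
`n_perm="all"` enumerates every distinct group assignment, making the
p-values exact — feasible for small cohorts and used to validate the
sampled mode. The permutation core computes all group sums and sums of
squares by batched matrix products, so 10,000 permutations on a 68-node,
44-subject cohort take seconds.

Covariates are not included in the edge model (the ANCOVA covariates
apply to topology metrics only); whether to adjust edges is left to the
caller via prior residualization.

## Group inference

The group effect on any metric is the partial F for the group term in
the OLS model `metric ~ group + age + IQ + sex`, sex as a fixed-effect
indicator; fitting is statsmodels OLS with an explicit nested-model RSS
comparison, and the reported denominator df is the honest residual df of
the fitted model (39 for a 44-subject cohort with the three covariates;
a printed df of 35 in comparable published designs implies unstated extra
terms or exclusions and is not reproduced). Collinear designs raise with
the offending terms named. Degenerate covariate sets reduce exactly to
the two-sample comparison (F = t²), which the tests verify.

FDR control is Benjamini–Hochberg at α = 0.05 via statsmodels, with
families kept within each analysis: across nodes for nodal tests, across
costs for efficiency curves, across nodes within each score for the
clinical regressions. Clinical regressions are per-node simple least
squares of nodal efficiency on a DSM T-score in the patient group; the
slope is in efficiency units per T-score point and the model F equals
the squared slope t.

Demographic-table utilities (two-sample t, chi-square for sex) are
provided for cohort description only.

## Synthetic cohorts

The generator emulates a two-group block-design attention study: 22
subjects per group, 68 nodes, 150 frames at TR = 2 s. Subject signals
are draws from a zero-mean multivariate normal whose correlation matrix
is the *base network*: six interleaved modules (module = node index mod
6) with within-module correlation 0.55, between-module 0.15, jitter
SD 0.02, repaired to the nearest correlation matrix if needed. The
planted component defaults to a 7-edge chain over nodes 0–7; since
consecutive nodes sit in different modules, the chain crosses module
boundaries, and its base correlation is set to 0.35 so that multiplying
it by (1 − effect_size) keeps both group covariances positive definite
over the whole effect range (a planted effect inside a strongly
correlated module drives the matrix indefinite — the generator detects
and reports that instead of silently repairing it, because repair would
leak the group difference onto unplanted edges).

Independent AR(1) noise (coefficient 0.3, innovation SD 0.4 in latent
units) is added per node, attenuating observed correlations uniformly by
a known factor without moving group differences off the planted edges.
An optional boxcar mean term (30 s on/off) exists for realism and is off
by default: connectivity, not activation, is the analysis target.
Covariates are drawn per group to match a typical cohort of this design
(age ≈ 12 ± 2.5 y, IQ ≈ 115/107 ± 15, DSM T-scores ≈ 45/75 ± 7); DSM
scores are independent of the planted effect unless
`scores_track_effect=True`. Everything is a pure function of the spec's
seed.

Planted effect sizes are free parameters of the simulation — no
published effect-size estimates exist for the emulated design — so the
power figures quoted by the test suite (e.g. ≥ 80% recovery of ≥ 5/7
planted edges at effect 0.8) characterize the method under these
synthetic conditions, not any real cohort.

What the generator does *not* model: haemodynamic response shapes,
scanner drift and physiological noise spectra, spatial autocorrelation
between ROIs, motion-BOLD coupling, or realistic inter-subject
variability in network structure. Passing tests therefore demonstrate
correctness and calibration of the *algorithms*, not sensitivity under
real acquisition noise.

Motion fixtures are integrated-random-walk drift (rotations drifting 50×
less than translations) plus sparse translation spikes. Benchmark graphs
come from networkx generators (ring lattice, G(n, m), Watts–Strogatz)
plus a degree-matched rewiring of the lattice; `connectivity_from_graph`
embeds any binary graph in a pseudo-connectivity matrix (edges uniform
in (0.5, 1), non-edges in (0, 0.5)) whose thresholding at the graph's
own cost reproduces it exactly.

## Pipeline and determinism

`run_pipeline` chains QC → connectivity → group-mean matrices →
small-world regimes → hubs → NBS → ANCOVA/FDR/clinical regressions,
writing TSV artifacts per stage and one consolidated JSON report. Every
stage derives its seed from the config seed by hashing the stage name,
so reruns are byte-identical and stages are independently reproducible;
the report and artifacts embed the config hash. Stage failures halt with
stage-tagged errors; QC-excluded subjects are logged and dropped,
mirroring cohort attrition. All tabular I/O is TSV with headers; motion
files use the 6-column realignment dialect.

## Problem sizes in the validation suite

The statistical acceptance checks run at: 500 no-effect cohorts with 200
permutations each for the NBS type-I rate; 50 planted-effect replicates
with 500 permutations for recovery; 1000 simulations each for ANCOVA and
regression calibration; 3000 draws for the hub false-positive rate;
n = 5000 samples for power-law recovery; and a 10-instance ensemble for
the matched-random small-world benchmark. These sizes were chosen so the
binomial error of each estimated rate is small against its acceptance
band while the whole suite stays interactive.

## Known limitations

- MODWT phase alignment uses the LA-family shift formula; for other
  filter families the cross-scale alignment is approximate. This affects
  the scale-averaged series slightly but not any single-scale analysis.
- The regular (ring-lattice) null is deterministic; its leftover-edge
  placement gives the first nodes one extra degree when K is not a
  multiple of N.
- Exhaustive NBS enumeration grows as C(n_a+n_b, n_a) and is only
  practical for toy cohorts.
- `fit_truncated_power_law` fits the *shape* parameters by discrete MLE;
  it does not select k_min or compare against alternative families.
- The ANCOVA assumes homoscedastic Gaussian residuals; no robust or
  permutation variant is provided for the metric-level tests.
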