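# Methods

`strucnet` re-implements, as a tested and reusable pipeline, the analysis
chain used in white-matter structural-network studies of dementia: streamline
tractography summarized into region-by-region fiber-count connectomes,
binary-graph small-world metrics normalized against degree-preserving random
networks, the network-based statistic (NBS) for edge-level group inference,
and covariate-adjusted group comparison of global and nodal metrics with FDR
correction and ROC/AUC discrimination. Because subject-level diffusion data
of such studies are generally not deposited, the pipeline is driven by a
synthetic-cohort generator with planted, recoverable group effects; every
stage is therefore testable end-to-end without any download.

## Connectome construction

The toy tracker implements the FACT rule on a voxel grid: from each seed it
steps (default 0.5 voxel) bidirectionally along the principal diffusion
direction of the *containing* voxel (nearest-voxel lookup, no
interpolation), choosing the direction's sign to minimize turning, and
terminates a half-track when the next voxel's fractional anisotropy falls
below 0.2, the turn between successive steps exceeds 45 degrees, the track
leaves the grid, or 2000 steps are reached. Tracking is fully deterministic.
Streamlines are assigned to regions by their two *endpoints* (the dominant
convention for count connectomes, and the easiest to verify independently);
streamlines ending in background or within a single region are discarded.

An edge of the binary network exists where the streamline count is
**strictly greater than 3** — a count of exactly 3 is not an edge, 4 is the
minimum. This off-by-one matters: it silently changes every downstream
metric, so the threshold is echoed into every output file.

## Graph metrics

All metrics are computed on the binary adjacency (the edge rule that defines
the network is binary; a weighted variant is out of scope):

- characteristic path length `Lp`: mean hop distance over reachable ordered
  pairs; global efficiency `Eg`: mean inverse distance with 1/inf = 0;
- local efficiency `Eloc`: mean over nodes of the neighbor subgraph's global
  efficiency; clustering `Cp`: mean of 2T_i / k_i(k_i - 1);
- betweenness `BC(v)`: unnormalized Brandes sums of shortest-path fractions
  (on this scale 90-node hubs land in the hundreds, matching how nodal
  values are usually tabulated);
- `gamma = Cp / <Cp_null>`, `lambda = Lp / <Lp_null>`, `sigma =
  gamma/lambda` (exact identity), against 100 degree-preserving nulls by
  default. Because the clustering ratio is rarely written out in applied
  papers, `gamma` is defined symmetrically with the path-length ratio.

Disconnected graphs are handled with the reachable-pairs convention (`Lp`
and `BC` average over reachable pairs; results carry a `connected=False`
flag) so that occasional noise-disconnected subjects do not abort a run.

Null networks use Maslov–Sneppen double-edge swaps with a budget of 10x|E|
swap *attempts*; connectivity is checked once per null and the whole null is
redrawn (bounded restarts) if it disconnected. This is faster and more
robust than per-swap connectivity checking and cannot loop forever on
swap-free graphs (a triangle returns unchanged with a warning); neither
construction samples exactly uniformly from connected degree-matched graphs,
and the ensemble is used only to center `Cp` and `Lp`. Shortest paths are
delegated to `scipy.sparse.csgraph`, betweenness to `networkx` (Brandes);
the test suite re-derives both by matrix-power enumeration on small graphs.

## Network-based statistic

At every edge present (count > 3) in at least 50 % of subjects
(configurable), an OLS model `edge ~ intercept + group + age + sex +
education` yields the group-coefficient t statistic. Edges beyond a primary
threshold in the requested tail (`decrease`, `increase`, or two-sided
`both`) form a suprathreshold graph whose connected components are the
candidate effects; the family-wise p-value of a component of size `s` (edge
count) is `(1 + #{null max size >= s}) / (1 + n_perm)` under permutation.

Covariates are handled with the Freedman–Lane scheme: residuals of the
reduced (covariate-only) model are permuted and the reduced fit added back,
preserving exchangeability under the null with nuisance terms present. The
statistic runs on the count matrices by default (more informative); a
binary-adjacency mode exists for sensitivity analysis. One call tests one
tail; decreased and increased connectivity are reported as two runs,
mirroring how such results are tabulated.

The primary threshold (default t = 3.0) is a genuine tuning knob and is
echoed into all outputs. A calibration caveat discovered while validating:
with ~280 candidate edges and t = 3.0, the max-component-size null is
supported on {0, 1, 2, 3} and the add-one permutation test, while valid,
is extremely conservative (empirical size ~0.003 at nominal 0.05). The
type-I-error acceptance experiment therefore calibrates at threshold 1.5,
where the statistic is granular enough for the test to be near-exact
(empirical size 0.07 at alpha 0.05 over 200 null cohorts); error control
holds at every threshold.

## Group comparison, FDR, ROC

Each metric is compared between groups by the t statistic of the group
coefficient in `metric ~ intercept + group + age + sex + education`; with no
covariates this is algebraically the classical pooled two-sample t. The 90
nodal betweenness tests of one contrast form one Benjamini–Hochberg family;
the handful of global metrics form their own. The usual reporting rule
"p < 0.001, FDR-corrected" is ambiguous between thresholding raw and
adjusted p; both flags are computed and the adjusted reading is the default.
Zero-residual-variance responses (e.g. a node with identically zero BC) are
defined to carry no evidence (t = 0, p = 1) unless the group coefficient
itself is nonzero (perfect separation).

ROC discrimination uses the midrank Mann–Whitney AUC (ties count 1/2) with
curve points from `scikit-learn`; single-sample AUCs are reported oriented
(>= 0.5, direction flagged), matching the convention of reporting
discriminative AUCs. The closed form `AUC = Phi(|mu1 - mu2| / sqrt(sd1^2 +
sd2^2))` for binormal scores serves as the analytic reference. The
moment-resampling experiment (`auc_recovery_experiment`) draws normal
samples at published group means/SDs and sizes and averages the
*directional* AUC over replicates — the directional estimator is unbiased
for P(X > Y) + P(X = Y)/2, so it converges to the binormal value (and to
0.5 under equal moments, where the oriented estimator would be biased up).

## Synthetic cohort generator

What it emulates: a three-group study (31 AD-like, 19 SIVD-like, 17
controls) of 90-node streamline-count connectomes with nuisance covariates.

- **Template.** One shared "healthy" count matrix: 6 equal modules
  (labelled frontal, prefrontal, temporal, occipital, subcortical, parietal
  — generative block assignments, *not* real AAL anatomy), edges present
  with probability 0.4 within and 0.015 between modules, counts
  negative-binomial with mean 30 and dispersion k = 2 (variance m + m^2/k,
  the heavy-tailed regime of empirical streamline counts). These values were
  fixed once so that the binary template is connected, has density ~0.07 and
  mean degree ~6, and is robustly small-world (sigma ~ 3–4 per subject) —
  qualitatively the regime reported for control structural connectomes. The
  template is redrawn (bounded budget) until its binary form is connected.
- **Covariates.** Age and education normal at the published group moments
  (e.g. AD age 72.19 +/- 8.90, SIVD 79.10 +/- 7.07, NC 68.06 +/- 8.33 years),
  truncated to [40, 100] and >= 0 respectively (bounds chosen to exclude
  impossible values); sex Bernoulli at the published F/M ratios (17/14,
  9/10, 11/6), encoded F = 1 in design matrices.
- **Pathology.** Multiplicative block effects on counts: the AD-like profile
  attenuates temporal/occipital blocks (x0.5) and inflates the
  frontal-prefrontal block (x1.5); the SIVD-like profile attenuates all
  blocks among frontal, prefrontal, and subcortical (x0.35) — geometry
  following the reported group differences, magnitudes the generator's own
  choice of a clearly detectable planted effect.
- **Noise.** Per-subject lognormal multiplicative noise (sigma = 0.25) on
  every count, rounded once to integers; symmetry and the zero diagonal are
  preserved by construction. With all factors at 1 the groups are i.i.d.
  from the same generator, which the type-I-error experiments rely on.
- **Determinism.** One master seed feeds a `SeedSequence`; template,
  covariates, and each subject's noise use spawned substreams, so a spec
  reproduces its cohort bit-for-bit down to serialized TSV bytes.

What it does **not** emulate: spatially realistic anatomy or geometry
(modules are index blocks), scanner/tractography biases (distance-dependent
false positives, gyral bias), realistic degree distributions beyond what
modular Bernoulli + heavy-tailed counts produce, correlated
covariate-connectivity structure, or longitudinal effects. Passing recovery
tests therefore show the *inference machinery* is correct and calibrated on
data with the stated moments and planted effects — not that the pipeline
would reproduce any particular clinical finding from real scans.

### Localized nodal knockouts

Attenuating a hub's incident edges necessarily re-routes shortest paths and
measurably shifts many other nodes' betweenness; with a shared template
those knock-on effects are real and resolvable, so no "reduce this node's
edges" construction has ground truth localized to the chosen nodes. For
nodal recovery experiments the generator instead provides a knockout by
transposition (`hub_knockout_profiles`): spare low-degree nodes are zeroed
in *both* groups and the affected group swaps each target with a spare. The
two group graphs are then isomorphic via the transpositions, so every
non-planted node's betweenness is exchangeable between groups and the
planted ground truth is exact: targets decrease, spares increase. Detection
is counted as "significant with t in the planted (decrease) direction".

## Problem sizes used by the validation suite

Chosen as comfortable desk-scale defaults: metric oracles on 200 random
graphs with n <= 8 (exact agreement); small-world self-consistency on a
40-node null draw with 100 nulls; NBS type-I error over 200 exchangeable
15+15 cohorts at 500 permutations; NBS power over 50 replicates of a
12-edge x0.3 planted component at 20+20; nodal recovery over 20 knockout
replicates at 20+20; AUC recovery over 1000 normal resamples per target;
and a byte-identity check of two demo pipeline runs (8+8+8 subjects, 20
nulls, 200 permutations).

## Known limitations

- Metrics are binary-only; weighted/count-based variants are not provided.
- The rewiring ensemble is not an exactly uniform sample of connected
  degree-matched graphs (true of all practical swap-based samplers).
- The permutation max-component-size test is conservative when the
  suprathreshold graph is very sparse (see calibration caveat above).
- The tracker is a didactic FACT implementation on synthetic fields — no
  tensor fitting, registration, or real DWI preprocessing.
- AAL-style region names are display metadata only; no atlas is shipped.
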