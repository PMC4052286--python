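# Methods

## Model and estimation

`pathsem` fits observed-variable path models: every variable is a measured
gene (or a principal-component composite of genes), there is no latent
measurement layer. The structural system is Y = ν + B Y + U with
Cov(U) = Ψ; B has a zero diagonal and one free entry per module edge, Ψ a
free diagonal and off-diagonal entries only where a bi-directed edge
(correlated errors, a hidden common cause) has been added by refinement.
All observed variables are assumed jointly Gaussian; estimation is
maximum likelihood on the covariance structure
Σ(θ) = (I − B)⁻¹ Ψ (I − B)⁻ᵀ.

The optimizer is L-BFGS-B on the free parameters with analytic gradients;
error variances are parameterized on the log scale so Ψ's diagonal stays
positive without constraints. Starting values are per-equation OLS
regressions of each variable on its model parents, which are already the
exact MLE for recursive models with diagonal Ψ — in those (common) cases
the optimizer only verifies stationarity, which is why saturated models
reach χ² and SRMR below 1e−6. Optimization failures trigger up to
`restarts` jittered re-starts under a fixed seed before an error carrying
the best-found state is raised. Sample covariances use the ML divisor n;
incomplete samples are removed listwise with a logged count.

### Fit indices and conventions

* χ² = m·F at the optimum, with m = N by default (`chisq_n_convention`);
  m = N−1 is available. The total-N default is the convention that
  reproduces published RMSEA values recomputed from printed χ², df and N
  (e.g. χ² = 339.410, df = 105, N = 27 → 0.288).
* RMSEA = √max(0, (χ² − d)/(d·m)), same convention switch. The close-fit
  probability uses the noncentral χ²(λ, d) with λ = (n−1)·d·ε², ε = 0.05
  by default; ε = 0 degenerates to the central exact-fit tail.
* SRMR follows the standard form including diagonal residuals, with
  denominator p(p+1)/2. (A common display of the formula sums only the
  off-diagonal terms while keeping the p(p+1)/2 denominator; we implement
  the internally consistent version.)
* Standard errors come from the observed information — a central
  finite-difference Hessian of the analytic gradient at the optimum —
  with a delta-method transform back to the natural scale for variances.
  A singular information matrix raises an "empirically under-identified"
  error rather than returning garbage.
* Modification indices are univariate score (Lagrange-multiplier)
  statistics computed with the expected (Fisher) information, which is
  analytic in dΣ/dθ: MI_j = U_j² [I⁻¹]_jj for the candidate's score U_j
  partialled against all free parameters. The expected parameter change
  (EPC) is U_j divided by the same Schur complement. Ties — including the
  exactly score-equivalent β(i←j)/β(j←i)/ψ(i,j) triples that arise from a
  single residual covariance — resolve deterministically: path
  coefficients before covariances, then lexicographically by target and
  source.

## Identifiability

Initial models must be *bow-free* (no pair with both a free directed edge
and a free error covariance) and *block-recursive* (strongly connected
components of the directed part limited to two variables, i.e. feedback
only in reciprocal pairs), and must satisfy t ≤ p(p+1)/2. The same guard
runs before every refinement step; a candidate that would break it is
rejected and blacklisted. These are sufficient structural conditions, not
empirical ones — a structurally identified model can still be empirically
under-identified on degenerate data, which surfaces through the singular-
information error above.

## Module extraction and composites

Shortest paths are computed on the directed pathway graph (minimum hop
count); both orientations of every DEG pair are attempted because directed
reachability is asymmetric, and unreachable pairs are recorded, not fatal.
Among equally short paths the lexicographically smallest node sequence is
kept, making extraction reproducible across platforms. The fused module
keeps each node and edge once, inherits interaction types, drops
self-loops and preserves cycles.

Superfamily composites are PCA-based: members are standardized
(correlation-matrix PCA, so the ≥50% acceptance rule is scale-free; a
covariance option exists), the first principal axis is normalized with its
largest-magnitude loading positive, and per-sample PC1 scores become the
composite's data. Families whose PC1 explains less than half the variance
stay as individual genes. Collapsing re-targets edges onto composites,
drops merge-created self-loops and keeps the lexicographically first
interaction type among merged duplicates.

## Refinement

The stepwise loop: compute MIs for all fixed parameters, take the largest
*admissible* candidate, free it, refit, and keep it only if its one-sided
z exceeds 1.64; rejected or non-convergent candidates are blacklisted
permanently. Admissibility is evidential: an error covariance needs an
interaction-database (STRING-style) pair; a path coefficient may instead
be supported by a directed route between the two genes in the original
pathway (database evidence takes precedence in the provenance label).
Group-indicator parameters are never candidates. The loop stops as soon
as the model is adequate — exact-fit P > 0.05, or close-fit P > 0.05, or
SRMR < 0.10 — or when no admissible candidate remains, or at a step cap
(default 50). Because the candidate set is finite and blacklisting is
permanent, termination is guaranteed; the log replays to the final model
exactly.

A practical consequence of the disjunctive stopping rule worth knowing:
a single omitted edge in a larger module often leaves SRMR just below
0.10, in which case the loop (correctly) never engages. Refinement
matters for grossly incomplete initial models, which is exactly the
regime pathway-derived skeletons live in.

Pipeline-level fits (initial fit and refinement) use the pooled
within-group covariance Σ_g n_g S_g / n so that group mean differences do
not masquerade as covariance misfit.

## Two-group analysis

Both groups are fitted jointly with a saturated mean structure
(intercepts ν, implied means (I − B)⁻¹ν). Equality constraints implement
the omnibus tests: the mean test compares shared-ν to free-ν fits, both
under a shared covariance structure (df = p); the covariance test compares
shared-(B, Ψ) to free fits with means free (df = t). The local screens use
the unconstrained fit:

* t_C: difference of structural intercepts (experimental − control),
  the conditional mean difference given the gene's parents, equivalent to
  the group-indicator path under 1/0 coding. Variables are centered at the
  pooled per-variable mean first; every contrast is invariant to that
  shift, but without it intercept contrasts absorb (B̂₁ − B̂₂)·ȳ noise
  proportional to the raw expression level. When slopes truly differ
  between groups, the conditional difference of the target gene is
  evaluated at the average operating point — a real effect, reported as
  such.
* t_D: d_ij = b_ij(1) − b_ij(2) with the SE of the contrast taken from
  the joint parameter covariance (groups are independent, so this reduces
  to √(SE₁² + SE₂²) when nothing is shared).
* t₁/t₂: per-group one-sided tests of b_ij = 0 in the direction of the
  annotated interaction sign (activation/phosphorylation positive,
  inhibition negative, otherwise the sign of the pooled estimate); ON
  means one-sided p < α.

P-values are asymptotic normal by default; a nonparametric bootstrap
(resampling within groups, percentile-based two-sided p) is switchable,
with B = 1000 default replicates. Benjamini–Hochberg adjustment is
available but off by default, matching the convention of reporting raw
screen p-values.

## Synthetic scenarios

The generator emulates exactly the statistical structure the estimator
assumes: Gaussian linear-system data per group. The default scenario is a
12-gene causal chain (alternating activation +0.6 / inhibition −0.5, unit
error variances, baseline expression level 8 on a log₂-like scale) wrapped
in a pathway with 4 decoy nodes (dead ends and upstream sources that never
lie on DEG geodesics). Two superfamilies of two adjacent connector genes
are emitted as noisy indicators (member = composite + 0.5 SD noise, so PC1
explains ≈90%). Group 1 receives intercept shifts of δμ = 1 residual SD on
two interior DEGs and an edge difference δβ = 0.5 on the last all-gene
chain edge; an optional hidden edge (present in both groups' truth and in
the evidence pairs, absent from the pathway) exercises refinement.
n = 150 samples per group by default — large enough that recovery studies
measure correctness rather than power.

What the generator does *not* emulate: heavy-tailed or count-scale
expression, measurement batch effects, unmodeled confounding, feedback
loops, or pathway graphs with realistic degree distributions. Passing
recovery tests therefore demonstrates that the machinery is correct under
its own assumptions, not that those assumptions hold for any particular
microarray or RNA-seq dataset.

## Problem sizes used in the test suite

Chosen as the package's standing study conditions: type-I calibration of
the single-group LRT uses a 5-variable chain at n = 200 over 500
replicates; omnibus calibration and screen-uniformity use a 4-variable
chain at n = 100 per group over 500 replicates; parameter recovery uses
n = 5000; planted-edge refinement recovery uses a 5-variable chain with an
omitted β = 0.8 edge at n = 300 over 100 seeds (at that strength the
initial model's population SRMR ≈ 0.15, safely past the adequacy stop, so
the loop engages in essentially every replicate); the end-to-end pipeline
checks run the default 12-gene scenario.

## Known limitations

* Mean structures are always saturated per group; structured mean models
  (e.g. regressions of means on covariates) are out of scope.
* Exactly two groups; no covariate adjustment.
* The bootstrap p-value for screens is percentile-based and approximate.
* The block-recursive check bounds feedback blocks at two equations;
  larger cyclic blocks are rejected rather than estimated.
* MI uses expected information while SEs use observed information; the
  two agree asymptotically but can differ visibly at very small n.
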