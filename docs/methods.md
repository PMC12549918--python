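# Methods

This note records the statistical model, the numerical conventions and
the scope of the synthetic generator, in the package's own words. It
makes no empirical claims beyond what the test suite and
`scripts/acceptance.py` compute.

## 1. Data model

A cohort is a table with one row per participant: a `group` label, the
covariates `age`, `sex`, `education`, and one column per cognitive
measure. Each measure carries metadata: cognitive `domain`,
`orientation` (`higher_better` / `higher_worse`), `scale_type`
(`continuous` / `discrete_bounded`) and optional `instrument`.

## 2. Preprocessing

Applied in a fixed order; every step returns a report of what it did.

1. **Orientation.** `higher_worse` measures are negated and their
   metadata flipped, so a second application is a no-op.
2. **Missingness filter.** Measures with a missing fraction *strictly
   greater* than 0.15 are excluded (exactly 15% is retained); remaining
   rows are reduced to complete cases.
3. **Skew reduction.** Measures with |Fisher–Pearson skew| > 1 get
   `log1p(x − min(x))` (right skew) or the reflected version (left
   skew). These maps are strictly monotone, so Spearman correlations —
   and everything downstream — are unchanged; the step exists so that
   means, z-scores and composites are not dominated by tails.
4. **Residualization.** Each measure is regressed on age, sex and
   education, pooled across groups (per-group fits would remove part of
   the group effect itself). Ordinary least squares via `statsmodels`
   for continuous measures; logistic regression (residual = observed −
   fitted probability) for `discrete_bounded` measures taking ≤ 2
   values. Requires ≥ 10 rows and non-constant covariates.
5. **Reference z-scoring.** Residuals are standardized by the mean and
   SD (ddof = 1) of the reference group.
6. **Domain composites.** Mean of a domain's member z-scores (a
   descriptive output; connectome nodes remain individual measures).

## 3. Connectome construction

Per group, the connectome is the pairwise Spearman matrix (average
ranks for ties, then Pearson on ranks) of the preprocessed measures,
with the diagonal set to 0. Requires ≥ 3 rows, no missing values and no
constant measure.

**Binarization.** At density *d* with *n* nodes, keep
`k = floor(d·n(n−1)/2 + 0.5)` edges (round half up; n = 24, d = 0.20
gives 55 of 276). Edges are ranked by *signed* weight descending —
strong negative correlations are the weakest candidates — with ties
broken lexicographically by node-pair index: the condensed
upper-triangle vector is in lexicographic pair order, and a stable sort
on the negated weights preserves it. This makes binarization fully
deterministic and invariant to any strictly increasing transform of the
weights. Edge sets are nested across densities.

**Density grid.** Default 10–30% in 1% steps (21 densities; median
20%). `select_density_range` can choose the range from the reference
connectome instead: the lower bound is the smallest candidate density
at which no node is isolated, the upper bound the largest at which the
graph is still small-world (σ > 1). One documented consequence of the
lexicographic tie-break: on a fully tied matrix with n = 24, edges fill
in pair order and every node is first touched once 23 edges fit, so the
deterministic lower bound on the 5–50% candidate grid is 9%, not the
first grid density.

**Fragmenting nodes.** Measures with degree 0 at the top of the density
range barely correlate with the rest of the battery; they are reported
so the caller can drop them and rebuild.

## 4. Graph measures

On the weighted matrix: nodal strength (signed row sums) and average
strength. On each binary graph:

- **Global efficiency**: mean of 1/d(i,j) over ordered pairs, with
  unreachable pairs contributing 0.
- **Transitivity**: 3 × triangles / connected triples
  (= 6·Σtriangles / Σ k(k−1) over nodes).
- **Local efficiency** of node *i*: global efficiency of the subgraph
  induced by *i*'s neighbours (0 for degree < 2).
- **Characteristic path length**: mean shortest path over reachable
  pairs.
- **Participation coefficient**: 1 − Σ_s (k_is / k_i)² over a-priori
  cognitive-domain communities (0 for isolated nodes).
- **Small-worldness** σ = (C/C_rand)/(L/L_rand), with C = transitivity
  and L = characteristic path length, against degree-preserving
  Maslov–Sneppen rewired graphs (10 attempted swaps per edge, seeded;
  default 100 null graphs).

Shortest paths use breadth-first search. All binary-graph kernels are
`numba`-compiled and are verified in the test suite against naive
brute-force oracles (Floyd–Warshall, triangle enumeration, direct
formulas) to 1e-12 on random graphs, and against `networkx`.

## 5. Group comparison

Permutation framework: pool the two groups' rows, repeatedly re-split
preserving the group sizes, and rebuild both connectomes per
pseudo-split. Defaults: 1000 permutations, α = 0.05.

- **Average strength**: one two-tailed test with add-one p-value
  `p = (1 + #{|null| ≥ |observed|}) / (n_perm + 1)`.
- **Global binary measures** (global efficiency, transitivity, local
  efficiency): at each grid density the observed group difference is
  compared to the 2.5–97.5 percentile null envelope; the difference is
  *significant* only when it lies outside the envelope at ≥ 5
  consecutive densities. The consecutive rule trades single-density
  power for family-wise control across the 21 correlated densities;
  the acceptance tests verify that its family-wise false-positive rate
  is strictly below that of flagging any single density, while the
  per-density outside rate stays near the nominal 5%.
- **Nodal measures** (strength, participation, nodal global and local
  efficiency): tested at the median density with add-one p-values and
  Benjamini–Hochberg FDR across nodes (one family per measure per
  density, via `statsmodels`); decisions are additionally checked for
  consistency at the two adjacent densities.

**Stability.** `leave_k_out` repeats the comparison after removing k
random participants per group (default k = 5, 5 iterations, seeds fanned
out from one `SeedSequence`); a finding *replicates* when every
iteration reproduces the same significance flag and, when significant,
the same direction. `size_matched_subsample` re-runs the comparison
with the larger group subsampled (without replacement) to the smaller
group's size. With k = 0 the primary analysis is reproduced exactly.

## 6. Synthetic cohort generator

Each participant's score on measure *m* of domain *D* is

    x_m = a·f_D + b·g + sqrt(1 − a² − b²)·ε_m + shift_D + covariate terms

with standard-normal domain factors f_D, global factor g and noise ε_m,
so each score has unit variance and within-domain Pearson correlation
a² + b² (between domains: b²). Defaults a = 0.75, b = 0.40, chosen so
the reference connectome is strongly modular with global integration —
its 20%-density graph is small-world (σ ≈ 2.5–2.8 in the demo). For
Gaussian scores, Spearman ρ_s = (6/π)·asin(ρ/2), verified in the tests.

Topology profiles scale both loadings: `smallworld` (×1.0),
`intermediate` (×0.65), `degraded` (×0.30) — progressively weaker,
more random connectomes. Per-group, per-domain mean shifts produce the
clinical impairment profiles of the four demo groups (hc n = 300,
mci_lb n = 88, mci_ad n = 300, dlb n = 104). Optional features:
covariate effects applied to *centered* covariates (so they change
correlations, not group means), planted right skew via exp(x/2),
inverted (`higher_worse`) scales via negation, missing-completely-at-
random masking, `free_measures` (zero-loading pure-noise measures, used
to exercise fragmenting-node detection) and `domain_within_scale`
(per-group scaling of one domain's within-loading, used to plant nodal
effects).

Scope: the generator is a validation and demonstration instrument, not
a clinical simulator. It produces linear-factor Gaussian data with
monotone distortions; it does not model item-level floor/ceiling
effects, non-MCAR missingness, longitudinal structure or diagnosis
uncertainty.

## 7. Determinism and numerics

One global seed fans out to per-stage seeds via
`numpy.random.SeedSequence(seed, spawn_key=(stage,))`, reduced mod 2³¹.
The pipeline writes a manifest with SHA-256 hashes of every artefact;
two runs with the same config and seed are byte-identical (an
acceptance test asserts this). Floating-point conventions: densities
are rounded to 10 decimals when the grid is materialized; correlations
are clipped to [−1, 1]; z-scores use ddof = 1; unreachable node pairs
contribute 0 to efficiency and are excluded from path length.

## 8. Problem sizes and runtime

Designed for batteries of ~20–40 measures and groups of ~50–500
participants. The permutation engine binarizes and measures each
pseudo-split over all 21 densities in compiled kernels; a 1000-
permutation global comparison of two groups of 100 participants and 24
measures runs in a few seconds on one CPU core. The full demo pipeline
(three group pairs, stability analyses) completes in minutes.

## 9. Limitations

- Fixed-density thresholding discards weight information in the binary
  measures; the signed ranking means strong negative correlations are
  treated as weak edges, not strong ones (use `nodal_strength(...,
  absolute=True)` to inspect absolute-strength hubs).
- The consecutive-density rule is conservative by construction and has
  no closed-form error rate; its calibration is established empirically
  in the acceptance tests for the default grid and rule length.
- Pooled residualization assumes covariate effects are shared across
  groups.
- FDR families are defined per measure per density; no correction is
  applied across measures or across group pairs.
- Small-worldness for very dense or very sparse graphs is unstable; σ
  is reported as NaN when the rewired null degenerates.
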