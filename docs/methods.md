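# Methods

`radcascade` implements an eliminative, geometry-based classifier for
two-class ("resistant" vs. "sensitive") bulk expression cohorts, together
with the cross-cohort marker-selection statistics that feed it and a
synthetic cohort generator used for all testing. This note records the
models, the tunable parameters, the numerical choices, and the limits of
what the synthetic experiments can show.

## Radial projection model

A layout places k ≥ 2 genes as anchors on the unit circle. Listed order
must run counter-clockwise; 4-gene layouts default to the Cartesian axes
(0°, 90°, 180°, 270°) and 3-gene layouts to arms at 90°, 210°, 330°. For a
sample with per-gene weights u ∈ [0,1]^k the projected point is the
normalized barycentre p = Σ uᵢAᵢ / Σ uᵢ. This closed form is exactly the
equilibrium of the spring analogy (stiffness uᵢ, rest point Aᵢ): the energy
½Σ uᵢ‖Aᵢ − p‖² is quadratic with gradient Σ uᵢ(p − Aᵢ), which vanishes at
the barycentre. The test suite keeps an independent numeric energy
minimizer (`spring_oracle`) solely to check this identity (< 1e-8 over
1000 random instances; observed ~1e-15).

Degenerate cases are fixed by convention: an all-zero weight vector maps
to the origin; a gene that was constant in the reference cohort
contributes the neutral weight 0.5. Projected points always lie in the
convex hull of the anchors. Inside `project` the weighted sum is
accumulated in alphabetical gene order so that permuting genes together
with their anchors reproduces points bit-identically.

**Normalization** is per-gene min–max, learned once on a reference cohort
and frozen; prediction clips out-of-range values into [0, 1]. Freezing
makes prediction deterministic and single-sample capable, and makes a
step's outcome independent of which samples survived earlier steps.
Interactive visualization tools instead renormalize whatever subset is
displayed; `fit_cascade(..., renormalize_per_step=True)` preserves that
alternative reading, refitting bounds on each step's surviving samples.

**Regions** are closed angular sectors between two *adjacent* anchors plus
a dead zone: membership requires the point's angle to lie in the closed
arc and its radius to be ≥ `r_min` (default 0.05). The dead zone excludes
the near-origin area where all springs roughly balance and placement is
least informative; with `r_min = 0`, the origin (atan2 angle 0) would fall
in any sector whose arc contains angle zero, which is why the default is
positive. Points exactly on a boundary ray belong to both neighbouring
sectors (closed arcs, tolerance 1e-9 rad).

## Differential expression

For each gene, the effect measure is the difference of group means
(resistant − sensitive) on the provided scale; the module is
scale-agnostic (microarray log2 intensities are the intended input; no
fold changes are computed). The pooled residual variance s² has
d = n₁ + n₂ − 2 degrees of freedom. Under `empirical_bayes` moderation the
variance is shrunk to s̃² = (d₀s₀² + d·s²)/(d₀ + d), with the prior (d₀,
s₀²) estimated by moment matching of log s² across genes: the digamma/
trigamma identities for log-chi-square moments give d₀ via a Newton
inversion of the trigamma function, exactly the classic microarray
moderated-t construction. Two-sided p-values use a t distribution with
d₀ + d df (normal when d₀ = ∞). This implementation reproduces
Bioconductor limma's `eBayes` to ~1e-14 on a frozen fixture (see
`tests/test_deg_stats.py`). Degenerate genes: zero residual variance with
zero mean difference yields t = 0, p = 1 (a flat gene is null, not an
error); zero variance with a real difference yields ±∞.

Multiple testing uses Benjamini–Hochberg (delegated to statsmodels).
Thresholds are strict everywhere: the primary DEG filter keeps
p_raw < 0.05 and t > 2 (up) or t < −2 (down); a gene at exactly t = 2 is
excluded. Blank gene symbols are never selected.

**Cross-cohort panel.** Over three cohorts, a candidate passes the primary
filter in the same direction in ≥ 2 cohorts; it is excluded if any
remaining cohort shows opposite-signed mean difference, |t| < 1, or
p_raw ≥ 0.075 (i.e. retention demands concordant sign, |t| ≥ 1 and
acceptable significance p < 0.075). Genes significant in all three cohorts
(the Venn core) are always retained. Output panels are ordered by
decreasing mean |t| across cohorts, ties alphabetical. Pearson correlation
matrices over panel genes report two-sided p-values from the exact t
transform with n − 2 df and significance tiers * p < 0.05, ** p < 0.005,
*** p < 0.001; zero-variance genes yield missing entries with a warning.

## Cascade training

Hand-drawn elimination regions are replaced by a purity-constrained
exhaustive search. One step enumerates every size-k subset of the
candidate pool, every distinct circular ordering ((k−1)!/2 after fixing
rotation and reflection), and every adjacent-anchor sector. A candidate
must reach purity ≥ `purity_min` (default 1.0 — eliminate homogeneous
samples only) and coverage ≥ `coverage_min` (default 3) on a seeded
stratified 70 % split of each class, then again on the full cohort; among
verified candidates the maximal full-cohort coverage wins, ties broken by
higher purity and then by lexicographic enumeration order, making the fit
bit-reproducible for a fixed seed. The pool is capped at 12 genes (so a
k = 4 search stays at 495 × 3 = 1485 layouts × 4 sectors); `fit_cascade`
pre-ranks larger panels by |moderated t| on the remaining samples,
stratified by direction, before each step.

`fit_cascade` is greedy: each schedule entry (k, target label) fits one
step on the samples not yet eliminated and removes the samples its sector
covers. The last entry fits the dual-region final stage: the search runs
for the entry's label, then the opposite label gets the best verified
sector on the same layout. Entries that cannot reach the constraints are
skipped with a warning. Genes are not reused across steps unless
`allow_reuse` is set. Undetermined is a first-class output; evaluation
reports Selected/Correct per class with integer-rounded percentages, plus
the two error directions (false-sensitive = truly resistant called
sensitive).

A preset reproduces the published four-stage FOLFOX cascade over 14 named
markers; its normalization bounds are fitted against whatever cohort it is
applied to, since the original cohorts' scales are not shipped.

## Synthetic cohorts

The generator draws samples from a Gaussian block factor model: one shared
latent factor loads +c on the up panel and −c on the down panel, one extra
factor per panel loads w, and independent noise has SD `noise_sd`. Given
targets rho_within and rho_cross (≤ 0), c² = −rho_cross·v and
w² = (rho_within + rho_cross)·v with total variance
v = noise_sd²/(1 − rho_within); the construction is positive semi-definite
exactly when rho_within ≥ |rho_cross|, which is validated at build time.
Defaults: 30 + 30 samples, a 10-up/5-down panel, effect 1.5 (in units of
the total per-gene SD), rho_within 0.4, rho_cross −0.2, 200 background
genes, 2 resistant subtypes, noise_sd √0.6 (total SD 1), baseline 8 —
log2-intensity-like numbers typical of small treated-tumour microarray
cohorts. Resistant samples of subtype s (round-robin assignment) shift by
+effect·SD on that subtype's round-robin share of the up panel and
−effect·SD on every down gene; with ≥ 2 subtypes no single sector can
cover all resistant samples purely, which is what forces multi-step
cascades. Everything is deterministic given the seed; triple cohorts use
seed offsets of 1000 and optional per-cohort effect/noise multipliers and
sign-flipped decoy genes.

What the generator does *not* emulate: probe-level artifacts, batch
effects, RNA-seq count noise, annotation drift, class imbalance between
cohorts, or label noise from response-criteria scoring. Passing tests
therefore demonstrate the correctness and internal consistency of the
algorithms under the assumed correlation structure, not clinical
performance on real cohorts.

## Benchmark sizes and observed behaviour

The test suite and the acceptance script use desk-scale problem sizes
chosen to exercise every code path quickly: 1000 random projection
instances, 200 null cohorts (15 + 15 samples) for type-I calibration
(observed rate ≈ 0.05, asserted within [0.03, 0.07]), 20 triple-cohort
replicates for panel recall (observed ≈ 0.97–0.98), and 20 train/hold-out
cohort pairs at the default conditions for the end-to-end benchmark. On
hold-out cohorts the fitted cascades call ~75 % of samples with ~84–85 %
of calls correct; training partitions are 100 % pure by construction. The
purity-1.0 search is deliberately conservative and boundary-hugging, so
late steps fitted on few surviving samples generalize worst — the known
cost of demanding homogeneous elimination, mirrored in the method's
external-cohort behaviour where roughly one call in five or six on a new
cohort is expected to be wrong.

## Known limitations

- Purity-constrained search is exhaustive only within the 12-gene pool
  cap; larger panels are pre-ranked, so the search is not globally optimal
  over the full panel.
- The final stage's layout is chosen by the first label's search; the
  second label only picks among that layout's sectors.
- Min–max normalization is sensitive to single outlier samples in the
  reference cohort (bounds are extremes, not quantiles).
- The moderated-t module covers two-group designs only — no covariates,
  no multi-factor designs, no log-transformation detection.
- GEO Series Matrix parsing is strict (delimiters required, numeric cells
  enforced); probe annotation beyond a two-column probe→gene map is out of
  scope, as is any network access.
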