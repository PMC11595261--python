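# radcascade

Step-by-step eliminative prediction of chemotherapy response from gene
expression, built on radial data visualization (RadViz).

## The problem

Colorectal tumours treated with the FOLFOX regimen (folinic acid,
5-fluorouracil, oxaliplatin) split into responders ("sensitive") and
non-responders ("resistant"), but no single gene separates the two groups
reliably across cohorts. `radcascade` implements an interpretable
alternative to black-box classifiers: a short cascade of geometric
elimination rules over a small panel of marker genes, designed for
clinicians to read step by step.

## The method

**Projection.** Each rule places k = 3 or 4 marker genes as *anchors* on the
unit circle (4-gene rules on the Cartesian axes at 0°/90°/180°/270°, 3-gene
rules at 90°/210°/330°). A sample with min–max-normalized expression
weights u₁…u_k sits at the spring equilibrium

    p = Σᵢ uᵢ Aᵢ / Σᵢ uᵢ ,   Aᵢ = (cos θᵢ, sin θᵢ),

the unique point where the spring forces Σᵢ uᵢ(Aᵢ − p) cancel: strongly
expressed genes pull the sample toward their anchors.

**Elimination.** Each rule owns one closed angular sector between two
adjacent anchors (a "quarter" or "arm") with a small dead zone (radius
< 0.05) around the ambiguous origin. Samples landing in the sector are
called with the rule's label and leave the game; survivors proceed. The
final stage carries two labelled sectors — one per class — and whatever
remains is reported *undetermined*, never coerced into a class.

**Marker selection.** Per cohort, genes are scored with a moderated
t-statistic (empirical-Bayes variance shrinkage via moment matching on log
residual variances) and filtered at raw p < 0.05 and |t| > 2. Markers are
genes that pass concordantly in at least two of three cohorts while the
remaining cohort does not contradict them (same sign, |t| ≥ 1, p < 0.075);
genes passing in all three cohorts form the core trio.

**Training.** Instead of hand-drawn regions, each step is fitted by
exhaustive search over gene subsets, circular orderings and sectors,
constrained to purity 1.0 (only homogeneous samples eliminated) and
coverage ≥ 3 on a seeded 70 % split of each class, re-verified on the full
cohort, maximizing coverage.

The published four-stage FOLFOX cascade (TMEM182/MCM9/LRRFIP1/LAMP1 →
FAM161A/KLHL36/ETV5 → RNF168/SRSF11/NCKAP5/CRTAP → VAMP2/ZBTB49/RIMBP2)
ships as a preset: `published_folfox_cascade()`.

## Worked example

`examples/05_fit_and_evaluate_cascade.py` trains a cascade on a synthetic
cohort (30 sensitive + 30 resistant, planted 1.5-SD marker effects, two
resistant subtypes) and scores a fresh cohort from the same conditions:

```
fitted cascade: 3 stages
  step 1: RESDN02/RESDN03/RESUP06/RESUP01 -> eliminate sensitive in RESDN02-RESDN03
  step 2: RESDN01/RESUP07/RESUP09 -> eliminate resistant in RESUP07-RESUP09
  final:  RESUP02/RESUP05/RESUP10 -> resistant in RESUP10-RESUP02

training cohort (n=60):
    class  selected  correct  percent_correct
sensitive        26       26              100
resistant        25       25              100
undetermined: 9   false-sensitive: 0

hold-out cohort (n=60):
    class  selected  correct  percent_correct
sensitive        27       23               85
resistant        23       21               91
undetermined: 10   false-sensitive: 4
```

Training calls are pure by construction (each fitted sector contains one
class only); on unseen data the called samples remain mostly correct while
ambiguous samples stay undetermined. `false-sensitive` counts the
clinically costly direction: truly resistant samples called sensitive.

The same stages are available from the shell:

```sh
radcascade simulate --out-prefix scratch/demo --seed 0
radcascade degs --matrix scratch/demo.series_matrix.txt \
    --labels scratch/demo.labels.json --probe-map scratch/demo.probe_map.tsv \
    --out-prefix scratch/demo
radcascade fit --matrix scratch/demo.series_matrix.txt \
    --labels scratch/demo.labels.json --probe-map scratch/demo.probe_map.tsv \
    --panel scratch/demo.panel.json --out scratch/demo.cascade.json --seed 0
radcascade predict --matrix scratch/demo.series_matrix.txt \
    --cascade scratch/demo.cascade.json --out scratch/demo.calls.tsv
radcascade eval --result scratch/demo.calls.tsv --out scratch/demo.report.tsv
```

`examples/run_geo_series.py` applies the pipeline to user-downloaded GEO
Series Matrix files (no network access is performed by the package).

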