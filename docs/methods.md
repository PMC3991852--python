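# Methods

## Study design and the size proxy

The pipeline targets a 2x2 design: genotype (control vs a liver-specific
Cdk1 knockout whose hepatocytes regenerate by hypertrophy) crossed with
timepoint (before vs after partial hepatectomy). Each sample carries a
*relative nuclear radius* — nuclear size tracks cell size and ploidy, so it
serves as the per-sample cell-size covariate. Radii are expressed relative
to the control/pre group: `normalize_radius` divides every radius by that
group's mean, making the reference mean exactly 1 (idempotent). The data
model carries a radius per sample, not per group, so both "each sample gets
its group mean" and per-animal radii are representable; no stage assumes
radii are constant within a group.

## Per-feature statistics

For every feature, Pearson r between abundance and relative radius is
computed over all samples on the linear abundance scale by default (the
expression–radius trends this analysis targets are close to linear in
abundance); an opt-in log2 transform (`log2_transform=True`, with a
pseudocount) is available. The two-sided p comes from
t = r·√((n−2)/(1−r²)) on n−2 df; the confidence interval (default level
0.90) from the Fisher z transform with standard error 1/√(n−3) (needs
n ≥ 4; reported as NaN at n = 3). Multiple testing uses Benjamini–Hochberg
step-up (delegated to statsmodels), applied over features with defined p.

Numerical choices:

- A feature with zero abundance variance has undefined r; "zero" is judged
  against the row magnitude (`||y_centered|| ≤ 1e-12·||y||`) because mean
  subtraction of a constant row can leave a ~1-ulp residue. Such features
  are excluded from the BH adjustment and carry NaN r/CI/p.
- When |r| reaches 1 exactly, p is reported as the smallest positive float
  rather than 0, keeping log-scale summaries finite; the CI collapses to
  [r, r].
- The size fold change is log2((mean_largest + c)/(mean_smallest + c)) with
  group means over replicates; the largest/smallest groups are picked by
  group-mean radius and a tie is an error (callers must subset explicitly).
  The pseudocount c defaults to 1 for gene matrices and 0 for metabolite
  intensities (strictly positive by construction).
- Correlation histograms tile [−1, 1] with left-closed/right-open bins and
  a closed terminal bin, so r = 1 is counted exactly once (numpy's
  histogram convention).
- The abundance-stratified summary ranks features by mean abundance with a
  stable sort (ties keep table order) and splits them into quantile strata.

## Gene-set scaling profiles

A profile is the binned per-feature statistic for one set plus the
background histogram rescaled by (set size / background size), so the
normalized background counts sum to the set's measured size — shapes are
directly comparable. The background defaults to the union of all annotated
measured features (`annotated_union`); `all_features` uses every measured
feature. The tested set stays inside the background by default (the
whole-cell profile is defined over all annotated genes); an exclusion flag
exists for sensitivity analysis. Sets are intersected with measured
features, and sets with fewer than 2 measured members are skipped with a
warning. Set-vs-background shifts use the two-sample two-sided KS test:
exact p when both samples have ≤ 25 values, asymptotic otherwise, no
continuity correction; KS p-values are reported raw and BH-adjusted across
the profiled sets (whether the original component-level p-values were
multiplicity-adjusted is not knowable, so both are emitted).

In `log2fc` mode the same machinery profiles a per-gene log2 fold-change
statistic (for two-condition designs without a size gradient). Fold changes
are unbounded, so log2fc mode tiles a symmetric range covering the data at
the requested bin width instead of [−1, 1]; the count-conservation
invariant holds in both modes.

Lipid classes reuse the per-feature table: classes with at least 5 measured
members ("more than four metabolites") are summarized by median r and mean
log2 fold change, ranked by median r. The geometric expectation curve is
1/r per sample: for isometric growth, surface scales as r² and volume as
r³, so membrane demand per unit volume falls as 1/r (normalized to 1 at the
reference radius).

## Connectivity null

"Connections per gene" is the induced-subgraph edge count divided by the
set size — not the degree sum, which would double each internal edge; the
convention is recorded in the output so ratios are comparable. Genes absent
from the network stay in the denominator (conservative). The null draws
same-size gene sets uniformly without replacement from a configurable
universe (all network nodes by default; optionally network nodes that were
measured). Monte Carlo mode (default 1000 iterations) reports the add-one
empirical p, (1 + #{null ≥ observed})/(iterations + 1), which can never be
0; exhaustive mode enumerates every subset (refused above 2·10⁶ subsets)
and reports the exact tail fraction. Enrichment ratio = observed / null
mean; a zero null mean with a positive observation is flagged as infinite.

## Genotype vs size effects

"Genotype-responsive" is operationalized as a per-feature Welch two-sample
t-test on log2(abundance + pseudocount) between genotypes at the pre-
hepatectomy timepoint by default — the contrast that isolates the deletion
response from the regeneration/size program — with BH adjustment, adjusted
p < 0.05 and |log2FC| ≥ log2(1.5). `post` and pooled (`both`) contrasts are
available. With 2–3 replicates per group this is a screening statistic, not
an inferential claim; all thresholds are echoed in the output. If both
groups have zero variance, differing means count as an (effectively
noiseless) extreme effect and identical means as a non-effect. Overlap is
reported as |A∩B| and as a percentage of the size-correlated set, raw and
rounded.

## Synthetic-data generator

The generator's defaults define the simulated study conditions:

- **Design**: 4 groups × 3 replicates; group mean radii (1.0, 1.05, 1.3,
  2.5) — control cells barely change after hepatectomy, knockout/post
  nuclei sit in the reported 2–3x range (2.5 chosen), knockout/pre modestly
  enlarged (1.3, a free choice). Per-sample radii are lognormal around the
  group mean with CV 0.05 (modest animal-to-animal variability), then
  renormalized so the control/pre mean is exactly 1. CV 0 reproduces the
  group means exactly.
- **Signal model**: log2(abundance) = baseline + slope·radius + N(0, σ),
  σ = 0.25. Linearity on the log2 scale is the simplest model consistent
  with near-linear expression–radius trends. Classes: 30% positive
  (slope +1), 12% negative (slope −1), 58% null — echoing the observed
  asymmetry between positive and negative strong correlators without
  claiming exact proportions. Class baselines (log2 means 4/8/6 for
  positive/negative/null, SD 2) put the negative class among the abundant
  features and the positive class among the lowly expressed, reproducing
  the pattern that size-coupled upregulation is carried by many
  low-expression genes while abundant genes are slightly repressed.
- **Genotype effect**: 40 null-class genes get a +2.5 log2 shift in
  knockout samples *before* hepatectomy only — a deletion response that the
  regeneration program overrides. A shift applied to all knockout samples
  would itself correlate ≈ 0.72 with the radius gradient (the genotype
  indicator and the radii are strongly collinear in this design) and would
  conflate the two planted effects; the pre-only shift keeps them
  statistically separable, which is what the overlap analysis is built to
  measure. The magnitude 2.5 makes the planted response reliably detectable
  by a Welch screen at n = 3 per group.
- **Annotations**: planted sets drawn from their classes (mito-like and an
  SREBP-like TF family from the negative class, cytoskeleton-like and an
  E2F-like family from the positive class, decoys from the null class),
  disjoint at overlap_fraction 0; an `all_tfs` union set supports the
  TF-histogram analysis. Lipid classes include a 20-member storage-lipid
  (triacylglycerol-like) class drawn from positively scaling metabolites,
  null membrane-lipid classes, and a deliberate 4-member class below the
  reporting cutoff.
- **Network**: independent Bernoulli edges — probability 0.3 within the
  planted module (the full negative class) and 0.02 elsewhere.
- **Determinism**: one global seed drives independent named substreams
  (design, gene matrix, metabolite matrix, annotations, lipid classes,
  network) via `SeedSequence([seed, stream])`, so artifacts can be
  regenerated independently and identical (config, seed) gives byte-identical
  outputs.

What the generator does *not* emulate: read-count noise and library-size
artifacts, batch effects, mass-spec peak shapes or missingness, correlated
noise between features, degree heterogeneity or scale-free topology in the
network, and per-animal random effects. Passing tests therefore demonstrate
that the statistical machinery recovers planted structure under idealized
log-linear noise — not that the pipeline is robust to every artifact of
real RNA-seq or metabolomics data.

## Problem sizes and defaults used in checks

The bundled checks run the default study (1000 genes, 300 metabolites,
12 samples), 100 seeds for planted-structure recovery, 2000 simulations for
interval coverage at n = 12, 1000 replicates for each p-value calibration
(KS set draws against a 5000-value background; connectivity p with 199 null
iterations on a 300-node random graph), and 100 random instances per
brute-force oracle comparison. These sizes were chosen to make the checks
statistically meaningful while keeping a full run in the minutes range on
one CPU.

## Known limitations

- Pearson-only size trend: no rank-based or nonlinear alternative, and no
  mixed-effects modeling over animals.
- The genotype screen is a two-group Welch test, not a count-based
  differential-expression model with dispersion shrinkage.
- The connectivity null randomizes gene identity, not network structure;
  degree-preserving rewiring nulls are out of scope.
- GO-style set hierarchies are not propagated; sets are taken as given.
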