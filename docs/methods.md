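# Methods

`apmsdiff` analyses label-free affinity-purification mass spectrometry
(AP-MS) experiments in which several bait variants (e.g. CFTR variants, or
bait-mimicking peptides) are each pulled down in 3–4 replicates alongside a
background capture from cells lacking the bait. The pipeline starts from
quantified peptide- or protein-level tables; identification, FDR control and
search-engine output are upstream and out of scope.

## Quantification

**iBAQ.** For each protein and replicate, iBAQ = (sum of its peptide
intensities) / (number of theoretically observable peptides). The observable
count is a per-protein integer ≥ 1 supplied with the peptide table. iBAQ is
linear in intensity and proportional to molar amount under equal
ionisation-efficiency assumptions.

**Total normalisation.** Each (condition, replicate) column is divided by its
column sum, correcting for pull-down depth. All-zero columns are an error.
This assumes nonspecific protein mass dominates every sample, so totals are
comparable; the synthetic generator is built to respect this assumption (see
below).

**Zero handling.** Exported tables record missing proteins as true zeros.
Before any ratio or log2, zeros are resolved by one of two policies:

* `floor` (default): substitute half the column's smallest nonzero value.
  Keeps every ratio finite and preserves within-column rank. A floored
  control value turns a background-absent protein into a large positive
  ratio — intended, since background-absent proteins are the interesting
  specific binders.
* `drop`: mark zeros as missing; combination values touching them are
  omitted, and a protein missing from a whole side of a comparison is
  excluded from it.

The policy in force is recorded in the run manifest. Proteins never detected
in any replicate of a bait condition are removed from that condition's
combination set regardless of policy (floor values alone are not evidence).

## Background-referenced combination test

For each bait condition, every sample replicate is referenced against every
background replicate: 3×3 = 9 ordered pairs, 4×3 = 12. Two equivalent
arithmetic routes are provided and never mixed within a comparison:

* `ibaq_ratio`: pair value = sample / control on normalised intensities;
* `holistic`: pair value = sample − control on log2 normalised intensities.

The per-protein **median of combinations** is the background-referenced
affinity. Because the median commutes with monotone maps,
`median(ratios) = 2^median(log2 differences)` exactly (tested to 1e-9), so
the routes differ only in their zero-handling surface.

**Replicate overlap.** Reproducibility of a condition is summarised as
|intersection| / |union| of the per-replicate detection sets (detection =
value > 0), reported as a percentage. All-way intersection-over-union is the
default reading of "overlap"; mean pairwise Jaccard is available
(`overlap_method="pairwise"`).

## Differential affinity and the permutation volcano

For a condition pair (A, B), the per-protein affinity difference is
Δ = log2(median_A / median_B) (ratio route) or Δ = median_A − median_B
(log2 route); Δ(A,B) = −Δ(B,A). Two calling rules are implemented:

* **threshold classification**: |Δ| > 5 log2 units → differential
  (`higher_A` / `higher_B`), else nonspecific;
* **volcano calls**: |Δ| ≥ 6 **and** permutation p < 0.025
  (−log10 p > 1.60).

**Permutation test.** Per protein, the observed statistic is
|median(A combinations) − median(B combinations)| on the log2 scale. The
null pools the two combination vectors and randomly reassigns values to two
groups of the original sizes, B = 10,000 times; p = (#{null ≥ observed} + 1)
/ (B + 1), so p is never 0 and −log10 p is finite. Ties count as ≥
(conservative). The statistic is pluggable (`median` default, `mean`
alternative); conditions are ordered canonically so p(A,B) ≡ p(B,A) at the
same seed. Exhaustive enumeration replaces sampling for pools up to
`exhaustive_max` values.

**Validity caveat — read this before interpreting p-values.** The 9 + 9
combination values of one protein are *not* exchangeable: each bait
replicate contributes to three values, and both conditions share the same
control replicates. Value-level permutation therefore overstates the
effective sample size, and on null simulations the fraction of proteins
with p < 0.025 is roughly 0.09–0.11 rather than 0.025. The exactly valid
alternative — permuting the six bait replicates themselves
(`permutation_unit="replicates"`) — has only C(6,3) = 20 distinct
reassignments, so its smallest achievable two-sided p is 0.1 and *nothing*
can ever pass a 0.025 threshold with 3 + 3 replicates. There is no
per-protein permutation scheme at this design size that is both exact and
able to reach the published significance level; the volcano's p-values
should be read as a ranking/filtering score calibrated by the fold-change
bound, not as exact error rates. No multiple-testing correction is applied
across proteins, consistent with the analysis the pipeline reproduces; the
enrichment module, by contrast, does correct (Benjamini–Hochberg).

## Interactome sets and comparison

A protein belongs to a condition's qualitative interactome iff it is
detected (value > 0) in ≥ `min_replicates` replicates (default 2). The
membership rule is stored on every set; comparing sets built under different
rules warns. Jaccard index = |∩| / |∪| (0 for two empty sets, with a
warning); 1 − Jaccard satisfies the triangle inequality and is
property-tested as a metric. Venn partitions assign every accession of the
union to exactly one region (2–4 sets). `cross_reference` intersects a set
with an external accession list (one accession per line).

## Projection and clustering

The protein × condition matrix of combination medians (missing entries
filled with the condition floor, or dropped) is decomposed by plain SVD with
**no centering and no scaling** — all columns share the same
background-referenced provenance, so the origin is meaningful. Explained
fractions are σ_i² / Σσ², i.e. fractions of the **total sum of squares**,
not of variance about the mean; with a large shared offset the first
component absorbs it, which inflates PC1's fraction relative to centered-PCA
conventions. Scores and loadings satisfy `scores @ loadings.T = input`
exactly over all components, and on a mean-zero matrix the result coincides
with classical centered PCA (limit-case tested against scikit-learn).

Proteins are clustered by average-linkage agglomeration on Euclidean row
distances (cosine selectable), computing one dendrogram and cutting it at
every k in 3–12 (cuts are nested). The default report uses k = 8. Labels
are renumbered by first appearance so runs are reproducible; clustering
operates on the median matrix by default, or on the first three PCA scores
(`cluster_on_scores=True`) — the choice is recorded in the manifest.

## Over-representation stand-in

`hypergeom_enrich` tests a study set (e.g. volcano hits) against annotation
terms (two-column TSV or GMT) within the background of all proteins
quantified in the run — standard ORA practice, narrower than web services
that default to a whole-proteome background. For a term covering K of N
background proteins with k hits among the n study proteins, p = P(X ≥ k),
X ~ Hypergeometric(N, K, n), with fold enrichment (k/n)/(K/N) and BH
adjustment across terms.

## Synthetic data generator

`generate_experiment` emulates the quantified output of such a study: one
background condition plus `n_conditions` baits, `n_replicates` ∈ {3, 4}
each. Protein classes: a majority of background binders (equal expected
level in every pull-down), condition-specific interactors (elevated by
`enrichment_log2` in exactly one bait), and shared-specific interactors
(elevated in all baits). Per-replicate values are
2^(expected log2 + N(0, noise_sigma)); dropout zeroes cells independently
with probability `dropout_rate`. A peptide table splits each protein
intensity across 5–30 observable peptides with fixed Dirichlet weights, so
peptide sums reconstruct protein intensities exactly and the iBAQ path is
exercised. One seed drives everything through per-condition substreams;
identical configs are byte-identical.

Defaults: 4 baits × 3 replicates, 800 background binders, 50 specific per
condition, 30 shared, enrichment 8 log2 units, noise 0.5 log2 units,
dropout 0.1. Background binders draw base abundance uniformly on
log2 ∈ [18, 30] (the typical MS dynamic range, wide enough that
normalisation matters). Specific interactors draw their background-capture
base from the low end ([18, 30 − enrichment]) so that their *enriched*
level stays within the same range: bait-specific partners are near the
detection floor of a control pull-down, and without this a single planted
protein can dominate a bait sample's total, which would shift every
normalised ratio in that sample — a property of total normalisation, not of
the biology being modelled.

What the generator does **not** emulate: intensity-dependent (left-censored)
missingness, correlated contaminant structure, peptide-level noise and
mis-assignment, batch effects, or interactors that change level between
baits by less than full presence/absence. Passing recovery tests therefore
show the pipeline's arithmetic and calling logic are correct under the
stated noise model — not that real interactomes at these thresholds are
recovered with the same sensitivity.

## Numerical choices and problem sizes

* Medians use the standard midpoint convention for even counts; NaN pairs
  are ignored, all-NaN vectors propagate as missing.
* p-estimator: +1/(B+1) correction; ties count toward the null.
* Floors are per column, half the minimum nonzero value.
* Degenerate inputs raise typed errors (`DataError`,
  `ConfigurationError`) naming the offender: all-zero columns, rank-0
  matrices, k outside [2, n], single-replicate overlap, study sets outside
  the background.
* Null-calibration runs use 2,000 proteins × 10,000 permutations;
  recovery runs use ~400 proteins (300 background + 100 planted) — sizes
  chosen so the full validation completes in well under a minute while
  binomial standard errors stay a small fraction of the quantities checked.

## Known limitations

* The permutation p-values are anticonservative by construction at this
  replicate count (see the validity caveat); the fold-change bound does the
  bulk of the false-positive control.
* Only 2–4-way Venn partitions are supported.
* Accessions are opaque strings; no identifier mapping is attempted.
* The drop policy can leave a protein with fewer than two combination
  values on a side, in which case it is excluded from testing and logged.
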