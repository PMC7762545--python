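# Methods

This note documents the statistical model behind `genofabric`, the
estimators and conventions it adopts where the methodology leaves room,
what the synthetic-data generator does and does not emulate, and the known
limitations of the small-replicate design the package targets.

## Study design and data model

The target design profiles several regions of one tissue (e.g. a normal
margin, two primary tumor nodules and a metastasis) with a small number of
biological replicates per region — four by default, obtained by splitting
each region sample into quarters profiled separately. Expression is
measured at spot level on a redundant platform: a unigene may be probed by
1–20 spots (the emulated 4×44K array averages ≈3.3 spots per unigene).
Replicates from one region are treated as near-identical systems exposed
to slightly different non-regulatory local conditions, which is what makes
the variability and correlation analyses meaningful.

Quality control mirrors the two-color microarray convention: a spot is
discarded when flagged corrupted or when its foreground fluorescence falls
below twice the background in *any* replicate of *any* region (the
boundary fg = 2·bg is retained — the rule is a strict "less than"); a gene
is kept only if at least one of its spots is fully quantified in every
region/replicate, so the quantified universe is the intersection over all
samples. QC followed by elimination is idempotent.

## Estimators

**AVE** averages replicate means with equal weight per spot, so a heavily
probed gene is not dominated by its redundancy.

**REV** is a chi-square-corrected pooled coefficient of variation, in
percent. The per-spot CVs `s_ik/μ_ik` are pooled as the square root of
their mean square, then multiplied by the mid-interval correction
`½(r/χ²(r;0.975) + r/χ²(r;0.025))` at `r = n·R − 1` degrees of freedom.
Two conventions are deliberate:

* the χ²(r; p) terms are p-quantiles (inverse CDF), which makes the
  correction > 1 and monotonically decreasing toward 1 — a conservative
  penalty on weakly probed genes (7.11 at r = 3, 1.53 at r = 31);
* the correction multiplies the pooled CV *outside* the square root, so
  REV stays on the percent scale of a CV.

Genes with AVE = 0 (or any zero spot mean) have no defined REV and are
excluded from REV-based stages; they instead carry on/off information for
the regulation caller.

**Coordination** is the Pearson correlation of two genes' log2 expression
across biological replicates. By default each gene is reduced to its
per-replicate spot mean, giving n paired observations and dof = n − 2 for
the two-tail t-test — the conservative choice that works for unequal
redundancy; spot-level pairing (dof = n·R − 2) is available when both
genes have the same spot count. At 4 replicates the exact significance
line is |ρ| = 0.95 (and the null distribution of r is uniform on [−1, 1],
so p-values are exact despite the tiny sample). Classes: S (ρ > 0,
p < 0.05), A (ρ < 0, p < 0.05), I when p ≥ 0.95 — i.e. |ρ| below the
0.95-level critical value (≈0.05 at dof 2), the operationalization chosen
here for "statistically indistinguishable from zero", since no numeric
band is established in the field — blank otherwise. Genes with any zero
replicate value in a region are excluded from coordination in that region.
No multiplicity adjustment is applied to correlation or regulation
p-values, matching the framework's convention; users can apply their own
on the exported long-format tables.

**Region-level REV summaries** compare the median REV of a gene set
between regions (percent reduction vs the reference) and attach a
two-sample z-test on the REV values, under the framework's normality
assumption for REVs. A permutation oracle in the test suite confirms the
z-test p within 0.01 on normal data; for markedly non-normal REV
distributions the z-test should be read as approximate.

## Regulation calls

The signed fold change `x(A→B)` is `μ_B/μ_A` when B is higher and
`−μ_A/μ_B` when lower (+1 on exact equality), so |x| ≥ 1 always. The
cutoff `CUT = 1 + sqrt(2(REV_A² + REV_B²))/100` makes the required fold
change grow with the combined noise of the gene in the two regions
(CUT = 1.83 when both REVs are 41.5%). The significance gate is a
two-tail Welch t-test on the log2 replicate-level values (n·R per side) —
the weakest distributional assumption compatible with the replicate
design; both gates must pass. The radical grouping of the cutoff is
typographically ambiguous in its source; the adopted reading is isolated
in `regulation_cutoff` for easy revision. Genes with all-zero replicates
on exactly one side are turned_on/turned_off (the ratio is undefined at
AVE = 0); a zero-AVE side with non-zero replicates is refused as
unquantified rather than guessed. Pathway-level regulation uses the
hypergeometric upper tail P(X ≥ observed), verified against exact
enumeration to 1e−12.

## Fabric geometry

A pathway's displacement between a region and the reference is summarized
by three percentage coordinates: the mean over pathway genes of
(AVE ratio − 1), of (REV ratio − 1), and a coordination axis; the
transcriptomic distance is the Euclidean norm of coordinate differences.
Coordinates are already percentages, so no second ×100 is applied in the
norm. The anchor gene of the coordination axis must be named explicitly
(no silent default), is dropped from the pathway if present, and genes
with zero/undefined reference values are excluded and reported.

The coordination axis supports two conventions because the two published
renderings of it disagree: `ratio_mean` (the printed formula — the mean of
per-gene anchor-correlation ratios) and `partner_count` (the percent
change in the *number* of significant anchor partners, which is how the
published coordinate values were evidently obtained). The ratio form is
the default for formula fidelity but is numerically fragile at 4
replicates: any reference correlation near zero inflates its ratio
arbitrarily, and coordinate magnitudes of thousands of percent arise on
clean synthetic data. `partner_count` is the recommended mode for real
4-replicate work and is what the distance example uses.

The two-gene expression-subspace view (`subspace_centroid_distance`)
places each replicate at its per-gene spot-mean expression, on the log2
scale by default, and measures the distance between region centroids —
"expression units" here are log2 units of the normalized input scale.

## Pair-wise relevance and the gene hierarchy

PWR multiplies three dimensionless factors — joint abundance relative to
the squared region mean AVE, squared coordination, and joint control
(squared region mean REV over the REV product). The region means are
taken over the *entire* quantified universe even when a landscape is
restricted to a pathway, so pathway landscapes share one scale. Ties in
the landscape ranking break by descending PWR then lexicographic pair
name. Relevance is deliberately decoupled from regulation: a pair can top
the landscape with no fold change at all (asserted on planted data).

GCH multiplies the transcription-control estimate ⟨REV⟩/REV_i (⟨⟩ =
median over scoreable genes) by exp(4·mean ρ²) over all other quantified
genes — the coordination factor is bounded in [1, e⁴ ≈ 54.6], and GCH is
invariant to uniform rescaling of all REVs. The mean ρ² uses every
defined pair, significant or not (undefined pairs leave the denominator).
The O(N²) correlation pass can stream in row blocks; block-wise results
are bit-identical to the full-matrix path. Hierarchy ties break toward
the lower-REV gene, then the name. The top gene is the region's GMR.

Absolute GCH values from 4-replicate data are noisy (sample ρ² at dof 2
has variance comparable to its mean), so the meaningful claims are about
ranks, and the package's validation is rank-based: a planted master gene
(loading 0.95 on the fabric factor, CV reduced to 0.3×, redundantly
probed) reaches the top 5 of a 300-gene hierarchy in ≈96% of seeded runs.

## Manipulation prediction

Overexpressing a target predicts upregulation of its S partners and
downregulation of its A partners; silencing predicts the opposite; I and
blank partners are predicted not regulated (the basis class is preserved
so the two are distinguishable). Predictions are sign-only — the
framework provides no effect-size model. Partner percentages round half
away from zero to integers. Class flips (S↔A between regions) are
reported only when both regions show a significant class; a blank side is
insufficient evidence.

## The synthetic-data generator

The generator emulates the spot-redundant multi-region design with known
ground truth:

* **Redundancy**: spots per gene drawn from a truncated geometric law on
  [1, 20] (p = 0.3 by default, mean ≈3.3 — the emulated platform's
  spots-per-unigene ratio).
* **Expression scale**: lognormal base levels (log2 mean 4, sigma 1.5 by
  default) on an arbitrary normalized scale; all downstream statistics
  are scale-free.
* **Replicate noise**: multiplicative lognormal per gene with planted CV
  (uniform on [0.02, 0.10] by default, which at the default redundancy
  yields median REVs of a few tens of percent). The lognormal sigma is
  chosen as sqrt(ln(1 + CV²)) and mean-corrected, so the planted CV is
  the exact per-spot coefficient of variation and planted fold changes
  are preserved in expectation.
* **Coordination**: genes in a block share one standard-normal latent
  factor per region and replicate; a member with loading λ gets
  λ·(factor) plus sqrt(1−λ²) of residual noise on the log scale, so two
  members with loadings a, b have population log-scale correlation a·b
  (exact for single-spot genes; spot averaging can only raise it).
  Residual noise is drawn per spot *and* replicate: redundant probes are
  semi-independent measurements, which is precisely the assumption behind
  the pooled-CV estimator's n·R − 1 degrees of freedom.
* **Planted structure**: per-region fold changes (signed convention,
  0 = silenced, so turned-on/off genes are one multiplier away), a master
  gene with a high loading on the first block's factor, a reduced CV and
  a pinned spot redundancy (8 by default — a single-spot gene cannot
  display a low REV because the r = 3 correction dominates it), and a
  configurable fraction of spots planted to fail the 2× foreground rule
  plus corrupted flags, to exercise QC.
* **Fluorescence**: background is a constant (50 by default) with 5%
  lognormal noise; foreground is 2·bg + expression so that honest spots
  pass the QC rule with no margin artifacts.

All randomness flows from the explicit config seed; identical configs
write byte-identical fixtures. The truth sidecar (JSON) records per-gene
base level, CV, loading, block, redundancy and region multipliers plus
the master-gene identity.

Deliberately **not** emulated: dye bias, print-tip and normalization
artifacts (input is post-normalization by assumption), heavy-tailed
outliers, cross-region correlation of the latent factors, and cell-type
mixture effects. Passing tests on this generator therefore demonstrate
estimator and pipeline correctness under the declared noise model, not
robustness to upstream artifacts in real arrays.

## Numerical conventions and degenerate inputs

* Zero spot means ⇒ REV undefined (NaN), gene excluded from REV/PWR/GCH
  with the exclusion visible in the outputs.
* Constant log2 vectors ⇒ undefined ρ ⇒ blank class, pair dropped from
  mean-ρ² denominators.
* Fold change at exact equality ⇒ +1; both sides silent ⇒ not_regulated.
* Welch test with two zero-variance sides ⇒ p = 1 if the means agree,
  0 otherwise; the z-test degenerates the same way.
* Landscape and hierarchy tie-breaks are deterministic (documented above)
  so reruns are reproducible to the byte.
* The pipeline validates inputs (files, reference region, anchor gene in
  the universe) before writing anything, and hashes the analysis-relevant
  config (not the output location) into the manifest.

## Problem sizes used by the validation suite

The simulation-based checks run at sizes chosen to make their statistical
statements crisp while staying desk-scale: 300 genes × 4 replicates × 50
seeds for master-gene rank recovery; 300 genes × 2 regions × 2 seeds for
regulation power (planted 2.5× folds at CV ≤ 0.05 ⇒ ≥95% called) and the
null false-call rate (≤ α plus binomial noise); 150 genes × 20 seeds for
prediction sign agreement (≥80% among significant partners). The CV
rank-recovery property is checked at 12 replicates (Spearman ≈0.94),
where the pooled-CV estimator is identifiable; at the 4-replicate study
design the same quantity is ≈0.85 — an honest statement of how noisy
per-gene variability estimates are at n = 4.

## Known limitations

* With 4 replicates, correlation significance has only 2 degrees of
  freedom: individual S/A calls are exact but weak, partner counts and
  mean-ρ² values fluctuate strongly from draw to draw, and region-level
  coordination summaries inherit that variance.
* Published absolute GCH values for specific genes are not reproducible
  without the original patient arrays; the package's claims about GCH are
  rank-based.
* The z-test behind REV-reduction p-values assumes approximately normal
  REV distributions; its p-values should not be over-read far in the
  tails.
* The `ratio_mean` coordination axis is faithful to the printed formula
  but unstable at small n; prefer `partner_count` for real data.
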