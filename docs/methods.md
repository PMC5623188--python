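# Methods

## The analysis problem

Bulk RNA-seq of two enriched sensory-neuron populations — condition A (DRG
neurons, 6 replicates) and condition B (TG neurons, 4 replicates) — asks
three questions in sequence: which genes are *expressed* in each
population, which are *differentially expressed* between them, and which of
the differential calls are *trustworthy as neuronal* rather than artifacts
of residual non-neuronal contamination. A fourth stage measures how the
resulting profile agrees with an independent (possibly cross-species)
dataset, and a power module quantifies what fold changes the design can
detect. ganglioseq implements each stage as a separately testable module
and validates the chain end-to-end on simulated data with known truth.

## Expression calling

FPKM is computed with each sample's own total assigned counts as the depth
denominator and the annotated union-exon length as the effective length:
`fpkm[g,s] = counts[g,s]·10⁹ / (total[s]·length_bp[g])`. No between-sample
normalization and no fragment-length correction are applied at this stage
(the DE stage has its own size factors); TPM/CPM are out of scope.

A gene is *present* in a condition when FPKM reaches the cut-off (default
1.0) in at least `min_replicates` (default 2) replicates of that condition;
*detected* is the union over conditions. The comparison is inclusive (≥) by
default with a strict (>) option — the inclusive form is adopted because the
rule is procedural and a boundary value should count as evidence of
expression. The rule needs at least two replicates per condition, which the
configuration validates.

## Differential expression

The count model is the negative binomial with variance `μ + αμ²`. The stage
re-implements the standard pipeline transparently rather than wrapping an
existing tool; the target property is statistical calibration, not
bit-identity with any particular implementation.

**Size factors.** Median-of-ratios: over genes with non-zero counts in every
sample, `factor[s] = median_g counts[g,s] / geometric_mean_g`. Factors are
not rescaled afterwards; permutation-equivariant; invariant to all-zero
genes.

**Dispersion.** Gene-wise method of moments on size-factor-normalized
counts with within-condition pooling: `α̂_g = max(0, (s²_g − μ̄_g·ξ)/μ̄_g²)`
where `ξ = mean(1/sf)`. The `ξ` factor is required because under
normalization `Var(K/sf) = μ/sf + αμ²` — with a 4-fold spread of library
sizes the uncorrected form overestimates `α` at low means. A mean–dispersion
trend `α(μ) = a₁/μ + a₀` is fitted by robust (soft-L1) least squares over
genes with positive gene-wise estimates, coefficients constrained
non-negative; with fewer than 10 informative genes the trend falls back to a
flat median. The final per-gene value is the gene-wise estimate shrunk
halfway toward the trend in log space and **floored at the trend**:
below-trend gene-wise values are pulled up to the trend, above-trend values
keep half their (log) excess. The floor is what makes the Wald test
calibrated at this replication level: with ~10 samples the moment estimator
is noisy, and genes whose dispersion is under-estimated by chance are
exactly the genes whose Wald statistics become inflated. A symmetric shrink
left a null rejection rate of 0.075 at nominal 0.05; the floored form
measures 0.043–0.053 across seeds with zero BH discoveries on 5000-gene
null simulations.

**Wald test.** Group means are means of normalized counts. When one group is
all zero, a pseudo normalized-count of 0.5 is added to both group means, so
condition-exclusive genes receive large but finite `log2fc` (≈10–12 at
typical depths) instead of infinities — they must surface as ordinary
significant calls. `log2fc = log2(m_B/m_A)` (positive = higher in B); the
delta-method standard error uses
`Var(m_X) = m_X·Σ(1/sf)/n² + α·m_X²/n`; two-sided p-values come from the
standard normal; BH adjustment (via statsmodels) yields `adj_p`, and
`significant` means `adj_p < α` (default 0.05). Genes with zero counts
everywhere are flagged (`all_zero`, p = 1, log2fc = 0), not errored.
No covariates, LFC shrinkage, independent filtering or outlier refitting.

## Classification

Decision order per gene: not significant → `common`; significant but not
detected → `not_expressed`; significant but absent from the pure-neuron
reference set → `non_neuronal`; significant and present in exactly one
condition → `exclusive` for that condition; otherwise `up_a`/`up_b` by the
sign of `log2fc`. The order makes the categories a total partition and
encodes the filtering philosophy: an expression call you do not trust
should never be promoted to an exclusivity claim. Exclusivity additionally
requires significance, so presence asymmetry alone (e.g. a gene hovering at
the cut-off) is not enough. The reference criterion is set membership only;
how the reference set was derived is the provider's concern.

## Concordance

Ortholog matching is case-insensitive symbol equality (an explicit mapping
table can be substituted upstream by re-keying the comparison frame). Genes
absent from one dataset count as FPKM 0 before ranking; an intersect-only
mode restricts to shared keys. A pseudo-FPKM of 0.01 keeps zero-FPKM genes
finite in ratios and logs. A comparison ratio of exactly 1 counts as *not*
same-trend (a tie supports neither direction). The heatmap matrix is
row-standardized (per-gene z-scores with sample SD; constant rows → 0).

## Power

`power = Φ(√(n·ln²Δ / (2·(1/μ + cv²))) − z_{1−α/2})` with depth `μ`
(expected counts per gene), biological CV, fold change `Δ`, `n` replicates
per group, two-sided size `α` and no multiple-testing adjustment. The
sample-size inverse returns the smallest integer `n` meeting a target
power. `monte_carlo_power` verifies the formula by simulating NB genes with
dispersion `cv²` and the fold change split symmetrically around `μ`
(group means `μ/√Δ` and `μ·√Δ` — the same convention the simulator uses),
then applying the plug-in Wald test. The closed form is parameterized by a
single depth; under an asymmetric design (whole fold on one group) it is
conservative by up to ~0.07 at depth 10 with small CV, which users should
treat as a property of the formula, not of the implementation. Measured
agreement on the depth × CV × effect grid {10,50,200}×{0.2,0.4,0.6}×
{1.5,2,4} at the 80%-power sample size is within 0.023 absolute.

## The simulator and what it does (not) show

`SimConfig` defaults describe a plausible FACS-enriched two-condition
experiment: 6 vs 4 replicates; baseline means log-uniform on [5, 2000]
expected counts; shared NB dispersion 0.2 (a typical bulk-tissue value;
per-gene dispersion variation is not simulated); library sizes log-uniform
over a 4-fold range (only ratios matter); gene lengths uniform on
[500, 5000] bp; class mix 70% common, 5%+5% fold-changed, 2.5%+2.5%
exclusive, 5% glial-contaminant, 10% silent. DE classes split the
configured fold change symmetrically (`μ·2^{±fc/2}`); exclusive genes have
literal zero mean in their off condition, making truth unambiguous for
recovery tests. Class counts are made exact by largest-remainder rounding.

Contamination redirects a fraction `c` of each sample's expected total into
a fixed glial profile (drawn from the upper half of the mean range —
glia-enriched transcripts are abundant), so neuronal means scale by
`(1−c)` and glial-only genes receive counts purely through admixture.
`contamination_bias` multiplies `c` in condition B: a value ≠ 1 emulates the
between-ganglion tissue-composition difference that makes glial transcripts
appear differentially expressed in whole-tissue comparisons — the failure
mode the neuronal-origin filter exists to catch. With symmetric
contamination glial genes are never significant and the filter is exercised
vacuously; the filter scenarios therefore use bias 1.75 with fraction 0.2.

The comparison-table generator flips each differential gene's direction
with probability `1 − concordant_fraction`, giving exact control of the
expected trend concordance; ratio magnitudes are log-uniform on
`2^[0.5, 3]` so the two-fold threshold separates the counts non-trivially.

What passing these simulations does *not* show: robustness to per-gene
dispersion heterogeneity, batch effects, length biases within a gene,
isoform-level ambiguity, or real ortholog-mapping noise — none of which the
generator emulates. Results on real data depend on those factors.

## Problem sizes and numerical choices

The test suite and acceptance script use 5000-gene null simulations for
calibration, 2000 genes at depth 100 / dispersion 0.05 for fold-2 recovery,
1500 genes for the contamination scenario, 4000-gene Monte-Carlo batches
per power grid point, and 1000 differential genes for concordance recovery;
the whole suite runs in a few seconds on one CPU. Dispersion floors at
1e-8; the dispersion trend fit falls back to a flat median below 10
informative genes; BH caps at 1; top-k ranking breaks FPKM ties by
identifier order; `log2fc` ties at exactly 0 classify as `up_b` (never
observed off the degenerate all-zero case, which is flagged separately).

## Known limitations

- The Wald normal approximation is slightly liberal even with true
  dispersion at 6 vs 4 replicates (~0.054 at nominal 0.05); the trend floor
  compensates on average but the test is not exact at small n.
- The NB stage assumes a shared dispersion structure; strongly
  heteroskedastic genes will be over- or under-shrunk.
- Symbol-based ortholog matching silently drops genes whose symbols differ
  between species or datasets; `n_compared` is reported so the denominator
  is always visible.
- The power formula ignores multiple-testing correction, so its "power"
  corresponds to a per-gene test at size α, not an FDR-adjusted discovery
  probability.
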