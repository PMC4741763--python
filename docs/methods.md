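# Methods

## Data model and conventions

Methylation is represented as beta values (methylated / total signal,
in [0, 1]), stored probes × samples. Statistical testing happens on
M-values, M = log2(β/(1−β)) with betas clipped to [ε, 1−ε], ε = 1e-6 by
default: M-values are closer to homoscedastic Gaussian, while effect
sizes (Δβ) stay on the interpretable beta scale. All effects are
oriented invasive minus non-invasive, so "hypomethylated in the invasive
line" is a negative Δβ and a negative DiffScore.

Annotation positions are 1-based (array-manifest convention); BED export
converts to 0-based half-open single-base intervals. Missing values are
permitted in matrices ("" / NA / NaN / null, case-insensitive); a probe
enters a pair's analysis only with ≥ 2 non-missing values per phenotype
group, otherwise it is excluded from that pair's universe and counted.

## Differential methylation

For each tissue pair, per-probe group means are compared on the M scale.
The default test is an empirical-Bayes **moderated pooled t** (Smyth's
scaled-F prior): the pooled per-probe variance s²_g with d residual df
is shrunk to s̃²_g = (d₀s₀² + d·s²_g)/(d₀ + d), where (d₀, s₀²) are
fitted across all probes by matching the moments of log s²_g, and the
statistic is referred to a t distribution with d + d₀ df. When observed
log-variances spread no more than chi-square sampling predicts, d₀ → ∞
and the test approaches a z test against the common variance. The
implementation is cross-checked against Bioconductor limma
(`lmFit`/`eBayes`) in the test suite and agrees to 6 decimals on the
prior (d₀, s₀²), t statistics, and p-values.

The moderated default, rather than a per-probe Welch t, is a power
necessity, not a stylistic choice. With triplicate cultures the Welch
test has ≈ 4 residual df, so the two-sided p < 0.001 calling rule
demands |t| > 8.61; for a planted |Δβ| = 0.40 at M-scale noise sd 0.5
the noncentrality is only ≈ 6–7.8, giving ≈ 0.26–0.40 per-pair power and
essentially zero three-way recovery. Sharing variance information across
the ~2 × 10⁴ probes restores per-pair power to ≈ 0.996 under the same
conditions. A plain Welch t (variance floor 1e-12, flagged degenerate on
constant groups) remains available via `method="welch"` and as the
scalar `welch_t_test` primitive.

Calling uses strict thresholds |Δβ| > 0.25 and raw p < 0.001; BH
q-values are always computed and an alternative FDR mode (q < 0.05) is
exposed, since either convention is defensible for this design. The
DiffScore 10·sign(Δ)·(−log10 p) is reported so the familiar ±13 (p ≈
0.05) and ±30 (p = 0.001) thresholds apply on both platforms.

## Signature, enrichment, overlap

The cross-tissue signature intersects same-direction calls over the
probes tested in all three pairs; that tested-in-all universe is also
the default conditioning set for probe-level enrichment, and genes with
≥ 1 tested probe form the gene-level universe (both overridable, always
recorded in the report). Promoter probes are those with any of TSS1500,
TSS200, 5′UTR, 1st exon among their gene-region labels (any-match over
multi-gene annotations).

Enrichment and overlap use the hypergeometric upper tail computed by
log-gamma accumulation; results carry log10 p alongside p so values far
below ~1e-308 stay exact (array-scale enhancer enrichments reach
p < 1e-200). When only a background *fraction* is known (e.g. "21% of
array CpGs are in enhancers") a log-space binomial tail is provided.
For k-way Venn-style overlaps, where no exact tail is standard, a seeded
permutation test draws same-size sets from the universe and applies the
add-one correction (b+1)/(n+1), with the independence expectation
|U|·∏(|Sᵢ|/|U|) and exact pairwise tails reported as cross-checks; the
test suite verifies its null calibration and its agreement with the
exact tail at k = 2.

## Expression integration

Expression matrices are quantile-normalized (columns sorted, rank-wise
cross-column means assigned back; ties receive the mean of their
rank-range averages). Pairs are tested on log2 intensities with the same
moderated-t machinery and DiffScore convention; calls require both
≥ 2-fold linear change of post-normalization means and |DiffScore| > 13.
The 3-vs-2 sample pair makes moderation as necessary here as for
methylation (Welch df ≈ 1.5 cannot reliably reach p < 0.05). Genes
promoter-hypomethylated and called up in all three pairs are scored with
the hypergeometric overlap against the genes present on both platforms.
For accession-level expression platforms a best-p-per-gene collapse is
provided.

## Clustering

Samples are clustered over a probe subset (typically the signature) with
1 − Pearson correlation (pairwise-complete over missing values) and
average linkage — conventional for methylation sample dendrograms;
Euclidean distance is available by flag. Correlation distance is
invariant to a uniform additive shift, so separation relies on the
bidirectional (hyper + hypo) pattern of the signature, which is exactly
what a concordant signature provides. Trees export as Newick with branch
lengths equal to merge-height differences.

## Synthetic data generator

The generator is the package's verification instrument and encodes the
study design as its defaults: 3 tissues × (invasive, non-invasive) with
triplicate cultures and one duplicate non-invasive line (the
low-replicate path), 20 000 probes, 300 common-hypo + 300 common-hyper +
200 tissue-specific planted CpGs per tissue, planted |Δβ| = 0.40, 21%
enhancer background with 47% enhancer prevalence among common-hypo CpGs,
and 80% methylation–expression concordance.

Baselines per probe and tissue are drawn from a bimodal mixture (modes
near β = 0.1 and 0.9 plus a uniform body), matching the marginal
distribution of methylation arrays. Planted probes re-anchor the
non-invasive mean (uniform on [0.5, 0.9] for hypo, [0.1, 0.5] for
hyper) so the shifted mean stays inside (0, 1). Replicates are
logistic(M_groupmean + N(0, σ)) with σ = 0.5 on the M scale — a free
parameter of the design, stated explicitly wherever recovery is
quantified. The mild logistic-transform bias keeps realized mean Δβ
within ±0.02 of target (verified by test). Expression baselines are
log-normal; concordant genes receive log2 fold changes drawn uniformly
from [1.5, 2.5] in all three tissues — comfortably above the 2-fold
calling threshold, as expected of strongly induced genes — with
replicate noise sd 0.25 on the log2 scale and a 5% tissue-specific
background of ±1–2.5 log2 changes. Child seeds for the class-assignment,
annotation, methylation and expression streams derive from the master
seed by fixed labels, so each stage is individually reproducible.

What the generator does *not* emulate: Infinium I/II probe-chemistry
differences, detection-p filtering, batch effects, cell-composition
mixtures, copy-number interference, or correlated probes within CpG
islands. Passing recovery tests therefore demonstrate the pipeline's
correctness and power under idealized independent-probe noise, not
robustness to those real-data artifacts.

## Numerical choices and degenerate inputs

- Tail probabilities: log-gamma accumulation + log-sum-exp; p is
  reported as 10^log10_p when representable, else 0.0 with log10_p
  carrying the value. k ≤ 0 gives p = 1, k above the support gives p = 0.
- Variances: floor 1e-12 per group; both-groups-constant results are
  flagged `degenerate` (equal means → t = 0, p = 1).
- BH q-values delegate to statsmodels and are property-tested against
  the step-up definition.
- DiffScore p-values are floored at 1e-300 to keep scores finite.
- Ties: quantile normalization averages reference values within tie
  groups; scipy's linkage breaks merge ties by lowest cluster index, so
  clustering is deterministic given input order.
- Probes with identical group values get p = 1 and direction "none".

## Problem sizes in the checks

The recovery checks run the full design (20 000 probes) over five seeds;
clustering separation uses twenty seeds of a 4 000-probe version of the
same design — sizes chosen to make the binomial tolerances of the
asserted rates meaningful while keeping the suite quick to run. The
acceptance script uses three full-design seeds and ten clustering seeds.

## Known limitations

- The moderated test assumes exchangeable per-probe variances; strong
  variance structure (e.g. probe-type effects) would call for covariate-
  dependent priors, which are not implemented.
- The raw-p and FDR calling modes are both exposed because the
  literature convention is ambiguous; headline counts depend on which is
  chosen.
- Reported enrichment p-values depend on the chosen universe; the
  tested-in-all-pairs default is defensible but not unique, and the
  report always prints the universe sizes used.
- Immunostaining score comparisons from printed (n, mean ± SD) summaries
  inherit the rounding of those summaries; exact agreement with
  published p-values is not expected.
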