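# Methods

`sigforest` implements a paired tumor/normal expression-analysis chain for
squamous cell carcinoma of the larynx/hypopharynx and similar designs:
depth normalization, three differential-expression (DE) contrasts,
symbolic fold-change encoding, a seeded random-forest ensemble that
searches for a minimal subsite-discriminative gene signature, and the
ΔΔCt quantifications used for wet-lab validation (qPCR, qMSP). A
synthetic-data generator with planted truth makes every stage testable
without sequencing data.

## Data model

Counts are raw integer reads, genes × samples, with a sample sheet giving
each sample a pair identity, a condition (`tumor`/`normal`) and a class
label (`A` = larynx/hypopharynx-like, `B` = oral-cavity-like). Paired
operations require each pair to contain exactly one tumor and one normal.

## Normalization

Size factors are median-of-ratios: for sample *j*,
s_j = median_g c_gj / (∏_k c_gk)^{1/n}, the median taken over genes with a
strictly positive count in every sample (genes with any zero are excluded
from the reference — the standard convention that keeps the estimator
finite without pseudocounts). The median is taken on the ratio scale;
implementations that interpolate even-length medians on the log scale
differ only in that interpolation. Normalization is undefined when no
gene is expressed in all samples; the error suggests filtering or
pseudocounts rather than guessing.

## Fold changes and D/U/X encoding

Per pair p and gene g, FC(g,p) = (t̂ + c)/(n̂ + c) with t̂, n̂ the
normalized tumor and normal counts and pseudocount c = 0.5 (configurable).
The pseudocount keeps FC finite at zero-count normals and cancels exactly
when both members are zero (FC = 1). Encoding maps FC < 1−tol → `D`,
FC > 1+tol → `U`, else `X`. The default tol = 0 is the literal rule;
since FC = 1 is essentially measure-zero on normalized data, `X` is rare
unless a tolerance band is set.

## Differential expression

Three interpretations: `TN_P` (matched tumors vs matched normals),
`TN_UP` (all tumors vs all normals) and `T_P` (one contrast per pair).
Each gene is tested with a conditional negative-binomial test. The two
group sums of normalized counts are modeled as NB variables whose mean
and variance are moment-matched (including the shot-noise contribution
of reciprocal size factors); conditional on their rounded total, the
group-A sum follows the renormalized product of the two NB pmfs, and the
two-sided p-value sums all splits no more likely than the observed one.
The NB size parameter is capped at 1e8, beyond which the pmf is
numerically Poisson.

Dispersion is estimated per gene by method of moments on normalized
counts, α̂ = (s² − q·ξ)/q² with s² the within-group pooled variance, q
the grand mean and ξ the mean reciprocal size factor. Raw gene-wise
values at ~10 pairs are noisy enough to inflate the type-I error, so by
default they are replaced by a parametric mean-dispersion trend
α(q) = a₀ + a₁/q fitted across genes by a gamma GLM (`mode="trend"`);
`mode="gene"` restores the raw floored estimates. The fit falls back to
the median raw estimate when fewer than 50 genes are usable. Single-pair
contrasts carry no replication and borrow the per-gene trend dispersion
pooled across all samples.

Reported log2FC compares pseudocounted group means of normalized counts
(positive = up in tumor). Benjamini–Hochberg adjustment is applied
within each interpretation (delegated to statsmodels); the
genes-of-interest selection is the union over interpretations at
padj ≤ 0.05, ordered by minimal padj.

A caveat measured here and worth knowing: each interpretation's own FDR
is controlled at 5%, but the union over TN_P, TN_UP and the per-pair
contrasts concentrates false positives that do not replicate across
interpretations, so the union's false-discovery proportion is looser
(≈0.1–0.15 in our planted simulations at 13 pairs) even though recovery
of planted effects is essentially complete.

## Signature discovery

Observations are pairs; features are the D/U/X symbols of candidate
genes, indicator-expanded as three unordered categories per gene (no
ordinal embedding is assumed). Labels are binary: positive =
larynx/hypopharynx-type. Candidates are typically pre-filtered to
well-expressed genes: low-count genes have fold-change noise so heavy
that their symbols are chance marker mimics. One extraction runs per
seed:

1. A stratified subsample of the training pairs is drawn (default 80%
   per class) — the stability-selection perturbation that makes
   recurrence across seeds meaningful: a real signature survives every
   subsample, a chance correlation does not.
2. A ranking forest (default 500 trees, seeded by the ensemble seed,
   default feature subsampling) is grown on all candidate genes over
   the subsample; genes are ranked by impurity importance summed over
   their three indicator columns, with exact importance ties (typically
   all-zero importances) broken at random per seed so uninformative
   genes cannot recur by name order.
3. Starting from the top-`max_set_size` prefix, backward elimination
   repeatedly drops the gene whose removal best preserves
   (out-of-bag balanced accuracy, out-of-bag sensitivity), as long as
   the drop does not worsen that pair; elimination stops at two genes.
   The surviving set is the seed's predictive set and its sensitivity
   (percent of positive pairs recovered) is its S.

Two deliberately asymmetric choices keep the objective honest. First,
balanced accuracy — not sensitivity — drives the elimination:
sensitivity alone is maximized by the degenerate always-positive
classifier (and under a wide no-change band most symbol patterns are
uninformative, making that degenerate solution cheap), while balanced
accuracy scores it at 50. Sensitivity remains the reported S and the
quantity the signature score rewards. Second, the forests are
unweighted: balanced class weights tip large uninformative leaves
toward the minority positive class, which again manufactures high
sensitivity out of no signal; unweighted trees resolve those leaves to
the majority (negative) class.

Pairs a forest was trained on are always judged out-of-bag — a
memorized forest cannot trivially report S = 100 — and pairs outside
the training subsample by direct prediction; a `resubstitution` flag
restores literal re-prediction. Subset evaluation refits a bagging
forest (no feature subsampling within the small refit set, default 200
trees) seeded by the ensemble seed. Every extraction is a pure function
of (data, labels, seed, config); reruns are manifest-identical.

Identical sets are aggregated: ni = number of seeds extracting the set,
S = mean of their sensitivities, and the signature score is

    R = S · ni / ng,

ng the set size. R rewards sets that detect well, recur across seeds and
stay small; with 500 seeds, S ≤ 100 and ng ≥ 2 the ceiling is
100·500/2 = 25000. Candidates are ranked by R, ties to smaller sets then
lexicographic gene order.

## ΔΔCt quantifications

qPCR: log2FC = −[(Ct_gene,T − Ct_ACTB,T) − (Ct_gene,N − Ct_ACTB,N)], the
2^−ΔΔCt quantity on the log2 scale against the beta-actin housekeeping
assay; negative = down in tumor. qMSP: percent methylation =
100·Qm/(Qm+Qu) with Qm = 2^−(Ct_M,target − Ct_M,ACTB) and Qu its
unmethylated-primer analogue. Amplification efficiency is fixed at 100%
(factor 2 per cycle); technical replicates collapse by mean Ct before
differencing. Both statistics are invariant to per-sample Ct shifts and
antisymmetric/complementary as the algebra requires.

## Synthetic data

The generator emulates the discovery-study conditions: negative-binomial
counts (variance μ + αμ², α default 0.1) with baseline means log-uniform
on [5, 5000] to span the regimes where median-of-ratios is well- and
ill-behaved; per-sample size factors log-uniform on [0.5, 2]; a
`de_fraction` of genes shifted in all tumors by a constant signed
`de_log2fc_mean`; and signature genes shifted in class-A tumors only,
so that the classes differ in tumor/normal fold change, not raw
expression — mirroring the classifier's feature space. Signature genes
draw their baselines from the well-expressed range [200, 2000]: a
usable expression marker is by construction detectably expressed.

The default signature pattern is a mosaic: the positive-class tumors
partition round-robin over the signature genes and each tumor strongly
expresses only its assigned marker (8-fold, `signature_log2fc = 3`) —
the heterogeneous, near-mutually-exclusive behavior of marker families
such as cancer-testis antigens. The mosaic is what makes a planted
signature genuinely minimal: under uniform planting the genes are
mutually redundant and any two of them classify as well as all three,
so no selection principle can prefer the full set; under the mosaic,
dropping any gene forfeits the positive pairs only it covers. A
`signature_pattern="uniform"` mode keeps the fully redundant variant.
At 11 positive pairs, sub-2-fold effects are additionally
unidentifiable against the most chance-extreme null genes (a binomial
extreme at n = 11 mimics a large encoded-rate gap), and a signature
that cannot beat chance extremes is not a signature. One root seed
drives hierarchical per-stage RNG streams, so runs are bitwise
reproducible.

Ct fixtures are built by inverting the ΔΔCt algebra exactly, with
optional Gaussian cycle noise; at zero noise the assay operations
recover the planted log2FC and methylation fractions to machine
precision (generator/analysis closure).

What the generator does not emulate: GC/length biases, batch effects,
library-preparation artifacts, correlated gene modules, isoforms, or
amplification-efficiency variation in PCR. Passing tests therefore
demonstrate correctness of the algorithms under the stated model, not
robustness to those real-data features.

## Problem sizes used in validation

The packaged test suite exercises the DE calibration at 5000 genes × 10
pairs (type-I error within [0.04, 0.06] at p < 0.05; 20 replicates for
the null FDR check) and the signature-recovery study on a 60-gene
universe (~35 well-expressed candidates) with an 11-vs-29 pair
structure, a planted mosaic trio, up-calls beyond 3-fold
(encoding tol = 2), 100 ensemble seeds, ranking and evaluation forests
of 50 trees and max_set_size 4 — sizes chosen so the whole study runs
on a single desk-scale CPU while leaving the statistical conclusions
unchanged; the ensemble defaults (500 seeds, 500 trees, max_set_size
10) remain the production settings. Label-permutation nulls in that
study are drawn with chance-level overlap to the true classes, since a
permutation that happens to retain half the true positives is not a
null.

## Known limitations

- The NB test targets calibration, not exact numerical parity with any
  particular DE package; shrunken fold-change estimators and covariate
  designs are out of scope.
- The union selection rule inflates the union FDP (see above).
- Out-of-bag sensitivity of a set selected on the same pairs retains
  selection bias. The ensemble's defenses are the per-seed pair
  subsampling (no chance set survives resampling often, so ni stays
  small under the null) and unweighted forests (uninformative regions
  predict the majority class, so null sensitivity collapses instead of
  inflating); permuted-label top scores then sit near zero.
- Single-pair (T_P) contrasts have power only for large effects and rely
  entirely on the pooled dispersion trend.
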