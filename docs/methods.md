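# Methods

## Problem and approach

`gpmkit` looks for digenic disease signals in case-control genotype
data: pairs of DNA variants whose *joint* genotype distribution differs
between affected and unaffected individuals even when neither variant
shows a marginal (single-variant) effect. Instead of pruning the search
with frequent-pattern heuristics, every variant pair — and, at a finer
grain, every genotype pair — is tested exhaustively; the pair id range
is split into contiguous chunks so the scan parallelizes trivially and
deterministically.

## The variant-pair interaction test

For a pair of biallelic variants with genotypes coded 0 (A/A), 1 (A/B),
2 (B/B), the 3×3 genotype table per phenotype group carries 8 df: 2 + 2
for the two main effects and 4 for interaction. The scan isolates the
interaction component with likelihood-ratio (G-test) statistics

G² = 2 Σⱼ nⱼ log(nⱼ / eⱼ),

computed for the case table, the control table, and their cellwise sum,
and forms

C = G²_case + G²_ctrl − G²_case+ctrl.

Under the null of equal interaction structure in both groups, C is
referred to χ²(4). Main effects shift rows/columns of both tables the
same way and cancel in C, so the test is insensitive to single-variant
association.

Numerical conventions: natural logarithms; 0·log 0 ≡ 0; cells in
all-zero rows/columns are structurally empty and excluded from the
expected-count screen. A pair is "analyzable" only if every expected
count in all three G² computations reaches a configurable limit
(default 1.0). Simpson-type configurations can make C ≤ 0; the
statistic is reported as computed and p is clamped to 1, which is
conservative.

Multiplicity: p_B = min(1, p · M_t), where M_t counts the pairs that
actually passed the screen (computed in a second pass after the scan,
since the screen is data-driven).

## Genotype-pair (pattern) tests

Each variant pair contributes up to nine genotype pairs. For a pattern
X the unit of testing is the 2×2 table of phenotype × presence with
cells a, b, c, d, where the "absent" column is obtained from
*known-genotype* totals: the scan first builds a 4×4 table treating
"missing" as a fourth genotype, then restricts to the 3×3 known
subtable, so an individual missing at either variant contributes to
neither column. This exact missing-data accounting is the reason the
test count (the Bonferroni multiplier) is exact rather than an upper
bound.

Patterns with support a+c below a minimum (default 10) are not tested;
a minimum confidence a/(a+c) can be imposed on top (default 0, i.e. no
restriction). Support-0 patterns are never tested since confidence is
undefined there. Tests: Pearson chi-square (1 df, no continuity
correction, with the same expected-count screen as above) or Fisher's
exact test — F2 (one-sided, pattern enriched in cases), F1 (one-sided,
enriched in controls), F3 (two-sided by the point-probability rule,
with a 1e-7 relative tolerance for floating-point ties between equally
likely tables). The tested-pattern count is specific to the configured
test, because only the chi-square run screens expected counts.

Effect size: Haldane-corrected odds ratio
OR = (a+½)(d+½)/[(b+½)(c+½)] and the direction-free OR′ = max(OR,
1/OR). The per-pair drill-down (`pairsnps`) reports all nine patterns
of one pair ranked by OR′.

## Pair numbering and parallelism

Pairs are numbered 1..M, M = N(N−1)/2, in nested-loop order. The
inverse map id → (i, j) uses the closed-form triangular-root with an
integer correction step (O(1), exact for arbitrary ints; verified
against the loop enumeration for all N ≤ 200). Workers receive
contiguous id ranges of size ⌈M/t⌉ (the last possibly smaller or
empty); chunk results are concatenated in id order before ranking, so
results are bit-for-bit identical for any worker count. Chromosome
filtering compares labels by string equality — `"1"` and `"chr1"`
differ by design; normalization is the reader's job.

## Empirical ROC

Reading pattern presence as a phenotype predictor (F2 predicts "case",
F1 predicts "control") turns each 2×2 table into a decision matrix with
TPR = a/(a+b) and FPR = c/(c+d) (roles swapped for F1). The best
`top_k` patterns by the matching Fisher p (default 100) give a point
cloud that is condensed into `n_classes` equal-width FPR bins (default
20). Each nonempty bin is plotted at its members' mean (FPR, TPR);
empty bins are filled by linear interpolation at their midpoints, which
places them on the existing polyline and leaves the area unchanged;
anchors (0,0) and (1,1) are always present; AUC is the trapezoid-rule
area. Plotting nonempty bins at the mean FPR rather than the bin
midpoint was a deliberate choice: it makes a single perfect pattern
(FPR 0, TPR 1) yield AUC exactly 1 and a diagonal cloud exactly 0.5,
which midpoint abscissae cannot. De-duplication of patterns sharing a
variant is available behind a flag (`dedupe_variants`) and off by
default.

## Synthetic data generator

The generator emulates the data regime the scans assume: unrelated
individuals, independent biallelic background variants in
Hardy-Weinberg proportions (genotype ~ Binomial(2, MAF), per-variant
MAF uniform in `maf_range`), an exact number of cases and controls, and
MCAR missingness applied after phenotype assignment.

A planted digenic effect is a 3×3 table of odds multipliers over the
genotype pairs of one variant pair, feeding a logistic model
odds(case | g₁, g₂) = θ · R[g₁, g₂]. The intercept θ is bisected so the
marginal case probability hits n_case/(n_case+n_ctrl); individuals are
then drawn in batches and kept in draw order until both groups are
full, giving exact group sizes (rejection sampling from the correct
conditional distribution).

`pure_interaction_table(strength, maf1, maf2)` builds R = 1 + ε·u₁u₂ᵀ
with u the *carrier indicator* (0, 1, 1) centered at its Hardy-Weinberg
mean — i.e. dominant-coded epistasis, the canonical planted model in
epistasis-detection simulation studies. Rank-1 centered perturbations
make the HWE-weighted row and column means exactly 1, so single-variant
genotype distributions are identical in cases and controls in
expectation and the signal is visible only to interaction tests; ε is
solved in closed form so the max/min cell ratio equals `strength`
(all cells stay positive). The dominance coding concentrates the effect
contrast on common carrier classes rather than rare double
homozygotes, which is also what gives the default conditions
(strength 6, MAF 0.3, 500/500 individuals, 50 variants) their high
detection power. The logistic link is nonlinear, so the planted pair's
marginal null-ness is exact on the odds scale and approximate (very
close) on the probability scale.

What the generator does *not* emulate: linkage disequilibrium between
variants, population structure/relatedness, genotyping error,
informative missingness, and main-effect variants. Passing tests
therefore demonstrate correctness of the statistics and the machinery
on idealized data, not robustness to confounding in real cohorts; on
real data, LD pruning and the cross-chromosome filter are the intended
mitigations.

## Problem sizes used in the test suite

The suite exercises the full pipeline at desk scale: the published
worked-example pair as a 146-individual two-variant dataset; simulated
scans with 10–50 variants and 80–500 individuals per group; 50 seeds
for the planted-pair recovery rate and 8 pooled null replicates
(~9,800 analyzable pairs) for type-I calibration; Fisher tests checked
exhaustively against a hypergeometric enumeration oracle for all 2×2
tables with cells ≤ 6 plus 600 random tables with grand total ≤ 60;
pair-id inversion checked against the loop enumeration for every
N ≤ 200. These sizes were chosen so the whole suite runs in well under
a minute while every statistical claim is still measured, not assumed.

## Known limitations

- The χ²(4) reference for C is asymptotic; the expected-count screen
  (default limit 1) is the only small-sample guard, exactly as in the
  scan design. Pattern-level chi-square inherits the same caveat;
  Fisher variants do not.
- p_B is Bonferroni over data-driven test counts; no FDR alternative is
  provided.
- Quantitative phenotypes, covariates and permutation-based corrections
  are out of scope.
- The TSV reader loads the full matrix into memory; for large PLINK
  filesets the bed decoding is vectorized but also memory-resident
  (one byte per genotype after decoding).
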