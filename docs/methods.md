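# Methods

## The analysis

`hetvig` analyses a parent–parent–hybrid ("trio") RNA-seq design. For
each cross, three pairwise differential-expression comparisons are run on
raw counts — hybrid vs maternal line, hybrid vs paternal line, paternal
vs maternal line — and each gene's triple of calls, together with its
normalized means, is mapped to an expression class describing how the
hybrid relates to its parents. Phenotype-level heterosis is summarized
separately from line means. The package's statistics are described below
in the order the pipeline applies them.

## Count model and differential expression

Counts are modelled as negative binomial with variance μ + αμ², the
overdispersion α shared between the two groups of one comparison.

**Normalization.** Size factors use the median-of-ratios rule: for every
gene with nonzero counts in all samples, the ratio of each sample's count
to the gene's geometric mean is formed, and s_j is the per-sample median
of these ratios (linear-space median; for an even number of genes the two
middle ratios are averaged arithmetically). Matrices in which no gene is
expressed in every sample are rejected with advice to pre-filter rather
than silently dropping samples.

**Dispersion.** With z = k/s the normalized counts, Var(z) ≈
μ·mean(1/s) + αμ², so the per-gene moment estimate is
(pooled within-group variance − μ·mean(1/s)) / μ², floored at zero.
A parametric trend α(μ) = a₀ + a₁/μ is fitted across genes by least
squares (coefficients floored at zero) and the working dispersion is
max(own estimate, trend value). This sharing rule is deliberately
conservative: it protects the exact test against the severe variance
underestimation of 3-replicate moment estimates at the cost of power
(in null simulations the realized false-call rate is far below the
nominal 5%). Designs without any 2-replicate group fall back to a
"blind" pooled estimate across all samples, with a logged warning,
since treatment signal then inflates α.

**Exact test.** The test conditions on the pooled total S of the two
group sums. Each group sum is a sum of independent NB variables with
per-replicate means q·s_j (q the pooled normalized mean) and common α;
it is approximated by a single NB matched to the summed mean and summed
variance. With α = 0 both marginals are Poisson and the approximation is
exact — the conditional law is then Binomial(S, μ_A/(μ_A+μ_B)). The
two-sided p-value sums the probabilities of all splits (a, S−a) whose
joint probability does not exceed the observed split's; ties are included
with a relative tolerance of 1e-8 so that exactly symmetric splits (e.g.
a balanced total under equal size factors) count as ties rather than
falling to floating-point noise. An all-zero gene is assigned p = 1.

**Multiple testing.** Benjamini–Hochberg step-up, applied within each of
the three comparisons separately (per-comparison adjustment is the
default of the count-based exact-test tools this family follows; a joint
adjustment across the trio would change the DEG universe definition).
Significance is padj < 0.05 with no fold-change filter.

## Expression-class decision table

Calls are written c_fm, c_fp, c_mp ∈ {up, down, ns}, "up" meaning the
second-named member is higher. The table, evaluated in order:

1. all three ns → `nonDEG`;
2. c_fm = c_fp = up → transgressive up: class 3 (c_mp = up), 7 (ns), 10 (down);
3. c_fm = c_fp = down → transgressive down: class 6 (up), 8 (ns), 5 (down);
4. c_fp = ns, c_fm ≠ ns, c_mp ≠ ns → ELD toward the paternal parent:
   class 2 (paternal higher) or 11 (paternal lower);
5. c_fm = ns, c_fp ≠ ns, c_mp ≠ ns → ELD toward the maternal parent:
   class 4 (maternal higher) or 9 (maternal lower);
6. all three significant with opposite-direction hybrid calls and the
   hybrid mean strictly between the parents → additive: class 1
   (maternal < paternal) or 12 (maternal > paternal);
7. anything else → `conflicting`.

The function is total over all 27 call combinations × mean orderings and
deterministic; swapping parental roles permutes 2↔4, 11↔9, 3↔10, 6↔5,
1↔12 and fixes 7, 8, nonDEG and conflicting (tested exhaustively).

Two conventions are choices rather than forced facts. First, the
category-to-class-set mapping (additive {1,12}; ELD-paternal {2,11};
ELD-maternal {4,9}; up {3,7,10}; down {5,6,8}; low-parent dominance in 9
and 11) is fixed; the numbering *within* a category's set (e.g. which of
3/7/10 gets which parent ordering) follows the convention above, and all
summaries and tests bind at the category level. Second, `additive`
demands significance in all three comparisons *and* strict betweenness;
call combinations with opposite hybrid calls but a hybrid mean outside
the parental range are sent to `conflicting` rather than forced into a
class, because the twelve classes are mutually exclusive and no residual
class exists for such patterns.

**Zero-read exclusion.** Genes with zero counts across every replicate of
at least one line are set aside before classification (`excluded`); no
within-line signal exists for them and the exact test's size-factor
scaling degenerates. A stricter variant — exclude on any single zero
sample — is available via `zero_rule="any"`.

**DEG universe.** The DEG set of a cross is every non-excluded gene
significant in at least one of the three comparisons; category
proportions are reported over this set and sum to one. The common
dominance set is the intersection across crosses of genes in classes
{2, 4, 9, 11}.

**Clustering.** Samples are clustered by average linkage on
1 − Pearson correlation of RPKM values (RPKM = C·10⁹/(N·L); when
per-sample mapped-read totals are not supplied, column sums of the count
matrix stand in for them). Samples are sorted by identifier before
linkage so tie-breaks are reproducible; constant samples are rejected
because their correlation is undefined.

## Phenotype heterosis

MPV = (P1 + P2)/2 and RH = 100·(F1 − MPV)/MPV. Significance of F1
against the mid-parent uses the normal contrast
z = (F1 − MPV)/√(SE_F1² + (SE_P1² + SE_P2²)/4) with a two-sided normal
p-value, marked `**` below 0.01 and `*` below 0.05. This is a
large-sample approximation chosen for transparency; with hundreds of
individuals per line (the shipped body-weight table has n ≥ 410
everywhere) it is indistinguishable from a t-based contrast. Its
empirical type-I rate on null simulations is checked to sit in [3%, 7%]
at nominal 5%.

Printed 2-dp values use decimal half-up rounding (`round_half_up`):
binary floats place a value like 98.135 a hair below its decimal
representation, and banker's rounding would print 98.13 where summary
tables print 98.14. `heterosis_rate(round_mpv=True)` (the default in
table output) computes RH from the 2-dp-rounded MPV, matching the
convention evident in published tables where RH to 2 dp is consistent
with the rounded MPV rather than the exact one; `round_mpv=False`
retains full precision.

ΔΔCt relative expression for qPCR-style validation is
2^−ΔΔCt with ΔΔCt = (Ct_target,test − Ct_ref,test) −
(Ct_target,ctrl − Ct_ref,ctrl).

## Length-bias-corrected enrichment

Longer genes accumulate more reads and are more likely to be called DE at
a fixed true effect. The probability weighting function (PWF) estimates
P(DE | length): genes are ranked by length and split into up to 40
equal-occupancy bins, the per-bin DE fraction is smoothed by isotonic
(pool-adjacent-violators) regression on bin median length, and each gene
gets its bin's fitted value clipped to (1e-6, 1 − 1e-6). Binned isotonic
regression replaces a monotone spline fit: it is deterministic,
dependency-light and converges to the same monotone regression function
as gene count grows. With a single bin (all lengths equal) every gene
receives the overall DE fraction.

A term's bias odds is mean(PWF inside term) / mean(PWF outside); the
over-representation p-value is P(X ≥ k) under Wallenius' noncentral
hypergeometric (the biased-urn law of drawing n genes without replacement
with weight ∝ PWF), evaluated with `scipy.stats.nchypergeom_wallenius`.
Odds within 1e-12 of 1 are snapped to exactly 1, where the distribution
reduces analytically to the central hypergeometric and the tail is
evaluated in closed form. The tail is validated in tests against exact
enumeration (central case) and a 200,000-draw vectorized urn simulation
(noncentral case). A plain central hypergeometric test is available for
pathway-style analyses. BH adjustment runs within each ontology
separately; the flagging threshold defaults to 0.05 and is a parameter.

## Synthetic data generator

The generator emulates a three-line inbred cross experiment: for each
cross a maternal line, paternal line and F1 hybrid with `n_reps`
biological replicates each, and per-gene true means fixed by the gene's
class. With base mean b and fold change fc (parents that differ do so by
exactly fc):

| category | hybrid mean |
|---|---|
| additive (1, 12) | (μ_m + μ_p)/2 |
| ELD (2, 11, 4, 9) | the matched parent's mean |
| transgressive up (3, 7, 10) | fc · max(μ_m, μ_p) |
| transgressive down (5, 6, 8) | min(μ_m, μ_p)/fc |

Transgressive-down means divide rather than subtract so means stay
positive and the design is symmetric with transgressive-up. Counts are
NB(s_j·μ, α) with per-sample size factors drawn uniformly from
`size_factor_range`; α = 0 falls back to Poisson. One integer seed
drives everything; per-gene generator sub-streams are derived from
(seed, cross index, gene index) so output is independent of gene order
and identical across reruns.

Defaults mirror the emulated study design and desk-scale validation:
2 replicates per line as in the emulated design (the validation analyses
use 3), base mean 200 (a comfortably detected mid-expression gene),
fold change 4, dispersion 0.01 (tight biological replication of inbred
lines), size factors in [0.8, 1.2] (modest library-size variation). The
fixed fold change is a stand-in for the unknown effect-size distribution
of real DEGs, not an estimate of it.

**What passing tests do and do not show.** The generator realizes the
class geometry exactly, uses a single dispersion for all genes, no
outliers, no batch or sex structure, no length-expression coupling, and
annotation terms independent of class. Recovery rates near 95% on this
data demonstrate the pipeline's statistical machinery is correct and
calibrated, not that real tissue comparisons achieve that accuracy;
real data adds dispersion heterogeneity, composition shifts and
correlated genes that this design deliberately omits. The phenotype
generator draws iid normal body weights, matching how line summaries
(mean ± SE, n) are consumed downstream.

## Numerical choices

- Exact-test tie tolerance: relative 1e-8 on split probabilities
  (log-space comparison); probability sums via `logsumexp`.
- Group sums with estimated variance ≤ mean are treated as Poisson.
- Dispersion trend coefficients floored at zero; genes with zero base
  mean get α = 0.
- PWF clipping ε = 1e-6; odds snapped to 1 within 1e-12.
- TSV output uses `%.10g` floats so identical runs are byte-identical.
- BH is a vectorized step-up (`minimum.accumulate` over reversed ranked
  values); NaN inputs are rejected rather than propagated.

## Problem sizes

The validation analyses use 1200 genes × 3 crosses × 9 samples for
category recovery, 2000 genes for null calibration, and 2000 replications
of n = 500 normal samples for the mid-parent test's type-I rate; all are
chosen as comfortable desk-scale sizes at which the binomial error of the
measured rates is a fraction of the margins being asserted.

## Known limitations

- The exact test approximates unequal-size-factor group sums by one
  moment-matched NB; this is exact for α = 0 and accurate for the small
  α of inbred-line replication, but is not the GLM route one would take
  for designs with covariates.
- The dispersion trend α(μ) = a₀ + a₁/μ is a two-parameter stand-in for
  a local-regression fit; with max(gene, trend) sharing it errs
  conservative.
- The mid-parent contrast is asymptotic; with very small line samples a
  permutation or t-based variant should replace it (the formula is
  isolated in `mpv_significance_test` for exactly that reason).
- The classifier's `conflicting` bucket absorbs call patterns the twelve
  classes do not cover; on real data its size is a useful diagnostic of
  threshold miscalibration.
- Enrichment treats terms as flat gene sets: no ontology graph
  propagation or pathway topology.
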