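# Methods

## Quantification model

The package quantifies relative gene expression from threshold cycles (CT)
and per-gene amplification factors (E, the per-cycle amplification, 2 =
perfect doubling).  Every statistic is computed on the efficiency-weighted
delta-CT scale

    wdCT = log2(E_target)·CT_target − log2(E_ref)·CT_ref,

a log2-scale quantity.  Relative expression within a condition is
RE = 2^−(mean wdCT) (delta-CT method); fold change between a condition and a
calibrator is FC = 2^−(mean wdCT_Tr − mean wdCT_Co) (delta-delta-CT method).
Two identities pin the arithmetic down and are enforced as property tests:
with all E = 2 the results equal the classical Livak 2^-ddCT formula
exactly, and with gene-wise constant efficiencies they equal the Pfaffl
efficiency-corrected ratio to machine precision.

The modelling assumption is that RE and FC are lognormal, equivalently that
wdCT is normal on the log2 scale.  Inference (t-tests, linear and mixed
models, marginal-mean contrasts) therefore runs on wdCT, and the final
back-transformation y = 2^−x is applied to point estimates and interval
endpoints only.  Standard errors are reported both on the log2 scale (`se`)
and as the asymmetric back-transformed band

    Lower.se = 2^(log2(FC) − se),   Upper.se = 2^(log2(FC) + se),

which is multiplicatively symmetric around the estimate.  Confidence limits
use the two-sided t quantile at the contrast's degrees of freedom rather
than the normal quantile, because qPCR designs are small (3–6 biological
replicates per cell is typical).

**Two reference genes.**  When a second reference gene is present, the two
weighted reference terms are averaged on the log2 scale before subtraction,
which is equivalent to normalising against the geometric mean of the
reference quantities.  (Summing instead of averaging would change the scale
of wdCT; the averaged form keeps wdCT comparable between one- and
two-reference tables.)

## Statistical procedures

**t-test fold change** (two conditions, any number of target genes).  Each
target observation is paired with the same-replicate reference
observation(s) by row order within its (condition, gene) cell — the layout
carries no explicit replicate column, so row order *is* the pairing, which
is stated loudly here and in the docstrings.  The test compares treatment
vs control wdCT per gene: pooled-variance by default, Welch
(`var_equal=False`) or paired (`paired=True`) on request.  p-values across
genes are Benjamini–Hochberg adjusted by default; significance marks
(`**` ≤ 0.01, `*` ≤ 0.05, `.` ≤ 0.1) follow the adjusted values whenever
adjustment is on.  Identical noiseless groups return the degenerate
FC 1 / p 1 row; zero variance in both groups with a nonzero difference is
an error because no t-test is defined there.

**ANOVA / ANCOVA fold change.**  The wdCT response is fitted with the full
factorial of all factor columns (ANOVA) or the main factor plus the other
factors as additive covariates, no interactions (ANCOVA).  The biological
replicate — and the block, when present — enters as a random intercept;
crossed random terms are expressed as variance components.  Marginal means
of the main factor are computed on an equal-weight reference grid
(balanced-population definition, matching the usual estimated-marginal-means
convention), and each level is contrasted against the calibrator.  The
calibrator's own row reports FC 1 with p 1 (and LCL/UCL written as 0, the
publication-table convention).  If any interaction involving the main factor
is significant at alpha, a warning is attached, since main-factor
comparisons alone can then mislead.

**Relative-expression ANOVA.**  One row per factor-level combination with
RE, back-transformed se band and t interval, plus a compact letter display
of all pairwise contrasts at alpha = 0.05; rows are sorted by RE descending
and letters assigned in that order.  The model-based se drives the reported
bands; the SD of the back-transformed raw per-replicate values is carried
separately (`replicate_sd`) because the two answer different questions
(precision of the mean vs spread of replicates).

**Repeated measures.**  Fixed time (crossed with treatment when present)
with a random intercept per individual, so time contrasts are estimated
within individuals; per-individual baseline offsets cancel exactly in
balanced designs, which the tests verify on noiseless data with large
simulated id offsets.

**Marginal-mean comparisons** (`qpcr_means`) accept a main effect
(`"f1"`), interaction cells (`"f1:f2"`) or slices (`"f1 | f2"`), return all
pairwise contrasts back-transformed to ratio scale, BH-adjusted by default.

**Compact letter display** uses the insert-and-absorb algorithm.  Its
defining property — two means share at least one letter **iff** their
pairwise p ≥ alpha — holds exactly and is tested against brute-force clique
enumeration on all matrices with up to five groups.

**Residual diagnostics**: Shapiro–Wilk on residuals and the median-centred
(Brown–Forsythe) Levene test across factor cells, with QQ and
residual-vs-fitted plot data.  When an assumption looks violated the report
names the standard non-parametric alternatives (Mann–Whitney,
Kruskal–Wallis) without executing them; they are out of scope.

## Mixed-model numerics

Mixed models are REML fits (statsmodels MixedLM).  A single random
intercept uses the grouped formulation; multiple intercepts (replicate +
block) are crossed variance components on one group.  The default
statsmodels optimizer (lbfgs) was found to stop at wrong REML optima on
small balanced designs, so fits run bfgs → powell → cg in sequence; on a
balanced test design the resulting contrast estimate, standard error and
df agree with the reference mixed-model implementation in R (lme4/lmerTest
with emmeans) to at least four significant figures — the test suite runs
that cross-check through Rscript.

Degrees of freedom for contrasts: statsmodels provides no Satterthwaite
approximation, so the package charges each random intercept its level
degrees of freedom, df = n − k_fixed − Σ(q_j − 1).  In balanced designs
this equals the Satterthwaite/classical denominator df (verified against
lmerTest), and it is conservative relative to the naive n − k_fixed.

Degenerate cases fall back to fixed-effects OLS with a warning: boundary
REML fits (all variance components ≈ 0), non-convergence, or a response
with (near-)zero variance.  With noiseless data the OLS covariance is
clamped to zero and contrasts report p = 1 for zero differences and p = 0
otherwise; ANOVA F for a term with signal over a zero residual is reported
as infinite with p = 0.

Marginal means are built from the patsy design matrix of the fitted model
evaluated on the full factor grid, so they are consistent between OLS and
mixed fits and respect ANCOVA's additive structure.

## Standard curves

Efficiency is estimated by ordinary least squares of CT on log10 template
amount; E = 10^(−1/slope), percent efficiency (E − 1)·100; both are
reported since conventions differ.  A slope of −3.3219 cycles per decade ⇔
E = 2 ⇔ 100 %.  The dilution column may hold dilution fractions (1, 0.1, …)
or raw quantities — both are log10-transformed; pass `x_scale="log10"` for
already-logged values (auto-detection treats non-positive values as
logged).  Slope comparisons come from one joint model CT ~ log10(q) × gene,
so every pairwise slope contrast shares the pooled residual error
(ANCOVA-style); p-values are BH-adjusted beyond one pair.  A perfect
(zero-residual) joint fit makes the comparison degenerate: p is reported as
1 for zero slope differences instead of dividing by a numerically-zero se.

## Synthetic data generator

The generator realises exactly the model above: for each cell and
biological replicate it draws wdCT = −log2(true RE) + block effect +
replicate effect + N(0, noise_sd), writes a stable reference CT, and solves
the target CT from the wdCT definition, so noiseless data invert to the
true RE/FC at machine precision through any estimator in the package.
Block, replicate and individual effects are normal on the log2 scale and
crossed with the design (shared across cells), which is what the random
intercepts absorb.

Defaults describe a routine qPCR experiment: 3 biological replicates per
cell, wdCT noise SD 0.25 log2 units (≈ ±19 % on the expression scale),
reference CT 25 cycles, efficiencies 2.0, reference-CT jitter 0 so that
ground truth lives entirely in the target gene.  What the generator does
*not* emulate: raw amplification curves and CT-calling noise, pipetting
correlation between target and reference wells, inhibition or probe
chemistry, missing reactions, and reference-gene instability.  Passing
tests therefore demonstrate correctness of the estimators under the stated
lognormal model, not robustness to assay artefacts — that is what the
residual diagnostics are for on real data.

Simulation-based checks in the test suite use these sizes: 200 datasets for
confidence-interval coverage (true FC 4, noise SD 0.25, n = 6), 1000
datasets for type-I error (true FC 1, noise SD 0.3, n = 5), 50 random
instances for the t-test oracle, 300 random matrices (≤ 5 groups) for the
letter display; the full suite runs in well under a minute.

## Known limitations

- Missing values are rejected, never imputed; technical replicates are
  averaged on the CT scale before analysis.
- The mixed-model df rule is exact for balanced designs only; unbalanced
  designs get a conservative approximation rather than per-contrast
  Satterthwaite.
- ANOVA tables use type-II sums of squares (OLS) or per-term Wald F tests
  (mixed), which differ from type-I on unbalanced data.
- Efficiencies are taken as given (from standard curves or the user);
  per-reaction efficiency estimation from fluorescence traces, absolute
  quantification, non-parametric tests and reference-gene stability
  selection are out of scope.
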