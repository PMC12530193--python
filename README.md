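# qpcrkit

Statistical analysis of quantitative real-time PCR (qPCR) CT data:
efficiency-weighted relative quantification, fold-change and
relative-expression statistics, amplification-efficiency estimation from
dilution series, and publication-style tables and bar plots.

qpcrkit is for molecular biologists who have threshold-cycle (CT) values and
per-gene amplification efficiencies (E) from experiments with up to three
factors — treatment series, genotype panels, time courses with repeated
measures — and who want calibrated fold changes with honest standard errors,
confidence limits and multiple-comparison summaries, rather than a bare
2^-ddCT spreadsheet.

## The model

All inference happens on the **efficiency-weighted delta-CT** scale:

```
wdCT = log2(E_target) · CT_target − log2(E_ref) · CT_ref
```

Relative expression (delta-CT method) and fold change (delta-delta-CT
method) are back-transformations of means of wdCT:

```
RE = 2^−(mean wdCT)            FC = 2^−(mean wdCT_Tr − mean wdCT_Co)
```

Because RE and FC are lognormal, wdCT is normal, so t-tests and linear
(mixed) models apply directly on the wdCT scale; point estimates, standard
errors and confidence limits are transformed through `y = 2^−x` only at the
reporting step, giving the asymmetric bounds

```
Lower.se = 2^(log2(FC) − se)      Upper.se = 2^(log2(FC) + se)
```

With every `E = 2` the machinery reduces exactly to the classical Livak
2^-ddCT method; with gene-wise constant efficiencies it is algebraically
identical to the Pfaffl ratio (both identities are enforced by tests).
Amplification efficiencies come from standard curves: `E = 10^(−1/slope)` of
the regression of CT on log10 template amount, with pairwise slope
comparisons between genes from a single joint model.

Designs with more than two levels or factors are analysed with ANOVA (full
factorial) or ANCOVA (main factor plus additive covariates) on wdCT, with
the biological replicate — and the block and, for repeated measures, the
individual — as random intercepts; marginal means are compared against a
calibrator level (fold change) or pairwise with compact-letter-display
grouping (relative expression).

## Worked example

```python
from qpcrkit import SyntheticSpec, generate_dataset, anova_fc

spec = SyntheticSpec(
    design={"factor1": ["L1", "L2", "L3"]},
    true_re={"L1": 1.0, "L2": 2.0, "L3": 8.0},
    n_rep=3, noise_sd=0.2, seed=12,
)
fit, rows = anova_fc(generate_dataset(spec), main_factor="factor1",
                     calibrator="L1")
for r in rows:
    print(f"{r.label}: FC={r.fc:.4f}  se(log2)={r.se_log2:.4f}  "
          f"[{r.lower_se:.4f}, {r.upper_se:.4f}]  p={r.p_value:.4f} {r.sig}")
```

prints

```
L1: FC=1.0000  se(log2)=0.1098  [0.9267, 1.0791]  p=1.0000
L2 vs L1: FC=2.3179  se(log2)=0.1553  [2.0813, 2.5814]  p=0.0015 **
L3 vs L1: FC=7.8769  se(log2)=0.1553  [7.0729, 8.7723]  p=0.0000 **
```

The calibrator level L1 is 1 by definition; L2 and L3 are estimated fold
changes relative to L1 (true values 2 and 8), the bracketed interval is the
back-transformed one-standard-error band, and `**` marks p ≤ 0.01.  More
walkthroughs — t-test fold changes across genes, relative expression with
letter groups, repeated measures, standard curves, technical-replicate
averaging and file I/O — live in `examples/`.

A thin CLI wraps the same functions:

```
qpcrkit simulate --layout anova --levels 3 --seed 7 --out sim
qpcrkit anova-fc --input sim_data.csv --calibrator L1 --out results
qpcrkit ttest --input mydata.csv --no-var-equal --p-adjust BH --out fc
```

## Input layouts

Delimited text (comma/tab/semicolon) with a header row, columns mapped
positionally: factor column(s) first, then an optional block, the biological
replicate, and the E/CT block — target gene first, then one or two
reference genes.  The t-test layout is `condition, gene, E, Ct` with the
control level first and the reference gene(s) last; repeated measures use
`id, [treatment], time, E/CT…`; dilution series use a dilution column
followed by one CT column per gene.  See `qpcrkit.datamodel` for details
and validation rules.

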