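"""Relative expression per condition with letter grouping.

A 2x2 factorial (genotype x dose) is simulated and each cell's relative
expression (delta-CT method, target vs reference within the cell) is
estimated; all pairwise comparisons are summarised as compact letters.
"""

import warnings

from qpcrkit import SyntheticSpec, anova_re, generate_dataset

spec = SyntheticSpec(
    design={"geno": ["S", "R"], "dose": ["0", "0.5"]},
    true_re={("S", "0.5"): 3.0, ("S", "0"): 0.8},
    n_rep=3,
    noise_sd=0.15,
    seed=13,
)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    fit, rows = anova_re(generate_dataset(spec))

for r in rows:
    print(
        f"{' / '.join(r.levels):10s} RE={r.re:.4f}  "
        f"[{r.lower_se:.4f}, {r.upper_se:.4f}]  {r.letter}"
    )

# Rows are sorted by RE, descending.  Conditions that share no letter
# differ significantly at alpha = 0.05; here the induced S/0.5 cell stands
# apart from the rest.
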