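"""Two-condition fold change of several target genes via t-tests.

Simulates control/treatment CT data for three target genes (true fold
changes 4, 1 and 0.5) plus one reference gene, then tests each gene on the
efficiency-weighted delta-CT scale.
"""

from qpcrkit import generate_ttest_dataset, ttest_fc

table = generate_ttest_dataset(
    n_genes=3, n_rep=4, true_fc=[4.0, 1.0, 0.5], noise_sd=0.25, seed=11
)
for row in ttest_fc(table, var_equal=True, p_adjust="BH"):
    print(
        f"{row.label}: FC={row.fc:.3f}  95% CI [{row.lcl:.3f}, {row.ucl:.3f}]  "
        f"p={row.p_value:.4f}  p_adj={row.p_adj:.4f} {row.sig}"
    )

# FC > 1 means the gene is up-regulated in the treatment relative to the
# control after normalising to the reference gene; the BH-adjusted p tells
# you whether that change survives correction across the three genes.
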