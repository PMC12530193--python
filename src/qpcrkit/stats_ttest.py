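"""Two-condition fold-change analysis via t-tests on wdCT values.

For each target gene, every observation is paired by row order with the
same-replicate reference observation(s) to form an efficiency-weighted
delta-CT, and treatment is compared to control with a two-sample (pooled or
Welch) or paired t-test on that log2 scale.  The mean difference is
back-transformed to a fold change, FC = 2**(-(mean_Tr - mean_Co)), with
standard-error bounds and a t-based confidence interval.  p-values across
genes are Benjamini-Hochberg adjusted by default.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import core
from .datamodel import TTestTable
from .results import FCResult, sig_mark

__all__ = ["ttest_fc", "welch_ttest", "adjust_pvalues"]

_ADJUST_METHODS = {
    "bh": "fdr_bh",
    "fdr_bh": "fdr_bh",
    "by": "fdr_by",
    "holm": "holm",
    "bonferroni": "bonferroni",
    "hommel": "hommel",
    "sidak": "sidak",
}


def adjust_pvalues(p, method: str = "BH"):
    """Multiple-testing adjustment of a p-value vector (order preserving).

    ``method="BH"`` is the Benjamini-Hochberg step-up procedure; ``"none"``
    returns the input unchanged.  Adjusted values are >= the raw values and
    capped at 1.
    """
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if method.lower() == "none":
        return p.tolist()
    key = method.lower()
    if key not in _ADJUST_METHODS:
        raise ValueError(f"unknown adjustment method {method!r}")
    if p.size == 0:
        return []
    return multipletests(p, method=_ADJUST_METHODS[key])[1].tolist()


def welch_ttest(group_a, group_b):
    """Welch two-sample t-test (unequal variances).

    Returns ``(t, df, p)`` with the Welch-Satterthwaite degrees of freedom.
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 observations")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def _gene_wdct(table: TTestTable, gene: str, condition: str) -> np.ndarray:
    """wdCT values for one gene in one condition, paired by row order."""
    df = table.data
    sel = lambda g: df[
        (df[table.condition_col].astype(str) == condition)
        & (df[table.gene_col].astype(str) == g)
    ]
    tgt = sel(gene)
    refs = [sel(rg) for rg in table.ref_genes]
    n = len(tgt)
    for r in refs:
        if len(r) != n:
            raise ValueError(
                f"gene {gene!r}: target and reference replicate counts differ "
                f"in condition {condition!r}"
            )
    if table.n_ref == 2:
        return np.asarray(
            core.weighted_dct(
                tgt[table.e_col].to_numpy(), tgt[table.ct_col].to_numpy(),
                refs[0][table.e_col].to_numpy(), refs[0][table.ct_col].to_numpy(),
                refs[1][table.e_col].to_numpy(), refs[1][table.ct_col].to_numpy(),
            )
        )
    return np.asarray(
        core.weighted_dct(
            tgt[table.e_col].to_numpy(), tgt[table.ct_col].to_numpy(),
            refs[0][table.e_col].to_numpy(), refs[0][table.ct_col].to_numpy(),
        )
    )


def ttest_fc(
    table: TTestTable,
    paired: bool = False,
    var_equal: bool = True,
    p_adjust: str = "BH",
    conf_level: float = 0.95,
) -> list[FCResult]:
    """Fold-change t-test of every target gene, treatment vs control.

    Parameters
    ----------
    table
        Validated two-condition layout; the control level comes first and
        the reference gene(s) last.
    paired
        Treat the i-th treatment and control replicates as paired.
    var_equal
        Pooled-variance test when True, Welch when False (ignored when
        ``paired``).
    p_adjust
        Adjustment applied across target genes (default Benjamini-Hochberg,
        ``"none"`` to disable).  Significance marks use the adjusted values
        whenever adjustment is on.
    conf_level
        Two-sided confidence level for the back-transformed interval.

    Returns
    -------
    list of FCResult
        One row per target gene, in the table's gene order.
    """
    if table.n_rep < 2:
        raise ValueError("t-tests need >= 2 biological replicates per cell")
    co, tr = table.control, table.treatment
    rows = []
    for gene in table.target_genes:
        w_co = _gene_wdct(table, gene, co)
        w_tr = _gene_wdct(table, gene, tr)
        if paired and len(w_co) != len(w_tr):
            raise ValueError(
                f"gene {gene!r}: paired test requires equal replicate counts"
            )
        diff = float(np.mean(w_tr) - np.mean(w_co))
        if np.var(w_co) == 0 and np.var(w_tr) == 0:
            if abs(diff) > 1e-12:
                raise ValueError(
                    f"gene {gene!r}: zero variance in both groups; "
                    "the t-test is undefined"
                )
            # degenerate but well-defined: identical noiseless groups
            rows.append(
                FCResult(label=gene, fc=1.0, lcl=1.0, ucl=1.0, p_value=1.0,
                         p_adj=1.0, se_log2=0.0, lower_se=1.0, upper_se=1.0)
            )
            continue
        if paired:
            d = w_tr - w_co
            se = float(np.std(d, ddof=1) / np.sqrt(len(d)))
            df = len(d) - 1
            t = diff / se if se > 0 else np.inf * np.sign(diff)
            p = float(2 * stats.t.sf(abs(t), df)) if se > 0 else (1.0 if diff == 0 else 0.0)
        elif var_equal:
            n1, n2 = len(w_tr), len(w_co)
            sp2 = (
                (n1 - 1) * np.var(w_tr, ddof=1) + (n2 - 1) * np.var(w_co, ddof=1)
            ) / (n1 + n2 - 2)
            se = float(np.sqrt(sp2 * (1 / n1 + 1 / n2)))
            df = n1 + n2 - 2
            t = diff / se if se > 0 else np.inf * np.sign(diff)
            p = float(2 * stats.t.sf(abs(t), df)) if se > 0 else (1.0 if diff == 0 else 0.0)
        else:
            t, df, p = welch_ttest(w_tr, w_co)
            n1, n2 = len(w_tr), len(w_co)
            se = float(
                np.sqrt(np.var(w_tr, ddof=1) / n1 + np.var(w_co, ddof=1) / n2)
            )
        fc = core.fold_change(np.mean(w_tr), np.mean(w_co))
        lower_se, upper_se = core.se_bounds(fc, se)
        lcl, ucl = core.confidence_bounds(fc, se, max(df, 1), level=conf_level)
        lcl, ucl = min(lcl, ucl), max(lcl, ucl)
        rows.append(
            FCResult(
                label=gene, fc=fc, lcl=lcl, ucl=ucl, p_value=p, p_adj=p,
                se_log2=se, lower_se=lower_se, upper_se=upper_se,
            )
        )
    padj = adjust_pvalues([r.p_value for r in rows], method=p_adjust)
    for r, pa in zip(rows, padj):
        r.p_adj = float(pa)
        r.sig = sig_mark(r.p_adj if p_adjust.lower() != "none" else r.p_value)
    return rows
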