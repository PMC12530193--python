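"""Amplification-efficiency estimation from dilution series.

A standard curve regresses CT on log10 of the template amount.  Its slope
gives the per-cycle amplification factor

    E = 10 ** (-1 / slope)

so a slope of -3.3219 cycles per decade corresponds to E = 2 (100 percent
efficiency).  Slopes of several genes are compared in one joint linear model
(CT ~ log10(dilution) crossed with gene) so that pairwise slope contrasts
share a pooled error term, ANCOVA style.
"""

from __future__ import annotations

import warnings
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .results import EfficiencyResult, SlopeComparison
from .stats_ttest import adjust_pvalues

__all__ = [
    "fit_standard_curve",
    "efficiency_table",
    "compare_slopes",
    "standard_curve_plot_data",
]


def _log_quantity(x, x_scale: str = "auto") -> np.ndarray:
    """Convert the dilution column to log10 template quantity.

    ``x_scale``:
      - ``"dilution"``: values are dilution factors/quantities; take log10.
      - ``"log10"``: values are already log10 quantities; use as-is.
      - ``"auto"``: treat as already-logged quantities only when the values
        are non-positive or wider-than-decade integers are absent... in
        practice: values all <= 1 and positive -> dilution fractions
        (log10); any value > 1 -> quantities (log10); any value <= 0 ->
        already log10.
    """
    x = np.asarray(x, dtype=float)
    if x_scale == "log10":
        return x
    if x_scale == "dilution" or x_scale == "auto":
        if x_scale == "auto" and np.any(x <= 0):
            return x  # log-scale quantities can be zero or negative
        if np.any(x <= 0):
            raise ValueError("dilution factors must be positive")
        return np.log10(x)
    raise ValueError(f"unknown x_scale {x_scale!r}")


def fit_standard_curve(
    dilution: Sequence[float],
    ct: Sequence[float],
    gene: str = "target",
    x_scale: str = "auto",
) -> EfficiencyResult:
    """Ordinary least squares of CT on log10(dilution) for one gene.

    Returns the slope (cycles per decade), intercept, R^2, the amplification
    factor E = 10**(-1/slope) and percent efficiency (E - 1) * 100.
    A positive slope (CT rising with template amount) draws a warning but
    the fit is still returned.
    """
    x = _log_quantity(dilution, x_scale)
    y = np.asarray(ct, dtype=float)
    if len(x) != len(y):
        raise ValueError("dilution and ct must have equal length")
    if len(x) < 3:
        raise ValueError("need >= 3 points to fit a standard curve")
    if len(np.unique(x)) < 2:
        raise ValueError("all dilutions identical: the fit is singular")
    fit = stats.linregress(x, y)
    slope, intercept = float(fit.slope), float(fit.intercept)
    r2 = float(fit.rvalue) ** 2
    if slope >= 0:
        warnings.warn(
            f"gene {gene!r}: non-negative standard-curve slope {slope:.4f}; "
            "CT should fall as template amount rises",
            stacklevel=2,
        )
    e = float(10.0 ** (-1.0 / slope)) if slope != 0 else float("nan")
    return EfficiencyResult(
        gene=gene,
        slope=slope,
        intercept=intercept,
        r_squared=r2,
        e=e,
        percent_efficiency=(e - 1.0) * 100.0,
    )


def efficiency_table(table: pd.DataFrame, x_scale: str = "auto") -> list[EfficiencyResult]:
    """Fit every gene CT column of a dilution-series table.

    First column is the dilution; each remaining column is one gene.
    """
    cols = list(table.columns)
    if len(cols) < 2:
        raise ValueError("need a dilution column plus >= 1 gene CT column")
    return [
        fit_standard_curve(table[cols[0]], table[g], gene=g, x_scale=x_scale)
        for g in cols[1:]
    ]


def compare_slopes(
    table: pd.DataFrame,
    x_scale: str = "auto",
    p_adjust: str = "BH",
) -> list[SlopeComparison]:
    """Pairwise slope comparisons between genes from one joint model.

    Fits CT ~ log10(dilution) * gene over the long-format stack of all gene
    columns; each pairwise slope difference is an interaction contrast with
    the model's pooled residual error.  p-values are BH-adjusted when more
    than one pair is tested.
    """
    genes = list(table.columns[1:])
    if len(genes) < 2:
        raise ValueError("slope comparison needs >= 2 gene CT columns")
    x = _log_quantity(table.iloc[:, 0], x_scale)
    long = pd.concat(
        [
            pd.DataFrame({"logq": x, "ct": table[g].to_numpy(float), "gene": g})
            for g in genes
        ],
        ignore_index=True,
    )
    long["gene"] = pd.Categorical(long["gene"], categories=genes)
    res = smf.ols("ct ~ logq * gene", data=long).fit()
    names = list(res.params.index)
    slope_vec = {}
    for g in genes:
        v = np.zeros(len(names))
        v[names.index("logq")] = 1.0
        inter = f"logq:gene[T.{g}]"
        if inter in names:
            v[names.index(inter)] = 1.0
        slope_vec[g] = v

    perfect_fit = res.ssr < 1e-10 * max(1.0, float(res.centered_tss))
    rows, pvals = [], []
    for ga, gb in combinations(genes, 2):
        L = slope_vec[ga] - slope_vec[gb]
        diff = float(L @ res.params.to_numpy())
        se = float(np.sqrt(L @ res.cov_params().to_numpy() @ L))
        if perfect_fit or se == 0.0 or not np.isfinite(se):
            p = 1.0 if abs(diff) < 1e-8 else 0.0
            warnings.warn(
                f"slope comparison {ga} vs {gb}: zero residual variance; "
                "p-value is degenerate",
                stacklevel=2,
            )
        else:
            t = diff / se
            p = float(2 * stats.t.sf(abs(t), res.df_resid))
        rows.append((ga, gb, diff, se))
        pvals.append(p)
    padj = adjust_pvalues(pvals, method=p_adjust) if len(pvals) > 1 else list(pvals)
    return [
        SlopeComparison(ga, gb, diff, se, p, pa)
        for (ga, gb, diff, se), p, pa in zip(rows, pvals, padj)
    ]


def standard_curve_plot_data(
    table: pd.DataFrame,
    results: Optional[list[EfficiencyResult]] = None,
    x_scale: str = "auto",
) -> dict:
    """Deterministic plot-ready series for the standard curves.

    Returns ``{gene: {"x": ..., "ct": ..., "line_x": ..., "line_y": ...,
    "annotation": "slope=..., E=..., R2=..."}}`` with 4-significant-figure
    annotations.  Rendering is a pure serialisation of this structure.
    """
    if table.shape[1] < 2 or table.shape[0] == 0:
        raise ValueError("empty dilution-series table")
    if results is None:
        results = efficiency_table(table, x_scale=x_scale)
    x = _log_quantity(table.iloc[:, 0], x_scale)
    out = {}
    for r in results:
        line_x = np.array([x.min(), x.max()])
        out[r.gene] = {
            "x": x,
            "ct": table[r.gene].to_numpy(float),
            "line_x": line_x,
            "line_y": r.intercept + r.slope * line_x,
            "annotation": (
                f"slope={r.slope:.4g}, E={r.e:.4g}, R2={r.r_squared:.4g}"
            ),
        }
    return out
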