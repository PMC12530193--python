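"""Result-row containers shared by the statistics modules."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd


def sig_mark(p: float) -> str:
    """Significance mark: ``**`` at p<=0.01, ``*`` at p<=0.05, ``.`` at p<=0.1."""
    if np.isnan(p):
        return ""
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    if p <= 0.1:
        return "."
    return ""


@dataclass
class FCResult:
    """One fold-change row (gene, or contrast of a factor level vs calibrator)."""

    label: str
    fc: float
    lcl: float
    ucl: float
    p_value: float
    p_adj: float
    se_log2: float
    lower_se: float
    upper_se: float
    sig: str = ""


@dataclass
class REResult:
    """One relative-expression row for a factor-level combination."""

    levels: tuple
    re: float
    lcl: float
    ucl: float
    se_log2: float
    lower_se: float
    upper_se: float
    letter: str = ""
    p_value: float = float("nan")
    replicate_sd: float = float("nan")  # SD of back-transformed raw per-replicate REs


@dataclass
class EfficiencyResult:
    """Standard-curve fit of one gene: CT regressed on log10(dilution)."""

    gene: str
    slope: float
    intercept: float
    r_squared: float
    e: float
    percent_efficiency: float


@dataclass
class SlopeComparison:
    """Pairwise difference between two genes' standard-curve slopes."""

    gene_a: str
    gene_b: str
    slope_difference: float
    se: float
    p_value: float
    p_adj: float


def fc_frame(results: list[FCResult], style: str = "contrast") -> pd.DataFrame:
    """Fold-change results as a DataFrame in publication column order.

    ``style="gene"`` uses the t-test table order
    (Gene, FC, LCL, UCL, p value, ...); ``style="contrast"`` uses the ANOVA
    fold-change order (Contrast, FC, p value, sig, LCL, UCL, ...).
    """
    base = {
        "FC": [r.fc for r in results],
        "p value": [r.p_value for r in results],
        "p adj": [r.p_adj for r in results],
        "sig": [r.sig for r in results],
        "LCL": [r.lcl for r in results],
        "UCL": [r.ucl for r in results],
        "se": [r.se_log2 for r in results],
        "Lower.se": [r.lower_se for r in results],
        "Upper.se": [r.upper_se for r in results],
    }
    labels = [r.label for r in results]
    if style == "gene":
        order = ["Gene", "FC", "LCL", "UCL", "p value", "p adj", "sig",
                 "se", "Lower.se", "Upper.se"]
        base["Gene"] = labels
    else:
        order = ["Contrast", "FC", "p value", "p adj", "sig", "LCL", "UCL",
                 "se", "Lower.se", "Upper.se"]
        base["Contrast"] = labels
    return pd.DataFrame(base)[order]


def re_frame(results: list[REResult], factor_names: Optional[list[str]] = None) -> pd.DataFrame:
    """Relative-expression results as a DataFrame in publication column order."""
    if not results:
        return pd.DataFrame()
    k = len(results[0].levels)
    names = factor_names or [f"Factor{i + 1}" for i in range(k)]
    out = {names[i]: [r.levels[i] for r in results] for i in range(k)}
    out.update(
        {
            "RE": [r.re for r in results],
            "LCL": [r.lcl for r in results],
            "UCL": [r.ucl for r in results],
            "se": [r.se_log2 for r in results],
            "Lower.se": [r.lower_se for r in results],
            "Upper.se": [r.upper_se for r in results],
            "Letters": [r.letter for r in results],
        }
    )
    return pd.DataFrame(out)


def efficiency_frame(results: list[EfficiencyResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "Gene": [r.gene for r in results],
            "Slope": [r.slope for r in results],
            "Intercept": [r.intercept for r in results],
            "R2": [r.r_squared for r in results],
            "E": [r.e for r in results],
            "Efficiency%": [r.percent_efficiency for r in results],
        }
    )


def slope_comparison_frame(results: list[SlopeComparison]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "GeneA": [r.gene_a for r in results],
            "GeneB": [r.gene_b for r in results],
            "SlopeDiff": [r.slope_difference for r in results],
            "se": [r.se for r in results],
            "p value": [r.p_value for r in results],
            "p adj": [r.p_adj for r in results],
        }
    )
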