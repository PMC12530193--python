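"""Validated long-format qPCR tables and delimited-text I/O.

The supported layouts follow the column-arrangement convention used across
efficiency-weighted qPCR analyses: factor columns first, then an optional
blocking column, the biological-replicate column, and finally the E/CT
column block — target gene first, then one or two reference genes::

    factor1 [factor2 [factor3]] [block] rep targetE targetCt ref1E ref1Ct [ref2E ref2Ct]

The t-test layout is different (condition, gene, E, Ct long format with the
control condition level first and the reference gene(s) last), as is the
repeated-measures layout (id, [treatment], time, then E/CT columns) and the
dilution-series layout for efficiency analysis (dilution column followed by
one CT column per gene).

Column mapping is positional — names in the header are kept but roles are
assigned by position — and can be overridden explicitly via the keyword
arguments of :func:`read_table`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import core
from .results import (
    EfficiencyResult,
    FCResult,
    REResult,
    efficiency_frame,
    fc_frame,
    re_frame,
)

__all__ = [
    "QPCRTable",
    "TTestTable",
    "RepeatedTable",
    "SchemaError",
    "ParseError",
    "ValidationError",
    "read_table",
    "write_table",
    "write_results",
    "mean_technical_reps",
]


class SchemaError(ValueError):
    """The file's columns do not match the expected layout arrangement."""


class ParseError(ValueError):
    """A cell that must be numeric could not be parsed."""


class ValidationError(ValueError):
    """Values violate a table invariant (range, duplication, ...)."""


# ---------------------------------------------------------------------------
# table containers


def _ordered_categorical(s: pd.Series) -> pd.Categorical:
    """Categorical with levels in order of first appearance."""
    levels = list(pd.unique(s.astype(str)))
    return pd.Categorical(s.astype(str), categories=levels, ordered=True)


def _check_e_ct(df: pd.DataFrame, e_cols: Sequence[str], ct_cols: Sequence[str]) -> None:
    for c in list(e_cols) + list(ct_cols):
        v = df[c].to_numpy(dtype=float)
        if not np.all(np.isfinite(v)):
            raise ValidationError(f"column {c!r} contains non-finite values")
    for c in ct_cols:
        if np.any(df[c].to_numpy(dtype=float) <= 0):
            raise ValidationError(f"CT column {c!r} must be > 0")
    for c in e_cols:
        v = df[c].to_numpy(dtype=float)
        lo, hi = core.E_HARD_RANGE
        if np.any(v <= lo) or np.any(v > hi):
            raise ValidationError(
                f"efficiency column {c!r} outside ({lo}, {hi}]; "
                "expected amplification factors near 2"
            )
        slo, shi = core.E_SOFT_RANGE
        if np.any(v < slo) or np.any(v > shi):
            warnings.warn(
                f"efficiency column {c!r} has values outside [{slo}, {shi}]; "
                "check the standard curves",
                stacklevel=3,
            )


@dataclass
class QPCRTable:
    """Validated ANOVA/ANCOVA-layout table (1-3 factors, optional block).

    ``data`` keeps the original header names; the role columns are recorded
    alongside.  E/CT columns are, in order: targetE, targetCt, ref1E, ref1Ct
    and optionally ref2E, ref2Ct.
    """

    data: pd.DataFrame
    factor_cols: list[str]
    rep_col: str
    e_ct_cols: list[str]
    block_col: Optional[str] = None
    tech_rep_col: Optional[str] = None
    n_ref: int = 1

    def __post_init__(self):
        self.validate()

    # -- derived accessors ------------------------------------------------
    @property
    def target_e_col(self) -> str:
        return self.e_ct_cols[0]

    @property
    def target_ct_col(self) -> str:
        return self.e_ct_cols[1]

    def ref_cols(self, i: int) -> tuple[str, str]:
        """(E, CT) column names of reference gene ``i`` (1-based)."""
        return self.e_ct_cols[2 * i], self.e_ct_cols[2 * i + 1]

    def validate(self) -> None:
        df = self.data
        expect_ect = 4 + 2 * (self.n_ref - 1)
        if self.n_ref not in (1, 2):
            raise SchemaError("n_ref must be 1 or 2")
        if len(self.e_ct_cols) != expect_ect:
            raise SchemaError(
                f"expected {expect_ect} E/CT columns for {self.n_ref} reference gene(s)"
            )
        if not 1 <= len(self.factor_cols) <= 3:
            raise SchemaError("1-3 factor columns are supported")
        for c in self.factor_cols + [self.rep_col] + self.e_ct_cols:
            if c not in df.columns:
                raise SchemaError(f"column {c!r} missing from the table")
        # column-arrangement check: factors < block < rep < E/CT
        order = [df.columns.get_loc(c) for c in self.factor_cols]
        if self.block_col is not None:
            order.append(df.columns.get_loc(self.block_col))
        order.append(df.columns.get_loc(self.rep_col))
        if self.tech_rep_col is not None:
            order.append(df.columns.get_loc(self.tech_rep_col))
        order += [df.columns.get_loc(c) for c in self.e_ct_cols]
        if order != sorted(order):
            raise SchemaError(
                "column arrangement violated: factors must precede block, "
                "block precede rep, and E/CT columns come last"
            )
        e_cols = self.e_ct_cols[0::2]
        ct_cols = self.e_ct_cols[1::2]
        _check_e_ct(df, e_cols, ct_cols)
        key_cols = self.factor_cols + ([self.block_col] if self.block_col else [])
        key_cols = key_cols + [self.rep_col]
        if self.tech_rep_col:
            key_cols.append(self.tech_rep_col)
        if df.duplicated(subset=key_cols).any():
            raise ValidationError(f"duplicated observation key over columns {key_cols}")

    def wdct(self) -> pd.Series:
        """Per-row efficiency-weighted delta-CT."""
        df = self.data
        if self.n_ref == 2:
            v = core.weighted_dct(
                df[self.e_ct_cols[0]], df[self.e_ct_cols[1]],
                df[self.e_ct_cols[2]], df[self.e_ct_cols[3]],
                df[self.e_ct_cols[4]], df[self.e_ct_cols[5]],
            )
        else:
            v = core.weighted_dct(
                df[self.e_ct_cols[0]], df[self.e_ct_cols[1]],
                df[self.e_ct_cols[2]], df[self.e_ct_cols[3]],
            )
        return pd.Series(np.asarray(v), index=df.index, name="wdct")

    def analysis_frame(self) -> pd.DataFrame:
        """Factors/block/rep as ordered categoricals plus the wdct response."""
        out = pd.DataFrame(index=self.data.index)
        for c in self.factor_cols:
            out[c] = _ordered_categorical(self.data[c])
        if self.block_col:
            out[self.block_col] = _ordered_categorical(self.data[self.block_col])
        out[self.rep_col] = _ordered_categorical(self.data[self.rep_col])
        out["wdct"] = self.wdct().to_numpy()
        return out


@dataclass
class TTestTable:
    """Two-condition multi-gene layout: condition, gene, E, Ct.

    The first condition level encountered is the control; the last ``n_ref``
    gene levels encountered are the reference gene(s).  Within each
    (condition, gene) cell the i-th row is the i-th biological replicate, so
    target and reference observations are paired by row order.
    """

    data: pd.DataFrame
    n_ref: int = 1

    condition_col: str = field(init=False)
    gene_col: str = field(init=False)
    e_col: str = field(init=False)
    ct_col: str = field(init=False)

    def __post_init__(self):
        if self.data.shape[1] != 4:
            raise SchemaError(
                "t-test layout requires exactly 4 columns: "
                "condition (control level first), gene (reference gene(s) last), "
                "efficiency, Ct"
            )
        self.condition_col, self.gene_col, self.e_col, self.ct_col = self.data.columns
        self.validate()

    @property
    def conditions(self) -> list[str]:
        return list(pd.unique(self.data[self.condition_col].astype(str)))

    @property
    def genes(self) -> list[str]:
        return list(pd.unique(self.data[self.gene_col].astype(str)))

    @property
    def control(self) -> str:
        return self.conditions[0]

    @property
    def treatment(self) -> str:
        return self.conditions[1]

    @property
    def ref_genes(self) -> list[str]:
        return self.genes[-self.n_ref:]

    @property
    def target_genes(self) -> list[str]:
        return self.genes[: -self.n_ref]

    def validate(self) -> None:
        if len(self.conditions) != 2:
            raise SchemaError(
                f"exactly two condition levels required, found {self.conditions}"
            )
        if self.n_ref < 1:
            raise SchemaError("at least one reference gene is required")
        if len(self.genes) < self.n_ref + 1:
            raise SchemaError(">=2 genes with >=1 flagged as reference required")
        _check_e_ct(self.data, [self.e_col], [self.ct_col])
        counts = self.data.groupby(
            [self.condition_col, self.gene_col], observed=True
        ).size()
        if counts.nunique() != 1:
            raise ValidationError(
                "unequal observation counts per (condition, gene) cell: "
                f"{counts.to_dict()}"
            )

    @property
    def n_rep(self) -> int:
        return int(
            self.data.groupby(
                [self.condition_col, self.gene_col], observed=True
            ).size().iloc[0]
        )


@dataclass
class RepeatedTable:
    """Repeated-measures layout: id, [treatment], time, then E/CT columns.

    The same physical individual (id) is measured at every time point.
    """

    data: pd.DataFrame
    id_col: str
    time_col: str
    e_ct_cols: list[str]
    treatment_col: Optional[str] = None
    n_ref: int = 1

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        df = self.data
        _check_e_ct(df, self.e_ct_cols[0::2], self.e_ct_cols[1::2])
        key = [self.id_col, self.time_col]
        if self.treatment_col:
            key = [self.id_col, self.treatment_col, self.time_col]
        if df.duplicated(subset=key).any():
            raise ValidationError("an individual appears more than once per time point")
        per_id = df.groupby(df[self.id_col].astype(str), observed=True)[self.time_col].nunique()
        if (per_id == 1).all():
            raise ValidationError(
                "every individual is observed at a single time point only; "
                "this is not a repeated-measures design"
            )
        if (per_id == 1).any():
            singles = list(per_id.index[per_id == 1])
            warnings.warn(
                f"individuals observed at a single time point only: {singles}",
                stacklevel=3,
            )

    def wdct(self) -> pd.Series:
        df = self.data
        if self.n_ref == 2:
            v = core.weighted_dct(
                df[self.e_ct_cols[0]], df[self.e_ct_cols[1]],
                df[self.e_ct_cols[2]], df[self.e_ct_cols[3]],
                df[self.e_ct_cols[4]], df[self.e_ct_cols[5]],
            )
        else:
            v = core.weighted_dct(
                df[self.e_ct_cols[0]], df[self.e_ct_cols[1]],
                df[self.e_ct_cols[2]], df[self.e_ct_cols[3]],
            )
        return pd.Series(np.asarray(v), index=df.index, name="wdct")

    def analysis_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(index=self.data.index)
        out[self.id_col] = _ordered_categorical(self.data[self.id_col])
        if self.treatment_col:
            out[self.treatment_col] = _ordered_categorical(self.data[self.treatment_col])
        out[self.time_col] = _ordered_categorical(self.data[self.time_col])
        out["wdct"] = self.wdct().to_numpy()
        return out


# ---------------------------------------------------------------------------
# reading


def _read_delimited(path) -> pd.DataFrame:
    """Read a delimited text file, auto-detecting comma/tab/semicolon."""
    df = pd.read_csv(path, sep=None, engine="python", keep_default_na=False,
                     skipinitialspace=True)
    if df.shape[1] == 1 and df.shape[0] == 0:
        raise ParseError(f"{path}: empty or unreadable table")
    return df


def _coerce_numeric(df: pd.DataFrame, cols: Sequence[str], path) -> None:
    for c in cols:
        coerced = pd.to_numeric(df[c], errors="coerce")
        bad = coerced.isna()
        if bad.any():
            rows = list(df.index[bad][:5])
            raise ParseError(
                f"{path}: column {c!r} has non-numeric values at row(s) "
                f"{rows} (e.g. {df.loc[rows[0], c]!r}); missing values are not supported"
            )
        df[c] = coerced.astype(float)


def _looks_like_e(df: pd.DataFrame, col: str) -> bool:
    """Heuristic: a column of amplification factors lies in (1, 2.5]."""
    v = pd.to_numeric(df[col], errors="coerce")
    if v.isna().any():
        return False
    lo, hi = core.E_HARD_RANGE
    return bool((v > lo).all() and (v <= hi).all())


def _infer_n_ref(df: pd.DataFrame, n_ref: Optional[int]) -> int:
    """Decide between 4 (one ref gene) and 6 (two) trailing E/CT columns.

    E columns sit at fixed offsets from the right: one ref -> E-like at -4
    and -2 is CT... actually E columns are at -4, -2 is CT; pattern from the
    right is [E, CT, E, CT] or [E, CT, E, CT, E, CT].  Two refs require an
    E-like column at position -6 as well.
    """
    if n_ref is not None:
        return n_ref
    cols = list(df.columns)
    if len(cols) >= 8 and all(_looks_like_e(df, cols[i]) for i in (-6, -4, -2)):
        return 2
    return 1


def read_table(
    path,
    layout: str,
    *,
    n_ref: Optional[int] = None,
    n_factors: Optional[int] = None,
    block: Optional[bool] = None,
    tech_rep: bool = False,
) -> Union[QPCRTable, TTestTable, RepeatedTable, pd.DataFrame]:
    """Read a delimited text file into a validated table for ``layout``.

    Parameters
    ----------
    path
        CSV/TSV/semicolon-delimited file with a header row.
    layout
        One of ``efficiency``, ``ttest``, ``anova``, ``ancova``, ``repeated``.
        ``anova`` and ``ancova`` share the same arrangement.
    n_ref
        Number of reference genes (1 or 2); inferred from the E-like value
        range of the trailing columns when omitted.
    n_factors
        Number of leading factor columns; inferred from the column count
        when omitted.
    block
        Whether a blocking column follows the factors; inferred from a
        header name containing "block" when omitted.
    tech_rep
        Whether a technical-replicate column follows the biological-replicate
        column (layout of tables destined for :func:`mean_technical_reps`).
    """
    layout = layout.lower()
    if layout not in {"efficiency", "ttest", "anova", "ancova", "repeated"}:
        raise ValueError(f"unknown layout {layout!r}")
    df = _read_delimited(path)
    cols = list(df.columns)

    if layout == "efficiency":
        if len(cols) < 2:
            raise SchemaError(
                "efficiency layout requires a dilution column followed by "
                ">=1 gene CT column"
            )
        _coerce_numeric(df, cols, path)
        return df

    if layout == "ttest":
        if len(cols) != 4:
            raise SchemaError(
                f"t-test layout requires 4 columns "
                f"(condition, gene, efficiency, Ct); found {len(cols)}"
            )
        _coerce_numeric(df, cols[2:], path)
        return TTestTable(df, n_ref=n_ref or 1)

    if layout == "repeated":
        nr = _infer_n_ref(df, n_ref)
        n_ect = 4 + 2 * (nr - 1)
        lead = len(cols) - 1 - n_ect  # columns between id and the E/CT block
        if lead == 1:
            treatment_col = None
        elif lead == 2:
            treatment_col = cols[1]
        else:
            raise SchemaError(
                "repeated-measures layout requires id, optional treatment, "
                f"time, then {n_ect} E/CT columns; found {len(cols)} columns"
            )
        e_ct = cols[-n_ect:]
        _coerce_numeric(df, e_ct, path)
        return RepeatedTable(
            df, id_col=cols[0], time_col=cols[lead], e_ct_cols=e_ct,
            treatment_col=treatment_col, n_ref=nr,
        )

    # anova / ancova arrangement
    nr = _infer_n_ref(df, n_ref)
    n_ect = 4 + 2 * (nr - 1)
    n_lead = len(cols) - n_ect - 1 - (1 if tech_rep else 0)  # factors+block
    if block is None:
        block = any("block" in c.lower() for c in cols[:max(n_lead, 0)])
    nf = n_factors if n_factors is not None else n_lead - (1 if block else 0)
    if nf < 1 or nf > 3 or nf + (1 if block else 0) != n_lead:
        raise SchemaError(
            f"expected arrangement factor1[-factor3] {'- block ' if block else ''}"
            f"- rep {'- techRep ' if tech_rep else ''}- targetE - targetCt - "
            f"ref1E - ref1Ct{' - ref2E - ref2Ct' if nr == 2 else ''}; "
            f"found {len(cols)} columns ({cols})"
        )
    factor_cols = cols[:nf]
    block_col = cols[nf] if block else None
    rep_idx = nf + (1 if block else 0)
    rep_col = cols[rep_idx]
    tech_col = cols[rep_idx + 1] if tech_rep else None
    e_ct = cols[-n_ect:]
    _coerce_numeric(df, e_ct, path)
    return QPCRTable(
        df, factor_cols=factor_cols, rep_col=rep_col, e_ct_cols=e_ct,
        block_col=block_col, tech_rep_col=tech_col, n_ref=nr,
    )


# ---------------------------------------------------------------------------
# technical replicates


def mean_technical_reps(table: QPCRTable, groups: Optional[Sequence[str]] = None) -> QPCRTable:
    """Average technical replicates; one row per distinct grouping key.

    Each numeric E/CT column is replaced by its arithmetic mean within the
    group (averaging happens on the CT scale, before any delta-CT is formed);
    the technical-replicate column is dropped.  Re-running on the output is
    the identity.
    """
    df = table.data
    if groups is None:
        groups = table.factor_cols + (
            [table.block_col] if table.block_col else []
        ) + [table.rep_col]
    groups = list(groups)
    for g in groups:
        if g not in df.columns:
            raise KeyError(f"grouping column {g!r} not found")
    agg = (
        df.groupby(groups, sort=False, as_index=False, observed=True)[table.e_ct_cols]
        .mean()
    )
    return QPCRTable(
        agg,
        factor_cols=table.factor_cols,
        rep_col=table.rep_col,
        e_ct_cols=table.e_ct_cols,
        block_col=table.block_col,
        tech_rep_col=None,
        n_ref=table.n_ref,
    )


# ---------------------------------------------------------------------------
# writing


def write_table(table: Union[QPCRTable, TTestTable, RepeatedTable, pd.DataFrame], path) -> None:
    """Write a table back to CSV at full precision (round-trips on re-read)."""
    df = table if isinstance(table, pd.DataFrame) else table.data
    df.to_csv(path, index=False)


def write_results(results, path, style: str = "auto") -> None:
    """Write analysis results to CSV in publication column order, 4 d.p.

    ``results`` may be a list of :class:`FCResult`, :class:`REResult` or
    :class:`EfficiencyResult` rows, or a ready DataFrame.  ``style`` selects
    the fold-change column order: ``"gene"`` (t-test table), ``"contrast"``
    (ANOVA table) or ``"auto"`` (contrast order when any label reads
    "x vs y" or a calibrator row is present).
    """
    if results is None or (hasattr(results, "__len__") and len(results) == 0):
        raise ValueError("cannot write empty results")
    if isinstance(results, pd.DataFrame):
        df = results
    else:
        first = results[0]
        if isinstance(first, FCResult):
            if style == "auto":
                style = (
                    "contrast"
                    if any(" vs " in r.label for r in results)
                    else "gene"
                )
            df = fc_frame(results, style=style)
            if all(r.p_adj == r.p_value or np.isnan(r.p_adj) for r in results):
                df = df.drop(columns=["p adj"])
            if style == "gene":
                # Table-3-shaped output carries no significance-mark column
                df = df.drop(columns=["sig"])
        elif isinstance(first, REResult):
            df = re_frame(results)
        elif isinstance(first, EfficiencyResult):
            df = efficiency_frame(results)
        else:
            raise TypeError(f"unsupported result type {type(first).__name__}")
    df = df.copy()
    for c in df.columns:
        if pd.api.types.is_float_dtype(df[c]):
            df[c] = df[c].map(lambda x: f"{x:.4f}")
    df.to_csv(path, index=False)
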