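"""Linear (mixed) models on the wdCT scale.

ANOVA/ANCOVA fold-change analysis against a calibrator level,
relative-expression ANOVA with compact-letter-display grouping,
repeated-measures analysis with a random intercept per individual,
marginal-means comparisons, and residual diagnostics.

All inference happens on the efficiency-weighted delta-CT (log2) scale and
is back-transformed through 2**(-x) only for reporting.  The biological
replicate (and the block, when present) enters as a random intercept,
modelled as crossed variance components; when the random-effect variance is
degenerate or the mixed fit fails, the model falls back to fixed effects
only, with a warning.  Marginal means weight the cells of the reference
grid equally; contrast degrees of freedom are the residual df (OLS) or the
residual-df approximation n - k_fixed (mixed models).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from itertools import combinations, product
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from patsy import build_design_matrices
from scipy import stats

from . import core
from .datamodel import QPCRTable, RepeatedTable
from .results import FCResult, REResult, sig_mark
from .stats_ttest import adjust_pvalues

__all__ = [
    "ModelFit",
    "fit_wdct_model",
    "anova_fc",
    "anova_re",
    "repeated_fc",
    "qpcr_means",
    "compact_letter_display",
    "residual_diagnostics",
    "DiagnosticsReport",
]

_ZERO = 1e-12


# ---------------------------------------------------------------------------
# model container and fitting


@dataclass
class ModelFit:
    """A fitted wdCT model plus everything contrasts need."""

    formula: str
    data: pd.DataFrame            # analysis frame: categorical factors + wdct
    factor_cols: list[str]        # fixed-effect factors, in design order
    response: str
    beta: np.ndarray              # fixed-effect estimates (log2 scale)
    cov: np.ndarray               # covariance of beta
    df_contrast: float            # df used for t/F inference on contrasts
    design_info: object           # patsy DesignInfo of the fixed design
    anova: pd.DataFrame           # per-term F table (df, F, p)
    fitted: np.ndarray
    residuals: np.ndarray
    is_mixed: bool
    random_terms: list[str] = field(default_factory=list)
    result: object = None         # underlying statsmodels results object
    df_method: str = "residual"

    def levels(self, factor: str) -> list[str]:
        return list(self.data[factor].cat.categories)


def _wald_anova(beta, cov, design_info, df_resid) -> pd.DataFrame:
    """Per-term Wald F tests from the fixed-effect estimates."""
    rows = []
    for term, sl in design_info.term_name_slices.items():
        if term == "Intercept":
            continue
        idx = np.arange(sl.start, sl.stop)
        L = np.eye(len(beta))[idx]
        q = len(idx)
        Lb = L @ beta
        M = L @ cov @ L.T
        if np.all(np.abs(M) < _ZERO):
            f = np.inf if np.any(np.abs(Lb) > 1e-8) else 0.0
            p = 0.0 if np.isinf(f) else 1.0
        else:
            f = float(Lb @ np.linalg.pinv(M) @ Lb / q)
            p = float(stats.f.sf(f, q, df_resid))
        rows.append((term, q, f, p))
    return pd.DataFrame(rows, columns=["term", "df", "F", "p"]).set_index("term")


def _fixed_formula(factors: Sequence[str], analysis_type: str, main_factor: str) -> str:
    """Full factorial for ANOVA; main factor + additive covariates for ANCOVA."""
    if analysis_type == "anova":
        return "wdct ~ " + " * ".join(factors)
    others = [f for f in factors if f != main_factor]
    return "wdct ~ " + " + ".join([main_factor] + others)


def _fit(
    data: pd.DataFrame,
    formula: str,
    random_cols: Sequence[str],
    factor_cols: list[str],
) -> ModelFit:
    """Fit the mixed model, falling back to OLS when degenerate."""
    y_var = float(np.var(data["wdct"].to_numpy()))
    use_mixed = bool(random_cols) and y_var > _ZERO
    res = None
    is_mixed = False
    if use_mixed:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                if len(random_cols) == 1:
                    # single random intercept: ordinary grouped formulation
                    model = sm.MixedLM.from_formula(
                        formula, data=data, groups=data[random_cols[0]]
                    )
                else:
                    # crossed intercepts as variance components on one group
                    model = sm.MixedLM.from_formula(
                        formula, data=data, groups=np.ones(len(data)),
                        vc_formula={c: f"0 + C({c})" for c in random_cols},
                    )
                mres = model.fit(reml=True, method=["bfgs", "powell", "cg"])
            re_var = float(np.sum(np.diag(np.atleast_2d(mres.cov_re)))) + float(
                np.sum(np.asarray(mres.vcomp))
            )
            degenerate = (
                not mres.converged
                or not np.all(np.isfinite(mres.fe_params))
                or re_var < _ZERO * max(1.0, y_var)
            )
            if degenerate:
                warnings.warn(
                    "random-effect variance is degenerate; "
                    "falling back to fixed-effects-only fitting",
                    stacklevel=3,
                )
            else:
                res = mres
                is_mixed = True
        except (np.linalg.LinAlgError, ValueError):
            warnings.warn(
                "mixed-model fit failed; falling back to fixed-effects-only fitting",
                stacklevel=3,
            )

    if res is None:
        ols = smf.ols(formula, data=data)
        X = ols.exog
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            raise ValueError(
                "singular design: aliased terms among "
                f"{list(ols.data.design_info.term_names)}"
            )
        res = ols.fit()
        design_info = res.model.data.design_info
        beta = res.params.to_numpy()
        cov = res.cov_params().to_numpy()
        df_c = float(res.df_resid)
        if res.ssr < _ZERO * max(1.0, float(res.centered_tss)):
            # noiseless data: the usual scale estimate collapses to zero
            cov = np.zeros_like(cov)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                a = sm.stats.anova_lm(res, typ=2)
            anova = pd.DataFrame(
                {"df": a["df"], "F": a["F"], "p": a["PR(>F)"]}
            )
            resid_ms = a.loc["Residual", "sum_sq"] / max(a.loc["Residual", "df"], 1)
            if resid_ms < _ZERO:
                eff = anova.index != "Residual"
                big = a.loc[eff, "sum_sq"].to_numpy() > 1e-10
                anova.loc[eff, "F"] = np.where(big, np.inf, 0.0)
                anova.loc[eff, "p"] = np.where(big, 0.0, 1.0)
        except (ValueError, np.linalg.LinAlgError):
            anova = _wald_anova(beta, cov, design_info, df_c)
        fitted = np.asarray(res.fittedvalues)
    else:
        design_info = res.model.data.design_info
        k_fe = res.model.k_fe
        beta = np.asarray(res.fe_params)
        cov = np.asarray(res.cov_params())[:k_fe, :k_fe]
        # residual df after charging each random intercept its level dofs;
        # equals the Satterthwaite/classical denominator df in balanced designs
        re_df = sum(data[c].nunique() - 1 for c in random_cols)
        df_c = float(max(len(data) - k_fe - re_df, 1))
        anova = _wald_anova(beta, cov, design_info, df_c)
        X = res.model.exog
        fitted = X @ beta

    resid = data["wdct"].to_numpy() - fitted
    return ModelFit(
        formula=formula,
        data=data,
        factor_cols=list(factor_cols),
        response="wdct",
        beta=beta,
        cov=cov,
        df_contrast=df_c,
        design_info=design_info,
        anova=anova,
        fitted=np.asarray(fitted),
        residuals=resid,
        is_mixed=is_mixed,
        random_terms=list(random_cols),
        result=res,
        df_method="residual",
    )


def fit_wdct_model(
    table: QPCRTable,
    main_factor: Optional[str] = None,
    analysis_type: str = "anova",
    random_effects: bool = True,
) -> ModelFit:
    """Fit the wdCT linear (mixed) model for an ANOVA/ANCOVA-layout table.

    ``analysis_type="anova"`` fits the full factorial of all factor columns;
    ``"ancova"`` fits the main factor plus the remaining factors as additive
    covariates (no interactions).  The biological replicate and, when
    present, the block enter as crossed random intercepts; set
    ``random_effects=False`` for a plain fixed-effects fit.
    """
    analysis_type = analysis_type.lower()
    if analysis_type not in {"anova", "ancova"}:
        raise ValueError("analysis_type must be 'anova' or 'ancova'")
    factors = list(table.factor_cols)
    main_factor = main_factor or factors[0]
    if main_factor not in factors:
        raise ValueError(f"main_factor {main_factor!r} is not a factor column")
    data = table.analysis_frame()
    if data[main_factor].nunique() < 2:
        raise ValueError(f"main factor {main_factor!r} has < 2 levels")
    formula = _fixed_formula(factors, analysis_type, main_factor)
    random_cols = []
    if random_effects:
        random_cols.append(table.rep_col)
        if table.block_col:
            random_cols.append(table.block_col)
    return _fit(data, formula, random_cols, factors)


# ---------------------------------------------------------------------------
# marginal means (equal-weight reference grid)


def _reference_grid(fit: ModelFit) -> pd.DataFrame:
    levels = [fit.levels(f) for f in fit.factor_cols]
    grid = pd.DataFrame(list(product(*levels)), columns=fit.factor_cols)
    for f in fit.factor_cols:
        grid[f] = pd.Categorical(grid[f], categories=fit.levels(f), ordered=True)
    return grid


def _grid_design(fit: ModelFit, grid: pd.DataFrame) -> np.ndarray:
    return np.asarray(build_design_matrices([fit.design_info], grid)[0])


def marginal_means(
    fit: ModelFit,
    factors: Union[str, Sequence[str]],
    by: Optional[dict] = None,
) -> pd.DataFrame:
    """Equal-weight marginal means of wdCT for the requested effect.

    ``factors`` names one factor or an interaction (several factors); the
    returned rows carry the level combination, the estimated mean (log2
    scale), its standard error, and the contrast df.  ``by`` optionally
    restricts the averaging to a slice (``{other_factor: level}``).
    """
    if isinstance(factors, str):
        factors = [factors]
    for f in list(factors) + list((by or {})):
        if f not in fit.factor_cols:
            raise ValueError(f"effect {f!r} is not in the model ({fit.factor_cols})")
    grid = _reference_grid(fit)
    if by:
        mask = np.ones(len(grid), bool)
        for f, lv in by.items():
            mask &= grid[f].astype(str).to_numpy() == str(lv)
        if not mask.any():
            raise ValueError(f"slice {by!r} matches no reference-grid cell")
        grid = grid.loc[mask]
    X = _grid_design(fit, grid)
    combos = grid[list(factors)].astype(str).agg(tuple, axis=1)
    rows = []
    for combo in pd.unique(combos):
        sel = (combos == combo).to_numpy()
        L = X[sel].mean(axis=0)
        est = float(L @ fit.beta)
        se = float(np.sqrt(max(L @ fit.cov @ L, 0.0)))
        rows.append((*combo, est, se, L))
    out = pd.DataFrame(rows, columns=[*factors, "emmean", "se", "_L"])
    out.attrs["df"] = fit.df_contrast
    return out


def _contrast(fit: ModelFit, L: np.ndarray):
    """Estimate, se, t, p of a single linear contrast of the fixed effects."""
    est = float(L @ fit.beta)
    se = float(np.sqrt(max(L @ fit.cov @ L, 0.0)))
    if se < _ZERO:
        p = 1.0 if abs(est) < 1e-8 else 0.0
        t = 0.0 if abs(est) < 1e-8 else np.inf * np.sign(est)
    else:
        t = est / se
        p = float(2 * stats.t.sf(abs(t), fit.df_contrast))
    return est, se, t, p


def _fc_row(fit, label, est, se, p, p_adj, conf_level, use_adj) -> FCResult:
    fc = core.relative_expression(est)  # 2**(-est); est = mean_l - mean_cal
    lower_se, upper_se = core.se_bounds(fc, se)
    lcl, ucl = core.confidence_bounds(fc, se, max(fit.df_contrast, 1), level=conf_level)
    lcl, ucl = min(lcl, ucl), max(lcl, ucl)
    return FCResult(
        label=label, fc=fc, lcl=lcl, ucl=ucl, p_value=p, p_adj=p_adj,
        se_log2=se, lower_se=lower_se, upper_se=upper_se,
        sig=sig_mark(p_adj if use_adj else p),
    )


def _fc_vs_calibrator(
    fit: ModelFit,
    emm: pd.DataFrame,
    level_col: str,
    calibrator: str,
    p_adjust: str,
    conf_level: float,
) -> list[FCResult]:
    levels = [str(x) for x in emm[level_col]]
    if calibrator not in levels:
        raise ValueError(f"calibrator {calibrator!r} not among levels {levels}")
    emm = emm.set_index(emm[level_col].astype(str))
    L_cal = emm.loc[calibrator, "_L"]
    others = [lv for lv in levels if lv != calibrator]
    stats_rows = []
    for lv in others:
        L = emm.loc[lv, "_L"] - L_cal
        est, se, _, p = _contrast(fit, L)
        stats_rows.append((lv, est, se, p))
    padj = adjust_pvalues([r[3] for r in stats_rows], method=p_adjust)
    use_adj = p_adjust.lower() != "none"
    # calibrator's own row: FC 1 with p 1 by definition; se is the model se
    # of the calibrator marginal mean, LCL/UCL written as 0 by convention
    se_cal = float(emm.loc[calibrator, "se"])
    l_se, u_se = core.se_bounds(1.0, se_cal)
    rows = [
        FCResult(
            label=calibrator, fc=1.0, lcl=0.0, ucl=0.0, p_value=1.0, p_adj=1.0,
            se_log2=se_cal, lower_se=l_se, upper_se=u_se, sig="",
        )
    ]
    for (lv, est, se, p), pa in zip(stats_rows, padj):
        rows.append(
            _fc_row(fit, f"{lv} vs {calibrator}", est, se, p, float(pa),
                    conf_level, use_adj)
        )
    return rows


# ---------------------------------------------------------------------------
# public analyses


def anova_fc(
    table: QPCRTable,
    main_factor: Optional[str] = None,
    calibrator: Optional[str] = None,
    analysis_type: str = "anova",
    p_adjust: str = "none",
    conf_level: float = 0.95,
    alpha: float = 0.05,
    random_effects: bool = True,
) -> tuple[ModelFit, list[FCResult]]:
    """Fold-change analysis of a factor's levels against a calibrator.

    Fits the wdCT model (full factorial for ANOVA, additive covariates for
    ANCOVA), takes equal-weight marginal means of the main factor, and
    back-transforms each level-vs-calibrator contrast into a fold change
    with standard-error bounds and a t confidence interval.  The calibrator
    row reports FC 1 with p 1.  A warning is attached when an interaction
    involving the main factor is significant at ``alpha`` (comparisons of
    the main factor alone may then be misleading).
    """
    fit = fit_wdct_model(table, main_factor=main_factor,
                         analysis_type=analysis_type,
                         random_effects=random_effects)
    main_factor = main_factor or table.factor_cols[0]
    calibrator = str(calibrator) if calibrator is not None else fit.levels(main_factor)[0]
    emm = marginal_means(fit, main_factor)
    rows = _fc_vs_calibrator(fit, emm, main_factor, calibrator, p_adjust, conf_level)
    inter = [
        t for t in fit.anova.index
        if ":" in t and main_factor in t.split(":") and fit.anova.loc[t, "p"] < alpha
    ]
    if inter:
        warnings.warn(
            f"interaction(s) {inter} involving {main_factor!r} are significant "
            f"at alpha={alpha}; fold-change comparisons of {main_factor!r} "
            "levels alone may be misleading",
            stacklevel=2,
        )
    return fit, rows


def anova_re(
    table: QPCRTable,
    p_adjust: str = "none",
    alpha: float = 0.05,
    conf_level: float = 0.95,
    random_effects: bool = True,
) -> tuple[ModelFit, list[REResult]]:
    """Relative-expression ANOVA over all factor-level combinations.

    One row per combination: RE = 2**(-marginal mean wdCT) with back-
    transformed se and confidence limits, plus a compact letter display of
    all pairwise comparisons at ``alpha``.  Rows are sorted by RE,
    descending; combinations sharing no letter differ significantly.
    """
    fit = fit_wdct_model(table, analysis_type="anova", random_effects=random_effects)
    emm = marginal_means(fit, fit.factor_cols)
    cells = table.analysis_frame().groupby(fit.factor_cols, observed=False).size()
    empty = cells[cells == 0]
    if len(empty):
        raise ValueError(f"factor combination(s) with zero observations: {list(empty.index)}")

    emm = emm.copy()
    emm["re"] = [core.relative_expression(m) for m in emm["emmean"]]
    emm = emm.sort_values("re", ascending=False).reset_index(drop=True)
    n = len(emm)
    pmat = np.ones((n, n))
    raw = []
    pairs = list(combinations(range(n), 2))
    for i, j in pairs:
        L = emm.loc[i, "_L"] - emm.loc[j, "_L"]
        _, _, _, p = _contrast(fit, L)
        raw.append(p)
    adj = adjust_pvalues(raw, method=p_adjust)
    for (i, j), pa in zip(pairs, adj):
        pmat[i, j] = pmat[j, i] = pa
    labels = [" / ".join(map(str, t)) for t in emm[fit.factor_cols].itertuples(index=False)]
    letters = compact_letter_display(labels, pmat, alpha=alpha)

    # replicate-scale SD of the back-transformed raw values, per cell
    af = table.analysis_frame()
    af["re_raw"] = np.exp2(-af["wdct"])
    sd = af.groupby(fit.factor_cols, observed=True)["re_raw"].std(ddof=1)

    rows = []
    for i in range(n):
        key = tuple(str(emm.loc[i, f]) for f in fit.factor_cols)
        m, se = float(emm.loc[i, "emmean"]), float(emm.loc[i, "se"])
        re_v = float(emm.loc[i, "re"])
        l_se, u_se = core.se_bounds(re_v, se)
        lcl, ucl = core.confidence_bounds(re_v, se, max(fit.df_contrast, 1), level=conf_level)
        rows.append(
            REResult(
                levels=key, re=re_v, lcl=min(lcl, ucl), ucl=max(lcl, ucl),
                se_log2=se, lower_se=l_se, upper_se=u_se, letter=letters[i],
                replicate_sd=float(sd.get(key if len(key) > 1 else key[0], np.nan)),
            )
        )
    return fit, rows


def repeated_fc(
    table: RepeatedTable,
    baseline: Optional[str] = None,
    p_adjust: str = "none",
    conf_level: float = 0.95,
    random_effects: bool = True,
) -> tuple[ModelFit, list[FCResult]]:
    """Repeated-measures fold change of each time point vs a baseline.

    Mixed model on wdCT with fixed time (crossed with treatment when a
    treatment column is present) and a random intercept per individual;
    contrasts of the time marginal means against ``baseline`` (default: the
    first time level) are back-transformed as in :func:`anova_fc`.
    """
    data = table.analysis_frame()
    factors = ([table.treatment_col] if table.treatment_col else []) + [table.time_col]
    formula = "wdct ~ " + " * ".join(factors)
    random_cols = [table.id_col] if random_effects else []
    fit = _fit(data, formula, random_cols, factors)
    baseline = str(baseline) if baseline is not None else fit.levels(table.time_col)[0]
    emm = marginal_means(fit, table.time_col)
    rows = _fc_vs_calibrator(fit, emm, table.time_col, baseline, p_adjust, conf_level)
    return fit, rows


def qpcr_means(
    fit: ModelFit,
    spec: str,
    p_adjust: str = "BH",
    conf_level: float = 0.95,
) -> pd.DataFrame:
    """All pairwise comparisons for an effect of a fitted wdCT model.

    ``spec`` names a main effect (``"factor1"``), an interaction
    (``"factor1:factor2"``: comparisons among the cells), or a slice
    (``"factor1 | factor2"``: factor1 compared within each level of
    factor2).  Mean differences are back-transformed to fold-change ratios
    with standard-error bounds; p-values are BH-adjusted by default.
    """
    spec = spec.strip()
    m = re.match(r"^([\w.]+(?::[\w.]+)*)\s*(?:\|\s*([\w.]+))?$", spec)
    if not m:
        raise ValueError(f"cannot parse effect spec {spec!r}")
    factors = m.group(1).split(":")
    by_factor = m.group(2)
    for f in factors + ([by_factor] if by_factor else []):
        if f not in fit.factor_cols:
            raise ValueError(f"effect {f!r} is not in the model ({fit.factor_cols})")

    slices = fit.levels(by_factor) if by_factor else [None]
    out = []
    for sl in slices:
        by = {by_factor: sl} if by_factor else None
        emm = marginal_means(fit, factors, by=by)
        labels = [" / ".join(t) for t in emm[factors].astype(str).itertuples(index=False)]
        raw = []
        pairs = list(combinations(range(len(emm)), 2))
        for i, j in pairs:
            L = emm.loc[i, "_L"] - emm.loc[j, "_L"]
            est, se, t, p = _contrast(fit, L)
            raw.append((i, j, est, se, t, p))
        padj = adjust_pvalues([r[5] for r in raw], method=p_adjust)
        for (i, j, est, se, t, p), pa in zip(raw, padj):
            ratio = core.relative_expression(est)
            l_se, u_se = core.se_bounds(ratio, se)
            lcl, ucl = core.confidence_bounds(ratio, se, max(fit.df_contrast, 1),
                                              level=conf_level)
            row = {
                "contrast": f"{labels[i]} vs {labels[j]}",
                "ratio": ratio,
                "se": se,
                "df": fit.df_contrast,
                "t": t,
                "p value": p,
                "p adj": float(pa),
                "LCL": min(lcl, ucl),
                "UCL": max(lcl, ucl),
                "Lower.se": l_se,
                "Upper.se": u_se,
                "sig": sig_mark(float(pa) if p_adjust.lower() != "none" else p),
            }
            if by_factor:
                row = {by_factor: sl, **row}
            out.append(row)
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# compact letter display


def compact_letter_display(labels: Sequence[str], pmat, alpha: float = 0.05) -> list[str]:
    """Letter grouping of means from a pairwise p-value matrix.

    Insert-and-absorb algorithm: start with one group holding every label;
    for each significant pair, split every group containing both and absorb
    redundant subsets.  The result satisfies, exactly: two labels share at
    least one letter iff their pairwise p >= alpha.  Letters are assigned in
    the order groups first appear over the given label order (pass labels
    sorted by descending RE to reproduce publication ordering).
    """
    labels = list(labels)
    n = len(labels)
    P = pmat.to_numpy() if isinstance(pmat, pd.DataFrame) else np.asarray(pmat, float)
    if P.shape != (n, n):
        raise ValueError("p-value matrix shape does not match labels")
    if not np.allclose(P, P.T, equal_nan=True):
        raise ValueError("p-value matrix must be symmetric")
    groups: list[set[int]] = [set(range(n))]
    for i, j in combinations(range(n), 2):
        if P[i, j] >= alpha:
            continue
        new = []
        for g in groups:
            if i in g and j in g:
                new.append(g - {i})
                new.append(g - {j})
            else:
                new.append(g)
        # absorb groups contained in another
        groups = [
            g for k, g in enumerate(new)
            if g and not any(g < h or (g == h and k > m) for m, h in enumerate(new))
        ]
    # letter order: by smallest member index (labels are pre-sorted by RE)
    groups.sort(key=lambda g: min(g))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = ["" for _ in range(n)]
    for gi, g in enumerate(groups):
        letter = alphabet[gi] if gi < 26 else f"({gi + 1})"
        for i in g:
            out[i] += letter
    return out


# ---------------------------------------------------------------------------
# residual diagnostics


@dataclass
class DiagnosticsReport:
    shapiro_stat: float
    shapiro_p: float
    levene_stat: float
    levene_p: float
    qq_theoretical: np.ndarray
    qq_sample: np.ndarray
    fitted: np.ndarray
    residuals: np.ndarray
    degenerate: bool
    advisory: str


def residual_diagnostics(fit: ModelFit, alpha: float = 0.05) -> DiagnosticsReport:
    """Normality and variance-homogeneity checks of the model residuals.

    Shapiro-Wilk on the residuals; Brown-Forsythe (median-centred Levene)
    across the factor cells.  When either assumption looks violated the
    advisory names the usual non-parametric alternatives (Mann-Whitney,
    Kruskal-Wallis) without executing them.
    """
    resid = np.asarray(fit.residuals, float)
    if len(resid) < 3:
        raise ValueError("need >= 3 residuals for a normality test")
    degenerate = float(np.ptp(resid)) < 1e-10
    if degenerate:
        sw_stat = sw_p = lv_stat = lv_p = float("nan")
    else:
        sw_stat, sw_p = stats.shapiro(resid)
        cells = fit.data[fit.factor_cols].astype(str).agg("|".join, axis=1)
        grps = [resid[(cells == c).to_numpy()] for c in pd.unique(cells)]
        grps = [g for g in grps if len(g) >= 2]
        if len(grps) >= 2:
            lv_stat, lv_p = stats.levene(*grps, center="median")
        else:
            lv_stat, lv_p = float("nan"), float("nan")
    (osm, osr), _ = stats.probplot(resid, dist="norm")
    issues = []
    if not degenerate and sw_p < alpha:
        issues.append(
            "residuals depart from normality (Shapiro-Wilk "
            f"p={sw_p:.4g})"
        )
    if not degenerate and np.isfinite(lv_p) and lv_p < alpha:
        issues.append(
            "residual variances are heterogeneous across cells "
            f"(Brown-Forsythe p={lv_p:.4g})"
        )
    if degenerate:
        advisory = "residuals are (near-)constant; diagnostics are degenerate."
    elif issues:
        advisory = (
            "; ".join(issues)
            + ". Model-based p-values may be unreliable; consider the "
            "Mann-Whitney test (two groups) or the Kruskal-Wallis test "
            "(several groups), or the unequal-variance t-test option."
        )
    else:
        advisory = "no evidence against normality or variance homogeneity."
    return DiagnosticsReport(
        shapiro_stat=float(sw_stat), shapiro_p=float(sw_p),
        levene_stat=float(lv_stat), levene_p=float(lv_p),
        qq_theoretical=osm, qq_sample=osr,
        fitted=fit.fitted, residuals=resid,
        degenerate=degenerate, advisory=advisory,
    )
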