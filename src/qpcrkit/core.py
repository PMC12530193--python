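"""Efficiency-weighted quantification arithmetic.

All relative-quantification statistics in this package are computed on the
efficiency-weighted delta-CT scale

    wdCT = log2(E_target) * CT_target - log2(E_ref) * CT_ref

where E is the per-cycle amplification factor (E = 2 means perfect doubling).
wdCT is a log2-scale quantity: means, standard errors and test statistics are
formed on it, and results are back-transformed through ``y = 2**(-x)`` at the
last step.  With all E fixed at 2 the machinery reduces exactly to the
classical 2^-ddCT (Livak) method, and with gene-wise constant efficiencies it
is algebraically identical to the Pfaffl ratio.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = [
    "weighted_dct",
    "relative_expression",
    "fold_change",
    "se_bounds",
    "confidence_bounds",
    "livak_fc",
    "pfaffl_fc",
]

#: E values outside this closed interval are rejected outright.
E_HARD_RANGE = (1.0, 2.5)
#: E values outside this interval draw a warning (suspect chemistry).
E_SOFT_RANGE = (1.6, 2.2)


def _check_efficiency(e, name: str = "E"):
    e = np.asarray(e, dtype=float)
    if not np.all(np.isfinite(e)):
        raise ValueError(f"{name} contains non-finite values")
    if np.any(e <= E_HARD_RANGE[0]) or np.any(e > E_HARD_RANGE[1]):
        raise ValueError(
            f"{name} must lie in ({E_HARD_RANGE[0]}, {E_HARD_RANGE[1]}]: "
            "log2(E) <= 0 would invalidate the efficiency weighting"
        )
    return e


def weighted_dct(e_target, ct_target, e_ref1, ct_ref1, e_ref2=None, ct_ref2=None):
    """Efficiency-weighted delta-CT for one observation (or arrays of them).

    With one reference gene::

        log2(E_target)*CT_target - log2(E_ref1)*CT_ref1

    With two reference genes the two weighted reference terms are averaged on
    the log2 scale (equivalent to geometric-mean normalisation of the
    reference quantities) before subtraction.

    Parameters
    ----------
    e_target, ct_target
        Amplification factor and threshold cycle of the target gene.
    e_ref1, ct_ref1
        Amplification factor and threshold cycle of reference gene 1.
    e_ref2, ct_ref2
        Optional second reference gene; both must be given or neither.

    Returns
    -------
    float or ndarray
        wdCT in log2 units.
    """
    if (e_ref2 is None) != (ct_ref2 is None):
        raise ValueError("e_ref2 and ct_ref2 must be supplied together")
    e_t = _check_efficiency(e_target, "E_target")
    e_r1 = _check_efficiency(e_ref1, "E_ref1")
    ct_t = np.asarray(ct_target, dtype=float)
    ct_r1 = np.asarray(ct_ref1, dtype=float)
    if not (np.all(np.isfinite(ct_t)) and np.all(np.isfinite(ct_r1))):
        raise ValueError("CT values must be finite")
    ref_term = np.log2(e_r1) * ct_r1
    if e_ref2 is not None:
        e_r2 = _check_efficiency(e_ref2, "E_ref2")
        ct_r2 = np.asarray(ct_ref2, dtype=float)
        if not np.all(np.isfinite(ct_r2)):
            raise ValueError("CT values must be finite")
        ref_term = (ref_term + np.log2(e_r2) * ct_r2) / 2.0
    out = np.log2(e_t) * ct_t - ref_term
    return out if out.ndim else float(out)


def relative_expression(mean_wdct):
    """Relative expression RE = 2**(-mean wdCT)  (delta-CT method)."""
    m = np.asarray(mean_wdct, dtype=float)
    out = np.exp2(-m)
    return out if out.ndim else float(out)


def fold_change(mean_wdct_tr, mean_wdct_co):
    """Fold change FC = 2**(-(mean_Tr - mean_Co))  (delta-delta-CT method).

    Identical to ``relative_expression(tr) / relative_expression(co)``.
    """
    tr = np.asarray(mean_wdct_tr, dtype=float)
    co = np.asarray(mean_wdct_co, dtype=float)
    out = np.exp2(-(tr - co))
    return out if out.ndim else float(out)


def se_bounds(center, se_log2):
    """Back-transformed standard-error bounds around an FC or RE value.

    lower = 2**(log2(center) - se);  upper = 2**(log2(center) + se)

    The bounds are multiplicatively symmetric: upper/center == center/lower.
    """
    center = np.asarray(center, dtype=float)
    se_log2 = np.asarray(se_log2, dtype=float)
    if np.any(center <= 0):
        raise ValueError("center must be positive (FC/RE are ratios)")
    if np.any(se_log2 < 0):
        raise ValueError("se_log2 must be non-negative")
    lower = np.exp2(np.log2(center) - se_log2)
    upper = np.exp2(np.log2(center) + se_log2)
    if lower.ndim:
        return lower, upper
    return float(lower), float(upper)


def confidence_bounds(center, se_log2, df, level: float = 0.95):
    """Back-transformed two-sided t confidence limits for an FC or RE value.

    2**(log2(center) -/+ t_{df,level} * se_log2)
    """
    if not np.all(np.asarray(df) >= 1):
        raise ValueError("df must be >= 1")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    center = np.asarray(center, dtype=float)
    if np.any(center <= 0):
        raise ValueError("center must be positive")
    tcrit = stats.t.ppf(0.5 + level / 2.0, df)
    lcl = np.exp2(np.log2(center) - tcrit * np.asarray(se_log2, dtype=float))
    ucl = np.exp2(np.log2(center) + tcrit * np.asarray(se_log2, dtype=float))
    if lcl.ndim:
        return lcl, ucl
    return float(lcl), float(ucl)


def livak_fc(ct_target_tr, ct_ref_tr, ct_target_co, ct_ref_co):
    """Classical 2^-ddCT fold change, assuming E = 2 for every reaction.

    Exposed as an explicit reduction check: on any table with all
    efficiencies equal to 2, :func:`fold_change` over :func:`weighted_dct`
    values returns exactly this quantity.
    """
    dct_tr = np.mean(np.asarray(ct_target_tr, float)) - np.mean(np.asarray(ct_ref_tr, float))
    dct_co = np.mean(np.asarray(ct_target_co, float)) - np.mean(np.asarray(ct_ref_co, float))
    return float(np.exp2(-(dct_tr - dct_co)))


def pfaffl_fc(e_target, ct_target_tr, ct_target_co, e_ref, ct_ref_tr, ct_ref_co):
    """Pfaffl efficiency-corrected ratio.

        E_target^-(mean CT_target_Tr - mean CT_target_Co)
        -------------------------------------------------
          E_ref^-(mean CT_ref_Tr - mean CT_ref_Co)

    Requires a single (gene-wise constant) efficiency per gene.  Provided as
    an independent formulation; equals the wdCT route algebraically.
    """
    e_t = float(_check_efficiency(e_target, "E_target"))
    e_r = float(_check_efficiency(e_ref, "E_ref"))
    d_t = np.mean(np.asarray(ct_target_tr, float)) - np.mean(np.asarray(ct_target_co, float))
    d_r = np.mean(np.asarray(ct_ref_tr, float)) - np.mean(np.asarray(ct_ref_co, float))
    return float(e_t ** (-d_t) / e_r ** (-d_r))
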