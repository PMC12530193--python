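"""Synthetic qPCR datasets with known ground truth.

The generator realises the distributional model that underlies the whole
package: relative expression and fold change are lognormal, so the
efficiency-weighted delta-CT values are normal on the log2 scale.  For each
experimental cell and biological replicate it draws

    wdCT = -log2(true RE) + block effect + replicate effect + N(0, noise_sd)

then emits a (perfectly stable, by default) reference-gene CT and solves the
target CT from the wdCT definition:

    CT_target = (wdCT + log2(E_ref) * CT_ref) / log2(E_target)

so that running any estimator in this package on a noiseless dataset recovers
the true RE/FC exactly.  Block and replicate effects are normal on the log2
scale; replicate effects are shared across cells (crossed with the design),
which is what a random intercept per biological replicate absorbs.

Defaults emulate a routine plant-transcript qPCR experiment: 3 biological
replicates per cell, wdCT noise SD 0.25 log2 units (about +/-19% on the
expression scale), reference CT near 25 cycles, efficiencies 2.0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .datamodel import QPCRTable, RepeatedTable, TTestTable

__all__ = [
    "SyntheticSpec",
    "generate_dataset",
    "generate_ttest_dataset",
    "generate_repeated_dataset",
    "generate_dilution_series",
]

CellKey = Union[str, tuple]


@dataclass
class SyntheticSpec:
    """Design and ground truth for one simulated ANOVA/ANCOVA-layout dataset.

    Parameters
    ----------
    design
        Ordered mapping factor name -> list of level names (1-3 factors).
    true_re
        Map from cell key (level name for one factor, tuple of level names
        otherwise) to the true relative expression of that cell.  Cells not
        listed default to RE = 1.
    n_rep
        Biological replicates per cell.
    e_target, e_ref
        Amplification factors written into the E columns and used to solve
        the target CT.
    baseline_ref_ct
        Reference-gene CT (cycles).
    noise_sd
        SD of the wdCT residual noise, log2 units.
    block_levels, block_sd
        Optional blocking: number of blocks (replicates are nested in none,
        blocks cross the design) and SD of block intercepts (log2 units).
    rep_sd
        SD of per-replicate intercepts shared across cells (log2 units).
    ref_ct_jitter
        SD of reference CT jitter (cycles); 0 keeps the reference perfectly
        stable so ground truth lives entirely in the target gene.
    seed
        Seed for the dataset's own random generator; no global state.
    """

    design: Mapping[str, Sequence[str]]
    true_re: Mapping[CellKey, float] = field(default_factory=dict)
    n_rep: int = 3
    e_target: float = 2.0
    e_ref: float = 2.0
    baseline_ref_ct: float = 25.0
    noise_sd: float = 0.25
    block_levels: int = 0
    block_sd: float = 0.0
    rep_sd: float = 0.0
    ref_ct_jitter: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not 1 <= len(self.design) <= 3:
            raise ValueError("1-3 factors supported")
        if self.n_rep < 1:
            raise ValueError("n_rep must be >= 1")
        if self.noise_sd < 0 or self.block_sd < 0 or self.rep_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        for k, v in self.true_re.items():
            if not v > 0:
                raise ValueError(f"true_re must be positive; cell {k!r} has {v}")

    def cell_re(self, cell: tuple) -> float:
        key: CellKey = cell[0] if len(cell) == 1 else cell
        return float(self.true_re.get(key, 1.0))


def generate_dataset(spec: SyntheticSpec) -> QPCRTable:
    """Simulate a dataset in the ANOVA/ANCOVA column arrangement.

    Reproducible: the same spec (including seed) yields an identical table.
    """
    rng = np.random.default_rng(spec.seed)
    factor_names = list(spec.design)
    cells = list(product(*[spec.design[f] for f in factor_names]))
    n_blocks = spec.block_levels
    block_eff = rng.normal(0.0, spec.block_sd, n_blocks) if n_blocks else None
    rep_eff = rng.normal(0.0, spec.rep_sd, spec.n_rep)

    rows = []
    for cell in cells:
        base = -np.log2(spec.cell_re(cell))
        for r in range(spec.n_rep):
            wdct = base + rep_eff[r] + rng.normal(0.0, spec.noise_sd)
            blk = None
            if n_blocks:
                blk = r % n_blocks  # balanced assignment of reps to blocks
                wdct += block_eff[blk]
            ref_ct = spec.baseline_ref_ct + (
                rng.normal(0.0, spec.ref_ct_jitter) if spec.ref_ct_jitter else 0.0
            )
            target_ct = (wdct + np.log2(spec.e_ref) * ref_ct) / np.log2(spec.e_target)
            row = dict(zip(factor_names, cell))
            if n_blocks:
                row["block"] = f"b{blk + 1}"
            row.update(
                rep=r + 1,
                targetE=spec.e_target,
                targetCt=target_ct,
                ref1E=spec.e_ref,
                ref1Ct=ref_ct,
            )
            rows.append(row)
    df = pd.DataFrame(rows)
    return QPCRTable(
        df,
        factor_cols=factor_names,
        rep_col="rep",
        e_ct_cols=["targetE", "targetCt", "ref1E", "ref1Ct"],
        block_col="block" if n_blocks else None,
        n_ref=1,
    )


def generate_ttest_dataset(
    n_genes: int = 3,
    n_rep: int = 3,
    true_fc: Union[float, Sequence[float]] = 2.0,
    noise_sd: float = 0.25,
    efficiency: float = 2.0,
    baseline_wdct: float = 5.0,
    ref_ct: float = 25.0,
    seed: int = 0,
) -> TTestTable:
    """Simulate a two-condition (control, treatment) multi-gene t-test table.

    Row order within each (condition, gene) cell encodes replicate pairing.
    ``true_fc`` may be a scalar applied to every target gene or one value
    per gene.
    """
    if n_rep < 2:
        raise ValueError("t-test layouts need >= 2 biological replicates")
    fcs = np.broadcast_to(np.asarray(true_fc, float), (n_genes,))
    if np.any(fcs <= 0):
        raise ValueError("true_fc must be positive")
    rng = np.random.default_rng(seed)
    log2e = np.log2(efficiency)
    ref_term = log2e * ref_ct

    rows = []
    for cond, shift in (("control", 0.0), ("treatment", 1.0)):
        for g in range(n_genes):
            mu = baseline_wdct - shift * np.log2(fcs[g])
            wdct = mu + rng.normal(0.0, noise_sd, n_rep)
            ct = (wdct + ref_term) / log2e
            for r in range(n_rep):
                rows.append((cond, f"gene{g + 1}", efficiency, ct[r]))
        for r in range(n_rep):
            rows.append((cond, "ref", efficiency, ref_ct))
    df = pd.DataFrame(rows, columns=["condition", "gene", "E", "Ct"])
    return TTestTable(df, n_ref=1)


def generate_repeated_dataset(
    n_id: int = 3,
    times: Sequence[str] = ("T1", "T2", "T3"),
    true_fc_vs_baseline: Optional[Mapping[str, float]] = None,
    treatments: Optional[Sequence[str]] = None,
    id_sd: float = 0.0,
    noise_sd: float = 0.25,
    efficiency: float = 2.0,
    baseline_wdct: float = 5.0,
    ref_ct: float = 25.0,
    seed: int = 0,
) -> RepeatedTable:
    """Simulate a repeated-measures table (each individual at every time).

    ``true_fc_vs_baseline`` maps non-baseline time levels to the true fold
    change relative to the first time level; ``id_sd`` adds a normal
    intercept per individual on the wdCT scale.
    """
    if len(times) < 2:
        raise ValueError("need >= 2 time points")
    fc_map = dict(true_fc_vs_baseline or {})
    rng = np.random.default_rng(seed)
    log2e = np.log2(efficiency)
    ref_term = log2e * ref_ct
    treat_levels = list(treatments) if treatments else [None]
    rows = []
    uid = 0
    for tr in treat_levels:
        for _ in range(n_id):
            uid += 1
            id_eff = rng.normal(0.0, id_sd) if id_sd else 0.0
            for t in times:
                wdct = (
                    baseline_wdct
                    - np.log2(fc_map.get(t, 1.0))
                    + id_eff
                    + rng.normal(0.0, noise_sd)
                )
                ct = (wdct + ref_term) / log2e
                row = {"id": uid}
                if tr is not None:
                    row["treatment"] = tr
                row.update(time=t, targetE=efficiency, targetCt=ct,
                           ref1E=efficiency, ref1Ct=ref_ct)
                rows.append(row)
    df = pd.DataFrame(rows)
    return RepeatedTable(
        df,
        id_col="id",
        time_col="time",
        e_ct_cols=["targetE", "targetCt", "ref1E", "ref1Ct"],
        treatment_col="treatment" if treatments else None,
        n_ref=1,
    )


def generate_dilution_series(
    e_true: Union[float, Mapping[str, float]] = 2.0,
    ct_at_dilution1: float = 20.0,
    dilutions: Sequence[float] = (1.0, 0.1, 0.01),
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a standard-curve table: dilution column + one CT per gene.

    CT = CT(dilution 1) - log10(dilution)/log10(E) + N(0, noise_sd); for
    E = 2 the CT step per 10-fold dilution is log2(10) = 3.3219 cycles.
    """
    dil = np.asarray(dilutions, float)
    if np.any(dil <= 0):
        raise ValueError("dilutions must be positive")
    if len(np.unique(dil)) < 3:
        raise ValueError("need >= 3 distinct dilution levels")
    genes = e_true if isinstance(e_true, Mapping) else {"target": float(e_true)}
    for g, e in genes.items():
        if e <= 1:
            raise ValueError(f"E must exceed 1 (gene {g!r} has {e})")
    rng = np.random.default_rng(seed)
    out = {"dilution": dil}
    for g, e in genes.items():
        ct = ct_at_dilution1 - np.log10(dil) / np.log10(e)
        if noise_sd:
            ct = ct + rng.normal(0.0, noise_sd, len(dil))
        out[g] = ct
    return pd.DataFrame(out)
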