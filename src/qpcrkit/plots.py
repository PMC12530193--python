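"""Publication-style bar plots for fold-change and relative-expression rows.

Bar heights, whisker ends and annotations are first assembled into a plain
:class:`BarPlotData` structure; rendering to PNG/SVG/PDF is a pure
serialisation of that structure, so plots are testable without pixel
comparisons.  Switching the whisker source (standard-error bounds vs
confidence limits) never changes bar heights.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import matplotlib

matplotlib.use("Agg")  # headless rendering
import matplotlib.pyplot as plt
import numpy as np

from .results import FCResult, REResult

__all__ = ["BarPlotData", "fc_bar_data", "re_bar_data", "plot_fc_bars", "plot_re_bars"]

_ERROR_BARS = {"se", "ci"}


@dataclass
class BarPlotData:
    """Everything a bar panel shows, independent of rendering."""

    labels: list[str]
    heights: np.ndarray
    whisker_low: np.ndarray
    whisker_high: np.ndarray
    annotations: list[str]          # sig marks or letters above the bars
    guide_y: Optional[float] = None  # horizontal guide (FC = 1)
    group_labels: Optional[list[str]] = None  # outer grouping (dodged bars)
    ylabel: str = ""


def _check_error_bar(error_bar: str) -> str:
    if error_bar not in _ERROR_BARS:
        raise ValueError(f"error_bar must be one of {sorted(_ERROR_BARS)}")
    return error_bar


def fc_bar_data(results: Sequence[FCResult], error_bar: str = "se") -> BarPlotData:
    """Bar-plot structure for fold-change rows (one bar per gene/contrast)."""
    if not results:
        raise ValueError("no fold-change rows to plot")
    _check_error_bar(error_bar)
    lo = [r.lower_se if error_bar == "se" else r.lcl for r in results]
    hi = [r.upper_se if error_bar == "se" else r.ucl for r in results]
    return BarPlotData(
        labels=[r.label for r in results],
        heights=np.array([r.fc for r in results]),
        whisker_low=np.array(lo),
        whisker_high=np.array(hi),
        annotations=[r.sig for r in results],
        guide_y=1.0,
        ylabel="Fold change",
    )


def re_bar_data(results: Sequence[REResult], error_bar: str = "se") -> BarPlotData:
    """Bar-plot structure for relative-expression rows (letters on top)."""
    if not results:
        raise ValueError("no relative-expression rows to plot")
    _check_error_bar(error_bar)
    n_fac = len(results[0].levels)
    if n_fac > 3:
        raise ValueError("at most 3 grouping factors are supported")
    lo = [r.lower_se if error_bar == "se" else r.lcl for r in results]
    hi = [r.upper_se if error_bar == "se" else r.ucl for r in results]
    labels = [" / ".join(map(str, r.levels)) for r in results]
    groups = [str(r.levels[0]) for r in results] if n_fac > 1 else None
    return BarPlotData(
        labels=labels,
        heights=np.array([r.re for r in results]),
        whisker_low=np.array(lo),
        whisker_high=np.array(hi),
        annotations=[r.letter for r in results],
        group_labels=groups,
        ylabel="Relative expression",
    )


def _render(data: BarPlotData, path, dpi: int = 150) -> None:
    fig, ax = plt.subplots(figsize=(1.2 + 0.9 * len(data.labels), 4.0))
    x = np.arange(len(data.labels))
    colors = None
    if data.group_labels:
        uniq = list(dict.fromkeys(data.group_labels))
        cmap = plt.get_cmap("tab10")
        colors = [cmap(uniq.index(g) % 10) for g in data.group_labels]
    ax.bar(x, data.heights, color=colors or "steelblue", edgecolor="black",
           linewidth=0.6)
    yerr = np.vstack(
        [data.heights - data.whisker_low, data.whisker_high - data.heights]
    )
    ax.errorbar(x, data.heights, yerr=np.clip(yerr, 0, None), fmt="none",
                ecolor="black", capsize=3, linewidth=1)
    ymax = float(np.max(data.whisker_high)) if len(data.labels) else 1.0
    for xi, (h, hi, a) in enumerate(
        zip(data.heights, data.whisker_high, data.annotations)
    ):
        if a:
            ax.text(xi, hi + 0.02 * ymax, a, ha="center", va="bottom")
    if data.guide_y is not None:
        ax.axhline(data.guide_y, color="grey", linestyle="--", linewidth=0.8)
    ax.set_xticks(x)
    ax.set_xticklabels(data.labels, rotation=30, ha="right")
    ax.set_ylabel(data.ylabel)
    fig.tight_layout()
    fig.savefig(path, dpi=dpi)
    plt.close(fig)


def plot_fc_bars(
    results: Sequence[FCResult], path, error_bar: str = "se", dpi: int = 150
) -> BarPlotData:
    """Render fold-change bars with significance marks; returns the data."""
    data = fc_bar_data(results, error_bar=error_bar)
    _render(data, path, dpi=dpi)
    return data


def plot_re_bars(
    results: Sequence[REResult], path, error_bar: str = "se", dpi: int = 150
) -> BarPlotData:
    """Render relative-expression bars with letter groups; returns the data."""
    data = re_bar_data(results, error_bar=error_bar)
    _render(data, path, dpi=dpi)
    return data
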