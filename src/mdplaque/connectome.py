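"""Functional connectivity map: all-pairs Pearson correlation, thresholded
adjacency (strict r > 0.35 by default), degrees, and hub/lone classification.

Correlations are computed on smoothed (1 s window), linearly detrended F/F0 so
slow drift cannot fabricate edges; the preprocessing applied is recorded in the
output descriptor.  No p-values or multiple-testing machinery: the edge rule is
a fixed correlation cutoff.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import detrend as _linear_detrend

from .traces import NormalizedTraceMatrix, smooth_array

logger = logging.getLogger(__name__)

__all__ = [
    "CorrelationMatrix",
    "ConnectivityGraph",
    "CellClassification",
    "pairwise_correlation",
    "threshold_graph",
    "classify_hub_lone",
    "connectivity_summary",
    "write_correlation_csv",
    "write_edge_list_csv",
    "write_graphml",
    "plot_heatmap",
]


@dataclass
class CorrelationMatrix:
    cell_ids: list[str]
    r: np.ndarray  # symmetric, unit diagonal; NaN rows/cols for zero-variance cells
    preprocessing: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        n = len(self.cell_ids)
        if self.r.shape != (n, n):
            raise ValueError("correlation matrix shape mismatch")


@dataclass
class ConnectivityGraph:
    cell_ids: list[str]
    adjacency: np.ndarray  # boolean, symmetric, zero diagonal
    r_threshold: float
    degree: np.ndarray

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum() // 2)


@dataclass
class CellClassification:
    cell_ids: list[str]
    label: list[str]  # each in {"hub", "lone", "regular"}
    rule: str


def pairwise_correlation(
    norm: NormalizedTraceMatrix,
    smooth_window_s: float = 1.0,
    detrend: bool = True,
) -> CorrelationMatrix:
    """All-pairs Pearson r over the full common window.

    Zero-variance traces get NaN entries (off-diagonal) and are treated as
    non-edges downstream.
    """
    if norm.n_cells < 2:
        raise ValueError("need at least 2 cells")
    if norm.n_frames < 3:
        raise ValueError("need at least 3 samples")
    if norm.n_frames < 30:
        logger.warning("fewer than 30 samples; correlation estimates will be unstable")
    x = norm.values.astype(float)
    if smooth_window_s and smooth_window_s > 0:
        x = smooth_array(x, norm.fs_hz, smooth_window_s)
    if detrend:
        x = _linear_detrend(x, axis=1, type="linear")
    sd = x.std(axis=1)
    zero_var = sd == 0
    for i in np.flatnonzero(zero_var):
        logger.warning("zero-variance trace %s: correlations reported missing", norm.cell_ids[i])
    with np.errstate(invalid="ignore", divide="ignore"):
        xc = x - x.mean(axis=1, keepdims=True)
        denom = np.sqrt(np.outer((xc**2).sum(axis=1), (xc**2).sum(axis=1)))
        r = (xc @ xc.T) / denom
    r[zero_var, :] = np.nan
    r[:, zero_var] = np.nan
    np.fill_diagonal(r, 1.0)
    r = np.clip(r, -1.0, 1.0)
    r = (r + r.T) / 2.0  # kill FP asymmetry
    return CorrelationMatrix(
        cell_ids=list(norm.cell_ids),
        r=r,
        preprocessing={"smooth_window_s": smooth_window_s, "detrend": bool(detrend)},
    )


def threshold_graph(corr: CorrelationMatrix, r_threshold: float = 0.35) -> ConnectivityGraph:
    """Edge (i, j) iff r(i, j) > r_threshold, strictly; NaN never makes an edge."""
    if not -1.0 < r_threshold < 1.0:
        raise ValueError("r_threshold must be inside (-1, 1)")
    with np.errstate(invalid="ignore"):
        adj = corr.r > r_threshold
    np.fill_diagonal(adj, False)
    adj = adj & adj.T
    return ConnectivityGraph(
        cell_ids=list(corr.cell_ids),
        adjacency=adj,
        r_threshold=r_threshold,
        degree=adj.sum(axis=1).astype(int),
    )


def classify_hub_lone(
    graph: ConnectivityGraph,
    rule: str = "mean_plus_sd",
    param: float = 1.0,
) -> CellClassification:
    """Label every cell hub / lone / regular.

    lone <=> degree 0.  ``mean_plus_sd``: hub <=> degree >= mean + param*SD
    (population SD) and degree >= 2.  ``top_fraction``: hub <=> degree within
    the top ``param`` fraction (ties included) and degree >= 2.
    """
    deg = np.asarray(graph.degree)
    n = deg.size
    if n < 3:
        raise ValueError("need at least 3 cells to classify")
    if rule == "mean_plus_sd":
        cutoff = deg.mean() + param * deg.std()
        if deg.std() == 0:
            logger.info("all degrees equal; no hubs under mean_plus_sd rule")
            hub = np.zeros(n, dtype=bool)
        else:
            hub = (deg >= cutoff) & (deg >= 2)
    elif rule == "top_fraction":
        if not 0 < param <= 1:
            raise ValueError("top_fraction param must be in (0, 1]")
        k = max(int(np.ceil(param * n)), 1)
        cutoff = np.sort(deg)[::-1][k - 1]
        hub = (deg >= cutoff) & (deg >= 2)
    else:
        raise ValueError(f"unknown hub rule {rule!r}")
    labels = []
    for d, h in zip(deg, hub):
        if d == 0:
            labels.append("lone")
        elif h:
            labels.append("hub")
        else:
            labels.append("regular")
    return CellClassification(cell_ids=list(graph.cell_ids), label=labels, rule=f"{rule}({param})")


def connectivity_summary(graph: ConnectivityGraph, corr: CorrelationMatrix) -> dict:
    """Scalar plaque-level summary of the connectivity map."""
    n = len(graph.cell_ids)
    n_pairs = n * (n - 1) // 2
    classes = classify_hub_lone(graph) if n >= 3 else None
    iu = np.triu_indices(n, k=1)
    off = corr.r[iu]
    return {
        "n_cells": n,
        "n_edges": graph.n_edges,
        "connected_fraction": graph.n_edges / n_pairs if n_pairs else 0.0,
        "mean_offdiag_r": float(np.nanmean(off)) if off.size else float("nan"),
        "n_hubs": classes.label.count("hub") if classes else 0,
        "n_lone": int(np.sum(graph.degree == 0)),
        "degree_histogram": {int(d): int(c) for d, c in zip(*np.unique(graph.degree, return_counts=True))},
        "r_threshold": graph.r_threshold,
    }


# ---------------------------------------------------------------------------
# Export


def write_correlation_csv(corr: CorrelationMatrix, path: str | Path) -> None:
    pd.DataFrame(corr.r, index=corr.cell_ids, columns=corr.cell_ids).to_csv(path)


def write_edge_list_csv(graph: ConnectivityGraph, corr: CorrelationMatrix, path: str | Path) -> None:
    rows = []
    n = len(graph.cell_ids)
    for i in range(n):
        for j in range(i + 1, n):
            if graph.adjacency[i, j]:
                rows.append((graph.cell_ids[i], graph.cell_ids[j], corr.r[i, j]))
    pd.DataFrame(rows, columns=["cell_i", "cell_j", "r"]).to_csv(path, index=False)


def to_networkx(graph: ConnectivityGraph, corr: CorrelationMatrix,
                classes: CellClassification | None = None,
                positions: dict[str, tuple[float, float]] | None = None):
    import networkx as nx

    g = nx.Graph(r_threshold=graph.r_threshold)
    for i, cid in enumerate(graph.cell_ids):
        attrs = {"degree": int(graph.degree[i])}
        if classes is not None:
            attrs["cell_class"] = classes.label[i]
        if positions and cid in positions:
            attrs["x"], attrs["y"] = positions[cid]
        g.add_node(cid, **attrs)
    n = len(graph.cell_ids)
    for i in range(n):
        for j in range(i + 1, n):
            if graph.adjacency[i, j]:
                g.add_edge(graph.cell_ids[i], graph.cell_ids[j], r=float(corr.r[i, j]))
    return g


def write_graphml(graph: ConnectivityGraph, corr: CorrelationMatrix, path: str | Path,
                  classes: CellClassification | None = None,
                  positions: dict[str, tuple[float, float]] | None = None) -> None:
    import networkx as nx

    nx.write_graphml(to_networkx(graph, corr, classes, positions), path)


def plot_heatmap(corr: CorrelationMatrix, path: str | Path, title: str | None = None) -> None:
    """Pairwise-r heatmap (cells in input order, diverging 2-color scale)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(corr.r, cmap="bwr", vmin=-1.0, vmax=1.0)
    ax.set_xticks(range(len(corr.cell_ids)))
    ax.set_yticks(range(len(corr.cell_ids)))
    ax.set_xticklabels(corr.cell_ids, rotation=90, fontsize=5)
    ax.set_yticklabels(corr.cell_ids, fontsize=5)
    fig.colorbar(im, ax=ax, label="Pearson r")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
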