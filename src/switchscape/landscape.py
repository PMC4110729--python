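"""Attractor-pair orientation, directional/separate classification, density
grids and MFPT graphs.

For every unordered attractor pair the smaller of the two MFPTs is the
*forward* direction.  A pair is

* **separate** when even the forward MFPT is at least ``sep_threshold`` —
  both directions are hard, a high epigenetic barrier (transdifferentiation
  is blocked);
* **directional** when the reverse/forward ratio is at least
  ``dir_ratio_threshold`` (and the pair is not separate) — one-way movement
  as in differentiation;
* **neither** otherwise.

The thresholds are free parameters of the analysis and are echoed into all
tabular output; the defaults are ``dir_ratio_threshold = 10`` and
``sep_threshold = 1e3``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import networkx as nx
import numpy as np

from .errors import DomainError
from .markov import MfptMatrix

__all__ = [
    "PairRecord",
    "DensityGrid",
    "orient_pair",
    "classify_pair",
    "pair_records",
    "density_grid",
    "density_difference",
    "mfpt_graph",
    "prune",
    "DEFAULT_DIR_RATIO_THRESHOLD",
    "DEFAULT_SEP_THRESHOLD",
]

DEFAULT_DIR_RATIO_THRESHOLD = 10.0
DEFAULT_SEP_THRESHOLD = 1e3
#: default log10 histogram window; values outside are clipped into the edge bins
DEFAULT_LOG_RANGE = (0.0, 8.0)


@dataclass(frozen=True)
class PairRecord:
    """One oriented attractor pair."""

    attractor_i: int
    attractor_j: int
    forward_mfpt: float
    reverse_mfpt: float
    label: str = "unclassified"
    tie: bool = False


@dataclass(frozen=True)
class DensityGrid:
    """2-D histogram over (log10 forward, log10 reverse)."""

    hist: np.ndarray
    xedges: np.ndarray
    yedges: np.ndarray
    normalized: bool

    @property
    def mass(self) -> float:
        return float(self.hist.sum())


def orient_pair(mfpt_ij: float, mfpt_ji: float) -> tuple[float, float, bool]:
    """Return ``(forward, reverse, tie)`` with forward = the smaller MFPT.

    Ties keep the (i -> j) direction as forward and are flagged.
    """
    if not (mfpt_ij > 0 and mfpt_ji > 0) or not np.isfinite([mfpt_ij, mfpt_ji]).all():
        raise DomainError(f"MFPTs must be finite positive, got {mfpt_ij}, {mfpt_ji}")
    if mfpt_ij <= mfpt_ji:
        return float(mfpt_ij), float(mfpt_ji), mfpt_ij == mfpt_ji
    return float(mfpt_ji), float(mfpt_ij), False


def classify_pair(
    rec: PairRecord,
    dir_ratio_threshold: float = DEFAULT_DIR_RATIO_THRESHOLD,
    sep_threshold: float = DEFAULT_SEP_THRESHOLD,
) -> str:
    """Label an oriented pair ``separate`` / ``directional`` / ``neither``.

    Separation takes precedence: when the forward MFPT already exceeds
    ``sep_threshold`` both directions do, and the pair is a barrier, not a
    one-way transition.
    """
    if dir_ratio_threshold <= 0 or sep_threshold <= 0:
        raise DomainError("thresholds must be positive")
    if rec.forward_mfpt >= sep_threshold:
        return "separate"
    if rec.reverse_mfpt / rec.forward_mfpt >= dir_ratio_threshold:
        return "directional"
    return "neither"


def pair_records(
    mfpt: MfptMatrix,
    dir_ratio_threshold: float = DEFAULT_DIR_RATIO_THRESHOLD,
    sep_threshold: float = DEFAULT_SEP_THRESHOLD,
) -> list[PairRecord]:
    """Orient and classify every unordered attractor pair of an MFPT matrix."""
    out = []
    k = len(mfpt)
    for i in range(k):
        for j in range(i + 1, k):
            fwd, rev, tie = orient_pair(mfpt.values[i, j], mfpt.values[j, i])
            rec = PairRecord(
                attractor_i=mfpt.attractor_ids[i],
                attractor_j=mfpt.attractor_ids[j],
                forward_mfpt=fwd,
                reverse_mfpt=rev,
                tie=tie,
            )
            label = classify_pair(rec, dir_ratio_threshold, sep_threshold)
            out.append(
                PairRecord(
                    attractor_i=rec.attractor_i,
                    attractor_j=rec.attractor_j,
                    forward_mfpt=fwd,
                    reverse_mfpt=rev,
                    label=label,
                    tie=tie,
                )
            )
    return out


def density_grid(
    pairs: Sequence[PairRecord],
    bins: int = 40,
    log_range: tuple[float, float] = DEFAULT_LOG_RANGE,
    normalized: bool = False,
) -> DensityGrid:
    """Histogram of (log10 forward, log10 reverse) over a pair set.

    Values outside ``log_range`` are clipped into the boundary bins so that
    total mass always equals the number of pairs (or 1 when normalized).
    """
    if not pairs:
        raise DomainError("pair set must be nonempty")
    fwd = np.array([p.forward_mfpt for p in pairs])
    rev = np.array([p.reverse_mfpt for p in pairs])
    if np.any(fwd <= 0) or np.any(rev <= 0):
        raise DomainError("nonpositive MFPT in pair set")
    lo, hi = log_range
    eps = (hi - lo) / (bins * 1e6)
    x = np.clip(np.log10(fwd), lo, hi - eps)
    y = np.clip(np.log10(rev), lo, hi - eps)
    hist, xe, ye = np.histogram2d(
        x, y, bins=bins, range=[[lo, hi], [lo, hi]]
    )
    if normalized:
        hist = hist / hist.sum()
    return DensityGrid(hist=hist, xedges=xe, yedges=ye, normalized=normalized)


def density_difference(grid_a: DensityGrid, grid_b: DensityGrid) -> DensityGrid:
    """Elementwise ``a - b`` of two normalized grids on identical bins."""
    if grid_a.hist.shape != grid_b.hist.shape or not (
        np.allclose(grid_a.xedges, grid_b.xedges)
        and np.allclose(grid_a.yedges, grid_b.yedges)
    ):
        raise DomainError("density grids have mismatched binning")
    if not (grid_a.normalized and grid_b.normalized):
        raise DomainError("density difference requires normalized grids")
    return DensityGrid(
        hist=grid_a.hist - grid_b.hist,
        xedges=grid_a.xedges.copy(),
        yedges=grid_a.yedges.copy(),
        normalized=True,
    )


def mfpt_graph(mfpt: MfptMatrix) -> nx.DiGraph:
    """Weighted directed graph on attractors; edge weight = MFPT."""
    g = nx.DiGraph()
    for ident in mfpt.attractor_ids:
        g.add_node(ident)
    k = len(mfpt)
    for i in range(k):
        for j in range(k):
            if i != j:
                g.add_edge(
                    mfpt.attractor_ids[i],
                    mfpt.attractor_ids[j],
                    weight=float(mfpt.values[i, j]),
                )
    return g


def prune(graph: nx.DiGraph, threshold: float) -> nx.DiGraph:
    """Drop edges with MFPT above ``threshold``; the node set is unchanged.

    Successively raising the threshold on such graphs is the standard way
    to expose nested attractor clusters (low threshold = pluripotent,
    highly connected; high threshold = isolated, specialised).
    """
    if threshold <= 0:
        raise DomainError(f"threshold must be positive, got {threshold}")
    out = nx.DiGraph()
    out.add_nodes_from(graph.nodes(data=True))
    for u, v, data in graph.edges(data=True):
        if data["weight"] <= threshold:
            out.add_edge(u, v, **data)
    return out


def plot_density(grid: DensityGrid, path, title: Optional[str] = None) -> None:
    """Render a density (or difference) grid to PNG/SVG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 4))
    vmax = np.abs(grid.hist).max() or 1.0
    diverging = (grid.hist < 0).any()
    mesh = ax.pcolormesh(
        grid.xedges,
        grid.yedges,
        grid.hist.T,
        cmap="RdBu_r" if diverging else "viridis",
        vmin=-vmax if diverging else 0.0,
        vmax=vmax,
    )
    ax.set_xlabel("log10 forward MFPT")
    ax.set_ylabel("log10 reverse MFPT")
    if title:
        ax.set_title(title)
    fig.colorbar(mesh, ax=ax)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
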