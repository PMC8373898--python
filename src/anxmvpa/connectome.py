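"""Region-correlation connectome and seed-edge extraction.

For each diagnostic group, every atlas region is reduced to one time
series (voxel mean per task time point, then averaged across the group's
subjects, regardless of stimulus). The absolute Pearson correlation
between all region pairs forms a fully connected similarity matrix; edges
are retained either above an absolute threshold (|r| >= 0.6 is the study's
reporting convention) or in the top fraction of off-diagonal values
(top-30% percentile mode). Seed-edge extraction lists the suprathreshold
neighbours of a chosen seed region per group — the basis for comparing how
widely the seed couples to the rest of the brain in each group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .volume_io import TimePointDataset

__all__ = [
    "RegionCorrelationGraph",
    "region_mean_series",
    "correlation_network",
    "seed_edges",
]


@dataclass
class RegionCorrelationGraph:
    """Absolute region-correlation matrix plus its thresholded edge list."""

    matrix: pd.DataFrame  # R x R, |Pearson r|, diagonal 1
    threshold: float
    mode: str  # "absolute" or "percentile"
    edges: pd.DataFrame  # columns: region_i, region_j, abs_r (i < j)

    def to_networkx(self):
        """Export the thresholded graph (e.g. for GraphML serialization)."""
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(int(r) for r in self.matrix.index)
        for row in self.edges.itertuples(index=False):
            g.add_edge(int(row.region_i), int(row.region_j), abs_r=float(row.abs_r))
        return g


def region_mean_series(
    ds: TimePointDataset, group: str | None = None
) -> pd.DataFrame:
    """R x T region-mean time series, averaged across a group's subjects.

    Per region: mean over its voxels at each task time point, then mean
    over subjects (all subjects when ``group`` is None). All task time
    points are used regardless of stimulus.
    """
    if group is None:
        idx = np.arange(ds.n_subjects)
    else:
        idx = np.flatnonzero(ds.group_labels == group)
        if idx.size == 0:
            raise ValueError(f"no subjects in group {group!r}")
    rows = {}
    for rid, sl in sorted(ds.region_index.items()):
        block = ds.features[idx][:, :, sl]  # (n, T, V_r)
        if block.shape[2] == 0:
            raise ValueError(f"region {rid} is empty")
        rows[rid] = block.mean(axis=2).mean(axis=0)
    return pd.DataFrame.from_dict(rows, orient="index")


def correlation_network(
    series: pd.DataFrame,
    threshold: float | str = 0.6,
) -> RegionCorrelationGraph:
    """Absolute-Pearson correlation graph over region-mean series.

    ``threshold`` is either an absolute |r| cut in [0, 1] or a percentile
    spec string like ``"top30%"`` (retain the top fraction of off-diagonal
    |r| values). Zero-variance series give undefined correlations: their
    edges are dropped with a warning.
    """
    mat = series.to_numpy(dtype=float)
    R, T = mat.shape
    if R < 2:
        raise ValueError("need at least two regions")
    if T < 3:
        raise ValueError("need at least three time points")
    sd = mat.std(axis=1)
    degenerate = np.flatnonzero(sd == 0)
    if degenerate.size:
        warnings.warn(
            f"zero-variance region series {list(series.index[degenerate])}; "
            "their correlations are undefined and dropped",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.abs(np.corrcoef(mat))
    np.fill_diagonal(corr, 1.0)

    iu = np.triu_indices(R, k=1)
    offdiag = corr[iu]
    if isinstance(threshold, str):
        spec = threshold.strip().lower()
        if not (spec.startswith("top") and spec.endswith("%")):
            raise ValueError(f"bad percentile spec {threshold!r}; use e.g. 'top30%'")
        frac = float(spec[3:-1]) / 100.0
        if not 0 < frac <= 1:
            raise ValueError("percentile fraction must be in (0, 100]")
        finite = offdiag[np.isfinite(offdiag)]
        cut = float(np.quantile(finite, 1.0 - frac))
        mode = "percentile"
    else:
        cut = float(threshold)
        if not 0.0 <= cut <= 1.0:
            raise ValueError("absolute threshold must lie in [0, 1]")
        mode = "absolute"

    ids = list(series.index)
    edges = []
    for a, b in zip(*iu):
        r = corr[a, b]
        if np.isfinite(r) and r >= cut:
            edges.append((ids[a], ids[b], float(r)))
    edge_df = pd.DataFrame(edges, columns=["region_i", "region_j", "abs_r"])
    matrix = pd.DataFrame(corr, index=ids, columns=ids)
    return RegionCorrelationGraph(matrix=matrix, threshold=cut, mode=mode, edges=edge_df)


def seed_edges(graph: RegionCorrelationGraph, seed_region: int) -> pd.DataFrame:
    """Suprathreshold neighbours of the seed region, sorted by |r| descending.

    Returns a DataFrame (region, abs_r); its row count is the group's
    seed-edge count.
    """
    if seed_region not in graph.matrix.index:
        raise KeyError(f"seed region {seed_region} not in graph")
    e = graph.edges
    mask = (e["region_i"] == seed_region) | (e["region_j"] == seed_region)
    sub = e[mask]
    neigh = np.where(sub["region_i"] == seed_region, sub["region_j"], sub["region_i"])
    out = pd.DataFrame({"region": neigh, "abs_r": sub["abs_r"].to_numpy()})
    return out.sort_values("abs_r", ascending=False, kind="stable").reset_index(drop=True)
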