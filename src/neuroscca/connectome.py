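"""Weighted functional-connectome construction and betweenness centrality.

Per subject: a region x region Pearson correlation matrix is computed from
ROI time series, edges are soft-thresholded as ((r + 1) / 2) ** beta with
scale-free index beta (default 6), the resulting weights in [0, 1] are
variance-stabilized by Fisher's r-to-z transform, and node betweenness
centrality is computed on the weighted graph with edge length 1 / weight
(stronger connectivity = shorter path). Betweenness is unnormalized Brandes
counting: fractional credit when multiple shortest paths tie, endpoints
excluded.
"""

from __future__ import annotations

import numpy as np
import networkx as nx
import pandas as pd

from .errors import DataError
from .synthetic import RoiTimeSeriesPanel

__all__ = [
    "correlation_matrix",
    "soft_threshold_edge",
    "fisher_z",
    "connectivity_to_weights",
    "betweenness",
    "build_centrality_table",
]

DEFAULT_BETA = 6
#: weights at or below this are treated as absent edges (their 1/w length
#: would otherwise dominate every shortest path)
EDGE_EPS = 1e-12
#: clip soft-thresholded weights just below 1 where atanh diverges
ATANH_CLIP = 1e-7


def correlation_matrix(ts) -> pd.DataFrame:
    """Pearson correlation matrix of one subject's timepoints x regions data.

    Raises :class:`DataError` naming the offending region if any column is
    constant (its correlation is undefined).
    """
    if isinstance(ts, pd.DataFrame):
        region_ids = list(ts.columns)
        arr = ts.to_numpy(dtype=float)
    else:
        arr = np.asarray(ts, dtype=float)
        region_ids = [f"R{i + 1}" for i in range(arr.shape[1])]
    if arr.ndim != 2 or arr.shape[0] < 3:
        raise DataError("time series must be 2-D with at least 3 timepoints")
    sd = arr.std(axis=0)
    if np.any(sd == 0):
        bad = [region_ids[i] for i in np.flatnonzero(sd == 0)]
        raise DataError(f"constant time series for region(s) {bad}: correlation undefined")
    R = np.corrcoef(arr, rowvar=False)
    R = np.clip((R + R.T) / 2.0, -1.0, 1.0)
    return pd.DataFrame(R, index=region_ids, columns=region_ids)


def soft_threshold_edge(r, beta: int = DEFAULT_BETA):
    """Scale-free soft thresholding ((r + 1) / 2) ** beta, mapping [-1,1] -> [0,1]."""
    r = np.asarray(r, dtype=float)
    if beta < 1:
        raise DataError(f"beta must be >= 1, got {beta}")
    if np.any(r < -1) or np.any(r > 1):
        raise DataError("correlation outside [-1, 1]; input is corrupt")
    out = ((r + 1.0) / 2.0) ** beta
    return out if out.ndim else float(out)


def fisher_z(w):
    """Fisher r-to-z transform atanh(w), clipping at 1 - 1e-7 where it diverges."""
    w = np.asarray(w, dtype=float)
    if np.any(w < 0) or np.any(w > 1):
        raise DataError("soft-thresholded weight outside [0, 1]")
    out = np.arctanh(np.minimum(w, 1.0 - ATANH_CLIP))
    return out if out.ndim else float(out)


def connectivity_to_weights(R: pd.DataFrame, beta: int = DEFAULT_BETA) -> pd.DataFrame:
    """Soft-threshold and z-transform a correlation matrix into edge weights.

    The diagonal is zeroed: self-edges carry no path information.
    """
    W = fisher_z(soft_threshold_edge(R.to_numpy(), beta))
    np.fill_diagonal(W, 0.0)
    return pd.DataFrame(W, index=R.index, columns=R.columns)


def betweenness(W) -> np.ndarray:
    """Unnormalized weighted betweenness centrality of every node.

    ``W`` is a symmetric nonnegative weight matrix (connectivity strengths).
    Shortest-path edge length is 1 / weight; weights <= 1e-12 are treated as
    absent edges. Ties between shortest paths share credit fractionally
    (Brandes accumulation); path endpoints receive no credit.
    """
    if isinstance(W, pd.DataFrame):
        W = W.to_numpy(dtype=float)
    else:
        W = np.asarray(W, dtype=float)
    n = W.shape[0]
    if W.ndim != 2 or W.shape[1] != n:
        raise DataError("weight matrix must be square")
    if n < 3:
        raise DataError("need at least 3 nodes for betweenness")
    if np.any(W < 0):
        raise DataError("negative edge weight")
    if not np.allclose(W, W.T, atol=1e-12):
        raise DataError("weight matrix must be symmetric")

    G = nx.Graph()
    G.add_nodes_from(range(n))
    ii, jj = np.nonzero(np.triu(W, k=1) > EDGE_EPS)
    G.add_weighted_edges_from(
        ((int(i), int(j), 1.0 / W[i, j]) for i, j in zip(ii, jj)), weight="length"
    )
    bc = nx.betweenness_centrality(G, normalized=False, weight="length")
    return np.array([bc[i] for i in range(n)])


def build_centrality_table(panel: RoiTimeSeriesPanel, beta: int = DEFAULT_BETA) -> pd.DataFrame:
    """Per-subject composition: correlation -> soft threshold -> Fisher z -> betweenness."""
    rows = []
    for i, sid in enumerate(panel.subject_ids):
        try:
            R = correlation_matrix(panel.data[i])
            W = connectivity_to_weights(R, beta)
            rows.append(betweenness(W))
        except DataError as exc:
            raise DataError(f"subject {sid}: {exc}") from exc
    return pd.DataFrame(
        np.asarray(rows),
        index=pd.Index(panel.subject_ids, name="subject_id"),
        columns=panel.region_ids,
    )
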