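"""Phase-synchrony graphs and node-level network features.

For each narrowband frequency, the all-to-all phase-locking value (PLV)
matrix is the modulus of the time-averaged unit phasor of pairwise phase
differences. Node features on the weighted PLV graph:

* eigenvector centrality (EVC) — leading eigenvector, scaled to unit max;
* effective weight (We) — mean weight of a node's suprathreshold edges
  (threshold = graph-wide median edge weight), a first-order hub measure;
* clustering coefficient (Cc) — geometric-mean triangle intensity
  (Onnela formulation) on the suprathreshold graph;
* local efficiency (LE) — mean inverse shortest-path length within each
  node's neighborhood subgraph, distances = 1/weight on suprathreshold
  edges.

First-order measures (EVC, We) characterize strongly connected hubs;
second-order measures (Cc, LE) regions whose neighbors are densely
interconnected.
"""

from __future__ import annotations

import numpy as np
from scipy.sparse.csgraph import shortest_path


def plv_matrix(phases: np.ndarray) -> np.ndarray:
    """All-to-all phase-locking value.

    Parameters
    ----------
    phases : (n_channels, n_samples) instantaneous phases in radians
        (edge-contaminated samples already removed).
    """
    phases = np.asarray(phases, dtype=float)
    if phases.ndim != 2 or phases.shape[0] < 2:
        raise ValueError("need a 2D (channels x samples) phase array, >=2 channels")
    z = np.exp(1j * phases)
    n = phases.shape[1]
    plv = np.abs(z @ z.conj().T) / n
    np.fill_diagonal(plv, 1.0)
    return np.clip(plv, 0.0, 1.0)


def _check_weights(w: np.ndarray) -> np.ndarray:
    w = np.asarray(w, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("weight matrix must be square")
    w = w.copy()
    np.fill_diagonal(w, 0.0)
    return w


def eigenvector_centrality(w: np.ndarray) -> np.ndarray:
    """Leading-eigenvector centrality, non-negative, max-normalized."""
    w = _check_weights(w)
    if not np.any(w):
        raise ValueError("all-zero adjacency matrix")
    vals, vecs = np.linalg.eigh(w)
    v = np.abs(vecs[:, np.argmax(vals)])
    return v / v.max()


def _edge_threshold(w: np.ndarray) -> float:
    """Graph-wide median edge weight (upper triangle, off-diagonal)."""
    iu = np.triu_indices_from(w, k=1)
    return float(np.median(w[iu]))


def effective_weight(w: np.ndarray, threshold: float | None = None) -> np.ndarray:
    """Mean weight of each node's suprathreshold (>= median) edges.

    Nodes with no suprathreshold edge score 0. ``threshold=0`` reduces to
    plain node strength / (q - 1).
    """
    w = _check_weights(w)
    thr = _edge_threshold(w) if threshold is None else threshold
    mask = (w >= thr) & (w > 0)
    np.fill_diagonal(mask, False)
    counts = mask.sum(axis=1)
    sums = (w * mask).sum(axis=1)
    return np.divide(sums, counts, out=np.zeros(w.shape[0]), where=counts > 0)


def _suprathreshold(w: np.ndarray, threshold: float | None) -> np.ndarray:
    thr = _edge_threshold(w) if threshold is None else threshold
    ws = np.where(w >= thr, w, 0.0)
    np.fill_diagonal(ws, 0.0)
    return ws


def clustering_coefficient(w: np.ndarray, threshold: float | None = None) -> np.ndarray:
    """Weighted clustering coefficient, geometric-mean triangle intensity.

    Onnela's formulation on the suprathreshold graph with weights
    normalized by the maximum edge weight: for node i with degree k_i,
    Cc_i = (1 / (k_i (k_i - 1))) * sum_{j,h} (w_ij w_ih w_jh)^(1/3).
    Nodes of degree < 2 score 0.
    """
    w = _check_weights(w)
    ws = _suprathreshold(w, threshold)
    wmax = ws.max()
    if wmax == 0:
        return np.zeros(w.shape[0])
    cube = np.cbrt(ws / wmax)
    triangles = np.diag(cube @ cube @ cube)  # 2x the triangle intensity sum
    deg = (ws > 0).sum(axis=1)
    denom = deg * (deg - 1)
    return np.divide(
        triangles, denom, out=np.zeros(w.shape[0]), where=denom > 0
    )


def local_efficiency(w: np.ndarray, threshold: float | None = None) -> np.ndarray:
    """Mean inverse shortest-path length within each node's neighborhood.

    Distances are 1/weight on suprathreshold edges; paths are restricted to
    the neighborhood subgraph. Neighborhoods with < 2 nodes score 0.
    Weights in [0, 1] give distances >= 1, so LE lies in [0, 1].
    """
    w = _check_weights(w)
    ws = _suprathreshold(w, threshold)
    q = w.shape[0]
    le = np.zeros(q)
    for i in range(q):
        nbrs = np.flatnonzero(ws[i] > 0)
        if nbrs.size < 2:
            continue
        sub = ws[np.ix_(nbrs, nbrs)]
        with np.errstate(divide="ignore"):
            dist = np.where(sub > 0, 1.0 / sub, np.inf)
        np.fill_diagonal(dist, 0.0)
        sp = shortest_path(dist, method="D", directed=False)
        iu = np.triu_indices(nbrs.size, k=1)
        inv = np.where(np.isfinite(sp[iu]) & (sp[iu] > 0), 1.0 / sp[iu], 0.0)
        le[i] = inv.mean()
    return le


def synchrony_features(plv: np.ndarray) -> dict[str, np.ndarray]:
    """All four node features for one band's PLV matrix."""
    return {
        "evc": eigenvector_centrality(plv),
        "we": effective_weight(plv),
        "cc": clustering_coefficient(plv),
        "le": local_efficiency(plv),
    }
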