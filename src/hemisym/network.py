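"""Hemispheric network construction and graph-theoretic metrics.

From a full-scalp connectivity matrix, two 18-node hemispheric networks
are built (14 lateral electrodes of one side plus the 4 midline
electrodes); interhemispheric lateral connections are discarded.  Each
weighted network is proportionally thresholded — the top S% of the 153
possible edges are retained and binarised — and six topological
properties are computed on the binary graph:

* clustering coefficient  Cp(i) = E_i / (D_i (D_i - 1) / 2), network
  mean over all nodes (0 for degree < 2);
* characteristic path length Lp: mean shortest-path length over ordered
  pairs, disconnected pairs excluded (with a warning);
* global efficiency Eg: mean of 1/L_ij over ordered pairs, 1/inf = 0;
* local efficiency Eloc(i): global efficiency of the subgraph induced by
  i's neighbours (0 for fewer than 2 neighbours), network mean;
* nodal efficiency Enodal(i): mean of 1/L_ij over the other N-1 nodes;
* small-world index sigma = (Cp/Crandom) / (Lp/Lrandom) against a
  degree-preserving rewired null ensemble.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import shortest_path

from .connectivity import ConnectivityMatrix
from .exceptions import ValidationError
from .montage import Montage, deap_montage


class DisconnectedGraphWarning(UserWarning):
    """Raised when shortest-path averages exclude disconnected pairs."""


# ---------------------------------------------------------------------------
# Construction
# ---------------------------------------------------------------------------

@dataclass
class HemisphericAdjacency:
    """Thresholded adjacency of one hemispheric network."""

    nodes: tuple[str, ...]
    adjacency: np.ndarray
    sparsity: float
    hemisphere: str

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency, dtype=float)
        if a.ndim != 2 or a.shape[0] != a.shape[1] or a.shape[0] != len(self.nodes):
            raise ValidationError("adjacency shape does not match node list")
        if not np.array_equal(a, a.T) or np.any(np.diag(a) != 0):
            raise ValidationError("adjacency must be symmetric with zero diagonal")
        self.adjacency = a

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.adjacency, 1)))


def split_hemispheres(conn: ConnectivityMatrix | np.ndarray,
                      montage: Montage | None = None,
                      channels: tuple[str, ...] | None = None,
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Extract raw weighted left/right 18x18 hemispheric matrices.

    Node order is the montage's lateral order followed by the midline,
    so node i of the left matrix is the homolog of node i of the right
    matrix.  Entries connecting the opposite hemisphere's lateral
    channels appear in neither output.
    """
    montage = montage or deap_montage()
    if isinstance(conn, ConnectivityMatrix):
        values = conn.values
        channels = channels or conn.channels or montage.channels
    else:
        values = np.asarray(conn, dtype=float)
        channels = channels or montage.channels
    if values.shape[0] != montage.n_channels:
        raise ValidationError(
            f"expected {montage.n_channels}-channel matrix, got {values.shape}")
    order = montage.resolve(channels)
    full = values[np.ix_(order, order)]  # montage order
    out = []
    for side in ("left", "right"):
        ix = montage.indices(montage.hemisphere_channels(side))
        out.append(full[np.ix_(ix, ix)].copy())
    return out[0], out[1]


def edge_count(s_thr: float, n_nodes: int) -> int:
    """Edges retained at sparsity s_thr percent: round-half-away-from-zero
    of s_thr/100 x n(n-1)/2."""
    possible = n_nodes * (n_nodes - 1) // 2
    return int(np.floor(s_thr / 100.0 * possible + 0.5))


def sparsity_threshold(raw: np.ndarray, s_thr: float,
                       nodes: tuple[str, ...] = (),
                       hemisphere: str = "",
                       binarize: bool = True) -> HemisphericAdjacency:
    """Keep the top s_thr% of possible edges by weight.

    Ties among equal weights are broken deterministically by ascending
    (row, column) index.  By default the retained edges are binarised;
    ``binarize=False`` keeps the original weights.
    """
    raw = np.asarray(raw, dtype=float)
    n = raw.shape[0]
    if raw.ndim != 2 or raw.shape[1] != n:
        raise ValidationError("expected a square matrix")
    if not (0.0 < s_thr <= 100.0):
        raise ValidationError(f"sparsity threshold must be in (0, 100], got {s_thr}")
    if np.any(raw < 0):
        raise ValidationError("edge weights must be non-negative")
    k = edge_count(s_thr, n)
    iu, ju = np.triu_indices(n, 1)
    w = raw[iu, ju]
    # sort by descending weight, then ascending (i, j) for determinism
    order = np.lexsort((ju, iu, -w))[:k]
    adj = np.zeros((n, n))
    vals = 1.0 if binarize else w[order]
    adj[iu[order], ju[order]] = vals
    adj[ju[order], iu[order]] = vals
    if not nodes:
        nodes = tuple(str(i) for i in range(n))
    return HemisphericAdjacency(nodes, adj, s_thr / 100.0, hemisphere)


def _as_matrix(adj) -> np.ndarray:
    a = adj.adjacency if isinstance(adj, HemisphericAdjacency) else np.asarray(adj)
    return (a != 0).astype(float)


# ---------------------------------------------------------------------------
# Metrics (binary formulas)
# ---------------------------------------------------------------------------

def clustering_coefficient(adj) -> float:
    """Network clustering coefficient: mean over all N nodes of
    E_i / (D_i(D_i-1)/2), where E_i counts edges among i's neighbours."""
    a = _as_matrix(adj)
    deg = a.sum(axis=1)
    # (A^3)_ii = 2 x number of edges among neighbours of i
    e_i = np.einsum("ij,jk,ki->i", a, a, a) / 2.0
    denom = deg * (deg - 1) / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        cp_i = np.where(deg >= 2, e_i / np.where(denom > 0, denom, 1.0), 0.0)
    return float(cp_i.mean())


def _distances(a: np.ndarray) -> np.ndarray:
    if a.shape[0] == 0:
        return np.zeros((0, 0))
    return shortest_path(a, method="D", unweighted=True)


def characteristic_path_length(adj) -> float:
    """Mean shortest-path length over ordered node pairs.

    Disconnected pairs are excluded from the average (a
    :class:`DisconnectedGraphWarning` is emitted); if no pair is
    connected the value is NaN.
    """
    a = _as_matrix(adj)
    d = _distances(a)
    off = ~np.eye(a.shape[0], dtype=bool)
    finite = np.isfinite(d) & off
    n_inf = int(np.count_nonzero(off & ~np.isfinite(d)))
    if not finite.any():
        warnings.warn("graph has no connected pairs: Lp undefined",
                      DisconnectedGraphWarning, stacklevel=2)
        return float("nan")
    if n_inf:
        warnings.warn(
            f"{n_inf} disconnected ordered pairs excluded from Lp",
            DisconnectedGraphWarning, stacklevel=2)
    return float(d[finite].mean())


def _efficiency_matrix(a: np.ndarray) -> np.ndarray:
    d = _distances(a)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return inv


def global_efficiency(adj) -> float:
    """Mean of 1/L_ij over ordered pairs, with 1/inf = 0."""
    a = _as_matrix(adj)
    n = a.shape[0]
    if n < 2:
        return 0.0
    return float(_efficiency_matrix(a).sum() / (n * (n - 1)))


def nodal_efficiency(adj) -> np.ndarray:
    """Per-node efficiency: mean of 1/L_ij over the other N-1 nodes."""
    a = _as_matrix(adj)
    n = a.shape[0]
    if n < 2:
        return np.zeros(n)
    return _efficiency_matrix(a).sum(axis=1) / (n - 1)


def local_efficiency(adj) -> float:
    """Mean over nodes of the global efficiency of each node's
    neighbour-induced subgraph (0 for fewer than 2 neighbours)."""
    a = _as_matrix(adj)
    vals = np.zeros(a.shape[0])
    for i in range(a.shape[0]):
        nb = np.flatnonzero(a[i])
        if nb.size < 2:
            continue
        vals[i] = global_efficiency(a[np.ix_(nb, nb)])
    return float(vals.mean())


# ---------------------------------------------------------------------------
# Weighted generalizations
# ---------------------------------------------------------------------------

def _weights(adj) -> np.ndarray:
    a = adj.adjacency if isinstance(adj, HemisphericAdjacency) else np.asarray(adj)
    return a.astype(float)


def weighted_clustering_coefficient(adj) -> float:
    """Onnela weighted clustering: geometric-mean triangle intensity over
    weights normalised by the maximum weight; reduces to the binary value
    on 0/1 matrices."""
    w = _weights(adj)
    if w.max() == 0:
        return 0.0
    what = (w / w.max()) ** (1.0 / 3.0)
    deg = (w > 0).sum(axis=1).astype(float)
    num = np.einsum("ij,jk,ki->i", what, what, what)
    denom = deg * (deg - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cp_i = np.where(deg >= 2, num / np.where(denom > 0, denom, 1.0), 0.0)
    return float(cp_i.mean())


def _weighted_distances(w: np.ndarray) -> np.ndarray:
    """Shortest paths with edge lengths 1/weight (stronger = shorter)."""
    with np.errstate(divide="ignore"):
        lengths = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), 0.0)
    return shortest_path(lengths, method="D", directed=False)


def weighted_global_metrics(adj) -> "GlobalMetrics":
    """Weighted Lp/Eg/Eloc with 1/weight path lengths and Onnela Cp.

    Sigma is left undefined here: the degree-preserving null is a binary
    construct and is only reported for binary networks.
    """
    w = _weights(adj)
    n = w.shape[0]
    d = _weighted_distances(w)
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(d) & off
    lp = float(d[finite].mean()) if finite.any() else float("nan")
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    eg = float(inv.sum() / (n * (n - 1))) if n > 1 else 0.0
    eloc = np.zeros(n)
    for i in range(n):
        nb = np.flatnonzero(w[i])
        if nb.size < 2:
            continue
        sub = w[np.ix_(nb, nb)]
        dsub = _weighted_distances(sub)
        with np.errstate(divide="ignore"):
            invs = 1.0 / dsub
        invs[~np.isfinite(invs)] = 0.0
        np.fill_diagonal(invs, 0.0)
        eloc[i] = invs.sum() / (nb.size * (nb.size - 1))
    return GlobalMetrics(cp=weighted_clustering_coefficient(w), lp=lp,
                         eg=eg, eloc=float(eloc.mean()))


def weighted_nodal_efficiency(adj) -> np.ndarray:
    w = _weights(adj)
    n = w.shape[0]
    if n < 2:
        return np.zeros(n)
    d = _weighted_distances(w)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return inv.sum(axis=1) / (n - 1)


# ---------------------------------------------------------------------------
# Null model and small-world index
# ---------------------------------------------------------------------------

def random_rewire(adj, n_swaps: int, rng: np.random.Generator) -> np.ndarray:
    """Degree-preserving randomisation by attempted double-edge swaps.

    Each attempt picks two distinct edges (a,b), (c,d) and proposes
    (a,d), (c,b); the proposal is rejected if it would create a self-loop
    or a duplicate edge.  Exactly ``n_swaps`` attempts are made, so the
    degree sequence and edge count are invariant.
    """
    a = _as_matrix(adj).copy()
    iu, ju = np.nonzero(np.triu(a, 1))
    edges = list(zip(iu.tolist(), ju.tolist()))
    if len(edges) < 2:
        raise ValidationError("need at least 2 edges to rewire")
    m = len(edges)
    for _ in range(int(n_swaps)):
        e1, e2 = rng.integers(0, m), rng.integers(0, m)
        if e1 == e2:
            continue
        x1, y1 = edges[e1]
        x2, y2 = edges[e2]
        if rng.random() < 0.5:
            x2, y2 = y2, x2
        # propose (x1, y2) and (x2, y1)
        if len({x1, y1, x2, y2}) < 4:
            continue
        if a[x1, y2] or a[x2, y1]:
            continue
        a[x1, y1] = a[y1, x1] = 0.0
        a[x2, y2] = a[y2, x2] = 0.0
        a[x1, y2] = a[y2, x1] = 1.0
        a[x2, y1] = a[y1, x2] = 1.0
        edges[e1] = (min(x1, y2), max(x1, y2))
        edges[e2] = (min(x2, y1), max(x2, y1))
    return a


def small_world_sigma(adj, n_null: int = 100, rng: np.random.Generator | None = None,
                      swap_factor: int = 10, max_resample: int = 10,
                      ) -> tuple[float, float, float]:
    """Small-world index sigma = (Cp/Crandom) / (Lp/Lrandom).

    Crandom and Lrandom are means over ``n_null`` degree-preserving
    rewired surrogates (swap_factor x |E| attempted swaps each).  A null
    whose Lp is undefined is resampled up to ``max_resample`` times with
    a warning.  Returns (sigma, Crandom, Lrandom).
    """
    rng = rng if rng is not None else np.random.default_rng()
    a = _as_matrix(adj)
    cp = clustering_coefficient(a)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", DisconnectedGraphWarning)
        lp = characteristic_path_length(a)
    n_edges = int(np.count_nonzero(np.triu(a, 1)))
    c_nulls, l_nulls = [], []
    for _ in range(int(n_null)):
        for attempt in range(max_resample + 1):
            null = random_rewire(a, swap_factor * n_edges, rng)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", DisconnectedGraphWarning)
                l_null = characteristic_path_length(null)
            if np.isfinite(l_null):
                break
            warnings.warn("null surrogate with undefined Lp resampled",
                          stacklevel=2)
        c_nulls.append(clustering_coefficient(null))
        l_nulls.append(l_null)
    c_rand = float(np.mean(c_nulls))
    l_rand = float(np.nanmean(l_nulls))
    if c_rand == 0 or not np.isfinite(lp) or lp == 0 or l_rand == 0:
        warnings.warn("small-world index undefined for this graph", stacklevel=2)
        return float("nan"), c_rand, l_rand
    return (cp / c_rand) / (lp / l_rand), c_rand, l_rand


# ---------------------------------------------------------------------------
# Convenience aggregation
# ---------------------------------------------------------------------------

@dataclass
class GlobalMetrics:
    """The five global properties plus the null-model means behind sigma."""

    cp: float
    lp: float
    eg: float
    eloc: float
    sigma: float = float("nan")
    c_random: float = float("nan")
    l_random: float = float("nan")


def global_metrics(adj, include_sigma: bool = False, n_null: int = 100,
                   rng: np.random.Generator | None = None) -> GlobalMetrics:
    a = _as_matrix(adj)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", DisconnectedGraphWarning)
        lp = characteristic_path_length(a)
    gm = GlobalMetrics(
        cp=clustering_coefficient(a), lp=lp,
        eg=global_efficiency(a), eloc=local_efficiency(a),
    )
    if include_sigma:
        gm.sigma, gm.c_random, gm.l_random = small_world_sigma(
            a, n_null=n_null, rng=rng)
    return gm


__all__ = [
    "DisconnectedGraphWarning", "HemisphericAdjacency", "split_hemispheres",
    "edge_count", "sparsity_threshold", "clustering_coefficient",
    "characteristic_path_length", "global_efficiency", "local_efficiency",
    "nodal_efficiency", "random_rewire", "small_world_sigma",
    "GlobalMetrics", "global_metrics", "weighted_clustering_coefficient",
    "weighted_global_metrics", "weighted_nodal_efficiency",
]
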