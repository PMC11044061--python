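"""Weighted graph-theory metrics for thresholded similarity networks.

Implements the standard connectome-toolbox measures on weighted undirected
graphs with weights in [0, 1]:

* transitivity — ratio of weighted closed triplets (Onnela geometric-mean
  triangle intensity) to connected triplets, pooled over the whole network;
  a measure of segregation.
* global efficiency — mean inverse shortest weighted path length over all
  ordered node pairs; a measure of integration.  Path lengths use the
  similarity-network convention length = 1/weight.
* per-node weighted clustering (Onnela) and characteristic path length,
  which feed the small-world coefficient
  sigma = (C/C_rand) / (L/L_rand) against degree-preserving rewired null
  networks that keep the empirical weight multiset.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import connected_components, shortest_path

from msnpipe.errors import DisconnectedNetworkError, UndefinedMetricError
from msnpipe.msn import ThresholdedNetwork

logger = logging.getLogger(__name__)


def _weights(net: ThresholdedNetwork | np.ndarray) -> np.ndarray:
    w = net.weights if isinstance(net, ThresholdedNetwork) else np.asarray(net, dtype=float)
    if (w < 0).any() or (w > 1).any():
        raise ValueError("weights must lie in [0, 1]")
    return w


def transitivity_weighted(net: ThresholdedNetwork | np.ndarray) -> float:
    """Weighted transitivity: sum of geometric-mean triangle intensities
    around each node over the total count of connected triplets.

    T = tr((W^(1/3))^3) / sum_i k_i (k_i - 1), with k_i the binary degree.
    Returns 0 when no node has degree >= 2.
    """
    w = _weights(net)
    k = (w > 0).sum(axis=0)
    denom = float((k * (k - 1)).sum())
    if denom == 0:
        return 0.0
    root = np.cbrt(w)
    triangles = float(np.trace(root @ root @ root))
    return triangles / denom


def clustering_coefficient_weighted(net: ThresholdedNetwork | np.ndarray) -> np.ndarray:
    """Onnela per-node weighted clustering coefficient.

    c_i = [ (W^(1/3))^3 ]_ii / (k_i (k_i - 1)); 0 where k_i < 2.
    """
    w = _weights(net)
    k = (w > 0).sum(axis=0)
    root = np.cbrt(w)
    cyc = np.diagonal(root @ root @ root)
    denom = k * (k - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, cyc / np.where(denom > 0, denom, 1), 0.0)
    return c


def _distance_matrix(w: np.ndarray) -> np.ndarray:
    """All-pairs shortest weighted paths with edge length = 1/weight."""
    with np.errstate(divide="ignore"):
        lengths = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), 0.0)
    return shortest_path(lengths, method="D", directed=False, unweighted=False)


def global_efficiency_weighted(net: ThresholdedNetwork | np.ndarray) -> float:
    """Mean inverse shortest path length over ordered pairs; unreachable
    pairs contribute 0."""
    w = _weights(net)
    n = w.shape[0]
    if n < 2:
        return 0.0
    d = _distance_matrix(w)
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d) & (d > 0), 1.0 / np.where(d > 0, d, 1.0), 0.0)
    return float(inv[off].sum() / (n * (n - 1)))


def characteristic_path_length(net: ThresholdedNetwork | np.ndarray) -> float:
    """Mean shortest path length over reachable ordered pairs.

    On disconnected input, unreachable pairs are dropped with a warning.
    """
    w = _weights(net)
    n = w.shape[0]
    if n < 2:
        raise UndefinedMetricError("characteristic path length undefined for < 2 nodes")
    d = _distance_matrix(w)
    off = ~np.eye(n, dtype=bool)
    reachable = np.isfinite(d) & off
    if reachable.sum() < off.sum():
        logger.warning("network disconnected; path length computed over reachable pairs only")
    if reachable.sum() == 0:
        raise UndefinedMetricError("no reachable pairs: network has no edges")
    return float(d[reachable].mean())


def is_connected(net: ThresholdedNetwork | np.ndarray) -> bool:
    """True iff a single component spans all nodes (edges = nonzero weights)."""
    w = _weights(net)
    if w.shape[0] <= 1:
        return True
    n_comp, _ = connected_components((w > 0).astype(int), directed=False)
    return bool(n_comp == 1)


def _rewired_null(w: np.ndarray, rng: np.random.Generator, max_tries: int = 10) -> np.ndarray:
    """Degree-preserving rewired surrogate retaining the weight multiset.

    Maslov–Sneppen-style double-edge swaps on the binary topology (~10
    swaps per edge), then the empirical weights are reassigned to the
    rewired edges in random order.  Retries with a fresh sub-seed if the
    swap search stalls.
    """
    n = w.shape[0]
    iu, ju = np.nonzero(np.triu(w, k=1))
    weights = w[iu, ju]
    g = nx.Graph(zip(iu.tolist(), ju.tolist()))
    g.add_nodes_from(range(n))
    n_edges = g.number_of_edges()
    nswap = max(1, 10 * n_edges)
    last_err: Exception | None = None
    for _ in range(max_tries):
        seed = int(rng.integers(0, 2**31 - 1))
        trial = g.copy()
        try:
            if n_edges >= 2:
                nx.double_edge_swap(trial, nswap=nswap, max_tries=100 * nswap, seed=seed)
        except nx.NetworkXError as err:  # swap search exhausted
            last_err = err
            continue
        out = np.zeros_like(w)
        edges = np.array(sorted(trial.edges()))
        perm = rng.permutation(len(weights))
        out[edges[:, 0], edges[:, 1]] = weights[perm]
        out += out.T
        return out
    raise RuntimeError(f"degree-preserving rewiring failed after {max_tries} attempts: {last_err}")


def small_worldness(
    net: ThresholdedNetwork | np.ndarray, n_null: int = 10, seed: int = 0
) -> float:
    """Small-world coefficient sigma = (C/C_rand) / (L/L_rand).

    C is the mean Onnela weighted clustering coefficient and L the
    characteristic path length; the reference values are averaged over
    ``n_null`` degree-preserving rewired surrogates that keep the weight
    multiset.  sigma > 1 indicates small-world organization.  Requires a
    connected input.
    """
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    w = _weights(net)
    if not is_connected(w):
        raise DisconnectedNetworkError("small-worldness requires a connected network")
    c = float(clustering_coefficient_weighted(w).mean())
    length = characteristic_path_length(w)
    rng = np.random.default_rng(seed)
    c_rand = np.empty(n_null)
    l_rand = np.empty(n_null)
    for b in range(n_null):
        null = _rewired_null(w, rng)
        c_rand[b] = float(clustering_coefficient_weighted(null).mean())
        l_rand[b] = characteristic_path_length(null)
    c_bar = float(c_rand.mean())
    l_bar = float(l_rand.mean())
    if c_bar == 0 or l_bar == 0 or length == 0:
        raise UndefinedMetricError("null references degenerate; sigma undefined")
    return (c / c_bar) / (length / l_bar)
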