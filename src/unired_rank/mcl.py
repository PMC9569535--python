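"""Markov cluster algorithm (MCL) over weighted protein-association graphs.

MCL simulates flow on a graph: the column-stochastic transition matrix is
alternately *expanded* (matrix power, spreading flow along walks) and
*inflated* (entrywise power followed by column renormalization, sharpening
strong flows and starving weak ones) until the matrix converges to a
doubly idempotent limit whose attractor rows spell out the clusters. The
inflation exponent controls granularity; the default here is 2.0.

The production path operates on ``scipy.sparse`` CSC matrices and prunes
tiny entries between iterations; an independent dense iteration (used as an
oracle in the test suite) must agree with it on small graphs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import scipy.sparse as sp

from .errors import FormatError
from .knowledge_base import HUMAN, ClusterSet


@dataclass(frozen=True)
class MCLParams:
    """MCL tuning knobs; defaults reproduce the reference setting (inflation 2)."""

    inflation: float = 2.0
    expansion: int = 2
    prune_threshold: float = 1e-5
    max_iterations: int = 200
    convergence_tol: float = 1e-6

    def __post_init__(self) -> None:
        if self.inflation <= 1:
            raise ValueError("inflation must be > 1")
        if self.expansion < 2:
            raise ValueError("expansion must be >= 2")


_ATTRACTOR_EPS = 1e-8


def column_normalize(matrix):
    """Rescale every column to sum to 1. Accepts dense or sparse input."""
    if sp.issparse(matrix):
        m = matrix.tocsc()
        sums = np.asarray(m.sum(axis=0)).ravel()
        if np.any(sums <= 0):
            raise ValueError("zero column encountered (missing self-loop?)")
        return (m @ sp.diags(1.0 / sums)).tocsc()
    m = np.asarray(matrix, dtype=float)
    sums = m.sum(axis=0)
    if np.any(sums <= 0):
        raise ValueError("zero column encountered (missing self-loop?)")
    return m / sums


def inflate(matrix, r: float):
    """Entrywise power *r* followed by column renormalization."""
    if sp.issparse(matrix):
        return column_normalize(matrix.power(r))
    return column_normalize(np.asarray(matrix, dtype=float) ** r)


def _prune(m: sp.csc_matrix, threshold: float) -> sp.csc_matrix:
    """Drop entries below *threshold*, always retaining each column's maximum."""
    if threshold <= 0:
        return m
    m = m.tocsc()
    keep = m.data >= threshold
    # never empty a column: keep its largest entry regardless
    for j in range(m.shape[1]):
        lo, hi = m.indptr[j], m.indptr[j + 1]
        if lo < hi and not keep[lo:hi].any():
            keep[lo + int(np.argmax(m.data[lo:hi]))] = True
    mask = sp.csc_matrix((keep.astype(float), m.indices.copy(), m.indptr.copy()),
                         shape=m.shape)
    pruned = m.multiply(mask).tocsc()
    pruned.eliminate_zeros()
    return pruned


def _adjacency_with_self_loops(graph: nx.Graph) -> tuple[list, sp.csc_matrix]:
    nodes = sorted(graph.nodes)
    if not nodes:
        raise ValueError("graph is empty")
    for u, v, data in graph.edges(data=True):
        w = data.get("weight", 1.0)
        if u == v:
            raise FormatError(f"self-edge on {u!r} not allowed in input graphs")
        if w <= 0:
            raise FormatError(f"non-positive weight on edge ({u!r}, {v!r})")
    a = nx.to_scipy_sparse_array(graph, nodelist=nodes, weight="weight",
                                 format="csc", dtype=float)
    a = sp.csc_matrix(a)
    # self-loop weight = max incident edge weight (1.0 for isolated nodes)
    col_max = np.zeros(len(nodes))
    if a.nnz:
        col_max = a.max(axis=0).toarray().ravel()
    col_max[col_max <= 0] = 1.0
    return nodes, (a + sp.diags(col_max)).tocsc()


def _read_clusters(m: sp.csc_matrix, nodes: list) -> list[set]:
    """Interpret the limit matrix: attractor rows define the clusters.

    Rows with non-negligible diagonal mass are attractors; a node belongs to
    the cluster of every attractor row in which its column carries mass.
    Attractors that flow into one another are merged into a single cluster
    (they form one attractor system); overlap among ordinary nodes is kept.
    """
    m = m.tocsr()
    diag = m.diagonal()
    attractors = [i for i in range(len(nodes)) if diag[i] >= _ATTRACTOR_EPS]
    supports = {}
    for a in attractors:
        row = m.getrow(a)
        supports[a] = {j for j, v in zip(row.indices, row.data) if v >= _ATTRACTOR_EPS}

    # union-find over attractors sharing membership
    parent = {a: a for a in attractors}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    attractor_set = set(attractors)
    for a in attractors:
        for b in supports[a] & attractor_set:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[rb] = ra

    merged: dict[int, set] = {}
    for a in attractors:
        merged.setdefault(find(a), set()).update(supports[a])

    clusters = [set(members) for members in merged.values()]
    assigned = set().union(*clusters) if clusters else set()
    for i in range(len(nodes)):
        if i not in assigned:  # only possible when iteration was cut short
            clusters.append({i})
    return [{nodes[i] for i in c} for c in clusters]


def mcl(graph: nx.Graph, params: MCLParams | None = None, *,
        species: str = HUMAN, cluster_prefix: str = "MCL") -> ClusterSet:
    """Cluster *graph* with MCL and return a :class:`ClusterSet`.

    Deterministic for fixed input and parameters. On hitting
    ``max_iterations`` without convergence the current matrix is interpreted
    anyway and a :class:`RuntimeWarning` is emitted.
    """
    params = params or MCLParams()
    nodes, a = _adjacency_with_self_loops(graph)
    m = column_normalize(a)

    converged = False
    for _ in range(params.max_iterations):
        prev = m.copy()
        for _ in range(params.expansion - 1):
            m = (m @ m).tocsc()
        m = inflate(m, params.inflation)
        m = _prune(m, params.prune_threshold)
        m = column_normalize(m)
        delta = abs(m - prev).max() if (m - prev).nnz else 0.0
        if delta < params.convergence_tol:
            converged = True
            break
    if not converged:
        warnings.warn("MCL did not converge within max_iterations; "
                      "interpreting the current matrix", RuntimeWarning)

    raw = _read_clusters(m, nodes)
    raw.sort(key=lambda c: sorted(c))
    width = max(4, len(str(len(raw))))
    clusters = {f"{cluster_prefix}{i:0{width}d}": c for i, c in enumerate(raw, 1)}
    return ClusterSet(species=species, clusters=clusters)


def read_edge_list(path) -> nx.Graph:
    """Read a weighted edge list TSV (``protein_a``, ``protein_b``, ``weight``)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"protein_a": str, "protein_b": str})
    for col in ("protein_a", "protein_b", "weight"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r} "
                              "(expected header protein_a\tprotein_b\tweight)")
    g = nx.Graph()
    for a, b, w in zip(df["protein_a"], df["protein_b"], df["weight"]):
        g.add_edge(str(a).strip(), str(b).strip(), weight=float(w))
    return g


def write_cluster_table(clusters: ClusterSet, path) -> None:
    """Write clusters as a TSV consumable by ``load_cluster_table``."""
    with open(path, "w") as fh:
        fh.write("cluster_id\taccession\n")
        for cid in sorted(clusters.clusters):
            for acc in sorted(clusters.clusters[cid]):
                fh.write(f"{cid}\t{acc}\n")
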