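"""Independent reference implementations used only to cross-check the package.

These deliberately avoid the production code paths: the MCL oracle iterates
dense numpy matrices with no pruning, and the tier evaluator enumerates
clusters and evidence sets directly instead of going through ScoringIndex.
"""

from __future__ import annotations

import networkx as nx
import numpy as np

from unired_rank.knowledge_base import KnowledgeBase, other_species

_EPS = 1e-8


def dense_mcl(graph: nx.Graph, inflation: float = 2.0, expansion: int = 2,
              max_iter: int = 2000, tol: float = 1e-12) -> set[frozenset]:
    """Brute-force dense MCL iteration; returns clusters as frozensets."""
    nodes = sorted(graph.nodes)
    pos = {u: i for i, u in enumerate(nodes)}
    n = len(nodes)
    a = np.zeros((n, n))
    for u, v, data in graph.edges(data=True):
        w = float(data.get("weight", 1.0))
        a[pos[u], pos[v]] = a[pos[v], pos[u]] = w
    for i in range(n):
        m = a[:, i].max()
        a[i, i] = m if m > 0 else 1.0
    m = a / a.sum(axis=0)
    for _ in range(max_iter):
        prev = m
        m = np.linalg.matrix_power(m, expansion)
        m = m ** inflation
        m = m / m.sum(axis=0)
        if np.abs(m - prev).max() < tol:
            break

    attractors = [i for i in range(n) if m[i, i] >= _EPS]
    overlap = nx.Graph()
    overlap.add_nodes_from(attractors)
    for i in attractors:
        for j in attractors:
            if m[i, j] >= _EPS:
                overlap.add_edge(i, j)
    clusters: set[frozenset] = set()
    for system in nx.connected_components(overlap):
        members: set[str] = set()
        for i in system:
            members |= {nodes[j] for j in range(n) if m[i, j] >= _EPS}
        clusters.add(frozenset(members))
    return clusters


def tier_predicates(kb: KnowledgeBase, query: str, reference: str,
                    species: str) -> tuple[bool, bool, bool, bool]:
    """Evaluate all four tier predicates by direct enumeration.

    Returns (in_cluster, paralogue, complex_partner, orthologue); no
    precedence is applied.
    """
    clusters = kb.cluster_sets[species].clusters.values()
    qrec = kb.records[query]

    t1 = any(query in c and reference in c for c in clusters)

    t2 = any(p in c and reference in c
             for p in qrec.paralogues for c in clusters)

    partners: set[str] = set()
    table = kb.complexes.get(species)
    if table is not None:
        for cid, members in table.complexes.items():
            if query in members:
                partners |= members - {query}
    t3 = any(m in c and reference in c for m in partners for c in clusters)

    other = kb.cluster_sets.get(other_species(species))
    t4 = False
    if other is not None:
        rrec = kb.records[reference]
        t4 = any(a in c and b in c
                 for a in qrec.orthologues for b in rrec.orthologues
                 for c in other.clusters.values())
    return t1, t2, t3, t4


def first_true_tier(flags: tuple[bool, bool, bool, bool]) -> str | None:
    names = ("InCluster", "Paralogue", "Complex", "Orthologue")
    for name, flag in zip(names, flags):
        if flag:
            return name
    return None
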