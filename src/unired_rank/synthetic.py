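"""Synthetic knowledge bases and association graphs with planted structure.

Real deployments of the ranking engine sit on top of a literature-derived
cluster release plus Ensembl/ComplexPortal annotation dumps. For testing,
this module fabricates the same artifacts from scratch: a background of
randomly clustered proteins with configurable paralogue/complex/orthologue
annotation density, plus a *planted module* — a reference list and a query
list constructed so that each planted query protein is reachable from its
assigned reference through exactly one prescribed evidence tier, with all
earlier tiers explicitly falsified by construction. A ground-truth manifest
records, for every planted query, the tier that must fire and the evidence
pair that must be reported.

Accessions are synthetic but UniProt-shaped (``P00001`` for human,
``Q00001`` for mouse) so normalization and validation code paths are
exercised. Generation is a pure function of the spec and its seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .errors import AnalysisError
from .knowledge_base import (HUMAN, MOUSE, ClusterSet, ComplexTable,
                             KnowledgeBase, build_kb, kb_to_json,
                             other_species)


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic knowledge base.

    The background emulates a modest cluster release: ``n_proteins`` per
    species spread over ``n_clusters`` clusters, with the three evidence
    layers sampled at the given rates. The ``k_*`` counts size the planted
    module (one evidence row per planted query; ``k_none`` queries are
    clustered but evidence-free).
    """

    n_proteins: int = 300
    n_clusters: int = 30
    paralogue_rate: float = 0.1
    complex_rate: float = 0.05
    orthologue_coverage: float = 0.3
    n_reference: int = 10
    k_incluster: int = 2
    k_paralogue: int = 2
    k_complex: int = 2
    k_orthologue: int = 2
    k_none: int = 2
    species: str = HUMAN
    seed: int = 0

    @property
    def query_size(self) -> int:
        return (self.k_incluster + self.k_paralogue + self.k_complex
                + self.k_orthologue + self.k_none)

    def validate(self) -> None:
        for name in ("paralogue_rate", "complex_rate", "orthologue_coverage"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise AnalysisError(f"{name} must be in [0, 1], got {v}")
        if self.n_proteins < 1 or self.n_clusters < 1:
            raise AnalysisError("n_proteins and n_clusters must be positive")
        if min(self.k_incluster, self.k_paralogue, self.k_complex,
               self.k_orthologue, self.k_none) < 0:
            raise AnalysisError("planted tier counts must be non-negative")
        planted = self.query_size - self.k_none
        if planted > 0 and self.n_reference < 1:
            raise AnalysisError(
                "planted evidence tiers require at least one reference protein")


@dataclass
class FixtureTables:
    """Raw source tables of a generated fixture (what the loaders consume)."""

    clusters: dict[str, dict[str, set[str]]]
    paralogues: dict[str, set[frozenset]]
    orthologues: set[tuple[str, str]]
    complexes: dict[str, dict[str, set[str]]]
    id_mapping: dict[str, dict]
    manifest: dict = field(default_factory=dict)


_PREFIX = {HUMAN: "P", MOUSE: "Q"}


class _Namer:
    def __init__(self, prefix: str, start: int = 1) -> None:
        self.prefix = prefix
        self.i = start - 1

    def __call__(self) -> str:
        self.i += 1
        return f"{self.prefix}{self.i:05d}"


def _generate_tables(spec: FixtureSpec) -> FixtureTables:
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    sp, other = spec.species, other_species(spec.species)
    namer = {sp: _Namer(_PREFIX[sp]), other: _Namer(_PREFIX[other])}

    clusters: dict[str, dict[str, set[str]]] = {sp: {}, other: {}}
    paralogues: dict[str, set[frozenset]] = {sp: set(), other: set()}
    complexes: dict[str, dict[str, set[str]]] = {sp: {}, other: {}}
    orthologues: set[tuple[str, str]] = set()
    background: dict[str, list[str]] = {}

    # --- background -------------------------------------------------------
    for s in (sp, other):
        prefix = "HC" if s == spec.species else "OC"
        accs = [namer[s]() for _ in range(spec.n_proteins)]
        background[s] = accs
        assignment = rng.integers(0, spec.n_clusters, size=len(accs))
        for acc, c in zip(accs, assignment):
            clusters[s].setdefault(f"{prefix}{int(c):04d}", set()).add(acc)

        n_para = int(round(spec.paralogue_rate * spec.n_proteins))
        if len(accs) >= 2:
            while len(paralogues[s]) < n_para:
                a, b = rng.choice(len(accs), size=2, replace=False)
                paralogues[s].add(frozenset((accs[a], accs[b])))

        n_cpx = int(round(spec.complex_rate * spec.n_proteins)) if len(accs) >= 2 else 0
        for i in range(n_cpx):
            size = min(int(rng.integers(2, 6)), len(accs))
            members = rng.choice(len(accs), size=size, replace=False)
            complexes[s][f"CPX-{s[0].upper()}{i:04d}"] = {accs[j] for j in members}

    n_orth = int(round(spec.orthologue_coverage * spec.n_proteins))
    ha = rng.permutation(spec.n_proteins)[:n_orth]
    ma = rng.permutation(spec.n_proteins)[:n_orth]
    h_bg = background[sp] if sp == HUMAN else background[other]
    m_bg = background[other] if sp == HUMAN else background[sp]
    for i, j in zip(ha, ma):
        orthologues.add((h_bg[int(i)], m_bg[int(j)]))

    # --- planted module ----------------------------------------------------
    refs = [namer[sp]() for _ in range(spec.n_reference)]
    for j, r in enumerate(refs):
        clusters[sp][f"KREF{j:03d}"] = {r}

    expected: dict[str, dict] = {}
    queries: list[str] = []
    ref_orth: dict[str, str] = {}
    ref_cycle = 0

    def next_ref() -> tuple[int, str]:
        nonlocal ref_cycle
        j = ref_cycle % len(refs)
        ref_cycle += 1
        return j, refs[j]

    for _ in range(spec.k_incluster):
        q = namer[sp]()
        j, r = next_ref()
        clusters[sp][f"KREF{j:03d}"].add(q)
        queries.append(q)
        expected[q] = {"tier": "InCluster", "reference": r,
                       "evidence_pair": [q, r]}

    own = 0
    for _ in range(spec.k_paralogue):
        q, p = namer[sp](), namer[sp]()
        j, r = next_ref()
        clusters[sp][f"KQ{own:03d}"] = {q}
        own += 1
        clusters[sp][f"KREF{j:03d}"].add(p)
        paralogues[sp].add(frozenset((q, p)))
        queries.append(q)
        expected[q] = {"tier": "Paralogue", "reference": r,
                       "evidence_pair": [p, r]}

    for i in range(spec.k_complex):
        q, m = namer[sp](), namer[sp]()
        j, r = next_ref()
        clusters[sp][f"KQ{own:03d}"] = {q}
        own += 1
        clusters[sp][f"KREF{j:03d}"].add(m)
        complexes[sp][f"CPX-PLANT{i:03d}"] = {q, m}
        queries.append(q)
        expected[q] = {"tier": "Complex", "reference": r,
                       "evidence_pair": [m, r]}

    for i in range(spec.k_orthologue):
        q = namer[sp]()
        qo = namer[other]()
        j, r = next_ref()
        if r not in ref_orth:
            ref_orth[r] = namer[other]()
        ro = ref_orth[r]
        clusters[sp][f"KQ{own:03d}"] = {q}
        own += 1
        clusters[other][f"KORTH{i:03d}"] = {qo, ro}
        for a, b in ((q, qo), (r, ro)):
            orthologues.add((a, b) if sp == HUMAN else (b, a))
        queries.append(q)
        expected[q] = {"tier": "Orthologue", "reference": r,
                       "evidence_pair": [qo, ro]}

    for _ in range(spec.k_none):
        q = namer[sp]()
        clusters[sp][f"KQ{own:03d}"] = {q}
        own += 1
        queries.append(q)
        expected[q] = {"tier": None}

    # --- identifier mapping -------------------------------------------------
    id_mapping: dict[str, dict] = {}
    all_accs = sorted(
        {a for cl in clusters.values() for members in cl.values() for a in members}
    )
    for acc in all_accs:
        if acc[-1] != "7":  # leave some gene names absent to exercise fallback
            id_mapping[acc] = {
                "gene_name": f"G{acc[1:].lstrip('0') or '0'}",
                "reviewed_flags": {"gene_name": True},
            }

    manifest = {
        "species": sp,
        "seed": spec.seed,
        "reference": refs,
        "query": queries,
        "expected": expected,
        "n_background_per_species": spec.n_proteins,
    }
    return FixtureTables(clusters=clusters, paralogues=paralogues,
                         orthologues=orthologues, complexes=complexes,
                         id_mapping=id_mapping, manifest=manifest)


def generate_kb(spec: FixtureSpec) -> tuple[KnowledgeBase, dict]:
    """Generate a knowledge base plus its ground-truth manifest."""
    tables = _generate_tables(spec)
    kb = build_kb(
        cluster_sets={s: ClusterSet(species=s, clusters=cl)
                      for s, cl in tables.clusters.items() if cl},
        paralogue_pairs=tables.paralogues,
        orthologue_pairs=sorted(tables.orthologues),
        complex_tables={s: ComplexTable(species=s, complexes=cx)
                        for s, cx in tables.complexes.items() if cx},
        id_mappings=tables.id_mapping,
        version_tag=f"synthetic-seed{spec.seed}",
    )
    return kb, tables.manifest


@dataclass(frozen=True)
class GraphSpec:
    """Planted-block association graph: dense blocks, optional weak bridges."""

    n_blocks: int = 3
    block_size: int = 4
    intra_weight: float = 1.0
    bridge_weight: float = 0.0
    seed: int = 0


def generate_graph(spec: GraphSpec) -> tuple[nx.Graph, dict]:
    """Build a block graph and a manifest naming the intended clusters.

    Each block is a clique at ``intra_weight``; if ``bridge_weight`` > 0,
    consecutive blocks are joined by a single bridge edge of that weight.
    """
    if spec.n_blocks < 1 or spec.block_size < 1:
        raise AnalysisError("n_blocks and block_size must be positive")
    namer = _Namer("P")
    g = nx.Graph()
    blocks: list[list[str]] = []
    for _ in range(spec.n_blocks):
        nodes = [namer() for _ in range(spec.block_size)]
        blocks.append(nodes)
        g.add_nodes_from(nodes)
        for i in range(len(nodes)):
            for j in range(i + 1, len(nodes)):
                g.add_edge(nodes[i], nodes[j], weight=spec.intra_weight)
    if spec.bridge_weight > 0:
        for b1, b2 in zip(blocks, blocks[1:]):
            g.add_edge(b1[0], b2[0], weight=spec.bridge_weight)
    manifest = {"blocks": blocks, "seed": spec.seed}
    return g, manifest


# ---------------------------------------------------------------------------
# On-disk emission (formats consumed by the loaders / the CLI)
# ---------------------------------------------------------------------------


def write_fixture(spec: FixtureSpec, out_dir: str | Path) -> dict:
    """Emit a full fixture to *out_dir*: source TSVs, KB JSON, input lists.

    Returns the manifest (also written as ``manifest.json``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables = _generate_tables(spec)
    kb = build_kb(
        cluster_sets={s: ClusterSet(species=s, clusters=cl)
                      for s, cl in tables.clusters.items() if cl},
        paralogue_pairs=tables.paralogues,
        orthologue_pairs=sorted(tables.orthologues),
        complex_tables={s: ComplexTable(species=s, complexes=cx)
                        for s, cx in tables.complexes.items() if cx},
        id_mappings=tables.id_mapping,
        version_tag=f"synthetic-seed{spec.seed}",
    )

    for s, cl in tables.clusters.items():
        with open(out / f"clusters_{s}.tsv", "w") as fh:
            fh.write("cluster_id\taccession\n")
            for cid in sorted(cl):
                for acc in sorted(cl[cid]):
                    fh.write(f"{cid}\t{acc}\n")
    for s, pairs in tables.paralogues.items():
        with open(out / f"paralogues_{s}.tsv", "w") as fh:
            fh.write("protein_a\tprotein_b\n")
            for pair in sorted(tuple(sorted(p)) for p in pairs):
                fh.write(f"{pair[0]}\t{pair[1]}\n")
    with open(out / "orthologues.tsv", "w") as fh:
        fh.write("human\tmouse\n")
        for h, m in sorted(tables.orthologues):
            fh.write(f"{h}\t{m}\n")
    for s, cx in tables.complexes.items():
        with open(out / f"complexes_{s}.tsv", "w") as fh:
            fh.write("complex_id\taccession\n")
            for cid in sorted(cx):
                for acc in sorted(cx[cid]):
                    fh.write(f"{cid}\t{acc}\n")
    with open(out / "id_mapping.tsv", "w") as fh:
        fh.write("accession\tgene_name\tgene_name_reviewed\n")
        for acc in sorted(tables.id_mapping):
            info = tables.id_mapping[acc]
            fh.write(f"{acc}\t{info.get('gene_name', '')}\t"
                     f"{str(info['reviewed_flags'].get('gene_name', '')).lower()}\n")

    kb_to_json(kb, out / "kb.json")
    (out / "query.csv").write_text(",".join(tables.manifest["query"]) + "\n")
    (out / "reference.csv").write_text(",".join(tables.manifest["reference"]) + "\n")
    (out / "manifest.json").write_text(
        json.dumps(tables.manifest, indent=1, sort_keys=True) + "\n")
    return tables.manifest
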