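"""Four-tier evidence scoring of query proteins against a reference list.

Every (query, reference) pair is pushed through a strict evidence hierarchy
and receives the score of the *first* tier whose predicate holds:

1. **InCluster** (1.0) — query and reference share a literature cluster.
2. **Paralogue** (0.5) — a paralogue of the query shares a cluster with the
   reference.
3. **Complex** (0.5) — a complex partner of the query shares a cluster with
   the reference (default reading); an alternative reading, selected with
   ``complex_mode="member"``, asks instead whether the reference itself is a
   member of a complex that contains the query.
4. **Orthologue** (0.5) — the orthologues of query and reference share a
   cluster in the other species.

Once a tier fires, later tiers are not evaluated. Paralogue/complex
expansion applies to the query side only, so scoring is deliberately
asymmetric. A query's *overall* score is the sum of its pairwise scores
over the reference list; queries are ranked by overall score, descending.
Proteins absent from every cluster are excluded from the analysis entirely.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal

import pandas as pd

from .errors import AnalysisError
from .knowledge_base import KnowledgeBase, other_species

IN_CLUSTER = "InCluster"
PARALOGUE = "Paralogue"
COMPLEX = "Complex"
ORTHOLOGUE = "Orthologue"

ComplexMode = Literal["partner", "member"]


@dataclass(frozen=True)
class ScoreScheme:
    """Per-tier scores; the defaults are the published scheme (1, 0.5, 0.5, 0.5)."""

    in_cluster_score: float = 1.0
    paralogue_score: float = 0.5
    complex_score: float = 0.5
    orthologue_score: float = 0.5

    def __post_init__(self) -> None:
        for name in ("in_cluster_score", "paralogue_score",
                     "complex_score", "orthologue_score"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def for_type(self, association_type: str) -> float:
        return {
            IN_CLUSTER: self.in_cluster_score,
            PARALOGUE: self.paralogue_score,
            COMPLEX: self.complex_score,
            ORTHOLOGUE: self.orthologue_score,
        }[association_type]


@dataclass(frozen=True)
class AssociationEvidence:
    """One scored pair: which tier fired and through which protein pair."""

    query: str
    reference: str
    association_type: str
    evidence_pair: tuple[str, str]
    score: float


@dataclass
class ScoreResult:
    """Full outcome of scoring a query list against a reference list."""

    queries: list[str]
    references: list[str]
    matrix: dict[str, dict[str, float]]
    overall: dict[str, float]
    ranking: list[str]
    evidence: list[AssociationEvidence]
    excluded: list[tuple[str, str]]  # (accession, role)
    labels: dict[str, str] = field(default_factory=dict)


class ScoringIndex:
    """Precomputed cluster lookups for fast repeated pair scoring.

    Per accession and on demand, caches the cluster-id sets reachable
    through each evidence type. All hot-path checks reduce to
    ``frozenset.isdisjoint`` calls.
    """

    def __init__(self, kb: KnowledgeBase, species: str,
                 complex_mode: ComplexMode = "partner") -> None:
        if species not in kb.cluster_sets:
            raise AnalysisError(f"knowledge base has no {species!r} clusters")
        if complex_mode not in ("partner", "member"):
            raise ValueError(f"complex_mode must be 'partner' or 'member'")
        self.kb = kb
        self.species = species
        self.complex_mode: ComplexMode = complex_mode
        self._cs = kb.cluster_sets[species]
        self._other_cs = kb.cluster_sets.get(other_species(species))
        self._complexes = kb.complexes.get(species)
        self._clusters: dict[str, frozenset] = {}
        self._para: dict[str, frozenset] = {}
        self._partner: dict[str, frozenset] = {}
        self._members: dict[str, frozenset] = {}
        self._ortho: dict[str, frozenset] = {}

    def is_analyzed(self, acc: str) -> bool:
        return bool(self._cs.clusters_of(acc))

    def clusters_of(self, acc: str) -> frozenset:
        try:
            return self._clusters[acc]
        except KeyError:
            v = frozenset(self._cs.clusters_of(acc))
            self._clusters[acc] = v
            return v

    def _record_set(self, acc: str, attr: str) -> set[str]:
        rec = self.kb.records.get(acc)
        return getattr(rec, attr) if rec is not None else set()

    def paralogue_clusters(self, acc: str) -> frozenset:
        try:
            return self._para[acc]
        except KeyError:
            v = frozenset().union(
                *(self._cs.clusters_of(p) for p in self._record_set(acc, "paralogues"))
            ) if self._record_set(acc, "paralogues") else frozenset()
            self._para[acc] = v
            return v

    def complex_partners(self, acc: str) -> frozenset:
        """All other members of complexes containing *acc*."""
        try:
            return self._members[acc]
        except KeyError:
            partners: set[str] = set()
            if self._complexes is not None:
                for cid in self._record_set(acc, "complex_ids"):
                    partners |= self._complexes.complexes.get(cid, set())
            partners.discard(acc)
            v = frozenset(partners)
            self._members[acc] = v
            return v

    def partner_clusters(self, acc: str) -> frozenset:
        try:
            return self._partner[acc]
        except KeyError:
            partners = self.complex_partners(acc)
            v = frozenset().union(
                *(self._cs.clusters_of(p) for p in partners)
            ) if partners else frozenset()
            self._partner[acc] = v
            return v

    def orthologue_clusters(self, acc: str) -> frozenset:
        try:
            return self._ortho[acc]
        except KeyError:
            v = frozenset()
            if self._other_cs is not None:
                orths = self._record_set(acc, "orthologues")
                if orths:
                    v = frozenset().union(
                        *(self._other_cs.clusters_of(o) for o in orths))
            self._ortho[acc] = v
            return v

    # -- hot path -----------------------------------------------------------

    def pair_score(self, query: str, reference: str, scheme: ScoreScheme) -> float:
        """Score of the first satisfied tier, or 0.0 when none fires."""
        rc = self.clusters_of(reference)
        if not rc.isdisjoint(self.clusters_of(query)):
            return scheme.in_cluster_score
        if not rc.isdisjoint(self.paralogue_clusters(query)):
            return scheme.paralogue_score
        if self.complex_mode == "partner":
            if not rc.isdisjoint(self.partner_clusters(query)):
                return scheme.complex_score
        else:
            if reference in self.complex_partners(query):
                return scheme.complex_score
        if not self.orthologue_clusters(query).isdisjoint(
                self.orthologue_clusters(reference)):
            return scheme.orthologue_score
        return 0.0


def _first_coclustered(candidates: Iterable[str], ref_clusters: frozenset,
                       cs) -> str:
    """Lexicographically smallest candidate sharing a cluster with the reference."""
    return min(c for c in sorted(candidates)
               if not ref_clusters.isdisjoint(cs.clusters_of(c)))


def score_pair(kb: KnowledgeBase, query: str, reference: str, species: str,
               scheme: ScoreScheme | None = None,
               complex_mode: ComplexMode = "partner",
               index: ScoringIndex | None = None) -> AssociationEvidence | None:
    """Score one (query, reference) pair through the tier hierarchy.

    Both accessions must be clustered (unanalyzed proteins are filtered
    upstream by :func:`score_lists`). Returns ``None`` when no tier fires.
    The reported evidence pair is deterministic: the lexicographically
    smallest satisfying pair.
    """
    scheme = scheme or ScoreScheme()
    idx = index if index is not None else ScoringIndex(kb, species, complex_mode)
    if not idx.is_analyzed(query) or not idx.is_analyzed(reference):
        raise AnalysisError(
            f"score_pair requires clustered accessions; got {query!r}, {reference!r}")

    rc = idx.clusters_of(reference)
    cs = kb.cluster_sets[species]

    if not rc.isdisjoint(idx.clusters_of(query)):
        return AssociationEvidence(query, reference, IN_CLUSTER,
                                   (query, reference), scheme.in_cluster_score)

    if not rc.isdisjoint(idx.paralogue_clusters(query)):
        p = _first_coclustered(kb.records[query].paralogues, rc, cs)
        return AssociationEvidence(query, reference, PARALOGUE,
                                   (p, reference), scheme.paralogue_score)

    if idx.complex_mode == "partner":
        if not rc.isdisjoint(idx.partner_clusters(query)):
            m = _first_coclustered(idx.complex_partners(query), rc, cs)
            return AssociationEvidence(query, reference, COMPLEX,
                                       (m, reference), scheme.complex_score)
    elif reference in idx.complex_partners(query):
        return AssociationEvidence(query, reference, COMPLEX,
                                   (query, reference), scheme.complex_score)

    qo = idx.orthologue_clusters(query)
    if not qo.isdisjoint(idx.orthologue_clusters(reference)):
        other_cs = kb.cluster_sets[other_species(species)]
        qorth = kb.records[query].orthologues
        rorth = kb.records[reference].orthologues
        best = min(
            (oq, orf)
            for oq in qorth for orf in rorth
            if not frozenset(other_cs.clusters_of(oq)).isdisjoint(
                other_cs.clusters_of(orf))
        )
        return AssociationEvidence(query, reference, ORTHOLOGUE,
                                   best, scheme.orthologue_score)
    return None


def _dedupe(accessions: Iterable[str]) -> list[str]:
    seen: set[str] = set()
    out: list[str] = []
    for a in accessions:
        if a not in seen:
            seen.add(a)
            out.append(a)
    return out


def score_lists(kb: KnowledgeBase, query_list: Iterable[str],
                reference_list: Iterable[str], species: str,
                scheme: ScoreScheme | None = None, *,
                skip_self_pairs: bool = True,
                complex_mode: ComplexMode = "partner") -> ScoreResult:
    """Score every query against every reference and rank the queries.

    Proteins from either list that belong to no cluster are diverted to the
    excluded table and contribute nothing. The result is invariant to input
    order and duplicates. Self-pairs (an accession present in both lists)
    are skipped by default so identity never inflates an overall score.
    """
    scheme = scheme or ScoreScheme()
    queries = _dedupe(query_list)
    references = _dedupe(reference_list)
    if not queries:
        raise AnalysisError("no analyzable query proteins")
    if not references:
        raise AnalysisError("no analyzable reference proteins")

    idx = ScoringIndex(kb, species, complex_mode)
    excluded = [(q, "query") for q in queries if not idx.is_analyzed(q)]
    excluded += [(r, "reference") for r in references if not idx.is_analyzed(r)]
    queries = [q for q in queries if idx.is_analyzed(q)]
    references = [r for r in references if idx.is_analyzed(r)]
    if not queries:
        raise AnalysisError("no analyzable query proteins")
    if not references:
        raise AnalysisError("no analyzable reference proteins")

    queries = sorted(queries)
    references = sorted(references)

    matrix: dict[str, dict[str, float]] = {}
    evidence: list[AssociationEvidence] = []
    overall: dict[str, float] = {}
    for q in queries:
        row: dict[str, float] = {}
        for r in references:
            if skip_self_pairs and q == r:
                continue
            ev = score_pair(kb, q, r, species, scheme, complex_mode, index=idx)
            if ev is not None:
                row[r] = ev.score
                evidence.append(ev)
        matrix[q] = row
        overall[q] = sum(row.values())

    ranking = sorted(queries, key=lambda q: (-overall[q], q))
    labels = {acc: kb.label(acc) for acc in set(queries) | set(references)}
    return ScoreResult(queries=queries, references=references, matrix=matrix,
                       overall=overall, ranking=ranking, evidence=evidence,
                       excluded=sorted(set(excluded)), labels=labels)


def rank(result: ScoreResult) -> pd.DataFrame:
    """Score matrix as a DataFrame, rows ordered by descending overall score.

    Row/column labels are ``ACCESSION (GENENAME)`` where a gene name is
    known, else the bare accession. Ties in the overall score break
    lexicographically by accession.
    """
    label = lambda a: result.labels.get(a, a)
    cols = [label(r) for r in result.references]
    rows = []
    for q in result.ranking:
        row = {label(r): result.matrix[q].get(r) for r in result.references}
        row["Overall"] = result.overall[q]
        rows.append(row)
    return pd.DataFrame(rows, index=[label(q) for q in result.ranking],
                        columns=cols + ["Overall"])


def evidence_table(result: ScoreResult) -> pd.DataFrame:
    """Evidence rows as a DataFrame (query, reference, type, pair, score)."""
    return pd.DataFrame(
        [
            {
                "query": ev.query,
                "reference": ev.reference,
                "association_type": ev.association_type,
                "evidence_pair": f"{ev.evidence_pair[0]}|{ev.evidence_pair[1]}",
                "score": ev.score,
            }
            for ev in result.evidence
        ],
        columns=["query", "reference", "association_type", "evidence_pair", "score"],
    )


def excluded_table(result: ScoreResult) -> pd.DataFrame:
    """Excluded (never-clustered) input proteins and the list they came from."""
    return pd.DataFrame(result.excluded, columns=["accession", "input_list"])
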