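"""The protein knowledge base: literature clusters plus evidence annotation.

The central data structure is a per-species partition (possibly with
overlaps) of proteins into literature-derived functional clusters, decorated
with three kinds of transferable evidence per protein: same-species
paralogues, cross-species (human/mouse) orthologues and curated complex
memberships. One :class:`ProteinRecord` exists for every protein that occurs
in at least one cluster; proteins outside every cluster are "not analyzed"
and can never contribute a score.

All source tables are headered, tab-delimited text:

=================  =====================================
table              columns
=================  =====================================
cluster table      ``cluster_id``, ``accession``
paralogue table    ``protein_a``, ``protein_b``
orthologue table   ``human``, ``mouse``
complex table      ``complex_id``, ``accession``
id-mapping table   ``accession``, ``gene_name``,
                   ``ncbi_gene_name``, ``ensembl_gene_id``
                   (+ optional ``<field>_reviewed`` booleans)
=================  =====================================

The assembled knowledge base serializes to a versioned JSON document with
top-level keys ``version``, ``species``, ``records``, ``clusters``,
``complexes``; serialization is deterministic (sorted keys) and lossless.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .accessions import normalize_accession
from .errors import BuildError, FormatError, SchemaError

log = logging.getLogger(__name__)

HUMAN = "human"
MOUSE = "mouse"
SPECIES = (HUMAN, MOUSE)


def other_species(species: str) -> str:
    if species == HUMAN:
        return MOUSE
    if species == MOUSE:
        return HUMAN
    raise ValueError(f"unknown species: {species!r}")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class ProteinRecord:
    """Annotation bundle for one clustered protein.

    ``paralogues`` are same-species accessions, ``orthologues`` accessions of
    the opposite species, ``complex_ids`` curated complex identifiers.
    ``reviewed_flags`` marks which identifier mappings are reviewed; the
    flags are carried through serialization but play no role in scoring.
    """

    accession: str
    species: str
    gene_name: str | None = None
    ncbi_gene_name: str | None = None
    ensembl_gene_id: str | None = None
    paralogues: set[str] = field(default_factory=set)
    orthologues: set[str] = field(default_factory=set)
    complex_ids: set[str] = field(default_factory=set)
    reviewed_flags: dict[str, bool] = field(default_factory=dict)

    @property
    def label(self) -> str:
        """Display label: ``ACCESSION (GENENAME)``, or the bare accession."""
        if self.gene_name:
            return f"{self.accession} ({self.gene_name})"
        return self.accession


@dataclass
class ClusterSet:
    """Clusters of functionally associated proteins for one species.

    Membership may overlap: a protein belonging to several clusters retains
    all memberships, and sharing *any* cluster counts as co-occurrence.
    """

    species: str
    clusters: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cid, members in self.clusters.items():
            if not members:
                raise ValueError(f"cluster {cid!r} is empty")
        self._index: dict[str, set[str]] = {}
        for cid, members in self.clusters.items():
            for acc in members:
                self._index.setdefault(acc, set()).add(cid)

    @property
    def index(self) -> dict[str, set[str]]:
        """accession -> identifiers of every cluster containing it."""
        return self._index

    def clusters_of(self, accession: str) -> set[str]:
        return self._index.get(accession, set())

    @property
    def analyzed(self) -> set[str]:
        """All proteins occurring in at least one cluster."""
        return set(self._index)

    def __len__(self) -> int:
        return len(self.clusters)


@dataclass
class ComplexTable:
    """Curated complex membership for one species (complexes have >= 2 members)."""

    species: str
    complexes: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cid, members in self.complexes.items():
            if len(members) < 2:
                raise ValueError(f"complex {cid!r} has fewer than 2 members")
        self._index: dict[str, set[str]] = {}
        for cid, members in self.complexes.items():
            for acc in members:
                self._index.setdefault(acc, set()).add(cid)

    @property
    def index(self) -> dict[str, set[str]]:
        """accession -> identifiers of every complex containing it."""
        return self._index

    def complexes_of(self, accession: str) -> set[str]:
        return self._index.get(accession, set())


@dataclass
class KnowledgeBase:
    """Everything scoring needs: records, clusters and complexes per species."""

    version_tag: str
    records: dict[str, ProteinRecord] = field(default_factory=dict)
    cluster_sets: dict[str, ClusterSet] = field(default_factory=dict)
    complexes: dict[str, ComplexTable] = field(default_factory=dict)
    unresolved: set[str] = field(default_factory=set)

    def is_analyzed(self, accession: str, species: str) -> bool:
        cs = self.cluster_sets.get(species)
        return cs is not None and bool(cs.clusters_of(accession))

    def record(self, accession: str) -> ProteinRecord | None:
        return self.records.get(accession)

    def label(self, accession: str) -> str:
        rec = self.records.get(accession)
        return rec.label if rec is not None else accession

    def validate(self) -> None:
        """Raise :class:`BuildError` if any structural invariant is violated."""
        for acc, rec in self.records.items():
            if not acc:
                raise BuildError("empty accession in records")
            if acc != rec.accession:
                raise BuildError(f"record key {acc!r} != accession {rec.accession!r}")
            if acc in rec.paralogues:
                raise BuildError(f"{acc} lists itself as a paralogue")
            for p in rec.paralogues:
                other = self.records.get(p)
                if other is not None and acc not in other.paralogues:
                    raise BuildError(f"paralogy not symmetric: {acc} / {p}")
            for o in rec.orthologues:
                partner = self.records.get(o)
                if partner is not None and partner.species == rec.species:
                    raise BuildError(
                        f"orthologue {o} of {acc} is not of the opposite species"
                    )
        for species, cs in self.cluster_sets.items():
            missing = cs.analyzed - set(self.records)
            if missing:
                raise BuildError(
                    f"clustered {species} proteins without records: {sorted(missing)[:5]}"
                )


# ---------------------------------------------------------------------------
# Table loaders
# ---------------------------------------------------------------------------

_PAIR_COLUMNS = {"paralogue": ("protein_a", "protein_b"), "orthologue": ("human", "mouse")}


def _read_tsv(path: str | Path, expected: tuple[str, ...]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        log.warning("%s is empty", path)
        return pd.DataFrame(columns=list(expected))
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise FormatError(
            f"{path}: missing column(s) {missing}; expected header "
            f"{chr(9).join(expected)!r}"
        )
    return df


def load_pair_table(path: str | Path, kind: str):
    """Load a paralogue or orthologue pair table.

    Paralogue pairs are same-species and returned symmetrized as a set of
    2-element frozensets; orthologue pairs are cross-species and returned as
    a set of ``(human, mouse)`` tuples. Duplicate rows collapse; self-pairs
    are dropped with a warning.
    """
    if kind not in _PAIR_COLUMNS:
        raise ValueError(f"kind must be 'paralogue' or 'orthologue', got {kind!r}")
    cols = _PAIR_COLUMNS[kind]
    df = _read_tsv(path, cols)
    pairs: set = set()
    for a, b in zip(df[cols[0]], df[cols[1]]):
        a, b = normalize_accession(a), normalize_accession(b)
        if not a or not b:
            continue
        if a == b:
            log.warning("self-pair %s dropped from %s", a, path)
            continue
        pairs.add(frozenset((a, b)) if kind == "paralogue" else (a, b))
    if not pairs:
        log.warning("no pairs loaded from %s", path)
    return pairs


def load_complex_table(path: str | Path, species: str) -> ComplexTable:
    """Load complex membership rows; complexes with < 2 members are dropped."""
    df = _read_tsv(path, ("complex_id", "accession"))
    raw: dict[str, set[str]] = {}
    for i, (cid, acc) in enumerate(zip(df["complex_id"], df["accession"]), start=2):
        cid = cid.strip()
        acc = normalize_accession(acc)
        if not cid or not acc:
            raise FormatError(f"{path}: malformed row at line {i}")
        raw.setdefault(cid, set()).add(acc)
    kept = {cid: m for cid, m in raw.items() if len(m) >= 2}
    for cid in sorted(set(raw) - set(kept)):
        log.warning("complex %s has <2 members; dropped", cid)
    return ComplexTable(species=species, complexes=kept)


def load_cluster_table(path: str | Path, species: str) -> ClusterSet:
    """Load a cluster membership table into a :class:`ClusterSet`."""
    df = _read_tsv(path, ("cluster_id", "accession"))
    clusters: dict[str, set[str]] = {}
    for cid, acc in zip(df["cluster_id"], df["accession"]):
        cid = cid.strip()
        acc = normalize_accession(acc)
        if cid and acc:
            clusters.setdefault(cid, set()).add(acc)
    return ClusterSet(species=species, clusters=clusters)


_MAPPING_FIELDS = ("gene_name", "ncbi_gene_name", "ensembl_gene_id")


def load_id_mapping(path: str | Path) -> dict[str, dict]:
    """Load identifier mappings: accession -> names/IDs (+ reviewed flags)."""
    df = _read_tsv(path, ("accession",))
    mapping: dict[str, dict] = {}
    for _, row in df.iterrows():
        acc = normalize_accession(row["accession"])
        if not acc:
            continue
        info: dict = {"reviewed_flags": {}}
        for f in _MAPPING_FIELDS:
            if f in df.columns and row[f]:
                info[f] = row[f].strip()
            flag_col = f + "_reviewed"
            if flag_col in df.columns and row[flag_col]:
                info["reviewed_flags"][f] = row[flag_col].strip().lower() in (
                    "true", "1", "yes",
                )
        mapping[acc] = info
    return mapping


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------


def build_kb(
    cluster_sets: Mapping[str, ClusterSet],
    paralogue_pairs: Mapping[str, Iterable[frozenset]] | None = None,
    orthologue_pairs: Iterable[tuple[str, str]] | None = None,
    complex_tables: Mapping[str, ComplexTable] | None = None,
    id_mappings: Mapping[str, dict] | None = None,
    version_tag: str = "unversioned",
) -> KnowledgeBase:
    """Assemble a :class:`KnowledgeBase` from its source tables.

    One record is created per clustered protein. Evidence naming proteins
    outside every cluster is kept on the record (such targets can never
    satisfy an in-cluster check, so they are inert for scoring) and the
    referenced accessions are collected in ``kb.unresolved``.
    """
    if not cluster_sets:
        raise BuildError("at least one species' cluster set is required")
    paralogue_pairs = paralogue_pairs or {}
    orthologue_pairs = list(orthologue_pairs or [])
    complex_tables = complex_tables or {}
    id_mappings = id_mappings or {}

    kb = KnowledgeBase(version_tag=version_tag, cluster_sets=dict(cluster_sets),
                       complexes=dict(complex_tables))

    for species, cs in cluster_sets.items():
        for acc in sorted(cs.analyzed):
            info = id_mappings.get(acc, {})
            kb.records[acc] = ProteinRecord(
                accession=acc,
                species=species,
                gene_name=info.get("gene_name"),
                ncbi_gene_name=info.get("ncbi_gene_name"),
                ensembl_gene_id=info.get("ensembl_gene_id"),
                reviewed_flags=dict(info.get("reviewed_flags", {})),
            )

    def _note_unresolved(acc: str) -> None:
        if acc not in kb.records:
            kb.unresolved.add(acc)

    for species, pairs in paralogue_pairs.items():
        for pair in pairs:
            a, b = sorted(pair)
            if a == b:
                continue
            for x, y in ((a, b), (b, a)):
                rec = kb.records.get(x)
                if rec is not None and rec.species == species:
                    rec.paralogues.add(y)
                _note_unresolved(y)

    for h, m in orthologue_pairs:
        hrec, mrec = kb.records.get(h), kb.records.get(m)
        if hrec is not None and hrec.species != HUMAN:
            raise BuildError(f"orthologue pair ({h}, {m}): {h} is not a human protein")
        if mrec is not None and mrec.species != MOUSE:
            raise BuildError(f"orthologue pair ({h}, {m}): {m} is not a mouse protein")
        if hrec is not None:
            hrec.orthologues.add(m)
        if mrec is not None:
            mrec.orthologues.add(h)
        _note_unresolved(h)
        _note_unresolved(m)

    for species, table in complex_tables.items():
        for cid, members in table.complexes.items():
            for acc in members:
                rec = kb.records.get(acc)
                if rec is not None and rec.species == species:
                    rec.complex_ids.add(cid)
                _note_unresolved(acc)

    kb.validate()
    return kb


# ---------------------------------------------------------------------------
# JSON serialization
# ---------------------------------------------------------------------------

_RECORD_KEYS = (
    "species", "gene_name", "ncbi_gene_name", "ensembl_gene_id",
    "paralogues", "orthologues", "complex_ids", "reviewed_flags",
)


def kb_to_json(kb: KnowledgeBase, path: str | Path | None = None) -> str:
    """Serialize deterministically (sorted keys); optionally write to *path*."""
    doc = {
        "version": kb.version_tag,
        "species": sorted(kb.cluster_sets),
        "records": {
            acc: {
                "species": rec.species,
                "gene_name": rec.gene_name,
                "ncbi_gene_name": rec.ncbi_gene_name,
                "ensembl_gene_id": rec.ensembl_gene_id,
                "paralogues": sorted(rec.paralogues),
                "orthologues": sorted(rec.orthologues),
                "complex_ids": sorted(rec.complex_ids),
                "reviewed_flags": dict(sorted(rec.reviewed_flags.items())),
            }
            for acc, rec in kb.records.items()
        },
        "clusters": {
            sp: {cid: sorted(m) for cid, m in cs.clusters.items()}
            for sp, cs in kb.cluster_sets.items()
        },
        "complexes": {
            sp: {cid: sorted(m) for cid, m in tab.complexes.items()}
            for sp, tab in kb.complexes.items()
        },
        "unresolved": sorted(kb.unresolved),
    }
    text = json.dumps(doc, sort_keys=True, indent=1)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


def kb_from_json(source: str | Path) -> KnowledgeBase:
    """Load a knowledge base from JSON text or a file path.

    Raises :class:`SchemaError` naming the offending key when the document
    does not match the published schema.
    """
    if isinstance(source, Path):
        text = source.read_text()
    else:
        text = str(source)
        if not text.lstrip().startswith("{"):
            text = Path(text).read_text()
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise SchemaError(f"not valid JSON: {exc}") from exc

    for key in ("version", "species", "records", "clusters", "complexes"):
        if key not in doc:
            raise SchemaError(f"missing required top-level key {key!r}")

    records: dict[str, ProteinRecord] = {}
    for acc, raw in doc["records"].items():
        for key in _RECORD_KEYS:
            if key not in raw:
                raise SchemaError(f"record {acc!r}: missing required key {key!r}")
        records[acc] = ProteinRecord(
            accession=acc,
            species=raw["species"],
            gene_name=raw["gene_name"],
            ncbi_gene_name=raw["ncbi_gene_name"],
            ensembl_gene_id=raw["ensembl_gene_id"],
            paralogues=set(raw["paralogues"]),
            orthologues=set(raw["orthologues"]),
            complex_ids=set(raw["complex_ids"]),
            reviewed_flags=dict(raw["reviewed_flags"]),
        )

    cluster_sets = {
        sp: ClusterSet(species=sp, clusters={cid: set(m) for cid, m in cl.items()})
        for sp, cl in doc["clusters"].items()
    }
    complexes = {
        sp: ComplexTable(species=sp, complexes={cid: set(m) for cid, m in cx.items()})
        for sp, cx in doc["complexes"].items()
    }
    kb = KnowledgeBase(
        version_tag=doc["version"],
        records=records,
        cluster_sets=cluster_sets,
        complexes=complexes,
        unresolved=set(doc.get("unresolved", [])),
    )
    kb.validate()
    return kb
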