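"""Input-list parsing, run configuration and the end-to-end pipeline.

Input lists are plain text, one or many accessions per line, comma- or
tab-separated. Tokens that fail UniProt accession validation are rejected
individually (with a reason) rather than aborting the run; duplicates
collapse keeping the first occurrence.

:func:`run_pipeline` ties everything together: parse both lists, load the
knowledge base, score, and write the three result tables (scores matrix
with the descending ``Overall`` column, the association-evidence table, and
the excluded-protein table), optionally followed by the permutation test.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

from .accessions import is_valid_accession, normalize_accession
from .errors import AnalysisError
from .knowledge_base import HUMAN, kb_from_json
from .permutation import permutation_test
from .scoring import (ComplexMode, ScoreScheme, evidence_table,
                      excluded_table, rank, score_lists)

log = logging.getLogger(__name__)

_SPLIT_RE = re.compile(r"[,\t]")


@dataclass
class InputList:
    """A parsed protein list: normalized accessions plus rejection log."""

    role: str  # "query" or "reference"
    source: str
    raw_tokens: list[str]
    accessions: list[str]  # normalized, ordered, deduplicated
    rejected: list[tuple[str, str]]  # (token, reason)
    n_duplicates: int = 0
    had_tabs: bool = False


def parse_input_list(path: str | Path, role: str) -> InputList:
    """Parse a comma- or tab-separated accession list file."""
    path = Path(path)
    text = path.read_text()
    raw: list[str] = []
    for line in text.splitlines():
        raw.extend(t for t in _SPLIT_RE.split(line) if t.strip())

    seen: set[str] = set()
    accessions: list[str] = []
    rejected: list[tuple[str, str]] = []
    n_dup = 0
    for token in raw:
        acc = normalize_accession(token)
        if not is_valid_accession(acc):
            rejected.append((token, "invalid accession format"))
            log.warning("%s: token %r rejected (invalid accession format)",
                        path, token)
            continue
        if acc in seen:
            n_dup += 1
            continue
        seen.add(acc)
        accessions.append(acc)
    if not accessions:
        raise AnalysisError(f"no valid accessions in {role} list {path}")
    return InputList(role=role, source=str(path), raw_tokens=raw,
                     accessions=accessions, rejected=rejected,
                     n_duplicates=n_dup, had_tabs="\t" in text)


@dataclass
class RunConfig:
    """Settings of one pipeline run; defaults are the published scheme."""

    species: str = HUMAN
    scheme: ScoreScheme = field(default_factory=ScoreScheme)
    complex_mode: ComplexMode = "partner"
    skip_self_pairs: bool = True
    run_permutation: bool = False
    n_permutations: int = 1000
    seed: int = 0
    out_dir: str | Path = "."
    delimiter: str | None = None  # None: mirror the query list's dialect


def run_pipeline(config: RunConfig, query_path: str | Path,
                 reference_path: str | Path, kb_path: str | Path) -> list[Path]:
    """Execute score -> rank -> write; returns the paths written.

    On any failure, files already written by this run are removed so no
    partial output survives.
    """
    queries = parse_input_list(query_path, "query")
    references = parse_input_list(reference_path, "reference")
    kb = kb_from_json(Path(kb_path))
    if config.species not in kb.cluster_sets:
        raise AnalysisError(
            f"knowledge base has no clusters for species {config.species!r}")

    sep = config.delimiter or ("\t" if queries.had_tabs else ",")
    ext = "tsv" if sep == "\t" else "csv"
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    written: list[Path] = []
    try:
        result = score_lists(kb, queries.accessions, references.accessions,
                             config.species, config.scheme,
                             skip_self_pairs=config.skip_self_pairs,
                             complex_mode=config.complex_mode)

        scores_path = out_dir / f"scores.{ext}"
        rank(result).to_csv(scores_path, sep=sep, index_label="query")
        written.append(scores_path)

        assoc_path = out_dir / f"associations.{ext}"
        evidence_table(result).to_csv(assoc_path, sep=sep, index=False)
        written.append(assoc_path)

        excl_path = out_dir / f"excluded.{ext}"
        excluded_table(result).to_csv(excl_path, sep=sep, index=False)
        written.append(excl_path)

        log.info("analyzed %d queries x %d references; %d evidence rows; "
                 "%d excluded", len(result.queries), len(result.references),
                 len(result.evidence), len(result.excluded))

        if config.run_permutation:
            perm = permutation_test(
                kb, queries.accessions, references.accessions, config.species,
                config.scheme, n_permutations=config.n_permutations,
                seed=config.seed, skip_self_pairs=config.skip_self_pairs,
                complex_mode=config.complex_mode)
            perm_path = out_dir / "permutation.json"
            perm_path.write_text(json.dumps({
                "observed_sum": perm.observed_sum,
                "p_value": perm.p_value,
                "n_permutations": perm.n_permutations,
                "seed": perm.seed,
                "universe_size": perm.universe_size,
                "query_size": perm.query_size,
                "metadata": perm.metadata,
            }, indent=1, sort_keys=True) + "\n")
            written.append(perm_path)
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise
    return written


def read_config_file(path: str | Path) -> dict:
    """Read a ``key = value`` configuration file into a flat dict."""
    out: dict[str, str] = {}
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise AnalysisError(f"{path}:{i}: expected 'key = value'")
        key, _, value = line.partition("=")
        out[key.strip()] = value.strip()
    return out
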