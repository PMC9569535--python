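"""UniProt/SwissProt accession handling.

All identifiers flowing through the pipeline are UniProt accessions
(e.g. ``P04637``). Tokens are normalized before validation: surrounding
whitespace is stripped, case is folded to upper, and isoform suffixes
(``P04637-2``) are reduced to the canonical accession.
"""

from __future__ import annotations

import logging
import re

log = logging.getLogger(__name__)

#: Published UniProt accession format (6- and 10-character forms).
ACCESSION_RE = re.compile(
    r"[OPQ][0-9][A-Z0-9]{3}[0-9]|[A-NR-Z][0-9](?:[A-Z][A-Z0-9]{2}[0-9]){1,2}"
)

_ISOFORM_RE = re.compile(r"-\d+$")


def normalize_accession(token: str) -> str:
    """Return the canonical form of an accession token.

    Strips whitespace, uppercases, and removes an isoform suffix if one is
    present (isoforms share all annotation of the canonical entry for the
    purposes of cluster/paralogue/complex lookups).
    """
    acc = token.strip().upper()
    stripped = acc
    while True:  # fixed point: normalization is idempotent
        nxt = _ISOFORM_RE.sub("", stripped)
        if nxt == stripped:
            break
        stripped = nxt
    if stripped != acc:
        log.info("isoform suffix stripped: %s -> %s", acc, stripped)
    return stripped


def is_valid_accession(acc: str) -> bool:
    """True if *acc* (already normalized) matches the UniProt format."""
    return ACCESSION_RE.fullmatch(acc) is not None
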