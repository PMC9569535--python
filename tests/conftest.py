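"""Shared fixtures: hand-built and generated knowledge bases."""

from __future__ import annotations

import pytest

from unired_rank import (ClusterSet, ComplexTable, FixtureSpec, build_kb,
                         generate_kb)


def make_tier_kb(t1: bool, t2: bool, t3: bool, t4: bool):
    """Hand-built KB in which each tier predicate for (Q00001, Q00002) holds
    iff the corresponding flag is set.

    Q00001 is the query, Q00002 the reference. Every evidence type is
    annotated in both the true and false configurations (pointing either at
    the reference's cluster or at a decoy cluster) so that a wrong
    precedence or a wrong predicate shows up as a different tier firing.
    """
    q, r = "Q00001", "Q00002"
    para, partner = "Q00003", "Q00004"
    filler_q, filler_r = "Q00005", "Q00006"
    q_orth, r_orth = "O00001", "O00002"

    human: dict[str, set[str]] = {}
    if t1:
        human["KQR"] = {q, r}
    else:
        human["KQ"] = {q, filler_q}
        human["KR"] = {r, filler_r}
    r_cluster = "KQR" if t1 else "KR"
    human["KPARA"] = {para} if not t2 else {para, "Q00007"}
    if t2:
        human[r_cluster].add(para)
    human["KPART"] = {partner, "Q00008"}
    if t3:
        human[r_cluster].add(partner)

    mouse: dict[str, set[str]] = {}
    if t4:
        mouse["MQR"] = {q_orth, r_orth}
    else:
        mouse["MQ"] = {q_orth}
        mouse["MR"] = {r_orth}

    return build_kb(
        cluster_sets={
            "human": ClusterSet(species="human", clusters=human),
            "mouse": ClusterSet(species="mouse", clusters=mouse),
        },
        paralogue_pairs={"human": {frozenset((q, para))}},
        orthologue_pairs=[(q, q_orth), (r, r_orth)],
        complex_tables={"human": ComplexTable(
            species="human", complexes={"CPX-1": {q, partner}})},
        version_tag="tier-truth-table",
    )


@pytest.fixture(scope="session")
def planted_spec() -> FixtureSpec:
    return FixtureSpec(seed=42)


@pytest.fixture(scope="session")
def planted(planted_spec):
    """Default synthetic KB with its ground-truth manifest."""
    return generate_kb(planted_spec)
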