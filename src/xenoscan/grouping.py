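"""Clustering of HGT candidates into putative single-event groups.

Three complementary clusterings are computed — shared homology hits
(default 70% overlap of hit sets), shared orthogroups, and shared protein
domains — and, per connected family of candidates, the most comprehensive
grouping consistent with a single predicted HGT event is retained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable

import networkx as nx
import pandas as pd

from .homology import HitTable

__all__ = [
    "CandidateGroup",
    "cluster_by_shared_hits",
    "cluster_by_orthogroups",
    "cluster_by_domains",
    "select_clustering",
    "read_orthogroups",
    "read_domains",
]

log = logging.getLogger(__name__)

#: tie-break order when clusterings yield admissible groups of equal size
METHOD_ORDER = ("shared_hits", "orthogroup", "domain")


@dataclass
class CandidateGroup:
    group_id: str
    query_ids: frozenset[str]
    method: str
    subject_union: frozenset[str] = frozenset()
    unresolved: bool = False

    def __len__(self) -> int:
        return len(self.query_ids)


def _components_to_groups(
    graph: nx.Graph, method: str, subjects: dict[str, set[str]] | None = None
) -> list[CandidateGroup]:
    groups = []
    comps = sorted(nx.connected_components(graph), key=lambda c: sorted(c)[0])
    for i, comp in enumerate(comps):
        union: set[str] = set()
        for q in comp:
            union |= (subjects or {}).get(q, set())
        groups.append(
            CandidateGroup(f"{method}_{i:04d}", frozenset(comp), method, frozenset(union))
        )
    return groups


def cluster_by_shared_hits(
    table: HitTable, candidate_ids: Iterable[str], overlap_threshold: float = 0.70
) -> list[CandidateGroup]:
    """Single-linkage clustering by fraction of shared homology hits.

    Two candidates are linked when ``|hits(q1) & hits(q2)| / min(|hits(q1)|,
    |hits(q2)|) >= overlap_threshold``; groups are connected components.
    """
    if not 0 < overlap_threshold <= 1:
        raise ValueError("overlap_threshold must be in (0, 1]")
    ids = sorted(set(candidate_ids))
    subjects = {q: table.subject_ids(q) for q in ids}
    g = nx.Graph()
    g.add_nodes_from(ids)
    for i, q1 in enumerate(ids):
        if not subjects[q1]:
            log.warning("candidate %s has zero hits; kept as singleton", q1)
            continue
        for q2 in ids[i + 1 :]:
            if not subjects[q2]:
                continue
            shared = len(subjects[q1] & subjects[q2])
            if shared / min(len(subjects[q1]), len(subjects[q2])) >= overlap_threshold:
                g.add_edge(q1, q2)
    return _components_to_groups(g, "shared_hits", subjects)


def cluster_by_orthogroups(
    candidate_ids: Iterable[str], orthogroup_table: dict[str, str]
) -> list[CandidateGroup]:
    """Group candidates sharing an orthogroup id; unassigned ones are singletons."""
    ids = sorted(set(candidate_ids))
    g = nx.Graph()
    g.add_nodes_from(ids)
    by_og: dict[str, list[str]] = {}
    for q in ids:
        og = orthogroup_table.get(q)
        if og is not None:
            by_og.setdefault(og, []).append(q)
    for members in by_og.values():
        for a, b in zip(members, members[1:]):
            g.add_edge(a, b)
    return _components_to_groups(g, "orthogroup")


def cluster_by_domains(
    candidate_ids: Iterable[str], domain_table: dict[str, set[str]]
) -> list[CandidateGroup]:
    """Link candidates whose domain-accession sets intersect; connected components."""
    ids = sorted(set(candidate_ids))
    g = nx.Graph()
    g.add_nodes_from(ids)
    by_dom: dict[str, list[str]] = {}
    for q in ids:
        for d in domain_table.get(q, set()):
            by_dom.setdefault(d, []).append(q)
    for members in by_dom.values():
        for a, b in zip(members, members[1:]):
            g.add_edge(a, b)
    return _components_to_groups(g, "domain")


def select_clustering(
    groups_by_method: dict[str, list[CandidateGroup]],
    event_counter: Callable[[CandidateGroup], int],
) -> list[CandidateGroup]:
    """Retain, per family of candidates, the most comprehensive single-event group.

    Candidates are first joined into families by the union of all methods'
    groups. Within a family, every proposed group is *admissible* when
    ``event_counter(group) == 1``; the largest admissible group is selected
    (ties broken by method order shared_hits > orthogroup > domain), its
    members are removed, and selection repeats. Candidates never covered by
    an admissible multi-member group fall back to singletons. Groups whose
    event count cannot be computed are flagged ``unresolved`` and excluded
    from merging.
    """
    all_groups = [g for groups in groups_by_method.values() for g in groups]
    universe: set[str] = set()
    fam = nx.Graph()
    for g in all_groups:
        universe |= g.query_ids
        members = sorted(g.query_ids)
        fam.add_nodes_from(members)
        for a, b in zip(members, members[1:]):
            fam.add_edge(a, b)

    admissible: list[CandidateGroup] = []
    unresolved: list[CandidateGroup] = []
    counted: dict[frozenset, int] = {}
    for g in all_groups:
        if g.query_ids in counted:
            n = counted[g.query_ids]
        else:
            try:
                n = event_counter(g)
            except Exception as exc:  # noqa: BLE001 - callback contract
                log.warning("event counter failed on %s: %s", g.group_id, exc)
                unresolved.append(
                    CandidateGroup(g.group_id, g.query_ids, g.method, g.subject_union, True)
                )
                n = -1
            counted[g.query_ids] = n
        if n == 1:
            admissible.append(g)

    rank = {m: i for i, m in enumerate(METHOD_ORDER)}
    selected: list[CandidateGroup] = []
    for comp in sorted(nx.connected_components(fam), key=lambda c: sorted(c)[0]):
        remaining = set(comp)
        cands = [g for g in admissible if g.query_ids <= comp]
        cands.sort(key=lambda g: (-len(g.query_ids), rank.get(g.method, 99), sorted(g.query_ids)))
        for g in cands:
            if g.query_ids <= remaining:
                selected.append(g)
                remaining -= g.query_ids
        for q in sorted(remaining):
            selected.append(CandidateGroup(f"singleton_{q}", frozenset([q]), "singleton"))
    # renumber deterministically
    out = []
    for i, g in enumerate(sorted(selected, key=lambda g: sorted(g.query_ids)[0])):
        out.append(CandidateGroup(f"G{i:04d}", g.query_ids, g.method, g.subject_union, g.unresolved))
    return out


def read_orthogroups(path: str | Path) -> dict[str, str]:
    """Read a 2-column TSV (gene, orthogroup_id) into a mapping."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#", header=None,
                     names=["gene", "orthogroup"])
    return dict(zip(df["gene"], df["orthogroup"]))


def read_domains(path: str | Path) -> dict[str, set[str]]:
    """Read a 2-column TSV (gene, domain_accession) into gene -> set of domains."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#", header=None,
                     names=["gene", "domain"])
    out: dict[str, set[str]] = {}
    for g, d in zip(df["gene"], df["domain"]):
        out.setdefault(g, set()).add(d)
    return out
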