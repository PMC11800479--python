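"""Donor classification from rooted gene trees and event accounting.

After a candidate group's tree is rooted, the taxonomic composition of the
*sister branch* of the query clade and of the *ancestral sister branch*
(the sibling of the query clade's parent) determines the putative donor:
a uniformly bacterial sister with a bacterial (or empty/absent) ancestral
sister yields origin ``bacteria``; a sister of one kingdom with an
ancestral sister of a different kingdom yields the ambiguous
``complex:k1|k2``; nonanimal hits of mixed kingdoms yield ``other``; and
nonquery animal sequences in *both* branches reject the HGT hypothesis
(origin ``none``). Query clades may absorb recipient-lineage homologs
(cryptic species, same subfamily) without penalty.

Distinct HGT events are counted as maximal clades whose leaves are
exclusively query/recipient sequences — a lower bound, since a single
acquisition followed by duplication still forms one clade.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .grouping import CandidateGroup
from .taxonomy import RECIPIENT, SELF
from .trees import Tree

__all__ = [
    "SisterAnalysis",
    "HgtCall",
    "HgtEvent",
    "sister_branches",
    "classify_origin",
    "count_events",
    "combine_cross_species_groups",
    "shared_event_assessment",
    "UnresolvablePlacement",
]


class UnresolvablePlacement(ValueError):
    """Query leaves span the root: no sister branch exists."""


@dataclass
class SisterAnalysis:
    query_leaves: frozenset[str]
    clade_leaves: frozenset[str]  # smallest clade containing the queries
    sister_leaves: frozenset[str]
    ancestral_sister_leaves: frozenset[str] | None  # None when parent is root
    clade_support: tuple[float | None, float | None] | None


@dataclass
class HgtCall:
    group_id: str
    origin: str  # bacteria | fungi | viridiplantae | other | complex:<k1|k2> | none
    donor_count: int
    reason: str = ""
    au_p: float | None = None
    topology_verdict: str = "untested"  # hgt_supported | not_significant | untested
    clade_support: tuple[float | None, float | None] | None = None


def sister_branches(
    rooted_tree: Tree,
    query_leaves: set[str],
    leaf_category: dict[str, str] | None = None,
) -> SisterAnalysis:
    """Locate the query clade and read off its sister branches.

    The query clade Q is the smallest clade containing all query leaves (it
    may include co-recipient homologs). Sister = leaves of Q's sibling;
    ancestral sister = leaves of the sibling of Q's parent (None when the
    parent is the root). Supports come from Q's subtending branch.

    When ``leaf_category`` is given, Q absorbs sibling clades made up
    entirely of SELF-category leaves (recipient-lineage homologs such as
    cryptic-species or sister-species sequences) before the sister branches
    are read, mirroring the treatment of co-recipient homologs.
    """
    if not rooted_tree.rooted:
        raise ValueError("sister-branch analysis needs a rooted tree")
    q = rooted_tree.mrca(set(query_leaves))
    below = rooted_tree.clade_leaf_sets()
    if leaf_category is not None:
        benign = set(query_leaves) | {
            leaf for leaf, cat in leaf_category.items() if cat == SELF
        }
        while q.parent is not None and below[id(q.parent)] <= benign:
            q = q.parent
    if q is rooted_tree.root:
        raise UnresolvablePlacement("query leaves span the root")
    parent = q.parent
    sister: set[str] = set()
    for sib in parent.children:
        if sib is not q:
            sister |= below[id(sib)]
    grand = parent.parent
    anc: set[str] | None
    if grand is None:
        anc = None
    else:
        anc = set()
        for sib in grand.children:
            if sib is not parent:
                anc |= below[id(sib)]
    return SisterAnalysis(
        frozenset(query_leaves),
        frozenset(below[id(q)]),
        frozenset(sister),
        None if anc is None else frozenset(anc),
        q.support,
    )


def _kingdoms(leaves: frozenset[str], leaf_category: dict[str, str]) -> tuple[set[str], int, int]:
    """(donor kingdoms present, donor leaf count, nonself-recipient count)."""
    kingdoms: set[str] = set()
    n_donor = n_recipient = 0
    for leaf in leaves:
        cat = leaf_category[leaf]
        if cat.startswith("DONOR:"):
            kingdoms.add(cat.split(":", 1)[1])
            n_donor += 1
        elif cat == RECIPIENT:
            n_recipient += 1
        # SELF leaves are recipient-lineage homologs: benign, not counted
    return kingdoms, n_donor, n_recipient


def classify_origin(
    analysis: SisterAnalysis,
    leaf_category: dict[str, str],
    group_id: str = "",
) -> HgtCall:
    """Assign a donor origin from the sister-branch composition.

    ``leaf_category`` maps each nonquery leaf to SELF / RECIPIENT /
    DONOR:<kingdom> / DONOR:other (query leaves may be omitted).
    """
    cats = dict(leaf_category)
    for q in analysis.query_leaves:
        cats.setdefault(q, SELF)
    sk, s_donor, s_rec = _kingdoms(analysis.sister_leaves, cats)
    if analysis.ancestral_sister_leaves is None:
        ak, a_donor, a_rec = set(), 0, 0
        anc_absent = True
    else:
        ak, a_donor, a_rec = _kingdoms(analysis.ancestral_sister_leaves, cats)
        anc_absent = False
    donor_count = s_donor + a_donor

    if s_rec > 0 and a_rec > 0:
        return HgtCall(group_id, "none", donor_count,
                       "animal sequences in sister and ancestral sister branches")
    if s_donor == 0:
        return HgtCall(group_id, "none", donor_count, "no donor evidence")
    if len(sk) > 1:
        return HgtCall(group_id, "other", donor_count, "mixed-kingdom sister branch")
    (kingdom,) = sk
    if anc_absent or a_donor == 0 or ak == {kingdom}:
        return HgtCall(group_id, kingdom, donor_count)
    if len(ak) == 1:
        (other,) = ak
        return HgtCall(group_id, f"complex:{kingdom}|{other}", donor_count,
                       "sister and ancestral sister from different kingdoms")
    return HgtCall(group_id, "other", donor_count, "mixed-kingdom ancestral sister")


def count_events(
    group_tree_rooted: Tree, recipient_leaves: set[str]
) -> tuple[int, dict[str, int]]:
    """Number of maximal recipient-only clades, with leaf -> event index.

    Counts each maximal clade whose leaves are exclusively query/recipient
    sequences as one acquisition; reported downstream as a lower bound.
    """
    below = group_tree_rooted.clade_leaf_sets()
    events: dict[str, int] = {}
    counter = [0]

    def walk(node) -> None:
        leaves = below[id(node)]
        members = leaves & recipient_leaves
        if not members:
            return
        if members == leaves:
            idx = counter[0]
            counter[0] += 1
            for leaf in sorted(leaves):
                events[leaf] = idx
            return
        for child in node.children:
            walk(child)

    walk(group_tree_rooted.root)
    return counter[0], events


def combine_cross_species_groups(
    groups_a: list[CandidateGroup],
    groups_b: list[CandidateGroup],
    orthogroup_table: dict[str, str],
) -> list[CandidateGroup]:
    """Merge groups across two related species via shared orthogroups.

    Groups (from either species) are merged whenever any member pair
    co-occurs in an orthogroup; merging is transitive. Merged groups carry
    both species' members and the union of database homologs.
    """
    all_groups = list(groups_a) + list(groups_b)
    g = nx.Graph()
    g.add_nodes_from(range(len(all_groups)))
    by_og: dict[str, list[int]] = {}
    for i, grp in enumerate(all_groups):
        for q in grp.query_ids:
            og = orthogroup_table.get(q)
            if og is not None:
                by_og.setdefault(og, []).append(i)
    for members in by_og.values():
        for a, b in zip(members, members[1:]):
            g.add_edge(a, b)
    out = []
    comps = sorted(nx.connected_components(g),
                   key=lambda c: sorted(sorted(all_groups[i].query_ids)[0] for i in c)[0])
    for ci, comp in enumerate(comps):
        queries: set[str] = set()
        subjects: set[str] = set()
        for i in comp:
            queries |= all_groups[i].query_ids
            subjects |= all_groups[i].subject_union
        method = all_groups[min(comp)].method if len(comp) == 1 else "combined"
        out.append(CandidateGroup(f"X{ci:04d}", frozenset(queries), method,
                                  frozenset(subjects)))
    return out


@dataclass
class HgtEvent:
    event_id: str
    members_by_species: dict[str, list[str]]
    origin: str
    sharing_verdict: str  # single_ancestral | single_ancestral_weak | independent
    #                      | inconclusive | single_species
    au_p: float | None = None
    clade_support: tuple[float | None, float | None] | None = None


def shared_event_assessment(
    combined_tree: Tree,
    species_a_leaves: set[str],
    species_b_leaves: set[str],
    support_thresholds: tuple[float, float] = (80.0, 95.0),
    au_p: float | None = None,
    alpha: float = 0.05,
) -> str:
    """Classify a cross-species event as shared-ancestral or independent.

    Monophyly of the two species' sequences with clade supports at or above
    both thresholds -> ``single_ancestral`` (below them ->
    ``single_ancestral_weak``); non-monophyly with the constrained-monophyly
    AU p below alpha -> ``independent``; otherwise ``inconclusive``.
    """
    if not species_a_leaves or not species_b_leaves:
        return "single_species"
    both = set(species_a_leaves) | set(species_b_leaves)
    if combined_tree.is_monophyletic(both):
        if len(both) == len(combined_tree.leaf_names()):
            return "single_ancestral_weak"
        node = combined_tree.mrca(both)
        sup = node.support
        lo, hi = support_thresholds
        if sup is not None and sup[0] is not None and sup[1] is not None \
                and sup[0] >= lo and sup[1] >= hi:
            return "single_ancestral"
        return "single_ancestral_weak"
    if au_p is not None and au_p < alpha:
        return "independent"
    return "inconclusive"
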