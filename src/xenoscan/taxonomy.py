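"""NCBI-style taxonomy table and clade-membership queries.

The pipeline partitions homology hits into three taxonomic categories:
*self* (the focal subfamily, e.g. Aleyrodinae — ignored during scoring),
*recipient* (the wider recipient clade, e.g. animals) and *donor* (one of
the configured donor kingdoms: Bacteria, Fungi, Viridiplantae). Everything
here operates on a plain parent-pointer table, loadable from a 4-column TSV
or from an NCBI ``nodes.dmp``-style ``|``-separated dump.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

__all__ = [
    "TaxonNode",
    "TaxonomyTable",
    "TaxonomyError",
    "load_taxonomy",
    "Category",
    "SELF",
    "RECIPIENT",
    "DONOR_OTHER",
    "donor",
]


class TaxonomyError(ValueError):
    """Structural or lookup problem in a taxonomy table."""


@dataclass(frozen=True)
class TaxonNode:
    taxid: int
    parent_taxid: int
    rank: str = ""
    name: str = ""


# Hit categories. Donor categories are parameterised by kingdom label.
SELF = "SELF"
RECIPIENT = "RECIPIENT"
DONOR_OTHER = "DONOR:other"
Category = str


def donor(kingdom: str) -> Category:
    """Category label for a hit inside a named donor kingdom."""
    return f"DONOR:{kingdom}"


@dataclass
class TaxonomyTable:
    """Parent-pointer taxonomy with O(depth) lineage queries.

    Exactly one root (``parent == taxid`` or ``parent == 0``); all other
    parents must exist and parent chains must be acyclic.
    """

    nodes: dict[int, TaxonNode]
    root: int = field(init=False)

    def __post_init__(self) -> None:
        roots = [
            n.taxid
            for n in self.nodes.values()
            if n.parent_taxid == n.taxid or n.parent_taxid == 0
        ]
        if len(roots) != 1:
            raise TaxonomyError(f"expected exactly one root, found {len(roots)}")
        self.root = roots[0]
        for node in self.nodes.values():
            if node.taxid != self.root and node.parent_taxid not in self.nodes:
                raise TaxonomyError(
                    f"taxid {node.taxid} has dangling parent {node.parent_taxid}"
                )
        # Acyclicity: every lineage must reach the root within len(nodes) steps.
        for taxid in self.nodes:
            self.lineage(taxid)

    def __contains__(self, taxid: int) -> bool:
        return taxid in self.nodes

    def lineage(self, taxid: int) -> list[int]:
        """Taxids from the root down to ``taxid`` inclusive."""
        if taxid not in self.nodes:
            raise TaxonomyError(f"unknown taxid {taxid}")
        chain: list[int] = []
        seen: set[int] = set()
        cur = taxid
        while True:
            if cur in seen:
                raise TaxonomyError(f"cycle in taxonomy at taxid {cur}")
            seen.add(cur)
            chain.append(cur)
            if cur == self.root:
                break
            cur = self.nodes[cur].parent_taxid
        chain.reverse()
        return chain

    def depth(self, taxid: int) -> int:
        return len(self.lineage(taxid)) - 1

    def is_descendant(self, taxid: int, ancestor_taxid: int) -> bool:
        """True iff ``ancestor_taxid`` lies on ``taxid``'s parent chain.

        A taxid counts as its own descendant.
        """
        if ancestor_taxid not in self.nodes:
            raise TaxonomyError(f"unknown taxid {ancestor_taxid}")
        return ancestor_taxid in self.lineage(taxid)

    def classify(
        self,
        taxid: int,
        recipient_clade: int,
        self_clade: int,
        donor_kingdoms: dict[str, int],
        unknown: str = "error",
    ) -> Category:
        """Assign a hit taxon to SELF / RECIPIENT / DONOR:<kingdom> / DONOR:other.

        SELF takes precedence over RECIPIENT. Non-recipient taxa are labeled
        by the first donor kingdom (in mapping order) whose clade contains
        them, else DONOR:other. ``unknown`` chooses the policy for taxids not
        present in the table: ``"error"`` (default) or ``"other"``.
        """
        if taxid not in self.nodes:
            if unknown == "other":
                return DONOR_OTHER
            raise TaxonomyError(f"unknown taxid {taxid}")
        if self.is_descendant(taxid, self_clade):
            return SELF
        if self.is_descendant(taxid, recipient_clade):
            return RECIPIENT
        for kingdom, clade in donor_kingdoms.items():
            if clade in self.nodes and self.is_descendant(taxid, clade):
                return donor(kingdom)
        return DONOR_OTHER


def _parse_rows(rows) -> TaxonomyTable:
    nodes: dict[int, TaxonNode] = {}
    for taxid, parent, rank, name in rows:
        taxid = int(taxid)
        if taxid in nodes:
            raise TaxonomyError(f"duplicate taxid {taxid}")
        nodes[taxid] = TaxonNode(taxid, int(parent), str(rank), str(name))
    if not nodes:
        raise TaxonomyError("empty taxonomy")
    return TaxonomyTable(nodes)


def load_taxonomy(path: str | Path, dialect: str = "tsv") -> TaxonomyTable:
    """Load a taxonomy table.

    ``dialect="tsv"`` expects 4 tab-separated columns
    (taxid, parent_taxid, rank, name); lines starting with ``#`` are
    ignored. ``dialect="ncbi"`` accepts ``nodes.dmp``-style rows
    (``taxid | parent | rank | ...``); names are left empty.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if dialect == "ncbi":
                parts = [p.strip() for p in line.split("|")]
                rows.append((parts[0], parts[1], parts[2] if len(parts) > 2 else "", ""))
            else:
                parts = line.split("\t")
                if len(parts) < 4:
                    raise TaxonomyError(f"expected 4 columns, got {len(parts)}: {line!r}")
                rows.append(tuple(parts[:4]))
    return _parse_rows(rows)


def taxonomy_from_rows(rows) -> TaxonomyTable:
    """Build a table from in-memory (taxid, parent, rank, name) rows."""
    return _parse_rows(rows)
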