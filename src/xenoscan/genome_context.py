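"""Genomic-neighborhood screening of HGT candidates.

A candidate surrounded by other HGT-flagged genes is suspicious: it may be
assembly contamination rather than a genuine acquisition (unless there is
evidence for tandem duplication after transfer, or multiple transfers).
The local score over the ``window_k`` genes on each side of the focal gene
is ``(n_nonHGT - n_HGT) / (n_nonHGT + n_HGT)`` in [-1, +1]; it is not
reported for scaffolds carrying fewer than 5 genes in total.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = ["GeneMap", "read_gene_map", "local_score", "duplication_evidence", "NOT_REPORTED"]

NOT_REPORTED = None  # sentinel returned for small scaffolds
MIN_SCAFFOLD_GENES = 5


@dataclass
class GeneMap:
    """Ordered gene lists per scaffold; each gene on exactly one scaffold."""

    scaffolds: dict[str, list[str]]
    _index: dict[str, tuple[str, int]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._index = {}
        for scaf, genes in self.scaffolds.items():
            for i, g in enumerate(genes):
                if g in self._index:
                    raise ValueError(f"gene {g!r} appears on more than one scaffold")
                self._index[g] = (scaf, i)

    def locate(self, gene_id: str) -> tuple[str, int]:
        if gene_id not in self._index:
            raise KeyError(f"gene {gene_id!r} not in gene map")
        return self._index[gene_id]

    def genes(self) -> list[str]:
        return list(self._index)

    def neighbors(self, gene_id: str, window_k: int) -> list[str]:
        scaf, i = self.locate(gene_id)
        genes = self.scaffolds[scaf]
        lo = max(0, i - window_k)
        return genes[lo:i] + genes[i + 1 : i + 1 + window_k]


def read_gene_map(path: str | Path) -> GeneMap:
    """Read a TSV (gene, scaffold, start, end); order within scaffold by start."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["gene", "scaffold", "start", "end"])
    scaffolds: dict[str, list[str]] = {}
    for scaf, sub in df.sort_values(["scaffold", "start"]).groupby("scaffold", sort=True):
        scaffolds[str(scaf)] = list(sub["gene"].astype(str))
    return GeneMap(scaffolds)


def local_score(
    gene_map: GeneMap, gene_id: str, hgt_flags: dict[str, bool], window_k: int = 10
) -> float | None:
    """Neighborhood score in [-1, +1], or ``None`` (not reported) when the
    focal gene's scaffold carries fewer than 5 genes. +1 means every
    neighbor looks vertically inherited; -1 means every neighbor is itself
    an HGT candidate."""
    scaf, _ = gene_map.locate(gene_id)
    if len(gene_map.scaffolds[scaf]) < MIN_SCAFFOLD_GENES:
        return NOT_REPORTED
    neigh = gene_map.neighbors(gene_id, window_k)
    n_hgt = sum(1 for g in neigh if hgt_flags[g])
    n_non = len(neigh) - n_hgt
    return (n_non - n_hgt) / (n_non + n_hgt)


def duplication_evidence(
    gene_map: GeneMap,
    gene_id: str,
    group_membership: dict[str, str],
    window_k: int = 10,
    hgt_flags: dict[str, bool] | None = None,
) -> bool:
    """True when a negative local score is explained by post-transfer copies
    rather than contamination: an HGT-flagged neighbor belongs to the same
    candidate group (tandem duplication), or the group spans >= 2 scaffolds
    (multiple insertions)."""
    group = group_membership.get(gene_id)
    if group is None:
        return False
    for g in gene_map.neighbors(gene_id, window_k):
        if hgt_flags is not None and not hgt_flags.get(g, False):
            continue
        if group_membership.get(g) == group and g != gene_id:
            return True
    scafs = {gene_map.locate(g)[0] for g, grp in group_membership.items() if grp == group}
    return len(scafs) >= 2
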