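"""Tabular homology-search results and the Aggregate Hit Score (AHS).

The AHS flags proteins that are more similar to nonanimal (donor) than to
animal (recipient) database sequences. With ``B`` the best bitscore among a
query's non-self hits, every hit contributes its max-normalized bitscore
``nbs = bitscore / B``; the score is

    AHS = sum(nbs over donor hits) - sum(nbs over recipient hits)

over all retained hits, self-hits excluded. AHS > 0 marks a candidate.
Summing over all hits (rather than the single best per category, as the
classical Alien Index does) makes the score robust to isolated database
contaminants and taxonomic misannotations.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .taxonomy import RECIPIENT, SELF, TaxonomyTable

__all__ = [
    "ColumnSpec",
    "HitTable",
    "AhsResult",
    "DonorStats",
    "read_hit_table",
    "filter_hits",
    "hit_category",
    "compute_ahs",
    "donor_hit_stats",
    "NoInformativeHits",
]

log = logging.getLogger(__name__)

#: canonical column names used internally
CANON = [
    "query_id",
    "subject_id",
    "pct_identity",
    "aln_length",
    "evalue",
    "bitscore",
    "subject_taxids",
    "query_coverage",
]

#: role -> source column name for a DIAMOND/BLAST outfmt-6 TSV with
#: ``staxids`` and ``qcovhsp`` extras
DEFAULT_COLUMNS = {
    "query": "qseqid",
    "subject": "sseqid",
    "identity": "pident",
    "length": "length",
    "evalue": "evalue",
    "bitscore": "bitscore",
    "taxids": "staxids",
    "qcov": "qcovhsp",
}

ColumnSpec = dict


class HitTableFormatError(ValueError):
    pass


class NoInformativeHits(ValueError):
    """Raised when a query has only self-hits (AHS undefined)."""


def _sort(df: pd.DataFrame) -> pd.DataFrame:
    # deterministic per-query order: bitscore desc, then evalue asc, then
    # subject id — the tie-break also governs top-N truncation
    return df.sort_values(
        ["query_id", "bitscore", "evalue", "subject_id"],
        ascending=[True, False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)


@dataclass
class HitTable:
    """Homology hits grouped by query, each group sorted by descending bitscore."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in CANON if c not in self.df.columns]
        if missing:
            raise HitTableFormatError(f"missing columns: {missing}")
        self.df = _sort(self.df)

    def queries(self) -> list[str]:
        return list(dict.fromkeys(self.df["query_id"]))

    def hits_for(self, query_id: str) -> pd.DataFrame:
        return self.df[self.df["query_id"] == query_id]

    def subject_ids(self, query_id: str) -> set[str]:
        return set(self.hits_for(query_id)["subject_id"])

    def __len__(self) -> int:
        return len(self.df)


def read_hit_table(
    path: str | Path,
    column_spec: ColumnSpec | None = None,
    *,
    lenient: bool = False,
) -> HitTable:
    """Read a DIAMOND/BLAST outfmt-6-style TSV (gzip-transparent).

    The file must carry a header row; ``column_spec`` maps the roles
    {query, subject, identity, length, evalue, bitscore, taxids, qcov} to
    column names in that header (default: DIAMOND names). Multi-taxid cells
    are split on ``;``. Non-numeric bitscores raise unless ``lenient``, in
    which case the offending rows are dropped with a warning.
    """
    spec = dict(DEFAULT_COLUMNS)
    if column_spec:
        spec.update(column_spec)
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        df = pd.read_csv(fh, sep="\t", dtype=str, comment="#")
    if df.empty:
        log.warning("empty hit table: %s", path)
        return HitTable(pd.DataFrame(columns=CANON))
    for role in ("query", "subject", "bitscore", "evalue", "identity", "length", "taxids", "qcov"):
        if spec[role] not in df.columns:
            raise HitTableFormatError(f"missing column {spec[role]!r} (role {role})")
    out = pd.DataFrame(
        {
            "query_id": df[spec["query"]],
            "subject_id": df[spec["subject"]],
            "pct_identity": pd.to_numeric(df[spec["identity"]], errors="coerce"),
            "aln_length": pd.to_numeric(df[spec["length"]], errors="coerce"),
            "evalue": pd.to_numeric(df[spec["evalue"]], errors="coerce"),
            "bitscore": pd.to_numeric(df[spec["bitscore"]], errors="coerce"),
            "subject_taxids": df[spec["taxids"]].map(
                lambda s: [int(t) for t in str(s).split(";") if t not in ("", "nan")]
            ),
            "query_coverage": pd.to_numeric(df[spec["qcov"]], errors="coerce"),
        }
    )
    bad = out["bitscore"].isna()
    if bad.any():
        if not lenient:
            raise HitTableFormatError(
                f"non-numeric bitscore in rows {list(out.index[bad])}"
            )
        log.warning("dropping %d rows with non-numeric bitscore", int(bad.sum()))
        out = out[~bad]
    return HitTable(out)


def hit_table_from_records(records) -> HitTable:
    """Build a HitTable from dicts keyed by the canonical column names."""
    return HitTable(pd.DataFrame.from_records(records, columns=CANON))


def filter_hits(table: HitTable, max_evalue: float = 1e-3, max_targets: int = 500) -> HitTable:
    """Keep per query the hits with evalue <= ``max_evalue``, truncated to
    the ``max_targets`` best by bitscore (ties: evalue asc, subject id)."""
    if max_evalue <= 0 or max_targets < 1:
        raise ValueError("max_evalue must be > 0 and max_targets >= 1")
    df = table.df[table.df["evalue"] <= max_evalue]
    df = _sort(df).groupby("query_id", sort=False).head(max_targets)
    return HitTable(df.reset_index(drop=True))


def hit_category(
    taxids: list[int],
    taxonomy: TaxonomyTable,
    recipient_clade: int,
    self_clade: int,
    donor_kingdoms: dict[str, int],
    unknown: str = "error",
) -> str:
    """Category of one hit, resolving multi-taxid subjects conservatively.

    SELF if *any* taxid is in the self clade; else DONOR only if *all*
    taxids fall outside the recipient clade (labeled by the first taxid's
    kingdom); else RECIPIENT. This biases ambiguous hits toward the
    recipient side, guarding against false HGT calls.
    """
    cats = [
        taxonomy.classify(t, recipient_clade, self_clade, donor_kingdoms, unknown=unknown)
        for t in taxids
    ]
    if any(c == SELF for c in cats):
        return SELF
    if all(c.startswith("DONOR") for c in cats):
        return cats[0]
    return RECIPIENT


@dataclass
class AhsResult:
    query_id: str
    ahs: float
    n_recipient_hits: int
    n_donor_hits: int
    best_bitscore: float
    is_candidate: bool = field(init=False)

    def __post_init__(self) -> None:
        self.is_candidate = self.ahs > 0


def compute_ahs(
    table: HitTable,
    query_id: str,
    taxonomy: TaxonomyTable,
    recipient_clade: int,
    self_clade: int,
    donor_kingdoms: dict[str, int] | None = None,
    unknown: str = "error",
) -> AhsResult:
    """Aggregate Hit Score for one query (see module docstring).

    Raises :class:`NoInformativeHits` if every hit is a self-hit.
    """
    donor_kingdoms = donor_kingdoms or {}
    hits = table.hits_for(query_id)
    if hits.empty:
        raise NoInformativeHits(f"query {query_id!r} has no hits")
    cats = [
        hit_category(t, taxonomy, recipient_clade, self_clade, donor_kingdoms, unknown)
        for t in hits["subject_taxids"]
    ]
    informative = [
        (b, c) for b, c in zip(hits["bitscore"], cats) if c != SELF
    ]
    if not informative:
        raise NoInformativeHits(f"query {query_id!r} has only self-hits")
    best = max(b for b, _ in informative)
    ahs = 0.0
    n_rec = n_don = 0
    for b, c in informative:
        nbs = b / best
        if c.startswith("DONOR"):
            ahs += nbs
            n_don += 1
        else:
            ahs -= nbs
            n_rec += 1
    return AhsResult(query_id, ahs, n_rec, n_don, best)


@dataclass
class DonorStats:
    mean_pct_identity: float
    max_pct_identity: float
    mean_aln_length: float
    mean_query_coverage: float
    count: int


def donor_hit_stats(table: HitTable, query_id: str, donor_leaf_ids: set[str]) -> DonorStats:
    """Arithmetic means over the designated donor hits of one query.

    An empty intersection yields count 0 (downstream validation treats that
    as a criterion-1 failure).
    """
    hits = table.hits_for(query_id)
    sel = hits[hits["subject_id"].isin(donor_leaf_ids)]
    if sel.empty:
        return DonorStats(float("nan"), float("nan"), float("nan"), float("nan"), 0)
    return DonorStats(
        float(sel["pct_identity"].mean()),
        float(sel["pct_identity"].max()),
        float(sel["aln_length"].mean()),
        float(sel["query_coverage"].mean()),
        int(len(sel)),
    )
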