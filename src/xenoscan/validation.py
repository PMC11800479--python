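"""Six-rule validation of HGT candidates and Table-style summaries.

A candidate is rejected if at least one criterion fails (unless the
failure is explicitly overridden by a curator-supplied annotation token):

c1  fewer than 3 donor sequences in the sister plus ancestral-sister branch
c2  HGT topology not significantly better than constrained animal monophyly
    (overridable: misannotated_animal, animal_is_hgt)
c3  a donor hit shares > 70% identity with the candidate AND either no
    homolog exists in the closely related cryptic species or database
    contamination is suspected (token contamination_suspected) — a
    contamination signature
c4  mean donor identity < 30% (alignments too unreliable to interpret)
c5  mean donor alignment length < 100 aa AND mean query coverage < 50%
c6  local genomic-neighborhood score < 0 without duplication evidence
    (not applicable when the score is unreported, i.e. scaffold < 5 genes)

Manual-judgment subclauses are never inferred: they enter only as explicit
override tokens with provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .genome_context import NOT_REPORTED
from .homology import DonorStats

__all__ = ["CriterionState", "ValidationRecord", "CandidateBundle", "apply_criteria",
           "summarize", "read_overrides"]

PASS, FAIL, OVERRIDDEN, NOT_APPLICABLE = "pass", "fail", "overridden", "not_applicable"
CriterionState = str

#: tokens that may override a given criterion's failure
C2_OVERRIDES = {"misannotated_animal", "animal_is_hgt"}
C3_OVERRIDES = {"donor_misannotated"}

ORIGIN_ROWS = ("bacteria", "fungi", "viridiplantae", "complex", "other")


@dataclass
class CandidateBundle:
    """Everything the validation engine needs for one candidate."""

    candidate_id: str
    donor_count: int | None
    topology_verdict: str  # hgt_supported | not_significant | untested
    donor_stats: DonorStats | None
    local_score: float | None  # None = not reported
    cryptic_homolog_present: bool | None
    duplication_evidence: bool
    overrides: set[str] = field(default_factory=set)


@dataclass
class ValidationRecord:
    candidate_id: str
    criteria: dict[str, CriterionState]
    overrides: set[str]
    verdict: str = field(init=False)
    rejection_reasons: list[str] = field(init=False)

    def __post_init__(self) -> None:
        self.rejection_reasons = [
            f"{c}: {_REASONS[c]}" for c, s in sorted(self.criteria.items()) if s == FAIL
        ]
        self.verdict = "rejected" if self.rejection_reasons else "validated"


_REASONS = {
    "c1": "fewer than 3 donor sequences in sister + ancestral sister branches",
    "c2": "HGT topology not significantly better than constrained alternative",
    "c3": "donor hit > 70% identity with contamination signature",
    "c4": "mean donor identity below 30%",
    "c5": "mean donor alignment < 100 aa with mean query coverage < 50%",
    "c6": "negative genomic-neighborhood score without duplication evidence",
}


class UnevaluableCandidate(ValueError):
    """Raised when mandatory evidence (donor stats) is missing."""


def apply_criteria(bundle: CandidateBundle) -> ValidationRecord:
    """Evaluate the six rejection criteria for one candidate.

    Criteria are independent: evaluation order never affects the record.
    """
    if bundle.donor_stats is None:
        raise UnevaluableCandidate(f"{bundle.candidate_id}: donor stats missing")
    ds = bundle.donor_stats
    crit: dict[str, CriterionState] = {}

    donor_count = bundle.donor_count if bundle.donor_count is not None else ds.count
    crit["c1"] = FAIL if donor_count < 3 else PASS

    if bundle.topology_verdict == "not_significant":
        crit["c2"] = OVERRIDDEN if bundle.overrides & C2_OVERRIDES else FAIL
    elif bundle.topology_verdict == "untested":
        crit["c2"] = NOT_APPLICABLE
    else:
        crit["c2"] = PASS

    if ds.count == 0:
        # no donor evidence at all: c1 already fails; identity rules untestable
        crit["c1"] = FAIL
        crit["c3"] = crit["c4"] = crit["c5"] = NOT_APPLICABLE
    else:
        high_identity = ds.max_pct_identity > 70
        contamination_signal = (
            bundle.cryptic_homolog_present is False
            or "contamination_suspected" in bundle.overrides
        )
        if high_identity and contamination_signal:
            crit["c3"] = OVERRIDDEN if bundle.overrides & C3_OVERRIDES else FAIL
        else:
            crit["c3"] = PASS
        crit["c4"] = FAIL if ds.mean_pct_identity < 30 else PASS
        crit["c5"] = (
            FAIL if (ds.mean_aln_length < 100 and ds.mean_query_coverage < 50) else PASS
        )

    if bundle.local_score is NOT_REPORTED:
        crit["c6"] = NOT_APPLICABLE
    elif bundle.local_score < 0:
        crit["c6"] = OVERRIDDEN if bundle.duplication_evidence else FAIL
    else:
        crit["c6"] = PASS

    return ValidationRecord(bundle.candidate_id, crit, set(bundle.overrides))


def _origin_row(origin: str) -> str:
    if origin.startswith("complex"):
        return "complex"
    return origin if origin in ORIGIN_ROWS else "other"


def summarize(
    records: dict[str, ValidationRecord],
    origins: dict[str, str],
    event_origins: list[str] | None = None,
) -> pd.DataFrame:
    """Counts by donor origin at candidate and event level (Table-1 shape).

    ``origins`` maps candidate id -> origin label; ``event_origins`` is one
    origin label per distinct validated event.
    """
    rows = []
    validated = {c for c, r in records.items() if r.verdict == "validated"}
    for origin in ORIGIN_ROWS:
        cand = sum(1 for c in records if _origin_row(origins.get(c, "other")) == origin)
        val = sum(1 for c in validated if _origin_row(origins.get(c, "other")) == origin)
        ev = sum(1 for o in (event_origins or []) if _origin_row(o) == origin)
        rows.append({"origin": origin, "candidates": cand, "validated": val, "events": ev})
    total = {
        "origin": "total",
        "candidates": len(records),
        "validated": len(validated),
        "events": len(event_origins or []),
    }
    return pd.DataFrame(rows + [total])


def read_overrides(path: str | Path) -> dict[str, set[str]]:
    """Read an overrides TSV (candidate_id, token, note) into id -> tokens."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["candidate_id", "token", "note"], dtype=str)
    out: dict[str, set[str]] = {}
    for cid, tok in zip(df["candidate_id"], df["token"]):
        out.setdefault(cid, set()).add(tok)
    return out
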