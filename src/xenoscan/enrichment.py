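"""GO-term overrepresentation among validated HGT candidates.

Per term, the raw p-value is the upper-tail hypergeometric probability
P(X >= k) of drawing k study genes annotated with the term when K of the N
population genes carry it and n are drawn. Family-wise error control is by
Holm's step-down procedure (default) or a Westfall–Young-style min-p
permutation null; redundancy between nested GO terms is removed by an
elim-style refinement pass from the DAG leaves upward.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

__all__ = [
    "GoDag",
    "EnrichmentResult",
    "read_go_dag",
    "read_annotations",
    "propagate_annotations",
    "hypergeometric_enrichment",
    "fwer_adjust",
    "refine_terms",
]

log = logging.getLogger(__name__)


@dataclass
class GoDag:
    """is_a parent edges per term; acyclic with >= 1 parent per non-root."""

    parents: dict[str, set[str]]
    namespaces: dict[str, str] = field(default_factory=dict)

    def ancestors(self, term: str) -> set[str]:
        out: set[str] = set()
        stack = list(self.parents.get(term, ()))
        while stack:
            t = stack.pop()
            if t not in out:
                out.add(t)
                stack.extend(self.parents.get(t, ()))
        return out

    def descendants(self, term: str) -> set[str]:
        children: dict[str, set[str]] = {}
        for t, ps in self.parents.items():
            for p in ps:
                children.setdefault(p, set()).add(t)
        out: set[str] = set()
        stack = list(children.get(term, ()))
        while stack:
            t = stack.pop()
            if t not in out:
                out.add(t)
                stack.extend(children.get(t, ()))
        return out

    def depth(self, term: str) -> int:
        ps = self.parents.get(term, set())
        if not ps:
            return 0
        return 1 + max(self.depth(p) for p in ps)


def read_go_dag(path: str | Path) -> GoDag:
    """Read an OBO-lite TSV (term, is_a parent); roots have parent '-'."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["term", "parent"], dtype=str)
    parents: dict[str, set[str]] = {}
    for t, p in zip(df["term"], df["parent"]):
        parents.setdefault(t, set())
        if p and p != "-":
            parents[t].add(p)
    return GoDag(parents)


def read_annotations(path: str | Path) -> dict[str, set[str]]:
    """Read a TSV (gene, GO id) into gene -> set of terms."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["gene", "term"], dtype=str)
    out: dict[str, set[str]] = {}
    for g, t in zip(df["gene"], df["term"]):
        out.setdefault(g, set()).add(t)
    return out


def propagate_annotations(
    dag: GoDag, gene_to_terms: dict[str, set[str]]
) -> dict[str, set[str]]:
    """Close annotations under is_a ancestors (true-path rule); idempotent.

    Terms absent from the DAG are kept as orphans with a warning.
    """
    out: dict[str, set[str]] = {}
    warned: set[str] = set()
    for gene, terms in gene_to_terms.items():
        closed = set(terms)
        for t in terms:
            if t not in dag.parents:
                if t not in warned:
                    log.warning("term %s not in DAG; kept as orphan", t)
                    warned.add(t)
                continue
            closed |= dag.ancestors(t)
        out[gene] = closed
    return out


@dataclass
class EnrichmentResult:
    term: str
    k: int  # study genes with the term
    K: int  # population genes with the term
    n: int  # study size
    N: int  # population size
    p_raw: float
    p_adjusted: float = float("nan")
    significant: bool = False
    representative: bool = False


def hypergeometric_enrichment(
    study_genes: set[str],
    population_genes: set[str],
    annotations: dict[str, set[str]],
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric p per term over the annotated population."""
    study = set(study_genes)
    population = set(population_genes)
    if not study <= population:
        raise ValueError("study genes must be a subset of the population")
    if not study:
        return []
    N, n = len(population), len(study)
    term_pop: dict[str, int] = {}
    term_study: dict[str, int] = {}
    for gene in population:
        for t in annotations.get(gene, ()):
            term_pop[t] = term_pop.get(t, 0) + 1
            if gene in study:
                term_study[t] = term_study.get(t, 0) + 1
    out = []
    for term in sorted(term_pop):
        K = term_pop[term]
        k = term_study.get(term, 0)
        p = float(hypergeom.sf(k - 1, N, K, n))
        out.append(EnrichmentResult(term, k, K, n, N, min(p, 1.0)))
    return out


def holm_adjust(p_raw: np.ndarray) -> np.ndarray:
    """Holm step-down Bonferroni; monotone nondecreasing in raw-p order."""
    m = len(p_raw)
    order = np.argsort(p_raw, kind="mergesort")
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p_raw[idx])
        adj[idx] = min(running, 1.0)
    return adj


def fwer_adjust(
    results: list[EnrichmentResult],
    method: str = "holm",
    alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int | None = None,
    study_size: int | None = None,
    population_genes: set[str] | None = None,
    annotations: dict[str, set[str]] | None = None,
) -> list[EnrichmentResult]:
    """Attach family-wise-error-adjusted p-values and significance flags.

    ``holm`` needs nothing extra; ``permutation`` (Westfall–Young min-p:
    resample study sets of the observed size, compare each raw p against
    the null distribution of the minimum raw p) additionally needs the
    population, the annotations, and a seed.
    """
    if not results:
        return results
    p_raw = np.array([r.p_raw for r in results])
    if method == "holm":
        adj = holm_adjust(p_raw)
    elif method == "permutation":
        if seed is None or population_genes is None or annotations is None:
            raise ValueError("permutation mode needs seed, population, annotations")
        if n_perm < 100:
            log.warning("n_perm=%d is small; adjusted p-values will be coarse", n_perm)
        n = study_size or results[0].n
        pop = sorted(population_genes)
        rng = np.random.default_rng(seed)
        minps = np.empty(n_perm)
        for b in range(n_perm):
            draw = set(rng.choice(pop, size=n, replace=False))
            null = hypergeometric_enrichment(draw, set(pop), annotations)
            minps[b] = min((r.p_raw for r in null), default=1.0)
        adj = np.array([(np.sum(minps <= p) + 1) / (n_perm + 1) for p in p_raw])
    else:
        raise ValueError(f"unknown FWER method {method!r}")
    for r, a in zip(results, adj):
        r.p_adjusted = float(a)
        r.significant = a <= alpha
    return results


def refine_terms(
    dag: GoDag,
    results: list[EnrichmentResult],
    study_genes: set[str],
    annotations: dict[str, set[str]],
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """elim-style redundancy refinement of significant terms.

    Working upward from the DAG leaves, a significant ancestor stays
    *representative* only if it remains nominally significant (raw p <=
    alpha) after discounting study genes already explained by a significant
    descendant; significant terms with no significant descendants are
    representative as-is.
    """
    sig = {r.term for r in results if r.significant}
    by_term = {r.term: r for r in results}
    for r in sorted(results, key=lambda r: (-dag.depth(r.term), r.term)):
        if not r.significant:
            r.representative = False
            continue
        sig_desc = dag.descendants(r.term) & sig
        if not sig_desc:
            r.representative = True
            continue
        explained = {
            g
            for g in study_genes
            if annotations.get(g, set()) & sig_desc
        }
        k2 = sum(
            1
            for g in study_genes - explained
            if r.term in annotations.get(g, set())
        )
        n2 = len(study_genes - explained)
        p2 = float(hypergeom.sf(k2 - 1, r.N, r.K, n2)) if n2 else 1.0
        r.representative = p2 <= alpha
    return results
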