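"""Alignment handling, distances, and (constrained) neighbor joining.

These are the in-repo tree-inference stages standing in for the external
aligner/trimmer/ML toolchain: exact-duplicate removal, gap-fraction column
trimming, Poisson-corrected amino-acid distances, Saitou–Nei neighbor
joining (plus a constrained variant that forces a chosen leaf set to be
monophyletic), and nonparametric bootstrap supports. Externally computed
trees can always be substituted via Newick import.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .trees import Node, Tree

__all__ = [
    "Alignment",
    "DistanceMatrix",
    "read_fasta_alignment",
    "write_fasta_alignment",
    "dedupe_identical",
    "trim_columns",
    "poisson_distance",
    "neighbor_joining",
    "constrain_monophyly",
    "bootstrap_support",
]

#: canonical amino-acid order for state encoding
AA = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AA)}
GAP_STATE = 20  # '-' and 'X' and anything unknown -> missing


@dataclass
class Alignment:
    """Equal-length aligned amino-acid sequences with gap symbol '-'."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids/rows length mismatch")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate sequence ids")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError(f"unequal row lengths: {sorted(lengths)}")

    @property
    def n_sites(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def __len__(self) -> int:
        return len(self.ids)

    def row(self, seq_id: str) -> str:
        return self.rows[self.ids.index(seq_id)]

    def subset(self, ids: Sequence[str]) -> "Alignment":
        keep = [i for i, x in enumerate(self.ids) if x in set(ids)]
        return Alignment([self.ids[i] for i in keep], [self.rows[i] for i in keep])

    def encoded(self) -> np.ndarray:
        """(n_seqs, n_sites) int8 matrix; 20 = gap/missing. Cached."""
        cached = getattr(self, "_encoded", None)
        if cached is not None:
            return cached
        lut = np.full(128, GAP_STATE, dtype=np.int8)
        for aa, i in AA_INDEX.items():
            lut[ord(aa)] = i
            lut[ord(aa.lower())] = i
        arr = np.vstack([
            lut[np.frombuffer(row.encode("ascii"), dtype=np.uint8)]
            for row in self.rows
        ]) if self.rows else np.zeros((0, 0), dtype=np.int8)
        object.__setattr__(self, "_encoded", arr)
        return arr

    def resample_columns(self, cols: np.ndarray) -> "Alignment":
        return Alignment(list(self.ids), ["".join(r[c] for c in cols) for r in self.rows])


def read_fasta_alignment(path: str | Path) -> Alignment:
    recs = list(SeqIO.parse(str(path), "fasta"))
    return Alignment([r.id for r in recs], [str(r.seq) for r in recs])


def write_fasta_alignment(aln: Alignment, path: str | Path) -> None:
    recs = [SeqRecord(Seq(row), id=sid, description="") for sid, row in zip(aln.ids, aln.rows)]
    SeqIO.write(recs, str(path), "fasta")


def dedupe_identical(aln: Alignment) -> tuple[Alignment, dict[str, str]]:
    """Drop exact duplicate sequences (first occurrence kept).

    Returns the reduced alignment and a removed -> kept id map.
    """
    seen: dict[str, str] = {}
    ids, rows, removed = [], [], {}
    for sid, row in zip(aln.ids, aln.rows):
        if row in seen:
            removed[sid] = seen[row]
        else:
            seen[row] = sid
            ids.append(sid)
            rows.append(row)
    return Alignment(ids, rows), removed


def trim_columns(aln: Alignment, max_gap_fraction: float = 0.5) -> tuple[Alignment, list[int]]:
    """Remove columns whose gap fraction exceeds the threshold (kept at
    equality); returns the trimmed alignment and the kept column indices."""
    if not 0 <= max_gap_fraction <= 1:
        raise ValueError("max_gap_fraction must be in [0, 1]")
    n = len(aln)
    keep = []
    for j in range(aln.n_sites):
        gaps = sum(1 for r in aln.rows if r[j] == "-")
        if gaps / n <= max_gap_fraction:
            keep.append(j)
    if not keep:
        raise ValueError("all columns removed by gap trimming")
    rows = ["".join(r[j] for j in keep) for r in aln.rows]
    return Alignment(list(aln.ids), rows), keep


@dataclass
class DistanceMatrix:
    ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(m, m.T) or np.any(np.diag(m) != 0) or np.any(m < 0):
            raise ValueError("distance matrix must be symmetric, nonnegative, zero-diagonal")
        self.matrix = m


def poisson_distance(aln: Alignment, d_max: float = 10.0) -> DistanceMatrix:
    """Poisson-corrected distances d = -ln(1 - p) over shared ungapped columns.

    Pairs with saturated divergence (p close to 1) or no shared columns are
    capped at ``d_max``.
    """
    enc = aln.encoded()
    n = len(aln)
    present = enc != GAP_STATE
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = present[i] & present[j]
            ns = int(shared.sum())
            if ns == 0:
                dij = d_max
            else:
                p = float(np.mean(enc[i, shared] != enc[j, shared]))
                dij = d_max if p >= 1 - 1e-9 else min(-np.log1p(-p), d_max)
            d[i, j] = d[j, i] = dij
    return DistanceMatrix(list(aln.ids), d)


def _nj_agglomerate(ids: list[str], d0: np.ndarray,
                    constraint: set[int] | None = None) -> Tree:
    """Core NJ loop (vectorized Q-matrix selection, deterministic ties).

    When ``constraint`` (a set of leaf indices) is given, joins pairing a
    pure-constraint cluster with an outside cluster are forbidden until all
    constrained leaves have coalesced, so the output tree contains the
    constrained bipartition.
    """
    n0 = len(ids)
    if n0 < 2:
        raise ValueError("need at least 2 taxa")
    nodes: dict[int, Node] = {i: Node(ids[i]) for i in range(n0)}
    D = np.zeros((2 * n0, 2 * n0))
    D[:n0, :n0] = d0
    active = list(range(n0))
    nxt = n0
    n_members = len(constraint) if constraint else 0
    counts = {i: (1 if constraint and i in constraint else 0) for i in range(n0)}
    done = n_members <= 1

    def join(i: int, j: int, li: float, lj: float) -> int:
        nonlocal nxt, done
        parent = Node(None)
        ni, nj = nodes.pop(i), nodes.pop(j)
        ni.length, nj.length = li, lj
        parent.add(ni)
        parent.add(nj)
        nodes[nxt] = parent
        for k in active:
            if k not in (i, j):
                duk = 0.5 * (D[i, k] + D[j, k] - D[i, j])
                D[nxt, k] = D[k, nxt] = max(duk, 0.0)
        active.remove(i)
        active.remove(j)
        active.append(nxt)
        counts[nxt] = counts.pop(i) + counts.pop(j)
        if counts[nxt] == n_members:
            done = True
        nxt += 1
        return nxt - 1

    def clamp(li: float, lj: float) -> tuple[float, float]:
        # clamp negatives, compensating on the sibling branch
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        return li, max(lj, 0.0)

    def pair_mask(act: np.ndarray) -> np.ndarray:
        if done:
            return np.ones((len(act), len(act)), dtype=bool)
        has = np.array([counts[k] > 0 for k in act])
        return has[:, None] == has[None, :]

    while len(active) > 3:
        act = np.array(active)
        m = len(act)
        Dm = D[np.ix_(act, act)]
        r = Dm.sum(axis=1)
        Q = (m - 2) * Dm - r[:, None] - r[None, :]
        Q[~pair_mask(act)] = np.inf
        np.fill_diagonal(Q, np.inf)
        flat = int(np.argmin(Q))
        ai, aj = divmod(flat, m)
        if not np.isfinite(Q[ai, aj]):
            raise ValueError("no allowed join (constraint infeasible)")
        i, j = int(act[min(ai, aj)]), int(act[max(ai, aj)])
        li = 0.5 * D[i, j] + (r[min(ai, aj)] - r[max(ai, aj)]) / (2 * (m - 2))
        join(i, j, *clamp(li, D[i, j] - li))

    if len(active) == 3:
        i, j, k = sorted(active)
        if not done:
            # resolve an allowed pair first, then join the final two clusters
            pairs = [(a, b) for a, b in ((i, j), (i, k), (j, k))
                     if (counts[a] > 0) == (counts[b] > 0)]
            if not pairs:
                raise ValueError("no allowed join (constraint infeasible)")
            a, b = pairs[0]
            ra = sum(D[a, x] for x in active if x != a)
            rb = sum(D[b, x] for x in active if x != b)
            la = 0.5 * D[a, b] + (ra - rb) / 2
            u = join(a, b, *clamp(la, D[a, b] - la))
            (c,) = [x for x in active if x != u]
            root = Node(None)
            nu, nc = nodes.pop(u), nodes.pop(c)
            nu.length = nc.length = max(D[u, c], 0.0) / 2
            root.add(nu)
            root.add(nc)
            return Tree(root, rooted=False)
        li = 0.5 * (D[i, j] + D[i, k] - D[j, k])
        lj = 0.5 * (D[i, j] + D[j, k] - D[i, k])
        lk = 0.5 * (D[i, k] + D[j, k] - D[i, j])
        root = Node(None)
        for idx, ln in ((i, li), (j, lj), (k, lk)):
            node = nodes.pop(idx)
            node.length = max(ln, 0.0)
            root.add(node)
        return Tree(root, rooted=False)

    i, j = sorted(active)  # 2 clusters: n0 == 2 or constrained endgame
    root = Node(None)
    ni, nj = nodes.pop(i), nodes.pop(j)
    ni.length = nj.length = max(D[i, j], 0.0) / 2
    root.add(ni)
    root.add(nj)
    return Tree(root, rooted=False)


def neighbor_joining(dm: DistanceMatrix) -> Tree:
    """Saitou–Nei neighbor joining; exact on additive matrices.

    Returns an unrooted tree (basal trifurcation). Negative branch-length
    estimates are clamped to zero with compensation on the sibling branch.
    """
    if len(dm.ids) < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    return _nj_agglomerate(list(dm.ids), dm.matrix.copy())


def constrain_monophyly(dm: DistanceMatrix, leaf_set: set[str]) -> Tree:
    """NJ variant whose output contains the bipartition ``leaf_set | rest``.

    Joins pairing a (pure) constrained cluster with an outside cluster are
    forbidden until all of ``leaf_set`` has coalesced into a single cluster.
    """
    ids = list(dm.ids)
    members = {i for i, x in enumerate(ids) if x in leaf_set}
    if len(members) <= 1:
        return neighbor_joining(dm)  # nothing to constrain
    if len(members) >= len(ids):
        raise ValueError("constraint must be a proper subset of the taxa")
    return _nj_agglomerate(ids, dm.matrix.copy(), constraint=members)


def bootstrap_support(
    aln: Alignment,
    B: int,
    seed: int,
    tree_builder: Callable[[Alignment], Tree] | None = None,
) -> Tree:
    """Nonparametric bootstrap: resample columns, rebuild, and annotate the
    full-data tree's internal branches with replicate bipartition frequencies
    (percent). Both slots of the dual support pair are set to the bootstrap
    percentage. Deterministic given the seed."""
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    counts: dict[frozenset[str], int] = {}
    if tree_builder is None:
        # fast path: column-weighted Poisson distances on the encoded matrix
        main = neighbor_joining(poisson_distance(aln))
        enc = aln.encoded()
        n = len(aln)
        iu, ju = np.triu_indices(n, k=1)
        present = enc != GAP_STATE
        both = (present[iu] & present[ju]).astype(float)  # (npairs, n_sites)
        mism = both * (enc[iu] != enc[ju])
        probs = np.full(aln.n_sites, 1.0 / aln.n_sites)
        d_max = 10.0
        for _ in range(B):
            w = rng.multinomial(aln.n_sites, probs).astype(float)
            denom = both @ w
            with np.errstate(divide="ignore", invalid="ignore"):
                p = np.where(denom > 0, (mism @ w) / np.maximum(denom, 1), 1.0)
            d = np.where(p >= 1 - 1e-9, d_max, np.minimum(-np.log1p(-np.minimum(p, 1 - 1e-12)), d_max))
            full = np.zeros((n, n))
            full[iu, ju] = d
            full[ju, iu] = d
            rep = _nj_agglomerate(list(aln.ids), full)
            for bp in rep.bipartitions():
                counts[bp] = counts.get(bp, 0) + 1
    else:
        main = tree_builder(aln)
        for _ in range(B):
            cols = rng.integers(0, aln.n_sites, size=aln.n_sites)
            rep = tree_builder(aln.resample_columns(cols))
            for bp in rep.bipartitions():
                counts[bp] = counts.get(bp, 0) + 1
    names = set(main.leaf_names())
    anchor = min(names)
    below = main.clade_leaf_sets()
    for node in main.postorder():
        if node.is_leaf or node is main.root:
            continue
        side = below[id(node)]
        if len(side) < 2 or len(side) > len(names) - 2:
            continue
        canon = frozenset(side if anchor not in side else names - side)
        pct = 100.0 * counts.get(canon, 0) / B
        node.support = (pct, pct)
    return main
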