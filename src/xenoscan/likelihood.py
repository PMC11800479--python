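"""Per-site phylogenetic likelihoods via Felsenstein pruning.

The default substitution model is the 20-state Poisson model (equal
exchangeabilities, uniform stationary frequencies), for which the
transition probabilities have the Jukes–Cantor-type closed form

    P(same)  = 1/20 + 19/20 * exp(-20 t / 19)
    P(other) = 1/20 -  1/20 * exp(-20 t / 19)

with t in expected substitutions per site. An arbitrary reversible
empirical exchangeability matrix can be plugged in; its transition matrix
is computed by eigendecomposition. Gaps and 'X' are treated as missing
data (all-ones conditionals). Branch lengths are optimized coordinate-wise
with bounded Brent passes; the total log-likelihood never decreases.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .phylo import GAP_STATE, Alignment
from .trees import Tree

__all__ = ["PoissonModel", "EmpiricalModel", "site_log_likelihoods", "optimize_branch_lengths"]

_K = 20


@dataclass
class PoissonModel:
    """Equal-rates, uniform-frequency 20-state model (closed-form P(t))."""

    k: int = _K

    @property
    def freqs(self) -> np.ndarray:
        return np.full(self.k, 1.0 / self.k)

    def transition(self, t: float) -> np.ndarray:
        k = self.k
        e = np.exp(-k * t / (k - 1))
        p = np.full((k, k), (1.0 - e) / k)
        np.fill_diagonal(p, (1.0 + (k - 1) * e) / k)
        return p


class EmpiricalModel:
    """Reversible model from an exchangeability matrix and frequencies.

    The rate matrix Q = S diag(pi), normalized to one expected substitution
    per unit time; P(t) comes from the symmetric eigendecomposition.
    """

    def __init__(self, exchangeability: np.ndarray, freqs: np.ndarray):
        s = np.asarray(exchangeability, float)
        pi = np.asarray(freqs, float)
        pi = pi / pi.sum()
        q = s * pi[None, :]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        scale = -np.sum(pi * np.diag(q))
        q /= scale
        # symmetrize: B = diag(sqrt(pi)) Q diag(1/sqrt(pi))
        rt = np.sqrt(pi)
        b = (q * rt[:, None]) / rt[None, :]
        w, v = np.linalg.eigh((b + b.T) / 2)
        self._w, self._v, self._rt = w, v, rt
        self.k = len(pi)
        self.freqs = pi

    def transition(self, t: float) -> np.ndarray:
        e = self._v @ np.diag(np.exp(self._w * t)) @ self._v.T
        p = (e / self._rt[:, None]) * self._rt[None, :]
        return np.clip(p, 0.0, None)


def _leaf_conditional(codes: np.ndarray, k: int) -> np.ndarray:
    """(n_sites, k) indicator conditionals; missing -> all ones."""
    n = len(codes)
    cond = np.zeros((n, k))
    obs = codes != GAP_STATE
    cond[obs, codes[obs].astype(int)] = 1.0
    cond[~obs, :] = 1.0
    return cond


def site_log_likelihoods(tree: Tree, aln: Alignment, model=None) -> np.ndarray:
    """Per-site log-likelihood vector by the pruning algorithm.

    Works on rooted and unrooted (basal multifurcation) trees; for
    reversible models the result is invariant to root placement.
    """
    model = model or PoissonModel()
    k = model.k
    enc = aln.encoded()
    index = {sid: i for i, sid in enumerate(aln.ids)}
    for name in tree.leaf_names():
        if name not in index:
            raise KeyError(f"leaf {name!r} has no sequence in the alignment")
    n_sites = aln.n_sites
    cond: dict[int, np.ndarray] = {}
    scale: dict[int, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_leaf:
            cond[id(node)] = _leaf_conditional(enc[index[node.name]], k)
            scale[id(node)] = np.zeros(n_sites)
            continue
        c = np.ones((n_sites, k))
        s = np.zeros(n_sites)
        for child in node.children:
            p = model.transition(max(child.length, 0.0))
            c = c * (cond[id(child)] @ p.T)
            s = s + scale[id(child)]
            m = c.max(axis=1)
            m = np.where(m > 0, m, 1.0)
            c = c / m[:, None]
            s = s + np.log(m)
        cond[id(node)] = c
        scale[id(node)] = s
    root = tree.root
    lik = cond[id(root)] @ model.freqs
    with np.errstate(divide="ignore"):
        out = np.log(lik) + scale[id(root)]
    if not np.all(np.isfinite(out)):
        raise ValueError("non-finite site likelihood (zero-probability site)")
    return out


def optimize_branch_lengths(
    tree: Tree,
    aln: Alignment,
    model=None,
    passes: int = 2,
    tol: float = 1e-4,
    max_length: float = 20.0,
) -> tuple[Tree, float]:
    """Coordinate-wise branch-length optimization (bounded Brent per branch).

    Repeats up to ``passes`` sweeps or until the total lnL gain in a sweep
    drops below ``tol``. Returns a new tree and its total log-likelihood;
    the likelihood never decreases across accepted updates.
    """
    model = model or PoissonModel()
    t = tree.copy()
    edges = [n for n in t.postorder() if n is not t.root]
    cur = float(site_log_likelihoods(t, aln, model).sum())
    for _ in range(max(passes, 1)):
        start = cur
        for node in edges:
            orig = node.length

            def neg(x: float, node=node) -> float:
                node.length = x
                return -float(site_log_likelihoods(t, aln, model).sum())

            res = minimize_scalar(neg, bounds=(0.0, max_length), method="bounded",
                                  options={"xatol": 1e-4})
            if -res.fun > cur:
                node.length = float(res.x)
                cur = -res.fun
            else:
                node.length = orig
        if cur - start < tol:
            break
    return t, cur
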