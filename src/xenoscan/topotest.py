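"""Tree topology tests on per-site log-likelihoods (RELL resampling).

Given per-site log-likelihood vectors for competing topologies (typically
the unconstrained HGT-supporting tree versus the constrained
animal-monophyly alternative), three tests are available:

* **KH** — normal approximation on the log-likelihood difference, with the
  standard error estimated by RELL (resampling estimated log-likelihoods,
  i.e. multinomial column weights, no re-optimization).
* **SH** — centered maximum statistic over the candidate set.
* **AU** — approximately unbiased test via multiscale bootstrap: bootstrap
  probabilities are computed at scale factors r in {0.5, ..., 1.4}
  (replicate length round(r*n)), the probit-transformed values are fitted
  by weighted least squares to ``z(r) = d*sqrt(r) + c/sqrt(r)``, and
  ``p_AU = Phi(c - d)`` (curvature minus signed distance).

All tests return one p-value per tree; a small p means that tree is
significantly worse than the best competitor. Deterministic given a seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

__all__ = ["TopologyTestResult", "kh_test", "sh_test", "au_test", "topology_test"]

log = logging.getLogger(__name__)

#: multiscale bootstrap scale factors (relative replicate lengths)
AU_SCALES = tuple(np.round(np.arange(0.5, 1.41, 0.1), 2))


@dataclass
class TopologyTestResult:
    method: str
    p_values: list[float]  # one per tree, same order as input
    statistics: list[float]  # observed lnL minus best competitor lnL
    low_confidence: bool = False


def _rell_sums(site_lnl: np.ndarray, B: int, rng: np.random.Generator,
               n_resample: int | None = None) -> np.ndarray:
    """(B, n_trees) matrix of RELL-resampled total lnL per tree.

    Columns are drawn uniformly with replacement (equivalent to multinomial
    weights) and summed per replicate; chunked to bound memory.
    """
    n_trees, n_sites = site_lnl.shape
    m = n_resample or n_sites
    out = np.empty((B, n_trees))
    chunk = max(1, min(B, int(4_000_000 / max(m, 1))))
    for lo in range(0, B, chunk):
        hi = min(lo + chunk, B)
        idx = rng.integers(0, n_sites, size=(hi - lo, m))
        for t in range(n_trees):
            out[lo:hi, t] = site_lnl[t][idx].sum(axis=1)
    return out


def _check(site_lnl: np.ndarray) -> tuple[np.ndarray, bool]:
    site_lnl = np.atleast_2d(np.asarray(site_lnl, float))
    if site_lnl.shape[0] < 2:
        raise ValueError("need at least two trees")
    low = site_lnl.shape[1] < 10
    if low:
        log.warning("alignment shorter than 10 columns; topology-test p-values "
                    "are low-confidence")
    return site_lnl, low


def kh_test(site_lnl: np.ndarray, B: int = 10_000, seed: int = 0) -> TopologyTestResult:
    """Kishino–Hasegawa test, normal approximation with RELL variance.

    For each tree, delta = lnL(tree) - lnL(best other tree); the p-value is
    Phi(delta / sd) where sd is the RELL standard deviation of delta. Two
    equally good trees give p near 0.5.
    """
    site_lnl, low = _check(site_lnl)
    rng = np.random.default_rng(seed)
    totals = site_lnl.sum(axis=1)
    reps = _rell_sums(site_lnl, B, rng)
    ps, stats = [], []
    for i in range(len(totals)):
        others = [j for j in range(len(totals)) if j != i]
        j = others[int(np.argmax(totals[others]))]
        d_site = site_lnl[i] - site_lnl[j]
        delta = float(d_site.sum())
        rep_d = reps[:, i] - reps[:, j]
        sd = float(np.std(rep_d - rep_d.mean(), ddof=1))
        if sd == 0:
            ps.append(0.5 if delta == 0 else (1.0 if delta > 0 else 0.0))
        else:
            ps.append(float(norm.cdf(delta / sd)))
        stats.append(delta)
    return TopologyTestResult("KH", ps, stats, low)


def sh_test(site_lnl: np.ndarray, B: int = 10_000, seed: int = 0) -> TopologyTestResult:
    """Shimodaira–Hasegawa test (centered max statistic over all trees)."""
    site_lnl, low = _check(site_lnl)
    rng = np.random.default_rng(seed)
    totals = site_lnl.sum(axis=1)
    t_obs = totals.max() - totals
    reps = _rell_sums(site_lnl, B, rng)
    centered = reps - reps.mean(axis=0, keepdims=True)
    s = centered.max(axis=1, keepdims=True) - centered  # (B, n_trees)
    ps = [float(np.mean(s[:, i] >= t_obs[i])) for i in range(len(totals))]
    return TopologyTestResult("SH", ps, list(map(float, totals - totals.max())), low)


def au_test(site_lnl: np.ndarray, B: int = 10_000, seed: int = 0,
            scales: tuple[float, ...] = AU_SCALES) -> TopologyTestResult:
    """Approximately unbiased test by multiscale bootstrap (see module doc).

    ``B`` replicates are drawn at each scale. Degenerate bootstrap
    proportions (0 or 1 across all scales) short-circuit to p = 0 or 1.
    """
    site_lnl, low = _check(site_lnl)
    rng = np.random.default_rng(seed)
    n_trees, n_sites = site_lnl.shape
    totals = site_lnl.sum(axis=1)
    bp = np.zeros((len(scales), n_trees))
    for si, r in enumerate(scales):
        m = max(1, int(round(r * n_sites)))
        reps = _rell_sums(site_lnl, B, rng, n_resample=m) * (n_sites / m)
        # break exact ties symmetrically (negligible for real lnL vectors)
        reps = reps + rng.uniform(0.0, 1e-9, size=reps.shape)
        winners = np.argmax(reps, axis=1)
        bp[si] = np.bincount(winners, minlength=n_trees) / B
    ps = []
    rs = np.asarray(scales)
    for i in range(n_trees):
        ps.append(_au_fit(bp[:, i], rs, B))
    return TopologyTestResult("AU", ps, list(map(float, totals - totals.max())), low)


def _au_fit(bp: np.ndarray, scales: np.ndarray, B: int) -> float:
    """WLS fit of z(r) = d*sqrt(r) + c/sqrt(r); p = Phi(c - d).

    Degenerate bootstrap curves (essentially no wins, or essentially all
    wins, at every scale) short-circuit to 0/1: the probit fit is undefined
    there and a handful of freak replicates must not dominate the fit.
    """
    counts = bp * B
    if counts.max() < 5:
        return 0.0
    if counts.min() > B - 5:
        return 1.0
    informative = (counts >= 1) & (counts <= B - 1)
    if informative.sum() >= 3:
        bp, scales = bp[informative], scales[informative]
    eps = 0.5 / B
    bpc = np.clip(bp, eps, 1 - eps)
    z = norm.ppf(1.0 - bpc)  # large BP -> negative z
    # binomial delta-method weights: var(z) = BP(1-BP) / (B * phi(z)^2)
    phi = norm.pdf(z)
    w = B * phi**2 / (bpc * (1 - bpc))
    x1 = np.sqrt(scales)
    x2 = 1.0 / np.sqrt(scales)
    X = np.column_stack([x1, x2])
    wx = X * w[:, None]
    beta = np.linalg.solve(X.T @ wx, wx.T @ z)
    d, c = beta
    return float(norm.cdf(c - d))


def topology_test(
    tree_site_lnl: dict[str, np.ndarray],
    method: str = "AU",
    B: int = 10_000,
    seed: int = 0,
) -> dict[str, float]:
    """Run one test over named trees' site-lnL vectors; returns name -> p."""
    names = list(tree_site_lnl)
    mat = np.vstack([tree_site_lnl[n] for n in names])
    fn = {"KH": kh_test, "SH": sh_test, "AU": au_test}[method.upper()]
    res = fn(mat, B=B, seed=seed)
    return dict(zip(names, res.p_values))
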