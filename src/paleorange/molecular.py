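"""Partitioned GTR+Gamma likelihood under a strict molecular clock.

Branch lengths in expected substitutions are ``duration (Myr) x clock
rate x partition multiplier x gamma-category rate``; per-site rate
heterogeneity uses the discrete-gamma approximation with equal-weight
categories and category means (4 categories by default).  The GTR
generator is normalized to one expected substitution per unit branch
length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammainc, logsumexp

from .characters import NUCLEOTIDES, PartitionedAlignment
from .trees import TimeTree

__all__ = ["GTRParams", "gtr_rate_matrix", "discrete_gamma_rates",
           "molecular_loglik", "JC_PARAMS"]


@dataclass
class GTRParams:
    """GTR exchangeabilities/frequencies plus clock and rate multipliers.

    ``exch`` orders pairs AC, AG, AT, CG, CT, GT.  ``rate_mult`` is the
    per-partition relative rate; ``clock`` is in substitutions/site/Myr.
    """

    exch: tuple = (1 / 6,) * 6
    freqs: tuple = (0.25,) * 4
    alpha: float = 1.0
    rate_mult: float = 1.0
    clock: float = 1.0

    def __post_init__(self):
        e = np.asarray(self.exch, dtype=float)
        f = np.asarray(self.freqs, dtype=float)
        if e.shape != (6,) or np.any(e <= 0):
            raise ValueError("need 6 positive exchangeabilities")
        if f.shape != (4,) or np.any(f <= 0):
            raise ValueError("need 4 positive base frequencies")
        self.exch = tuple(float(x) for x in e / e.sum())
        self.freqs = tuple(float(x) for x in f / f.sum())
        if self.alpha <= 0 or self.rate_mult <= 0 or self.clock <= 0:
            raise ValueError("alpha, rate_mult and clock must be > 0")


JC_PARAMS = GTRParams()


def gtr_rate_matrix(exch, freqs) -> np.ndarray:
    """Normalized GTR generator: q_ij = s_ij pi_j, mean rate 1."""
    s = np.zeros((4, 4))
    pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
    for k, (i, j) in enumerate(pairs):
        s[i, j] = s[j, i] = exch[k]
    pi = np.asarray(freqs, dtype=float)
    Q = s * pi[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    scale = -float(pi @ np.diag(Q))
    return Q / scale


def discrete_gamma_rates(alpha: float, k: int = 4) -> np.ndarray:
    """Mean rates of k equal-probability Gamma(alpha, alpha) categories."""
    from scipy.stats import gamma as gamma_dist
    edges = gamma_dist.ppf(np.linspace(0, 1, k + 1), alpha, scale=1.0 / alpha)
    # category mean via the incomplete-gamma identity
    upper = gammainc(alpha + 1, edges[1:] * alpha)
    lower = gammainc(alpha + 1, edges[:-1] * alpha)
    rates = k * (upper - lower)
    return rates / rates.mean() * 1.0


class _GTRPropagator:
    """Spectral decomposition of a reversible GTR generator."""

    def __init__(self, params: GTRParams):
        self.pi = np.asarray(params.freqs)
        Q = gtr_rate_matrix(params.exch, params.freqs)
        sq = np.sqrt(self.pi)
        B = (Q * sq[:, None]) / sq[None, :]
        B = 0.5 * (B + B.T)
        w, V = np.linalg.eigh(B)
        self.w = w
        self.left = V / sq[:, None]      # rows scaled by 1/sqrt(pi)
        self.right = V.T * sq[None, :]   # columns scaled by sqrt(pi)

    def matrix(self, t: float) -> np.ndarray:
        P = (self.left * np.exp(self.w * t)) @ self.right
        np.clip(P, 0.0, 1.0, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P


def _tip_partials_from_mask(mask_col: np.ndarray) -> np.ndarray:
    """(n_taxa,) bitmask column -> (n_taxa, 4) indicator partials."""
    bits = np.array([1, 2, 4, 8], dtype=np.uint8)
    return ((mask_col[:, None] & bits[None, :]) > 0).astype(float)


def _partition_loglik(tree: TimeTree, taxa_order, masks: np.ndarray,
                      params: GTRParams, n_cat: int) -> float:
    """Log-likelihood of one partition (masks: n_taxa x n_sites bitmasks)."""
    patterns, counts = np.unique(masks, axis=1, return_counts=True)
    n_pat = patterns.shape[1]
    prop = _GTRPropagator(params)
    rates = discrete_gamma_rates(params.alpha, n_cat)
    tip_idx = {label: k for k, label in enumerate(taxa_order)}
    per_cat = np.zeros((n_cat, n_pat))
    for ci, r in enumerate(rates):
        L: dict[int, np.ndarray] = {}
        scale = np.zeros(n_pat)
        for v in tree.postorder():
            if not tree.children[v]:
                L[v] = _tip_partials_from_mask(
                    patterns[tip_idx[tree.labels[v]]]).T  # (4, n_pat)
            else:
                acc = np.ones((4, n_pat))
                for c in tree.children[v]:
                    bl = tree.branch_length(c) * params.clock * params.rate_mult * r
                    P = prop.matrix(bl)
                    acc *= P @ L[c]
                    del L[c]
                m = acc.max(axis=0)
                if np.any(m <= 0):
                    return -np.inf
                scale += np.log(m)
                L[v] = acc / m
        site = prop.pi @ L[tree.root]
        if np.any(site <= 0):
            return -np.inf
        per_cat[ci] = np.log(site) + scale
    site_log = logsumexp(per_cat, axis=0) - np.log(n_cat)
    return float(counts @ site_log)


def molecular_loglik(tree: TimeTree, aln: PartitionedAlignment,
                     params, n_cat: int = 4) -> float:
    """Partitioned GTR+Gamma log-likelihood on a dated tree.

    ``params`` is either a single :class:`GTRParams` shared by all
    partitions or a mapping ``partition id -> GTRParams``.
    """
    taxa = aln.taxa()
    tree_tips = set(tree.tip_labels())
    if not tree_tips <= set(taxa):
        missing = sorted(tree_tips - set(taxa))
        raise ValueError(f"alignment missing tree tips: {missing[:5]}")
    masks = aln.encoded()
    total = 0.0
    for pid, sites in aln.partitions.items():
        p = params[pid] if isinstance(params, dict) else params
        total += _partition_loglik(tree, taxa, masks[:, sites], p, n_cat)
        if not np.isfinite(total):
            return -np.inf
    return total
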