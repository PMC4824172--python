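"""Codon substitution rate matrices (Goldman-Yang style).

Instantaneous rates between codons differing at exactly one nucleotide:
q_ij = pi_j * kappa^{ts} * omega^{nonsyn}; multi-hit rates are 0.  Matrices
are reversible with respect to pi, so transition probabilities are computed
through a symmetrized eigendecomposition rather than repeated expm calls.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.special import betainc
from scipy.stats import beta as beta_dist

from ..alignments import AMINO_ACIDS, CODONS

__all__ = ["build_rate_matrix", "codon_eig", "prob_matrix", "discretize_beta"]

_PURINES = {"A", "G"}


def _neighbor_structure():
    n = len(CODONS)
    ii, jj, ts, syn = [], [], [], []
    for i, j in itertools.combinations(range(n), 2):
        a, b = CODONS[i], CODONS[j]
        diff = [k for k in range(3) if a[k] != b[k]]
        if len(diff) != 1:
            continue
        (k,) = diff
        ii.append(i)
        jj.append(j)
        ts.append((a[k] in _PURINES) == (b[k] in _PURINES))
        syn.append(AMINO_ACIDS[i] == AMINO_ACIDS[j])
    return (
        np.array(ii),
        np.array(jj),
        np.array(ts, dtype=bool),
        np.array(syn, dtype=bool),
    )


_I, _J, _IS_TS, _IS_SYN = _neighbor_structure()


def _check_pi(pi: np.ndarray) -> np.ndarray:
    pi = np.asarray(pi, dtype=float)
    if pi.shape != (61,) or np.any(pi <= 0) or abs(pi.sum() - 1.0) > 1e-8:
        raise ValueError("pi must be 61 positive frequencies summing to 1")
    return pi


def _unscaled_q(kappa: float, omega: float, pi: np.ndarray) -> tuple[np.ndarray, float]:
    """Unscaled generator and its mean rate -sum(pi_i q_ii)."""
    if kappa <= 0 or omega < 0:
        raise ValueError("kappa must be > 0 and omega >= 0")
    q = np.zeros((61, 61))
    factor = np.where(_IS_TS, kappa, 1.0) * np.where(_IS_SYN, 1.0, omega)
    q[_I, _J] = factor * pi[_J]
    q[_J, _I] = factor * pi[_I]
    np.fill_diagonal(q, -q.sum(axis=1))
    rate = float(-(pi * np.diag(q)).sum())
    return q, rate


def build_rate_matrix(kappa: float, omega: float, pi: np.ndarray) -> np.ndarray:
    """61x61 generator rescaled to one expected substitution per site per unit time."""
    pi = _check_pi(pi)
    q, rate = _unscaled_q(kappa, omega, pi)
    return q / rate


@dataclass
class CodonEig:
    """Eigendecomposition of an unscaled codon generator.

    ``rate`` is the mean substitution rate of the unscaled generator; the
    caller divides branch lengths by the appropriate normalization (the
    class's own rate for single-class and branch models, the mixture-mean
    rate for site models) when requesting transition matrices.
    """

    v: np.ndarray
    lam: np.ndarray
    vinv: np.ndarray
    rate: float


def codon_eig(kappa: float, omega: float, pi: np.ndarray) -> CodonEig:
    pi = _check_pi(pi)
    q, rate = _unscaled_q(kappa, omega, pi)
    sq = np.sqrt(pi)
    sym = (q * sq[:, None]) / sq[None, :]
    sym = 0.5 * (sym + sym.T)
    lam, u = np.linalg.eigh(sym)
    v = u / sq[:, None]
    vinv = u.T * sq[None, :]
    return CodonEig(v, lam, vinv, rate)


def prob_matrix(eig: CodonEig, t: float) -> np.ndarray:
    """Transition matrix exp(Q_unscaled * t); pass t already normalized."""
    if t < 0:
        raise ValueError("branch length must be >= 0")
    p = (eig.v * np.exp(eig.lam * t)) @ eig.vinv
    np.clip(p, 0.0, None, out=p)
    p /= p.sum(axis=1, keepdims=True)
    return p


def discretize_beta(p: float, q: float, ncat: int = 8) -> tuple[np.ndarray, np.ndarray]:
    """Discretize Beta(p, q) into ``ncat`` equal-probability categories.

    Category values are the conditional means of the beta density within
    each inter-quantile bin (closed form through the incomplete beta
    function); each category has probability 1/ncat.
    """
    if p <= 0 or q <= 0:
        raise ValueError("beta shapes must be positive")
    if ncat < 1:
        raise ValueError("ncat must be >= 1")
    edges = beta_dist.ppf(np.linspace(0, 1, ncat + 1), p, q)
    # E[X | a < X < b] * P(a < X < b) = mean * (I_b(p+1,q) - I_a(p+1,q))
    upper = betainc(p + 1, q, edges)
    means = (p / (p + q)) * np.diff(upper) * ncat
    # guard float round-off at extreme shapes: means live strictly in (0, 1)
    means = np.clip(means, 1e-12, 1 - 1e-12)
    probs = np.full(ncat, 1.0 / ncat)
    return means, probs
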