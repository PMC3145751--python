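"""Reversible substitution models with discrete-gamma rate variation.

A model is a symmetric exchangeability matrix S, stationary frequencies pi,
and a gamma shape ``alpha`` approximated by ``k`` equal-probability rate
categories.  The rate matrix Q = S diag(pi) is rescaled so that branch
lengths are in expected substitutions per site, and category rates are the
category means of Gamma(alpha, alpha) (mean 1), following Yang's (1994)
mean-rate discretization.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

from ._aamodels import AA_ORDER, LG_FREQS, LG_RATES, WAG_FREQS, WAG_RATES

DNA_ORDER = "ACGT"


def discrete_gamma_rates(alpha: float, k: int) -> np.ndarray:
    """Mean rates of the k equal-probability categories of Gamma(alpha, alpha).

    The mean of the distribution is 1 and the category means average to 1
    exactly.  With k = 1 the single rate is 1 regardless of alpha.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k == 1:
        return np.ones(1)
    if alpha is None or alpha <= 0:
        raise ValueError("alpha must be positive")
    edges = gamma_dist.ppf(np.arange(k + 1) / k, a=alpha, scale=1.0 / alpha)
    # E[X | a<X<b] * P(a<X<b) = I(alpha+1, alpha*b) - I(alpha+1, alpha*a)
    cum = gammainc(alpha + 1.0, alpha * edges)
    cum[0], cum[-1] = 0.0, 1.0
    rates = k * np.diff(cum)
    return rates / rates.mean()


@dataclass(frozen=True)
class SubstModel:
    """Reversible substitution model + discrete-gamma among-site rates."""

    alphabet: str  # "dna" or "protein"
    exchangeabilities: np.ndarray  # (s, s) symmetric, zero diagonal
    freqs: np.ndarray  # simplex of length s
    alpha: float | None = None
    k: int = 1
    name: str = ""

    def __post_init__(self):
        S = np.asarray(self.exchangeabilities, dtype=float)
        pi = np.asarray(self.freqs, dtype=float)
        if S.shape[0] != S.shape[1] or S.shape[0] != pi.shape[0]:
            raise ValueError("exchangeability/frequency shapes disagree")
        if not np.allclose(S, S.T):
            raise ValueError("exchangeabilities must be symmetric")
        if np.any(S < 0) or np.any(pi < 0):
            raise ValueError("negative model parameters")
        if not np.isclose(pi.sum(), 1.0, atol=1e-8):
            raise ValueError("frequencies must sum to 1")
        object.__setattr__(self, "exchangeabilities", S)
        object.__setattr__(self, "freqs", pi / pi.sum())

    # -- derived quantities ----------------------------------------------
    @property
    def n_states(self) -> int:
        return self.freqs.shape[0]

    @property
    def states(self) -> str:
        return DNA_ORDER if self.alphabet == "dna" else AA_ORDER

    def rate_matrix(self) -> np.ndarray:
        """Q rescaled so the expected substitution rate at stationarity is 1."""
        S = self.exchangeabilities
        pi = self.freqs
        Q = S * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        Q[np.diag_indices_from(Q)] = -Q.sum(axis=1)
        mu = -(pi * np.diag(Q)).sum()
        if mu <= 0:
            raise ValueError("degenerate rate matrix (no substitutions)")
        return Q / mu

    def category_rates(self) -> np.ndarray:
        return discrete_gamma_rates(self.alpha if self.k > 1 else 1.0, self.k)

    def eigen(self):
        """Symmetric-form eigendecomposition for fast P(t) = exp(Qt)."""
        Q = self.rate_matrix()
        pi = self.freqs
        sq = np.sqrt(pi)
        A = (Q * sq[:, None]) / sq[None, :]
        w, V = np.linalg.eigh((A + A.T) / 2.0)
        left = V.T * sq[None, :]  # rows: V^T D
        right = V / sq[:, None]  # D^-1 V
        return w, right, left

    def transition_matrices(self, t: float) -> np.ndarray:
        """P(Q * r_j * t) for every rate category, shape (k, s, s)."""
        w, right, left = self.eigen()
        rates = self.category_rates()
        out = np.empty((self.k, self.n_states, self.n_states))
        for j, r in enumerate(rates):
            P = (right * np.exp(w * r * t)[None, :]) @ left
            np.clip(P, 0.0, None, out=P)
            P /= P.sum(axis=1, keepdims=True)
            out[j] = P
        return out

    def with_alpha(self, alpha: float) -> "SubstModel":
        return replace(self, alpha=alpha)

    # -- constructors ------------------------------------------------------
    @staticmethod
    def jc(alpha: float | None = None, k: int = 1) -> "SubstModel":
        S = np.ones((4, 4)) - np.eye(4)
        return SubstModel("dna", S, np.full(4, 0.25), alpha=alpha, k=k, name="JC69")

    @staticmethod
    def gtr(
        rates,
        freqs,
        alpha: float | None = None,
        k: int = 1,
    ) -> "SubstModel":
        """General time-reversible DNA model.

        ``rates`` is either a full symmetric 4x4 matrix or the 6 upper
        triangle exchangeabilities in order AC, AG, AT, CG, CT, GT.
        """
        rates = np.asarray(rates, dtype=float)
        if rates.shape == (6,):
            S = np.zeros((4, 4))
            S[np.triu_indices(4, 1)] = rates
            S = S + S.T
        else:
            S = rates
        return SubstModel("dna", S, np.asarray(freqs, float), alpha=alpha, k=k, name="GTR")

    @staticmethod
    def hky(kappa: float = 4.0, freqs=(0.25, 0.25, 0.25, 0.25), alpha=None, k=1) -> "SubstModel":
        """HKY-style model: transitions (AG, CT) scaled by kappa."""
        return SubstModel.gtr([1.0, kappa, 1.0, 1.0, kappa, 1.0], freqs, alpha=alpha, k=k)

    @staticmethod
    def lg(alpha: float | None = None, k: int = 1) -> "SubstModel":
        return SubstModel(
            "protein", np.array(LG_RATES), np.array(LG_FREQS), alpha=alpha, k=k, name="LG"
        )

    @staticmethod
    def wag(alpha: float | None = None, k: int = 1) -> "SubstModel":
        return SubstModel(
            "protein", np.array(WAG_RATES), np.array(WAG_FREQS), alpha=alpha, k=k, name="WAG"
        )

    @staticmethod
    def empirical_dna(aln, partition: str | None = None, alpha=None, k=1) -> "SubstModel":
        """Unit exchangeabilities with frequencies counted from an alignment.

        The simple one-pass surrogate for a fitted GTR when only rate
        classification is needed.
        """
        cols = aln.partitions[partition] if partition else np.arange(aln.n_cols)
        block = aln.data[:, cols]
        counts = np.array([(block == b).sum() for b in DNA_ORDER], dtype=float)
        counts = np.maximum(counts, 1.0)
        S = np.ones((4, 4)) - np.eye(4)
        return SubstModel("dna", S, counts / counts.sum(), alpha=alpha, k=k, name="F81-emp")
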