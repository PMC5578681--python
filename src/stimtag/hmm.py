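"""Exact smoothing for a single binary Markov chain.

Given per-time log evidence ``eta[t, s]`` (the expected log-likelihood of all
observations at time ``t`` under chain state ``s``), initial log weights and
transition log weights, :func:`forward_backward` returns the single-slice
marginals, the two-slice marginals and the log normalizer of the posterior

    q(z) ∝ exp( log_pi[z_0] + sum_t log_A[z_t, z_{t+1}] + sum_t eta[t, z_t] ).

Conventions: transition matrices are row-stochastic, ``A[i, j] = p(j | i)``,
and two-slice marginals are stored as ``Xi[t, i, j] = q(z_t = i, z_{t+1} = j)``.

The recursions run entirely in log space (pooled evidence from many units can
reach magnitudes of 1e4, far beyond what scaled-probability recursions
tolerate). The log weights need not be normalized: mean-field updates supply
sub-normalized ``exp(digamma)`` chain parameters, and the normalizer is simply
absorbed into ``log_Z``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

__all__ = ["ChainEvidence", "ChainPosterior", "forward_backward", "chain_entropy"]


@dataclass
class ChainEvidence:
    """Inputs to one smoothing pass: log evidence plus chain log weights."""

    log_evidence: np.ndarray  # (T, 2)
    log_pi: np.ndarray  # (2,)
    log_A: np.ndarray  # (2, 2), log_A[i, j] = log weight of i -> j

    def __post_init__(self) -> None:
        self.log_evidence = np.atleast_2d(np.asarray(self.log_evidence, dtype=float))
        self.log_pi = np.asarray(self.log_pi, dtype=float).reshape(2)
        self.log_A = np.asarray(self.log_A, dtype=float).reshape(2, 2)
        if self.log_evidence.shape[1] != 2:
            raise ValueError("log_evidence must have shape (T, 2)")
        if not np.all(np.isfinite(self.log_evidence)):
            t = int(np.argmax(~np.all(np.isfinite(self.log_evidence), axis=1)))
            raise FloatingPointError(f"non-finite log evidence at time_bin={t}")
        # -inf log weights encode structural zeros (deterministic chains) and
        # are legal; nan / +inf are not.
        for arr in (self.log_pi, self.log_A):
            if np.any(np.isnan(arr)) or np.any(arr == np.inf):
                raise FloatingPointError("invalid chain parameters (nan or +inf)")

    @property
    def n_time_bins(self) -> int:
        return self.log_evidence.shape[0]

    def is_normalized(self, atol: float = 1e-10) -> bool:
        """Whether exp(log_pi) and the rows of exp(log_A) sum to 1."""
        return bool(
            np.isclose(np.exp(self.log_pi).sum(), 1.0, atol=atol)
            and np.allclose(np.exp(self.log_A).sum(axis=1), 1.0, atol=atol)
        )


@dataclass
class ChainPosterior:
    """Smoothed marginals of one chain.

    ``xi[t, s]`` is the posterior probability of state ``s`` at time ``t``;
    ``Xi[t, i, j]`` the joint of ``(z_t = i, z_{t+1} = j)``; ``log_Z`` the log
    normalizer of the unnormalized chain potential.
    """

    xi: np.ndarray  # (T, 2)
    Xi: np.ndarray  # (T-1, 2, 2)
    log_Z: float

    @property
    def n_time_bins(self) -> int:
        return self.xi.shape[0]

    def check_consistency(self, atol: float = 1e-8) -> None:
        if not np.allclose(self.xi.sum(axis=1), 1.0, atol=1e-10):
            raise AssertionError("single-slice marginals do not normalize")
        if self.Xi.shape[0]:
            if not np.allclose(self.Xi.sum(axis=2), self.xi[:-1], atol=atol):
                raise AssertionError("Xi marginalized over 'to' state != xi[t]")
            if not np.allclose(self.Xi.sum(axis=1), self.xi[1:], atol=atol):
                raise AssertionError("Xi marginalized over 'from' state != xi[t+1]")


def _lse2(a: float, b: float) -> float:
    """log(exp(a) + exp(b)) on scalars, tolerant of -inf."""
    if a < b:
        a, b = b, a
    if b == -np.inf:
        return a
    return a + math.log1p(math.exp(b - a))


def forward_backward(ev: ChainEvidence) -> ChainPosterior:
    """Exact single- and two-slice marginals by log-space smoothing.

    The recursions run over scalars (two states) rather than array slices;
    at typical lengths (10^3-10^4 bins per chain per sweep) this is an order
    of magnitude faster than per-step array log-sum-exp.
    """
    eta, log_pi, log_A = ev.log_evidence, ev.log_pi, ev.log_A
    T = ev.n_time_bins
    e0 = eta[:, 0].tolist()
    e1 = eta[:, 1].tolist()
    a00, a01 = float(log_A[0, 0]), float(log_A[0, 1])
    a10, a11 = float(log_A[1, 0]), float(log_A[1, 1])

    la = np.empty((T, 2))
    f0, f1 = float(log_pi[0]) + e0[0], float(log_pi[1]) + e1[0]
    la[0, 0], la[0, 1] = f0, f1
    for t in range(1, T):
        # la[t, j] = logsum_i( la[t-1, i] + log_A[i, j] ) + eta[t, j]
        f0, f1 = (
            _lse2(f0 + a00, f1 + a10) + e0[t],
            _lse2(f0 + a01, f1 + a11) + e1[t],
        )
        la[t, 0], la[t, 1] = f0, f1
    log_Z = _lse2(f0, f1)

    lb = np.zeros((T, 2))
    b0 = b1 = 0.0
    for t in range(T - 2, -1, -1):
        c0, c1 = e0[t + 1] + b0, e1[t + 1] + b1
        b0, b1 = _lse2(a00 + c0, a01 + c1), _lse2(a10 + c0, a11 + c1)
        lb[t, 0], lb[t, 1] = b0, b1

    log_xi = la + lb
    log_xi -= logsumexp(log_xi, axis=1, keepdims=True)
    xi = np.exp(log_xi)

    if T > 1:
        log_Xi = (
            la[:-1, :, None]
            + log_A[None, :, :]
            + (eta[1:] + lb[1:])[:, None, :]
        )
        log_Xi -= logsumexp(log_Xi, axis=(1, 2), keepdims=True)
        Xi = np.exp(log_Xi)
    else:
        Xi = np.zeros((0, 2, 2))
    return ChainPosterior(xi=xi, Xi=Xi, log_Z=log_Z)


def chain_entropy(post: ChainPosterior, ev: ChainEvidence) -> float:
    """Entropy of the chain posterior.

    ``H[q] = log_Z - E_q[log w]`` with ``w`` the unnormalized potential; the
    expectation is a linear functional of the smoothed marginals.
    """
    if post.n_time_bins != ev.n_time_bins:
        raise ValueError(
            f"posterior covers T={post.n_time_bins} bins but evidence T={ev.n_time_bins}"
        )
    # 0 * (-inf) from deterministic initial states / transitions contributes 0
    with np.errstate(invalid="ignore"):
        pi_term = np.where(post.xi[0] > 0, post.xi[0] * ev.log_pi, 0.0)
    e_log_w = float(pi_term.sum()) + float(np.sum(post.xi * ev.log_evidence))
    if post.Xi.shape[0]:
        with np.errstate(invalid="ignore"):
            terms = np.where(post.Xi > 0, post.Xi * ev.log_A[None, :, :], 0.0)
        e_log_w += float(np.sum(terms))
    H = post.log_Z - e_log_w
    return max(H, 0.0) if H > -1e-8 else H
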