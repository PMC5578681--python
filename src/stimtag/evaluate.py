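"""Quantitative comparison of inferred tags against ground truth or labels.

Inferred tags come back from the fit as time series of posterior marginal
probabilities, in arbitrary order and with arbitrary on/off polarity relative
to the truth, so comparisons go through (a) a soft normalized mutual
information that consumes the marginals directly, and (b) an optimal
injective matching of true tags to inferred tags under that score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .inference import VariationalState

__all__ = [
    "FeatureMatch",
    "normalized_mutual_information",
    "match_features",
    "rate_reconstruction_error",
    "predict_rates",
]


@dataclass
class FeatureMatch:
    """Injective map from true-tag index to inferred-tag index with the
    per-pair NMI score of each match."""

    permutation: dict[int, int]
    matched_nmi: np.ndarray

    def __post_init__(self) -> None:
        if len(set(self.permutation.values())) != len(self.permutation):
            raise ValueError("permutation must be injective")


def _soft_joint(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Time-averaged joint distribution of two binary series.

    Either argument may be hard {0, 1} labels or marginal probabilities of
    state 1; expectations of the indicator co-occurrences are taken under
    them, i.e. the joint is estimated by averaging posteriors across time.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("series must be 1-D and of equal length")
    px = np.column_stack([1.0 - x, x])  # (T, 2)
    py = np.column_stack([1.0 - y, y])
    return px.T @ py / x.shape[0]  # (2, 2)


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def normalized_mutual_information(x: np.ndarray, y: np.ndarray) -> float:
    """``I(X; Y) / sqrt(H(X) H(Y))`` of two binary series.

    The geometric-mean normalization keeps the score in [0, 1]. A constant
    series has zero entropy and carries no information, so the score is
    defined as 0 in that case. Invariant to flipping the 0/1 labels of either
    argument.
    """
    joint = _soft_joint(x, y)
    px, py = joint.sum(axis=1), joint.sum(axis=0)
    hx, hy = _entropy(px), _entropy(py)
    if hx <= 0.0 or hy <= 0.0:
        return 0.0
    mi = 0.0
    for a in range(2):
        for b in range(2):
            if joint[a, b] > 0:
                mi += joint[a, b] * np.log(joint[a, b] / (px[a] * py[b]))
    return float(np.clip(mi / np.sqrt(hx * hy), 0.0, 1.0))


def match_features(truth: np.ndarray, inferred: np.ndarray) -> FeatureMatch:
    """Optimal injective assignment of true tags to inferred tags.

    Maximizes the total pairwise NMI by the Hungarian algorithm (exact for
    any K); ties resolve deterministically.
    """
    truth = np.atleast_2d(np.asarray(truth, dtype=float))
    inferred = np.atleast_2d(np.asarray(inferred, dtype=float))
    if truth.shape[0] != inferred.shape[0]:
        raise ValueError("truth and inferred must cover the same time bins")
    k_true, k_inf = truth.shape[1], inferred.shape[1]
    if k_true > k_inf:
        raise ValueError(
            f"cannot injectively match {k_true} true tags into {k_inf} inferred"
        )
    score = np.zeros((k_true, k_inf))
    for i in range(k_true):
        for j in range(k_inf):
            score[i, j] = normalized_mutual_information(truth[:, i], inferred[:, j])
    rows, cols = linear_sum_assignment(-score)
    perm = {int(i): int(j) for i, j in zip(rows, cols)}
    return FeatureMatch(
        permutation=perm,
        matched_nmi=np.array([score[i, perm[i]] for i in sorted(perm)]),
    )


def rate_reconstruction_error(
    predicted_rates: np.ndarray, empirical_rates: np.ndarray
) -> float:
    """Root-mean-square rate mismatch, normalized by the geometric mean of the
    two average rates: ``sqrt(mean((f_i - f_a)^2)) / sqrt(mean f_i * mean f_a)``.

    Dimensionless (so invariant to rescaling both series); multiply by 100 to
    quote a percentage.
    """
    f_i = np.asarray(predicted_rates, dtype=float)
    f_a = np.asarray(empirical_rates, dtype=float)
    if f_i.shape != f_a.shape:
        raise ValueError("rate series must have equal length")
    denom = f_i.mean() * f_a.mean()
    if denom <= 0:
        raise ValueError("rate series must have positive means")
    return float(np.sqrt(np.mean((f_i - f_a) ** 2)) / np.sqrt(denom))


def predict_rates(
    state: VariationalState,
    t_range: np.ndarray | slice | None,
    unit: int,
    covariates: np.ndarray | None = None,
    n_draws: int = 2000,
    seed: int = 0,
    interval: float = 0.95,
) -> dict[str, np.ndarray]:
    """Posterior mean and credible band of the rate surface for one unit.

    The mean is the analytic ``E[Lambda]``; the band comes from Monte-Carlo
    draws of every factor (gamma gains and Bernoulli tag states from the
    smoothed marginals). Pass the covariate matrix to propagate covariate-gain
    uncertainty; without it the cached mean covariate factor is used, which
    slightly narrows the band when covariates are present.
    """
    if not 0 <= unit < state.n_units:
        raise IndexError(f"unit {unit} out of range")
    T = state.f_factors.shape[1]
    if t_range is None:
        t_idx = np.arange(T)
    elif isinstance(t_range, slice):
        t_idx = np.arange(T)[t_range]
    else:
        t_idx = np.asarray(t_range, dtype=int)

    mean = state.expected_rate()[t_idx, unit]

    rng = np.random.default_rng(seed)
    K, R = state.n_features, state.n_covariates
    lam0 = rng.gamma(state.alpha0[unit], 1.0 / state.beta0[unit], size=n_draws)
    draws = np.tile(lam0[None, :], (t_idx.size, 1))
    for k in range(K):
        lamz = rng.gamma(state.alpha_z[unit, k], 1.0 / state.beta_z[unit, k], n_draws)
        xi1 = state.chain_posteriors[k].xi[t_idx, 1]
        z = rng.random((t_idx.size, n_draws)) < xi1[:, None]
        draws = draws * np.where(z, lamz[None, :], 1.0)
    for r in range(R):
        if covariates is not None:
            lamx = rng.gamma(
                state.alpha_x[unit, r], 1.0 / state.beta_x[unit, r], n_draws
            )
            x_col = np.asarray(covariates, dtype=float)[t_idx, r]
            draws = draws * lamx[None, :] ** x_col[:, None]
        else:
            draws = draws * state.g_factors[r][t_idx, unit][:, None]
    lo = (1.0 - interval) / 2.0
    return {
        "time_bin": t_idx,
        "mean": mean,
        "lower": np.quantile(draws, lo, axis=1),
        "upper": np.quantile(draws, 1.0 - lo, axis=1),
        "draws_mean": draws.mean(axis=1),
    }
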