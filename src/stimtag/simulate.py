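"""Forward simulation of the multiplicative tag model of stimulus-driven spiking.

The generative process: at each stimulus time bin ``t`` a set of ``K``
independent binary Markov chains ("tags") ``z_tk`` and ``R`` observed
covariates ``x_tr`` jointly set each unit's firing rate

    Lambda[t, u] = lam0[u] * prod_k lamz[u, k]**z[t, k] * prod_r lamx[u, r]**x[t, r]

and each observation ``m`` of (time ``t(m)``, unit ``u(m)``) yields a spike
count ``N_m ~ Poisson(Lambda * theta_m)`` with per-observation gain noise
``theta_m ~ Gamma(s_u, s_u)`` (mean 1, so the Poisson rate is unbiased but
overdispersed).

All rates are per time bin; the ``dt`` field exists only to report spikes/s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenerativeParams",
    "GroundTruth",
    "ObservationTable",
    "simulate_markov_chain",
    "compute_rate",
    "simulate_dataset",
    "benchmark_preset",
]


class SimulationError(RuntimeError):
    """Raised when the forward model produces non-finite rates or counts."""


def _check_transition_matrix(A: np.ndarray, name: str = "A") -> np.ndarray:
    A = np.asarray(A, dtype=float)
    if A.shape != (2, 2):
        raise ValueError(f"{name} must be 2x2, got shape {A.shape}")
    if not np.all(np.isfinite(A)) or np.any(A < 0):
        raise ValueError(f"{name} must have finite nonnegative entries")
    if not np.allclose(A.sum(axis=1), 1.0, atol=1e-12):
        raise ValueError(f"rows of {name} must sum to 1 (row-stochastic)")
    return A


@dataclass
class GenerativeParams:
    """Ground-truth parameters of the generative model.

    Attributes
    ----------
    baseline_gains : (U,) positive baseline rates ``lam0`` in counts/bin.
    feature_gains : (U, K) positive multiplicative gains ``lamz``.
    covariate_gains : (U, R) positive multiplicative gains ``lamx``.
    initial_probs : (K,) probability of state 1 at t=0 for each tag chain.
    transition_matrices : (K, 2, 2) row-stochastic; ``A[k, i, j]`` is the
        probability of moving from state ``i`` to state ``j``.
    overdispersion_shape : (U,) shape ``s_u`` of the Gamma(s, s) gain noise.
    n_time_bins : number of stimulus time bins ``T``.
    presentation_counts : (T, U) nonnegative integers ``M_tu``; the number of
        times unit ``u`` saw stimulus bin ``t`` (ragged designs allowed).
    covariate_initial_probs : (R,) on-probability at t=0 for binary Markov
        covariates, or None for no covariates.
    covariate_transition_matrices : (R, 2, 2) row-stochastic, or None.
    dt : bin width in seconds, for reporting rates as spikes/s only.
    """

    baseline_gains: np.ndarray
    feature_gains: np.ndarray
    covariate_gains: np.ndarray
    initial_probs: np.ndarray
    transition_matrices: np.ndarray
    overdispersion_shape: np.ndarray
    n_time_bins: int
    presentation_counts: np.ndarray
    covariate_initial_probs: np.ndarray | None = None
    covariate_transition_matrices: np.ndarray | None = None
    dt: float = 1.0

    def __post_init__(self) -> None:
        self.baseline_gains = np.atleast_1d(np.asarray(self.baseline_gains, dtype=float))
        self.feature_gains = np.atleast_2d(np.asarray(self.feature_gains, dtype=float))
        self.covariate_gains = np.atleast_2d(np.asarray(self.covariate_gains, dtype=float))
        self.initial_probs = np.atleast_1d(np.asarray(self.initial_probs, dtype=float))
        self.overdispersion_shape = np.atleast_1d(
            np.asarray(self.overdispersion_shape, dtype=float)
        )
        self.transition_matrices = np.asarray(self.transition_matrices, dtype=float).reshape(
            -1, 2, 2
        )
        self.presentation_counts = np.asarray(self.presentation_counts, dtype=int)
        self.validate()

    @property
    def n_units(self) -> int:
        return self.baseline_gains.shape[0]

    @property
    def n_features(self) -> int:
        return self.feature_gains.shape[1] if self.feature_gains.size else 0

    @property
    def n_covariates(self) -> int:
        return self.covariate_gains.shape[1] if self.covariate_gains.size else 0

    def validate(self) -> None:
        for name, arr in [
            ("baseline_gains", self.baseline_gains),
            ("feature_gains", self.feature_gains),
            ("covariate_gains", self.covariate_gains),
            ("overdispersion_shape", self.overdispersion_shape),
        ]:
            if arr.size and (not np.all(np.isfinite(arr)) or np.any(arr <= 0)):
                raise ValueError(f"{name} must be strictly positive and finite")
        if np.any(self.initial_probs < 0) or np.any(self.initial_probs > 1):
            raise ValueError("initial_probs must lie in [0, 1]")
        for k in range(self.transition_matrices.shape[0]):
            _check_transition_matrix(self.transition_matrices[k], f"transition_matrices[{k}]")
        if self.covariate_transition_matrices is not None:
            mats = np.asarray(self.covariate_transition_matrices, dtype=float).reshape(-1, 2, 2)
            for r in range(mats.shape[0]):
                _check_transition_matrix(mats[r], f"covariate_transition_matrices[{r}]")
        if self.n_time_bins < 1:
            raise ValueError("n_time_bins must be >= 1")
        if self.presentation_counts.shape != (self.n_time_bins, self.n_units):
            raise ValueError(
                "presentation_counts must have shape (T, U) = "
                f"({self.n_time_bins}, {self.n_units})"
            )
        if np.any(self.presentation_counts < 0):
            raise ValueError("presentation_counts must be nonnegative")


@dataclass
class GroundTruth:
    """Latent quantities drawn during one simulation.

    ``rates`` holds the noise-free rate surface ``Lambda[t, u]`` (counts/bin);
    ``overdispersion_draws`` are the per-observation gains ``theta_m`` aligned
    with the rows of the companion :class:`ObservationTable`.
    """

    latent_states: np.ndarray  # (T, K) binary
    covariates: np.ndarray  # (T, R)
    overdispersion_draws: np.ndarray  # (M,)
    rates: np.ndarray  # (T, U)


@dataclass
class ObservationTable:
    """Long-format spike-count records, one row per observation ``m``.

    Ragged designs are the norm: a (t, u) pair may appear zero or many times
    depending on how often that unit saw that stimulus bin.
    """

    time_bin: np.ndarray  # (M,) int
    unit_id: np.ndarray  # (M,) int
    count: np.ndarray  # (M,) int
    n_time_bins: int
    n_units: int

    def __post_init__(self) -> None:
        self.time_bin = np.asarray(self.time_bin, dtype=int)
        self.unit_id = np.asarray(self.unit_id, dtype=int)
        self.count = np.asarray(self.count, dtype=int)
        if not (self.time_bin.shape == self.unit_id.shape == self.count.shape):
            raise ValueError("time_bin, unit_id and count must have equal length")
        if self.n_observations:
            if self.time_bin.min() < 0 or self.time_bin.max() >= self.n_time_bins:
                raise ValueError("time_bin indices out of range [0, T)")
            if self.unit_id.min() < 0 or self.unit_id.max() >= self.n_units:
                raise ValueError("unit_id indices out of range [0, U)")
            if self.count.min() < 0:
                raise ValueError("counts must be nonnegative")

    @property
    def n_observations(self) -> int:
        return self.count.shape[0]

    def presentation_counts(self) -> np.ndarray:
        """The (T, U) matrix ``M_tu`` implied by the records."""
        M = np.zeros((self.n_time_bins, self.n_units), dtype=int)
        np.add.at(M, (self.time_bin, self.unit_id), 1)
        return M

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "observation_id": np.arange(self.n_observations),
                "time_bin": self.time_bin,
                "unit_id": self.unit_id,
                "count": self.count,
            }
        )

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, n_time_bins: int | None = None, n_units: int | None = None
    ) -> "ObservationTable":
        t = df["time_bin"].to_numpy(dtype=int)
        u = df["unit_id"].to_numpy(dtype=int)
        n = df["count"].to_numpy(dtype=int)
        T = n_time_bins if n_time_bins is not None else (int(t.max()) + 1 if t.size else 0)
        U = n_units if n_units is not None else (int(u.max()) + 1 if u.size else 0)
        return cls(t, u, n, T, U)


def simulate_markov_chain(
    pi: float, A: np.ndarray, T: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Draw a binary Markov chain of length ``T``.

    ``z_0 ~ Bernoulli(pi)`` and ``z_{t+1} | z_t`` follows row ``A[z_t]`` of the
    row-stochastic transition matrix. ``seed`` may be an integer or an already
    constructed Generator (used for sub-streaming inside larger simulations).
    """
    A = _check_transition_matrix(A)
    if not 0.0 <= pi <= 1.0:
        raise ValueError("pi must lie in [0, 1]")
    if T < 1:
        raise ValueError("T must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    z = np.empty(T, dtype=int)
    draws = rng.random(T)
    z[0] = int(draws[0] < pi)
    p_on = A[:, 1]  # probability of moving to state 1 from each state
    for t in range(1, T):
        z[t] = int(draws[t] < p_on[z[t - 1]])
    return z


def compute_rate(
    baseline: float,
    z: np.ndarray | None = None,
    feature_gains: np.ndarray | None = None,
    x: np.ndarray | None = None,
    covariate_gains: np.ndarray | None = None,
) -> float:
    """Rate of one (time, unit) cell: ``lam0 * prod lamz**z * prod lamx**x``.

    Empty feature or covariate sets contribute a factor of 1.
    """
    if baseline <= 0:
        raise ValueError("baseline must be strictly positive")
    rate = float(baseline)
    if z is not None and np.size(z):
        gains = np.asarray(feature_gains, dtype=float)
        if np.any(gains <= 0):
            raise ValueError("feature gains must be strictly positive")
        rate *= float(np.prod(gains ** np.asarray(z, dtype=float)))
    if x is not None and np.size(x):
        gains = np.asarray(covariate_gains, dtype=float)
        if np.any(gains <= 0):
            raise ValueError("covariate gains must be strictly positive")
        rate *= float(np.prod(gains ** np.asarray(x, dtype=float)))
    return rate


def _rate_surface(
    params: GenerativeParams, latent_states: np.ndarray, covariates: np.ndarray
) -> np.ndarray:
    """Vectorized (T, U) version of :func:`compute_rate`."""
    log_rate = np.log(params.baseline_gains)[None, :].repeat(params.n_time_bins, axis=0)
    if params.n_features:
        log_rate += latent_states.astype(float) @ np.log(params.feature_gains).T
    if params.n_covariates:
        log_rate += covariates @ np.log(params.covariate_gains).T
    with np.errstate(over="ignore"):  # overflow reported as SimulationError
        return np.exp(log_rate)


def simulate_dataset(
    params: GenerativeParams, seed: int
) -> tuple[ObservationTable, GroundTruth]:
    """Forward-simulate the full generative model.

    A single master ``seed`` is split into independent sub-streams (one per tag
    chain, one per covariate chain, one for the observation noise) so that e.g.
    the latent trajectories are unchanged when only the noise stream is varied.
    """
    T, U, K, R = params.n_time_bins, params.n_units, params.n_features, params.n_covariates
    ss = np.random.SeedSequence(seed)
    chain_seeds, cov_seeds, obs_seed = ss.spawn(3)

    z = np.zeros((T, K), dtype=int)
    for k, child in enumerate(chain_seeds.spawn(K)):
        z[:, k] = simulate_markov_chain(
            float(params.initial_probs[k]),
            params.transition_matrices[k],
            T,
            np.random.default_rng(child),
        )

    x = np.zeros((T, R), dtype=float)
    if R:
        if params.covariate_initial_probs is None or params.covariate_transition_matrices is None:
            raise ValueError("covariate gains given but no covariate chain parameters")
        cov_A = np.asarray(params.covariate_transition_matrices, dtype=float).reshape(-1, 2, 2)
        for r, child in enumerate(cov_seeds.spawn(R)):
            x[:, r] = simulate_markov_chain(
                float(params.covariate_initial_probs[r]),
                cov_A[r],
                T,
                np.random.default_rng(child),
            )

    rates = _rate_surface(params, z, x)
    if not np.all(np.isfinite(rates)):
        bad = np.argwhere(~np.isfinite(rates))[0]
        raise SimulationError(f"non-finite rate at time_bin={bad[0]}, unit={bad[1]}")

    M = params.presentation_counts
    t_idx = np.repeat(np.arange(T), M.sum(axis=1))
    u_idx = np.concatenate(
        [np.repeat(np.arange(U), M[t]) for t in range(T)]
    ) if M.sum() else np.zeros(0, dtype=int)

    rng = np.random.default_rng(obs_seed)
    s = params.overdispersion_shape[u_idx]
    theta = rng.gamma(shape=s, scale=1.0 / s) if s.size else np.zeros(0)
    mean = rates[t_idx, u_idx] * theta
    if mean.size and not np.all(np.isfinite(mean)):
        j = int(np.argmax(~np.isfinite(mean)))
        raise SimulationError(
            f"non-finite Poisson mean at time_bin={t_idx[j]}, unit={u_idx[j]}"
        )
    counts = rng.poisson(mean) if mean.size else np.zeros(0, dtype=int)

    table = ObservationTable(t_idx, u_idx, counts, T, U)
    truth = GroundTruth(latent_states=z, covariates=x, overdispersion_draws=theta, rates=rates)
    return table, truth


def _persistent_chain(p_stay_off: float, p_stay_on: float) -> np.ndarray:
    return np.array([[p_stay_off, 1.0 - p_stay_off], [1.0 - p_stay_on, p_stay_on]])


def benchmark_preset(
    seed: int,
    scale: float = 1.0,
    unit_scale: float | None = None,
    time_scale: float | None = None,
) -> GenerativeParams:
    """The synthetic validation experiment: 100 units, 10,000 bins of 33.3 ms.

    Baselines are gamma-distributed with population mean 10 spikes/s (shape 2,
    a realistic spread for cortical units); three binary tag chains carry
    Gamma(1, 1) population gains; three binary Markov covariates (persistence
    0.95) carry Gamma(1, 1) gains; every unit sees the stimulus stream once
    (``M_tu = 1``); gain noise has shape ``s_u = 10``. ``scale`` (or the
    separate ``unit_scale`` / ``time_scale``) shrinks U and T proportionally
    while keeping every distribution fixed.
    """
    if unit_scale is None:
        unit_scale = scale
    if time_scale is None:
        time_scale = scale
    U = max(1, round(100 * unit_scale))
    T = max(1, round(10_000 * time_scale))
    K, R = 3, 3
    dt = 0.0333

    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    mean_baseline = 10.0 * dt  # counts per bin
    baseline_shape = 2.0
    baselines = rng.gamma(shape=baseline_shape, scale=mean_baseline / baseline_shape, size=U)
    feature_gains = rng.gamma(shape=1.0, scale=1.0, size=(U, K))
    covariate_gains = rng.gamma(shape=1.0, scale=1.0, size=(U, R))

    # Tag chains dwell ~50 bins off / ~20 bins on; initialized at stationarity.
    A = _persistent_chain(0.98, 0.95)
    stationary_on = A[0, 1] / (A[0, 1] + A[1, 0])
    return GenerativeParams(
        baseline_gains=baselines,
        feature_gains=feature_gains,
        covariate_gains=covariate_gains,
        initial_probs=np.full(K, stationary_on),
        transition_matrices=np.broadcast_to(A, (K, 2, 2)).copy(),
        overdispersion_shape=np.full(U, 10.0),
        n_time_bins=T,
        presentation_counts=np.ones((T, U), dtype=int),
        covariate_initial_probs=np.full(R, 0.5),
        covariate_transition_matrices=np.broadcast_to(
            _persistent_chain(0.95, 0.95), (R, 2, 2)
        ).copy(),
        dt=dt,
    )
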