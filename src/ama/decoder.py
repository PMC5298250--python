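"""Bayes-optimal decoding of the latent variable from filter responses.

The posterior over latent levels given a response vector R is the sum of
within-level stimulus likelihoods normalized by the sum of all stimulus
likelihoods,

    p(X_k | R) = sum_{j in level k} p(R | s_kj) / sum_{ij} p(R | s_ij),

which follows from Bayes' rule with the counts-implied prior
p(X_i) = N_i / N and p(s_ij | X_i) = 1/N_i. All likelihood arithmetic is
done in log space with log-sum-exp reductions: with many levels and
thousands of exemplar stimuli, raw Gaussian densities underflow.

From the posterior come the optimal estimators (MAP for 0-1 cost, the
posterior mean for squared error) and the expected cost of a filter set
over the training set — the quantity filter learning minimizes. By default
the posterior is evaluated at the noiseless mean response of each stimulus
(a standard approximation); a Monte-Carlo mode averaging over noisy
response draws is retained for verification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .data import LabeledStimulusSet
from .response import FilterBank, NoiseModel, sample_noisy_responses

__all__ = [
    "PosteriorDecomposition",
    "CostSpec",
    "likelihood_op_counter",
    "posterior_over_levels",
    "posterior_matrix",
    "map_estimate",
    "mmse_estimate",
    "kl_cost_stimulus",
    "l2_cost_stimulus",
    "expected_zero_one_cost",
    "total_cost",
    "operation_count_full",
    "operation_count_batch",
]

_CHUNK = 1024  # observed-stimulus block size for the pairwise likelihood pass


class _OpCounter:
    """Counts likelihood-evaluation operations, one per
    (observed response, candidate stimulus, level) triple."""

    def __init__(self):
        self.count = 0

    def add(self, n_obs: int, n_candidates: int, n_levels: int) -> None:
        self.count += n_obs * n_candidates * n_levels

    def reset(self) -> None:
        self.count = 0


likelihood_op_counter = _OpCounter()


@dataclass(frozen=True)
class PosteriorDecomposition:
    """Numerator Y (per-level likelihood sums) and denominator Z of the
    posterior, kept in log space for stability."""

    log_Y: np.ndarray
    log_Z: float

    @property
    def Y(self) -> np.ndarray:
        return np.exp(self.log_Y)

    @property
    def Z(self) -> float:
        return float(np.exp(self.log_Z))

    @property
    def posterior(self) -> np.ndarray:
        return np.exp(self.log_Y - self.log_Z)


@dataclass(frozen=True)
class CostSpec:
    """Cost-function choice: 'L0_KL' (0-1 / KL-divergence) or 'L2'."""

    kind: str = "L0_KL"

    def __post_init__(self):
        if self.kind not in ("L0_KL", "L2"):
            raise ValueError("cost kind must be 'L0_KL' or 'L2'")


def _log_likelihood_block(
    obs: np.ndarray, cand_means: np.ndarray, cand_vars: np.ndarray
) -> np.ndarray:
    """(M, C) matrix of log p(R_m | s_c) under diagonal Gaussian noise."""
    ll = np.zeros((obs.shape[0], cand_means.shape[0]))
    for t in range(obs.shape[1]):
        v = cand_vars[:, t]
        diff = obs[:, t, None] - cand_means[None, :, t]
        ll -= 0.5 * (np.log(2 * np.pi * v)[None, :] + diff * diff / v[None, :])
    return ll


def _level_logsumexp(ll: np.ndarray, labels: np.ndarray, n_levels: int):
    """Reduce a (M, C) log-likelihood block to per-level log sums (M, L)."""
    log_y = np.empty((ll.shape[0], n_levels))
    for i in range(n_levels):
        cols = np.nonzero(labels == i)[0]
        log_y[:, i] = logsumexp(ll[:, cols], axis=1)
    return log_y


def _log_posterior_decomposition(
    responses: np.ndarray,
    stimulus_set: LabeledStimulusSet,
    filters: FilterBank,
    noise: NoiseModel,
):
    """log Y (M, L) and log Z (M,) for a batch of observed responses,
    decoded against all stimuli in ``stimulus_set``. Chunked over observed
    responses so large sets stay within memory."""
    responses = np.atleast_2d(np.asarray(responses, dtype=float))
    cand_means = stimulus_set.stimuli @ filters.filters
    cand_vars = noise.variances(cand_means)
    n_levels = stimulus_set.n_levels
    m = responses.shape[0]
    log_y = np.empty((m, n_levels))
    for start in range(0, m, _CHUNK):
        block = responses[start : start + _CHUNK]
        ll = _log_likelihood_block(block, cand_means, cand_vars)
        log_y[start : start + block.shape[0]] = _level_logsumexp(
            ll, stimulus_set.labels, n_levels
        )
    log_z = logsumexp(log_y, axis=1)
    if not np.isfinite(log_z).all():
        raise FloatingPointError(
            "posterior denominator degenerated to -inf; all likelihoods underflowed"
        )
    likelihood_op_counter.add(m, stimulus_set.n_stimuli, n_levels)
    return log_y, log_z


def posterior_over_levels(
    responses: np.ndarray,
    stimulus_set: LabeledStimulusSet,
    filters: FilterBank,
    noise: NoiseModel,
) -> PosteriorDecomposition:
    """Posterior over latent levels for a single response vector."""
    if (stimulus_set.counts == 0).any():
        raise ValueError("every level must contain at least one stimulus")
    log_y, log_z = _log_posterior_decomposition(
        responses, stimulus_set, filters, noise
    )
    return PosteriorDecomposition(log_y[0], float(log_z[0]))


def posterior_matrix(
    responses: np.ndarray,
    stimulus_set: LabeledStimulusSet,
    filters: FilterBank,
    noise: NoiseModel,
) -> np.ndarray:
    """(M, L) posterior matrix for many response vectors at once."""
    if (stimulus_set.counts == 0).any():
        raise ValueError("every level must contain at least one stimulus")
    log_y, log_z = _log_posterior_decomposition(
        responses, stimulus_set, filters, noise
    )
    return np.exp(log_y - log_z[:, None])


def map_estimate(post: PosteriorDecomposition | np.ndarray, levels: np.ndarray):
    """Level value with maximal posterior mass; ties break toward the
    lowest level index (the optimal estimator for 0-1 cost)."""
    p = post.posterior if isinstance(post, PosteriorDecomposition) else np.asarray(post)
    return levels[int(np.argmax(p))]


def mmse_estimate(post: PosteriorDecomposition | np.ndarray, levels: np.ndarray):
    """Posterior mean (the optimal estimator for squared-error cost)."""
    p = post.posterior if isinstance(post, PosteriorDecomposition) else np.asarray(post)
    levels = np.asarray(levels)
    if not np.issubdtype(levels.dtype, np.number):
        raise TypeError("posterior-mean estimation requires numeric level values")
    return float(p @ levels)


def _observed_responses(
    stimulus_set: LabeledStimulusSet,
    filters: FilterBank,
    noise: NoiseModel,
    indices: np.ndarray,
    approx: bool,
    n_draws: int,
    rng_seed: int,
):
    """Observed responses for the indexed stimuli: the noiseless means in
    approx mode, else ``n_draws`` noisy samples per stimulus."""
    means = stimulus_set.stimuli[indices] @ filters.filters
    if approx:
        return means[:, None, :]  # one pseudo-draw
    variances = noise.variances(means)
    tiled_m = np.repeat(means[:, None, :], n_draws, axis=1)
    tiled_v = np.repeat(variances[:, None, :], n_draws, axis=1)
    return sample_noisy_responses(tiled_m, tiled_v, rng_seed)


def _per_stimulus_costs(
    stimulus_set: LabeledStimulusSet,
    filters: FilterBank,
    noise: NoiseModel,
    kind: str,
    approx: bool = True,
    n_draws: int = 100,
    rng_seed: int = 0,
    indices: np.ndarray | None = None,
) -> np.ndarray:
    if indices is None:
        indices = np.arange(stimulus_set.n_stimuli)
    indices = np.atleast_1d(np.asarray(indices, dtype=int))
    obs = _observed_responses(
        stimulus_set, filters, noise, indices, approx, n_draws, rng_seed
    )
    m, draws, q = obs.shape
    post = posterior_matrix(
        obs.reshape(m * draws, q), stimulus_set, filters, noise
    ).reshape(m, draws, stimulus_set.n_levels)
    true_labels = stimulus_set.labels[indices]
    if kind == "L0_KL":
        with np.errstate(divide="ignore"):
            costs = -np.log(post[np.arange(m), :, true_labels])
    elif kind == "L2":
        levels = np.asarray(stimulus_set.levels, dtype=float)
        estimates = post @ levels
        costs = (estimates - levels[true_labels][:, None]) ** 2
    else:  # pragma: no cover
        raise ValueError(kind)
    return costs.mean(axis=1)


def kl_cost_stimulus(
    stimulus_index: int,
    stimulus_set: LabeledStimulusSet,
    filters: FilterBank,
    noise: NoiseModel,
    approx: bool = True,
    n_draws: int = 100,
    rng_seed: int = 0,
) -> float:
    """0-1/KL cost of one stimulus: the negative log posterior probability
    at the correct level, evaluated at the noiseless mean response
    (``approx=True``) or averaged over noisy response draws."""
    return float(
        _per_stimulus_costs(
            stimulus_set, filters, noise, "L0_KL", approx, n_draws, rng_seed,
            indices=np.array([stimulus_index]),
        )[0]
    )


def l2_cost_stimulus(
    stimulus_index: int,
    stimulus_set: LabeledStimulusSet,
    filters: FilterBank,
    noise: NoiseModel,
    approx: bool = True,
    n_draws: int = 100,
    rng_seed: int = 0,
) -> float:
    """Squared error between the posterior-mean estimate and the true
    latent value for one stimulus."""
    return float(
        _per_stimulus_costs(
            stimulus_set, filters, noise, "L2", approx, n_draws, rng_seed,
            indices=np.array([stimulus_index]),
        )[0]
    )


def expected_zero_one_cost(
    stimulus_set: LabeledStimulusSet,
    filters: FilterBank,
    noise: NoiseModel,
) -> float:
    """Diagnostic raw 0-1 expected cost: the fraction of stimuli whose MAP
    estimate (at the noiseless mean response) misses the correct level."""
    means = stimulus_set.stimuli @ filters.filters
    post = posterior_matrix(means, stimulus_set, filters, noise)
    map_idx = np.argmax(post, axis=1)
    return float(np.mean(map_idx != stimulus_set.labels))


def total_cost(
    stimulus_set: LabeledStimulusSet,
    filters: FilterBank,
    noise: NoiseModel,
    cost_spec: CostSpec = CostSpec(),
    approx: bool = True,
    n_draws: int = 100,
    rng_seed: int = 0,
) -> float:
    """Expected cost of a filter set: per-stimulus cost averaged over the
    whole training set — the objective that filter learning minimizes."""
    return float(
        _per_stimulus_costs(
            stimulus_set, filters, noise, cost_spec.kind, approx, n_draws, rng_seed
        ).mean()
    )


def operation_count_full(n: int, n_levels: int) -> int:
    """Likelihood operations to evaluate all N posteriors: N^2 * N_lvl."""
    return n * n * n_levels


def operation_count_batch(n: int, n_batch: int, n_levels: int) -> int:
    """Likelihood operations per SGD pass: N/N_bch batches of
    N_bch^2 * N_lvl each, i.e. N_bch * N_lvl * N."""
    if n_batch > n:
        raise ValueError("batch size cannot exceed the training-set size")
    return n_batch * n_levels * n
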