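"""Analytic gradients of the expected decoding cost with respect to the
encoding filters, for the 0-1/KL and squared-error cost functions.

Writing Y_k and Z for the numerator and denominator of the posterior at the
correct level, the KL-cost gradient over the training set is

    grad C = -(1/N) sum_kl [ grad Y_k / Y_k - grad Z / Z ],

and the squared-error gradient is

    grad C = (2/N) sum_kl (Xhat - X_k) grad Xhat,
    grad Xhat = sum_u X_u (Y_u / Z) [ grad Y_u / Y_u - grad Z / Z ].

Both reduce to gradients of pairwise Gaussian stimulus likelihoods
p(r(k,l) | s_ij). Each likelihood depends on a filter f_t three ways: via
the observed mean response r_kl = f_t . s_kl, via the candidate mean
r_ij = f_t . s_ij, and via the candidate noise variance
sigma^2 = alpha |r_ij| + sigma_0^2 (the scaled additive noise model makes
the variance itself filter-dependent). Writing D = r_kl - r_ij, the
gradient of one log-likelihood factor is

    d log p / d f_t = -(D / sigma^2) s_kl
                      + [ D / sigma^2
                          + alpha sign(r_ij) (D^2 / (2 sigma^4)
                                              - 1 / (2 sigma^2)) ] s_ij.

At r_ij = 0 the subgradient of |r| is taken to be 0 (a measure-zero event;
this keeps the gradient finite). Gradients are evaluated under the
noiseless-mean-response approximation of the cost, and a central
finite-difference oracle is provided for verification.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.special import logsumexp

from .data import LabeledStimulusSet
from .decoder import CostSpec
from .response import FilterBank, NoiseModel

__all__ = [
    "GradientResult",
    "grad_total_cost_kl",
    "grad_total_cost_l2",
    "grad_total_cost",
    "finite_difference_gradient",
    "raw_total_cost",
]


@dataclass(frozen=True)
class GradientResult:
    """Euclidean (unconstrained) gradient, d x q, plus the cost there."""

    grad: np.ndarray
    cost_at_point: float

    def __post_init__(self):
        if not np.isfinite(self.grad).all():
            raise FloatingPointError("gradient contains non-finite entries")


def _posterior_logs_raw(stimulus_set, raw_filters, noise):
    """Pairwise log-likelihoods and posterior pieces for a raw (possibly
    non-unit-norm) filter matrix, with the observed response of each
    stimulus set to its own noiseless mean."""
    s = stimulus_set.stimuli
    means = s @ raw_filters  # (N, q)
    variances = noise.variances(means)
    n = s.shape[0]
    ll = np.zeros((n, n))  # [observed kl, candidate ij]
    for t in range(raw_filters.shape[1]):
        v = variances[:, t]
        diff = means[:, t, None] - means[None, :, t]
        ll -= 0.5 * (np.log(2 * np.pi * v)[None, :] + diff * diff / v[None, :])
    labels = stimulus_set.labels
    n_levels = stimulus_set.n_levels
    log_y = np.empty((n, n_levels))
    for i in range(n_levels):
        log_y[:, i] = logsumexp(ll[:, labels == i], axis=1)
    log_z = logsumexp(log_y, axis=1)
    return means, variances, ll, log_y, log_z


def raw_total_cost(
    stimulus_set: LabeledStimulusSet,
    raw_filters: np.ndarray,
    noise: NoiseModel,
    kind: str = "L0_KL",
) -> float:
    """Approx-mode expected cost as a plain function of a raw filter
    matrix, without the unit-norm requirement. This is the function the
    analytic gradient differentiates and the finite-difference oracle
    probes."""
    _, _, _, log_y, log_z = _posterior_logs_raw(stimulus_set, raw_filters, noise)
    labels = stimulus_set.labels
    n = stimulus_set.n_stimuli
    if kind == "L0_KL":
        return float(-(log_y[np.arange(n), labels] - log_z).mean())
    if kind == "L2":
        post = np.exp(log_y - log_z[:, None])
        levels = np.asarray(stimulus_set.levels, dtype=float)
        est = post @ levels
        return float(((est - levels[labels]) ** 2).mean())
    raise ValueError(kind)


def _pairwise_weighted_grad(stimuli, means, variances, alpha, omega):
    """Accumulate sum_{kl,ij} omega[kl,ij] * d log p(kl|ij) / d f_t into a
    d x q gradient, using the per-filter coefficient decomposition
    a * s_kl + b * s_ij described in the module docstring."""
    d, q = stimuli.shape[1], means.shape[1]
    grad = np.empty((d, q))
    for t in range(q):
        inv_v = 1.0 / variances[:, t]  # candidate ij variance
        diff = means[:, t, None] - means[None, :, t]  # D[kl, ij]
        a = -diff * inv_v[None, :]
        b = diff * inv_v[None, :] + (
            alpha * np.sign(means[:, t])[None, :]
            * (diff * diff * (0.5 * inv_v * inv_v)[None, :]
               - (0.5 * inv_v)[None, :])
        )
        grad[:, t] = stimuli.T @ ((omega * a).sum(axis=1)) + stimuli.T @ (
            (omega * b).sum(axis=0)
        )
    return grad


def grad_total_cost_kl(
    stimulus_set: LabeledStimulusSet,
    filters: FilterBank | np.ndarray,
    noise: NoiseModel,
) -> GradientResult:
    """Gradient of the training-set 0-1/KL cost with respect to all filters."""
    raw = filters.filters if isinstance(filters, FilterBank) else np.asarray(filters)
    s = stimulus_set.stimuli
    labels = stimulus_set.labels
    n = stimulus_set.n_stimuli
    means, variances, ll, log_y, log_z = _posterior_logs_raw(
        stimulus_set, raw, noise
    )
    log_y_correct = log_y[np.arange(n), labels]
    same_level = labels[:, None] == labels[None, :]
    w_y = np.where(same_level, np.exp(ll - log_y_correct[:, None]), 0.0)
    w_z = np.exp(ll - log_z[:, None])
    omega = -(w_y - w_z) / n
    grad = _pairwise_weighted_grad(s, means, variances, noise.fano_factor, omega)
    cost = float(-(log_y_correct - log_z).mean())
    return GradientResult(grad, cost)


def grad_total_cost_l2(
    stimulus_set: LabeledStimulusSet,
    filters: FilterBank | np.ndarray,
    noise: NoiseModel,
) -> GradientResult:
    """Gradient of the training-set squared-error cost with respect to all
    filters (posterior-mean estimator)."""
    raw = filters.filters if isinstance(filters, FilterBank) else np.asarray(filters)
    s = stimulus_set.stimuli
    labels = stimulus_set.labels
    n = stimulus_set.n_stimuli
    levels = np.asarray(stimulus_set.levels, dtype=float)
    means, variances, ll, log_y, log_z = _posterior_logs_raw(
        stimulus_set, raw, noise
    )
    post = np.exp(log_y - log_z[:, None])  # (N, L)
    est = post @ levels
    resid = est - levels[labels]
    # grad Xhat(kl) = sum_ij [p(kl|ij)/Z] (X_{lab(ij)} - Xhat_kl) dlogp/df
    pair_post = np.exp(ll - log_z[:, None])
    omega = (2.0 / n) * resid[:, None] * pair_post * (
        levels[labels][None, :] - est[:, None]
    )
    grad = _pairwise_weighted_grad(s, means, variances, noise.fano_factor, omega)
    cost = float((resid**2).mean())
    return GradientResult(grad, cost)


def grad_total_cost(
    stimulus_set: LabeledStimulusSet,
    filters: FilterBank | np.ndarray,
    noise: NoiseModel,
    cost_spec: CostSpec = CostSpec(),
) -> GradientResult:
    if cost_spec.kind == "L0_KL":
        return grad_total_cost_kl(stimulus_set, filters, noise)
    return grad_total_cost_l2(stimulus_set, filters, noise)


def finite_difference_gradient(
    cost_callable: Callable[[np.ndarray], float],
    filters: FilterBank | np.ndarray,
    step: float = 1e-6,
) -> GradientResult:
    """Central finite differences per filter element: the verification
    oracle for the analytic gradients. Requires 2*d*q cost evaluations,
    which is exactly the overhead the analytic expressions remove."""
    if step <= 0:
        raise ValueError("step must be positive")
    raw = np.array(
        filters.filters if isinstance(filters, FilterBank) else filters,
        dtype=float,
    )
    grad = np.empty_like(raw)
    for idx in np.ndindex(*raw.shape):
        orig = raw[idx]
        raw[idx] = orig + step
        up = cost_callable(raw)
        raw[idx] = orig - step
        down = cost_callable(raw)
        raw[idx] = orig
        grad[idx] = (up - down) / (2 * step)
    return GradientResult(grad, float(cost_callable(raw)))
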