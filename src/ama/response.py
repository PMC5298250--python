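"""Gaussian filter response model with scaled additive (Poisson-like) noise.

A filter's mean response to a contrast-normalized stimulus is the inner
product r = f^T s. The noisy response is R = r + eta with
eta ~ N(0, sigma^2) and

    sigma^2 = alpha * |r| + sigma_0^2,

i.e. the noise variance grows linearly with the magnitude of the mean
response (fano factor ``alpha``, baseline variance ``sigma_0^2``). With
alpha = 0 the model reduces to constant additive noise. Noise is
independent across filters (diagonal covariance).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "FilterBank",
    "NoiseModel",
    "ResponseEnsemble",
    "normalize_stimulus",
    "mean_responses",
    "response_variances",
    "sample_noisy_responses",
    "log_likelihood",
]

_NORM_TOL = 1e-10

# Defaults consistent with response properties in early visual cortex.
DEFAULT_FANO_FACTOR = 1.36
DEFAULT_BASELINE_VAR = 0.23


@dataclass(frozen=True)
class FilterBank:
    """q unit-norm encoding filters over d stimulus dimensions.

    ``filters`` is stored d x q, one filter per column, every column with
    unit Euclidean norm.
    """

    filters: np.ndarray

    def __post_init__(self):
        filters = np.atleast_2d(np.asarray(self.filters, dtype=float))
        object.__setattr__(self, "filters", filters)
        norms = np.linalg.norm(filters, axis=0)
        if np.any(np.abs(norms - 1.0) > _NORM_TOL):
            t = int(np.argmax(np.abs(norms - 1.0)))
            raise ValueError(
                f"filter column {t} is not unit norm (norm {norms[t]:.17g})"
            )

    @property
    def dim(self) -> int:
        return self.filters.shape[0]

    @property
    def q(self) -> int:
        return self.filters.shape[1]

    def column(self, t: int) -> np.ndarray:
        return self.filters[:, t]

    @classmethod
    def random(cls, d: int, q: int, rng: np.random.Generator) -> "FilterBank":
        """Independent standard-normal vectors, normalized to unit norm."""
        f = rng.standard_normal((d, q))
        f /= np.linalg.norm(f, axis=0, keepdims=True)
        return cls(f)

    @classmethod
    def from_columns(cls, *cols: np.ndarray) -> "FilterBank":
        return cls(np.column_stack(cols))


@dataclass(frozen=True)
class NoiseModel:
    """Scaled additive response noise: variance = alpha*|r| + sigma_0^2."""

    fano_factor: float = DEFAULT_FANO_FACTOR
    baseline_var: float = DEFAULT_BASELINE_VAR

    def __post_init__(self):
        if self.fano_factor < 0:
            raise ValueError("fano_factor must be >= 0")
        if self.baseline_var <= 0:
            raise ValueError("baseline_var must be > 0")

    @property
    def mode(self) -> str:
        return "constant_additive" if self.fano_factor == 0 else "scaled_additive"

    def variances(self, means: np.ndarray) -> np.ndarray:
        return self.fano_factor * np.abs(means) + self.baseline_var

    def scaled(self, factor: float) -> "NoiseModel":
        """Noise model with overall power scaled by ``factor``."""
        return NoiseModel(self.fano_factor * factor, self.baseline_var * factor)


@dataclass(frozen=True)
class ResponseEnsemble:
    """Mean responses, their noise variances, and optional noisy samples."""

    means: np.ndarray
    variances: np.ndarray
    samples: np.ndarray | None = None

    def __post_init__(self):
        if self.means.shape != self.variances.shape:
            raise ValueError("means and variances must have the same shape")
        if self.samples is not None and self.samples.shape != self.means.shape:
            raise ValueError("samples must have the same shape as means")


def normalize_stimulus(x: np.ndarray) -> np.ndarray:
    """Contrast-normalize a raw intensity vector: zero mean, unit norm."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("stimulus must be a 1-d vector with >= 2 elements")
    centered = x - x.mean()
    norm = np.linalg.norm(centered)
    if norm == 0:
        raise ValueError("zero-contrast stimulus (constant intensity vector)")
    return centered / norm


def mean_responses(filters: FilterBank, stimuli) -> np.ndarray:
    """Mean responses r[i, t] = f_t . s_i for every stimulus and filter."""
    s = stimuli.stimuli if hasattr(stimuli, "stimuli") else np.asarray(stimuli)
    if s.shape[-1] != filters.dim:
        raise ValueError(
            f"stimulus dimension {s.shape[-1]} != filter dimension {filters.dim}"
        )
    return s @ filters.filters


def response_variances(means: np.ndarray, noise: NoiseModel) -> np.ndarray:
    return noise.variances(np.asarray(means, dtype=float))


def sample_noisy_responses(
    means: np.ndarray, variances: np.ndarray, rng_seed: int
) -> np.ndarray:
    """Independent Gaussian samples R = r + eta, deterministic given seed."""
    means = np.asarray(means, dtype=float)
    variances = np.asarray(variances, dtype=float)
    if (variances <= 0).any():
        raise ValueError("variances must be positive")
    rng = np.random.default_rng(rng_seed)
    return means + rng.standard_normal(means.shape) * np.sqrt(variances)


def log_likelihood(
    responses: np.ndarray, stimulus_means: np.ndarray, stimulus_vars: np.ndarray
) -> float:
    """log p(R | s): product of q independent univariate Gaussian densities."""
    responses = np.asarray(responses, dtype=float)
    stimulus_vars = np.asarray(stimulus_vars, dtype=float)
    if (stimulus_vars <= 0).any():
        raise ValueError("variances must be positive")
    return float(
        stats.norm.logpdf(
            responses, loc=stimulus_means, scale=np.sqrt(stimulus_vars)
        ).sum()
    )
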