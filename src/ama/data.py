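"""Labeled training sets for task-specific filter learning.

A training set is a matrix of contrast-normalized stimulus vectors, each
labeled with one of a small number of discrete latent-variable levels
(e.g. binocular disparities in arcmin). The relative number of stimuli per
level implicitly defines the prior over the latent variable.

This module provides the container type, a synthetic "energy-like" task
generator in which the latent variable is carried by the covariance of
quadrature filter-pair responses rather than by response means, prior
manipulation by random culling, and a PCA filter baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.decomposition import PCA

__all__ = [
    "LabeledStimulusSet",
    "EnergyTaskConfig",
    "generate_energy_task_set",
    "apply_prior_by_culling",
    "pca_baseline_filters",
]

_NORM_TOL = 1e-10


@dataclass(frozen=True)
class LabeledStimulusSet:
    """Contrast-normalized stimuli grouped into latent-variable levels.

    Parameters
    ----------
    stimuli : (N, d) ndarray
        One stimulus per row; every row has zero mean and unit Euclidean
        norm (contrast normalization).
    labels : (N,) int ndarray
        Level index of each stimulus, in ``range(n_levels)``.
    levels : (n_levels,) ndarray
        Latent-variable value of each level, in task units.
    """

    stimuli: np.ndarray
    labels: np.ndarray
    levels: np.ndarray

    def __post_init__(self):
        stimuli = np.asarray(self.stimuli, dtype=float)
        labels = np.asarray(self.labels, dtype=int)
        levels = np.asarray(self.levels)
        object.__setattr__(self, "stimuli", stimuli)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "levels", levels)
        if stimuli.ndim != 2:
            raise ValueError("stimuli must be a 2-d array (N, d)")
        if labels.shape != (stimuli.shape[0],):
            raise ValueError("labels must have one entry per stimulus")
        if levels.ndim != 1 or levels.size < 1:
            raise ValueError("levels must be a non-empty 1-d array")
        if labels.min(initial=0) < 0 or labels.max(initial=0) >= levels.size:
            raise ValueError("labels contain an invalid level index")
        means = stimuli.mean(axis=1)
        norms = np.linalg.norm(stimuli, axis=1)
        bad = np.nonzero(
            (np.abs(means) > _NORM_TOL) | (np.abs(norms - 1.0) > _NORM_TOL)
        )[0]
        if bad.size:
            raise ValueError(
                f"stimulus row {bad[0]} is not contrast normalized "
                f"(mean {means[bad[0]]:.3e}, norm {norms[bad[0]]:.17g})"
            )

    @property
    def n_stimuli(self) -> int:
        return self.stimuli.shape[0]

    @property
    def dim(self) -> int:
        return self.stimuli.shape[1]

    @property
    def n_levels(self) -> int:
        return self.levels.size

    @property
    def counts(self) -> np.ndarray:
        """Per-level stimulus counts N_i."""
        return np.bincount(self.labels, minlength=self.n_levels)

    @property
    def prior(self) -> np.ndarray:
        """Implied prior p(X_i) = N_i / N."""
        return self.counts / self.n_stimuli

    def level_indices(self, i: int) -> np.ndarray:
        return np.nonzero(self.labels == i)[0]

    def subset(self, indices: np.ndarray) -> "LabeledStimulusSet":
        """Subset by stimulus index; stimulus vectors are untouched."""
        indices = np.asarray(indices, dtype=int)
        return LabeledStimulusSet(
            self.stimuli[indices], self.labels[indices], self.levels
        )


@dataclass(frozen=True)
class EnergyTaskConfig:
    """Configuration of the synthetic disparity-like energy task.

    Each stimulus is a pair of half-windows (e.g. left/right retinal
    signals). The first half is a Hann-windowed sinusoid with random phase
    and amplitude; the second half carries the same sinusoid with its phase
    shifted by ``shift_gain * X_i``, so the latent level is expressed only
    in the *relative* phase — information carried by the covariance of
    quadrature filter-pair responses, not by their means.

    Parameters
    ----------
    d : even int
        Stimulus dimensionality (two concatenated half-windows of d/2).
    n_levels, level_range, n_per_level
        Latent levels are ``n_levels`` equally spaced values over
        ``level_range``; ``n_per_level`` stimuli are drawn per level.
    carrier_freq : float
        Carrier frequency in cycles per half-window.
    shift_gain : float
        Radians of phase shift per latent unit. The default 0.08 rad/unit
        keeps the extreme levels of the default +/-15 range inside
        (-pi, pi), so every level maps to a distinct relative phase.
    pixel_noise_sd : float
        Standard deviation of i.i.d. Gaussian pixel noise added to both
        half-windows before normalization.
    """

    d: int = 16
    n_levels: int = 19
    level_range: tuple[float, float] = (-15.0, 15.0)
    n_per_level: int = 400
    carrier_freq: float = 2.0
    shift_gain: float = 0.08
    pixel_noise_sd: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.d % 2 != 0 or self.d < 4:
            raise ValueError("d must be an even integer >= 4")
        if self.n_levels < 2:
            raise ValueError("n_levels must be >= 2")
        if self.n_per_level < 1:
            raise ValueError("n_per_level must be >= 1")
        if self.pixel_noise_sd < 0:
            raise ValueError("pixel_noise_sd must be >= 0")

    @property
    def levels(self) -> np.ndarray:
        return np.linspace(*self.level_range, self.n_levels)


def _contrast_normalize_rows(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean-subtract and unit-normalize each row; flag zero-contrast rows."""
    x = x - x.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(x, axis=1)
    ok = norms > 0
    x[ok] /= norms[ok, None]
    return x, ok


def generate_energy_task_set(config: EnergyTaskConfig) -> LabeledStimulusSet:
    """Generate a labeled set for the synthetic energy task.

    Returns ``n_levels * n_per_level`` contrast-normalized stimuli.
    Amplitudes are log-uniform over one decade (10**-0.5 to 10**0.5),
    phases uniform on [0, 2*pi). Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    h = config.d // 2
    t = np.arange(h) / h
    window = np.hanning(h)
    levels = config.levels
    n_total = config.n_levels * config.n_per_level

    stimuli = np.empty((n_total, config.d))
    labels = np.repeat(np.arange(config.n_levels), config.n_per_level)

    def draw(n: int, level_value: float) -> np.ndarray:
        phase = rng.uniform(0.0, 2 * np.pi, size=n)[:, None]
        amp = 10.0 ** rng.uniform(-0.5, 0.5, size=n)[:, None]
        arg = 2 * np.pi * config.carrier_freq * t[None, :]
        shift = config.shift_gain * level_value
        left = amp * window * np.cos(arg + phase)
        right = amp * window * np.cos(arg + phase + shift)
        raw = np.concatenate([left, right], axis=1)
        raw += rng.normal(0.0, config.pixel_noise_sd, size=raw.shape)
        return raw

    row = 0
    for i, x_val in enumerate(levels):
        raw, ok = _contrast_normalize_rows(draw(config.n_per_level, x_val))
        # Zero vectors after mean subtraction are a measure-zero pathology of
        # the noise draw; regenerate them, with a hard cap to surface a
        # recurring degeneracy instead of looping forever.
        attempts = 0
        while not ok.all():
            attempts += 1
            if attempts > 100:
                raise RuntimeError(
                    "recurrent zero-contrast draws while generating stimuli"
                )
            n_bad = int((~ok).sum())
            redo, redo_ok = _contrast_normalize_rows(draw(n_bad, x_val))
            raw[~ok] = redo
            ok_idx = np.nonzero(~ok)[0]
            ok[ok_idx] = redo_ok
        stimuli[row : row + config.n_per_level] = raw
        row += config.n_per_level

    return LabeledStimulusSet(stimuli, labels, levels)


def apply_prior_by_culling(
    stimulus_set: LabeledStimulusSet,
    target_weights: np.ndarray,
    rng_seed: int,
) -> LabeledStimulusSet:
    """Impose a prior by randomly culling stimuli from each level.

    The returned subset has per-level counts proportional to
    ``target_weights`` at the largest feasible scaling (rounded to nearest
    integer, at least one stimulus per level with nonzero weight). Stimuli
    are removed uniformly at random within each level; the surviving
    stimulus vectors are unchanged. Levels with zero weight are dropped and
    the remaining levels re-indexed, because the decoder requires every
    represented level to contain at least one stimulus.
    """
    w = np.asarray(target_weights, dtype=float)
    if w.shape != (stimulus_set.n_levels,):
        raise ValueError("target_weights must have one entry per level")
    if (w < 0).any():
        raise ValueError("target_weights must be non-negative")
    if not (w > 0).any():
        raise ValueError("target_weights must not be all zero")
    counts = stimulus_set.counts
    active = w > 0
    if (counts[active] == 0).any():
        raise ValueError("a level with nonzero weight has zero stimuli")

    # Largest scaling c such that round(c * w_i) <= N_i for every active level.
    c = np.min(counts[active] / w[active])
    desired = np.zeros_like(counts)
    desired[active] = np.clip(
        np.rint(c * w[active]).astype(int), 1, counts[active]
    )

    rng = np.random.default_rng(rng_seed)
    keep: list[np.ndarray] = []
    for i in range(stimulus_set.n_levels):
        idx = stimulus_set.level_indices(i)
        if desired[i] == idx.size:
            keep.append(idx)
        elif desired[i] > 0:
            keep.append(np.sort(rng.choice(idx, size=desired[i], replace=False)))
    kept = np.concatenate(keep)
    kept.sort()

    if active.all():
        return stimulus_set.subset(kept)
    # Drop zero-weight levels and re-index the labels.
    old_to_new = np.cumsum(active) - 1
    return LabeledStimulusSet(
        stimulus_set.stimuli[kept],
        old_to_new[stimulus_set.labels[kept]],
        stimulus_set.levels[active],
    )


def pca_baseline_filters(stimulus_set: LabeledStimulusSet, q: int):
    """Top-q principal components of the stimuli, ignoring labels.

    The task-agnostic baseline: directions of maximal stimulus variance.
    Each component is unit norm with a deterministic sign convention (the
    largest-magnitude element is positive). Raises if ``q`` exceeds the
    rank of the stimulus covariance.
    """
    from .response import FilterBank

    if not 1 <= q <= stimulus_set.dim:
        raise ValueError("q must satisfy 1 <= q <= d")
    pca = PCA(n_components=min(stimulus_set.dim, stimulus_set.n_stimuli),
              svd_solver="full")
    pca.fit(stimulus_set.stimuli)
    sv = pca.singular_values_
    rank = int((sv > sv[0] * 1e-10).sum()) if sv.size else 0
    if q > rank:
        raise np.linalg.LinAlgError(
            f"stimulus covariance has rank {rank} < q = {q}"
        )
    comps = pca.components_[:q]  # (q, d), unit rows, eigenvalue-ordered
    filters = comps.T.copy()
    for t in range(q):
        j = np.argmax(np.abs(filters[:, t]))
        if filters[j, t] < 0:
            filters[:, t] = -filters[:, t]
    return FilterBank(filters)
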