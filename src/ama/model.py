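"""Model/Results interface for accuracy-maximization filter learning.

``AMA`` bundles a labeled training set, a response-noise model, and a cost
function; ``fit`` learns the unit-norm encoding filters that minimize the
expected decoding cost and returns an ``AMAResults`` carrying the filters,
the training trace, diagnostics, and analysis methods (posterior decoding,
estimation, rotation landscapes, uncertainty ellipses, simulation).

Example
-------
>>> from ama import AMA, EnergyTaskConfig, generate_energy_task_set
>>> training = generate_energy_task_set(EnergyTaskConfig(n_levels=5,
...     n_per_level=100, seed=7))
>>> res = AMA.from_stimulus_set(training).fit(q=2, seed=7, max_iters=200)
>>> print(res.summary())
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from . import decoder, subspace
from .data import LabeledStimulusSet, pca_baseline_filters
from .decoder import CostSpec
from .optimize import SGDConfig, TrainingTrace, run_full_gd, run_sgd
from .response import FilterBank, NoiseModel

__all__ = ["AMA", "AMAResults"]


class AMA:
    """Accuracy Maximization Analysis model.

    Parameters
    ----------
    stimuli : (N, d) array
        Contrast-normalized stimulus vectors (zero mean, unit norm rows).
    labels : (N,) int array
        Latent-level index of each stimulus.
    levels : (n_levels,) array
        Latent-variable value of each level.
    noise : NoiseModel
        Scaled additive response noise (defaults: fano factor 1.36,
        baseline variance 0.23).
    cost : str or CostSpec
        'L0_KL' (default) or 'L2'.
    """

    def __init__(self, stimuli, labels, levels, noise: NoiseModel | None = None,
                 cost: str | CostSpec = "L0_KL"):
        self.data = LabeledStimulusSet(
            np.asarray(stimuli), np.asarray(labels), np.asarray(levels)
        )
        self.noise = noise if noise is not None else NoiseModel()
        self.cost = cost if isinstance(cost, CostSpec) else CostSpec(cost)

    @classmethod
    def from_stimulus_set(cls, stimulus_set: LabeledStimulusSet,
                          noise: NoiseModel | None = None,
                          cost: str | CostSpec = "L0_KL") -> "AMA":
        return cls(stimulus_set.stimuli, stimulus_set.labels,
                   stimulus_set.levels, noise=noise, cost=cost)

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, label_col: str = "label",
                       noise: NoiseModel | None = None,
                       cost: str | CostSpec = "L0_KL") -> "AMA":
        """Build the model from a DataFrame whose ``label_col`` holds the
        latent value of each row and whose remaining columns are the
        stimulus dimensions."""
        values = frame[label_col].to_numpy()
        levels, labels = np.unique(values, return_inverse=True)
        stimuli = frame.drop(columns=[label_col]).to_numpy(dtype=float)
        return cls(stimuli, labels, levels, noise=noise, cost=cost)

    # -- fitting ---------------------------------------------------------

    def fit(self, q: int = 2, method: str = "sgd",
            batch_stimuli_per_level: int | None = 30,
            step_size_init: float = 0.05, step_decay: float = 0.01,
            max_iters: int = 300, n_restarts: int = 1, seed: int = 0,
            learn_mode: str = "joint",
            init_filters: FilterBank | None = None,
            track_pass_cost: bool = False) -> "AMAResults":
        """Learn q filters by constrained (stochastic) gradient descent.

        ``method='sgd'`` uses stratified mini-batches of
        ``batch_stimuli_per_level`` stimuli per latent level;
        ``method='full'`` descends on the whole training set each
        iteration.
        """
        config = SGDConfig(
            q=q, batch_stimuli_per_level=batch_stimuli_per_level,
            step_size_init=step_size_init, step_decay=step_decay,
            max_iters=max_iters, n_restarts=n_restarts, seed=seed,
            cost=self.cost, learn_mode=learn_mode,
        )
        if method == "full":
            trace = run_full_gd(self.data, self.noise, config,
                                init_filters=init_filters)
        elif method == "sgd":
            trace = run_sgd(self.data, self.noise, config,
                            init_filters=init_filters,
                            track_pass_cost=track_pass_cost)
        else:
            raise ValueError("method must be 'sgd' or 'full'")
        return AMAResults(self, trace, config)

    # -- evaluation of arbitrary filters ---------------------------------

    def total_cost(self, filters: FilterBank, **kwargs) -> float:
        return decoder.total_cost(self.data, filters, self.noise,
                                  self.cost, **kwargs)

    def pca_filters(self, q: int = 2) -> FilterBank:
        """Task-agnostic PCA baseline on the same stimuli."""
        return pca_baseline_filters(self.data, q)


class AMAResults:
    """Learned filters plus diagnostics and downstream analyses."""

    def __init__(self, model: AMA, trace: TrainingTrace, config: SGDConfig):
        self.model = model
        self.trace = trace
        self.config = config
        self.filters: FilterBank = trace.final_filters
        self.cost: float = trace.final_cost

    # -- basic quantities -------------------------------------------------

    @property
    def params(self) -> np.ndarray:
        """Filter matrix, d x q."""
        return self.filters.filters

    @property
    def filter_correlations(self) -> np.ndarray:
        """Pairwise cosine similarities f_i . f_j of the learned filters."""
        f = self.filters.filters
        return f.T @ f

    @property
    def accepted_fraction(self) -> float:
        return float(self.trace.accepted.mean()) if self.trace.n_iterations else 0.0

    def posterior(self, responses: np.ndarray) -> np.ndarray:
        """Posterior over latent levels for one or more response vectors."""
        return decoder.posterior_matrix(
            responses, self.model.data, self.filters, self.model.noise
        )

    def estimate(self, responses: np.ndarray) -> np.ndarray:
        """Optimal estimate per response: MAP under the 0-1/KL cost, the
        posterior mean under the squared-error cost."""
        post = self.posterior(responses)
        levels = np.asarray(self.model.data.levels, dtype=float)
        if self.model.cost.kind == "L0_KL":
            return levels[np.argmax(post, axis=1)]
        return post @ levels

    def simulate_responses(self, rng_seed: int = 0):
        """Noisy filter responses to every training stimulus."""
        from .response import sample_noisy_responses

        means = self.model.data.stimuli @ self.filters.filters
        variances = self.model.noise.variances(means)
        return sample_noisy_responses(means, variances, rng_seed)

    # -- subspace analyses -------------------------------------------------

    def subspace_frame(self, i: int = 0, j: int = 1) -> subspace.SubspaceFrame:
        return subspace.build_frame(self.filters.column(i), self.filters.column(j))

    def rotation_landscape(self, theta_grid=None, delta_grid=None,
                           noise: NoiseModel | None = None,
                           i: int = 0, j: int = 1):
        """Cost landscape from rotating filters i and j within their span
        (defaults: 0-355 degrees in 5-degree steps, the pair's own angle
        difference)."""
        if theta_grid is None:
            theta_grid = np.arange(0.0, 360.0, 5.0)
        return subspace.rotation_cost_landscape(
            self.model.data, self.subspace_frame(i, j), theta_grid,
            noise if noise is not None else self.model.noise,
            self.model.cost, delta_grid=delta_grid,
        )

    def uncertainty_ellipse(self, stimulus_index: int, i: int = 0, j: int = 1):
        """Uncertainty ellipse of one stimulus in the orthonormal basis of
        the (i, j) filter subspace."""
        frame = self.subspace_frame(i, j)
        f = np.column_stack([self.filters.column(i), self.filters.column(j)])
        r = self.model.data.stimuli[stimulus_index] @ f
        return subspace.uncertainty_ellipse(
            frame, r, self.model.noise.variances(r)
        )

    # -- reporting ---------------------------------------------------------

    def summary(self) -> str:
        d = self.model.data
        rho = self.filter_correlations
        off = rho[np.triu_indices(self.filters.q, k=1)]
        lines = [
            "Accuracy Maximization Analysis Results",
            "=" * 54,
            f"{'Stimuli (N)':<32}{d.n_stimuli:>22}",
            f"{'Stimulus dimension (d)':<32}{d.dim:>22}",
            f"{'Latent levels (N_lvl)':<32}{d.n_levels:>22}",
            f"{'Filters (q)':<32}{self.filters.q:>22}",
            f"{'Cost function':<32}{self.model.cost.kind:>22}",
            f"{'Noise fano factor (alpha)':<32}{self.model.noise.fano_factor:>22.4g}",
            f"{'Noise baseline variance':<32}{self.model.noise.baseline_var:>22.4g}",
            f"{'Batch (stimuli/level)':<32}"
            f"{str(self.config.batch_stimuli_per_level):>22}",
            f"{'Iterations':<32}{self.trace.n_iterations:>22}",
            f"{'Accepted steps':<32}{self.accepted_fraction:>22.1%}",
            f"{'Initial cost':<32}{self.trace.initial_cost:>22.6g}",
            f"{'Final cost':<32}{self.cost:>22.6g}",
        ]
        if off.size:
            lines.append(
                f"{'Filter cosine similarity rho':<32}"
                f"{np.array2string(off, precision=3):>22}"
            )
        lines.append("=" * 54)
        return "\n".join(lines)

    def plot_trace(self, ax=None):
        """Batch cost per iteration (and full-set cost per pass if traced)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.trace.batch_costs, color="k", lw=0.8, label="batch cost")
        if self.trace.pass_costs is not None:
            x = np.linspace(0, self.trace.n_iterations,
                            len(self.trace.pass_costs))
            ax.plot(x, self.trace.pass_costs, color="r", lw=1.5,
                    label="full-set cost")
        ax.set_xlabel("iteration")
        ax.set_ylabel("cost")
        ax.legend()
        return ax
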