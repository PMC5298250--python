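"""Constrained filter learning on the unit hypersphere.

Filters are constrained to unit norm, so descent steps must stay on the
hypersphere: the Euclidean cost gradient is projected onto the tangent
plane at the current filter,

    f_grd = f_euclid - (f . f_euclid) f,

a unit-length step is taken along -f_grd, and the filter is renormalized
(the simplest retraction; the projected step leaves the sphere only at
second order). Stochastic gradient descent draws a stratified batch of
stimuli per iteration (a fixed number per latent level), computes cost and
gradient on the batch alone, and keeps the step only if the same batch's
cost decreased — random batches vary in difficulty, so an unconditional
step could be fooled by an easy batch. The step size decays by a fixed
fraction (default 1%) per iteration, and the loop quits after a set number
of iterations. Random restarts guard against non-global local minima of
the non-convex cost. With the batch equal to the full training set the
same loop performs deterministic full-batch descent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .data import LabeledStimulusSet
from .decoder import (
    CostSpec,
    likelihood_op_counter,
    operation_count_batch,
    operation_count_full,
)
from .gradients import grad_total_cost, raw_total_cost
from .response import FilterBank, NoiseModel

__all__ = [
    "SGDConfig",
    "TrainingTrace",
    "project_gradient_to_tangent",
    "sgd_step",
    "sample_batch",
    "run_sgd",
    "run_full_gd",
    "count_operations_per_pass",
]

_NORM_TOL = 1e-10
_TANGENT_TOL = 1e-12


@dataclass(frozen=True)
class SGDConfig:
    """Optimizer configuration.

    ``batch_stimuli_per_level=None`` means full-batch descent. The default
    initial step size 0.05 is a tunable; the 1% per-iteration decay and the
    fixed iteration budget are the stopping rule.
    """

    q: int = 2
    batch_stimuli_per_level: int | None = 30
    step_size_init: float = 0.05
    step_decay: float = 0.01
    max_iters: int = 300
    n_restarts: int = 1
    seed: int = 0
    cost: CostSpec = field(default_factory=CostSpec)
    learn_mode: str = "joint"
    grad_tol: float | None = None  # optional tangent-norm early stop

    def __post_init__(self):
        if self.q < 1:
            raise ValueError("q must be >= 1")
        if not 0 < self.step_decay < 1:
            raise ValueError("step_decay must lie in (0, 1)")
        if self.batch_stimuli_per_level is not None and self.batch_stimuli_per_level < 1:
            raise ValueError("batch_stimuli_per_level must be >= 1")
        if self.step_size_init <= 0:
            raise ValueError("step_size_init must be > 0")
        if self.learn_mode not in ("joint", "sequential_pairs"):
            raise ValueError("learn_mode must be 'joint' or 'sequential_pairs'")


@dataclass
class TrainingTrace:
    """Per-iteration record of one training run (best restart)."""

    batch_costs: np.ndarray  # cost on the batch before the step
    post_step_costs: np.ndarray  # cost on the same batch after the step
    accepted: np.ndarray  # bool, step kept
    step_sizes: np.ndarray
    final_filters: FilterBank = None
    final_cost: float = np.nan  # full-training-set cost of final filters
    initial_cost: float = np.nan
    pass_costs: np.ndarray | None = None  # full-set cost after each pass
    restart_costs: np.ndarray | None = None
    max_norm_deviation: float = 0.0
    max_tangent_deviation: float = 0.0

    @property
    def n_iterations(self) -> int:
        return len(self.batch_costs)


def project_gradient_to_tangent(f: np.ndarray, grad_euclid: np.ndarray) -> np.ndarray:
    """Project a Euclidean gradient onto the tangent plane of the unit
    hypersphere at f (applied twice to cancel rounding in f . f_grd)."""
    g = grad_euclid - (f @ grad_euclid) * f
    return g - (f @ g) * f


def sgd_step(f: np.ndarray, f_grd: np.ndarray, step_size: float) -> np.ndarray:
    """Unit-length step along the negative tangent gradient, then
    renormalization back onto the sphere. A zero gradient is a converged
    direction: the filter is returned unchanged."""
    norm = np.linalg.norm(f_grd)
    if norm == 0 or step_size == 0:
        return f
    new = f - step_size * f_grd / norm
    return new / np.linalg.norm(new)


def sample_batch(
    stimulus_set: LabeledStimulusSet,
    per_level: int,
    rng: np.random.Generator,
) -> LabeledStimulusSet:
    """Stratified batch: ``per_level`` stimuli drawn uniformly without
    replacement from every latent level."""
    counts = stimulus_set.counts
    if per_level > counts.min():
        raise ValueError(
            f"per_level={per_level} exceeds the smallest level count {counts.min()}"
        )
    idx = np.concatenate(
        [
            rng.choice(stimulus_set.level_indices(i), size=per_level, replace=False)
            for i in range(stimulus_set.n_levels)
        ]
    )
    return stimulus_set.subset(idx)


def _pass_batches(stimulus_set, per_level, rng):
    """Index arrays for one pass: each level's stimuli are shuffled and
    chunked so the batches partition (as closely as feasible) the set."""
    counts = stimulus_set.counts
    if per_level is None:
        yield np.arange(stimulus_set.n_stimuli)
        return
    n_batches = int(counts.min() // per_level)
    if n_batches < 1:
        raise ValueError(
            f"per_level={per_level} exceeds the smallest level count {counts.min()}"
        )
    if n_batches == 1 and per_level * stimulus_set.n_levels == stimulus_set.n_stimuli:
        # The single batch is the whole set: reduce exactly to full-batch
        # descent (canonical order, no randomness consumed).
        yield np.arange(stimulus_set.n_stimuli)
        return
    shuffled = [
        rng.permutation(stimulus_set.level_indices(i))
        for i in range(stimulus_set.n_levels)
    ]
    for b in range(n_batches):
        yield np.concatenate(
            [lev[b * per_level : (b + 1) * per_level] for lev in shuffled]
        )


def _check_geometry(trace: TrainingTrace, filters: np.ndarray, tangent_dots):
    norm_dev = float(np.max(np.abs(np.linalg.norm(filters, axis=0) - 1.0)))
    tan_dev = float(np.max(np.abs(tangent_dots))) if len(tangent_dots) else 0.0
    trace.max_norm_deviation = max(trace.max_norm_deviation, norm_dev)
    trace.max_tangent_deviation = max(trace.max_tangent_deviation, tan_dev)
    if norm_dev > _NORM_TOL:
        raise FloatingPointError(f"unit-norm constraint violated: {norm_dev:.3e}")
    if tan_dev > _TANGENT_TOL:
        raise FloatingPointError(f"tangent orthogonality violated: {tan_dev:.3e}")


def _descend(stimulus_set, noise, config, init_filters, rng, active_cols, trace,
             track_pass_cost):
    """Core accept/reject descent loop; updates only ``active_cols``."""
    filters = init_filters.copy()
    eps = config.step_size_init
    per_level = config.batch_stimuli_per_level
    batch_iter = iter(())
    pass_costs = []
    it = 0
    while it < config.max_iters:
        try:
            batch_idx = next(batch_iter)
        except StopIteration:
            if track_pass_cost and it > 0:
                pass_costs.append(
                    raw_total_cost(stimulus_set, filters, noise, config.cost.kind)
                )
            batch_iter = _pass_batches(stimulus_set, per_level, rng)
            batch_idx = next(batch_iter)
        batch = stimulus_set.subset(batch_idx)

        result = grad_total_cost(batch, filters, noise, config.cost)
        pre_cost = result.cost_at_point

        candidate = filters.copy()
        dots = []
        converged = True
        for t in active_cols:
            f_grd = project_gradient_to_tangent(filters[:, t], result.grad[:, t])
            dots.append(filters[:, t] @ f_grd)
            if np.linalg.norm(f_grd) > 0:
                converged = False
            candidate[:, t] = sgd_step(filters[:, t], f_grd, eps)
        _check_geometry(trace, candidate, dots)

        post_cost = raw_total_cost(batch, candidate, noise, config.cost.kind)
        accepted = post_cost < pre_cost
        if accepted:
            filters = candidate

        trace.batch_costs.append(pre_cost)
        trace.post_step_costs.append(post_cost)
        trace.accepted.append(accepted)
        trace.step_sizes.append(eps)
        eps *= 1.0 - config.step_decay
        it += 1

        if converged:
            break
        if config.grad_tol is not None:
            tangent_norms = [
                np.linalg.norm(
                    project_gradient_to_tangent(filters[:, t], result.grad[:, t])
                )
                for t in active_cols
            ]
            if max(tangent_norms) < config.grad_tol:
                break
    if track_pass_cost:
        pass_costs.append(
            raw_total_cost(stimulus_set, filters, noise, config.cost.kind)
        )
        trace.pass_costs = np.asarray(pass_costs)
    return filters


def run_sgd(
    stimulus_set: LabeledStimulusSet,
    noise: NoiseModel,
    config: SGDConfig,
    init_filters: FilterBank | None = None,
    track_pass_cost: bool = False,
) -> TrainingTrace:
    """Learn filters by constrained batch stochastic gradient descent.

    Runs ``n_restarts`` independent descents from random unit-norm initial
    filters (or from ``init_filters`` on the first restart) and keeps the
    restart with the lowest final full-training-set cost. Deterministic
    given ``config.seed``.
    """
    if config.cost.kind == "L2" and not np.issubdtype(
        np.asarray(stimulus_set.levels).dtype, np.number
    ):
        raise TypeError("L2 cost requires numeric latent level values")
    master = np.random.default_rng(config.seed)
    restart_seeds = master.integers(0, 2**31 - 1, size=config.n_restarts)

    best_trace = None
    restart_costs = []
    for r, rseed in enumerate(restart_seeds):
        rng = np.random.default_rng(rseed)
        if init_filters is not None and r == 0:
            filters = init_filters.filters.copy()
        else:
            filters = FilterBank.random(stimulus_set.dim, config.q, rng).filters
        trace = TrainingTrace([], [], [], [])
        trace.initial_cost = raw_total_cost(
            stimulus_set, filters, noise, config.cost.kind
        )
        if config.learn_mode == "sequential_pairs":
            final = filters
            for block_start in range(0, config.q, 2):
                active = list(range(block_start, min(block_start + 2, config.q)))
                final = _descend(
                    stimulus_set, noise, config, final, rng, active, trace,
                    track_pass_cost,
                )
        else:
            final = _descend(
                stimulus_set, noise, config, filters, rng, range(config.q),
                trace, track_pass_cost,
            )
        trace.final_filters = FilterBank(final)
        trace.final_cost = raw_total_cost(
            stimulus_set, final, noise, config.cost.kind
        )
        restart_costs.append(trace.final_cost)
        if best_trace is None or trace.final_cost < best_trace.final_cost:
            best_trace = trace

    best_trace.batch_costs = np.asarray(best_trace.batch_costs)
    best_trace.post_step_costs = np.asarray(best_trace.post_step_costs)
    best_trace.accepted = np.asarray(best_trace.accepted, dtype=bool)
    best_trace.step_sizes = np.asarray(best_trace.step_sizes)
    best_trace.restart_costs = np.asarray(restart_costs)
    return best_trace


def run_full_gd(
    stimulus_set: LabeledStimulusSet,
    noise: NoiseModel,
    config: SGDConfig,
    init_filters: FilterBank | None = None,
) -> TrainingTrace:
    """Full-batch descent: the same loop with the entire training set as
    the batch on every iteration (the non-stochastic benchmark)."""
    return run_sgd(
        stimulus_set,
        noise,
        replace(config, batch_stimuli_per_level=None),
        init_filters=init_filters,
    )


def count_operations_per_pass(
    stimulus_set: LabeledStimulusSet, config: SGDConfig
) -> int:
    """Likelihood operations in one pass, measured by running the posterior
    evaluations with the instrumented counter: N^2*N_lvl for a full pass,
    N_bch*N_lvl*N for an SGD pass."""
    from .decoder import posterior_matrix

    rng = np.random.default_rng(config.seed)
    filters = FilterBank.random(stimulus_set.dim, config.q, rng)
    before = likelihood_op_counter.count
    for batch_idx in _pass_batches(
        stimulus_set, config.batch_stimuli_per_level, rng
    ):
        batch = stimulus_set.subset(batch_idx)
        obs = batch.stimuli @ filters.filters
        posterior_matrix(obs, batch, filters, NoiseModel())
    return likelihood_op_counter.count - before
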