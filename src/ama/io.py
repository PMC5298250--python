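"""File formats, run configuration, and experiment orchestration.

Stimulus sets and filters travel as delimited numeric text (canonical,
human-readable) or as an ``.npz`` binary container for large sets. Runs
are described by a YAML config with ``task``, ``noise``, ``cost``,
``optimizer`` and optional ``landscape`` sections plus a ``seed``; a run
writes filters, the training trace, per-stimulus costs, and a manifest
recording the config hash, seed, and library versions, so every run is
reproducible from config + seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .data import (
    EnergyTaskConfig,
    LabeledStimulusSet,
    apply_prior_by_culling,
    generate_energy_task_set,
)
from .decoder import CostSpec, _per_stimulus_costs
from .model import AMA
from .response import FilterBank, NoiseModel

__all__ = [
    "read_stimulus_set",
    "write_stimulus_set",
    "read_filters",
    "write_filters",
    "RunConfig",
    "run_experiment",
]

log = logging.getLogger("ama")


def write_stimulus_set(stimulus_set: LabeledStimulusSet, path) -> None:
    """Write a stimulus set: text (header 'N d N_lvl', one line of level
    values, then one 'label v1 ... vd' row per stimulus, full float
    precision) or a binary ``.npz`` container if the path ends in .npz."""
    path = Path(path)
    if path.suffix == ".npz":
        np.savez(path, stimuli=stimulus_set.stimuli,
                 labels=stimulus_set.labels, levels=stimulus_set.levels)
        return
    with open(path, "w") as fh:
        fh.write(f"{stimulus_set.n_stimuli} {stimulus_set.dim} "
                 f"{stimulus_set.n_levels}\n")
        fh.write(" ".join(f"{x:.17g}" for x in stimulus_set.levels) + "\n")
        for label, row in zip(stimulus_set.labels, stimulus_set.stimuli):
            fh.write(f"{label} " + " ".join(f"{v:.17g}" for v in row) + "\n")


def read_stimulus_set(path) -> LabeledStimulusSet:
    """Read a stimulus set written by :func:`write_stimulus_set`, validating
    the header and row shapes; non-normalized rows are rejected by the
    container with the offending row named."""
    path = Path(path)
    if path.suffix == ".npz":
        with np.load(path) as npz:
            return LabeledStimulusSet(npz["stimuli"], npz["labels"],
                                      npz["levels"])
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) != 3:
            raise ValueError(f"{path}: malformed header, expected 'N d N_lvl'")
        n, d, n_lvl = (int(x) for x in header)
        levels = np.array([float(x) for x in fh.readline().split()])
        if levels.size != n_lvl:
            raise ValueError(
                f"{path}: header announces {n_lvl} levels, found {levels.size}"
            )
        labels = np.empty(n, dtype=int)
        stimuli = np.empty((n, d))
        for i in range(n):
            parts = fh.readline().split()
            if len(parts) != d + 1:
                raise ValueError(
                    f"{path}: row {i} has {len(parts) - 1} values, expected {d}"
                )
            labels[i] = int(parts[0])
            stimuli[i] = [float(x) for x in parts[1:]]
    return LabeledStimulusSet(stimuli, labels, levels)


def write_filters(filters: FilterBank, path) -> None:
    """Filters as text: header 'd q', then d rows of q columns."""
    with open(path, "w") as fh:
        fh.write(f"{filters.dim} {filters.q}\n")
        for row in filters.filters:
            fh.write(" ".join(f"{v:.17g}" for v in row) + "\n")


def read_filters(path) -> FilterBank:
    with open(path) as fh:
        d, q = (int(x) for x in fh.readline().split())
        mat = np.loadtxt(fh, ndmin=2)
    if mat.shape != (d, q):
        raise ValueError(f"{path}: filter matrix shape {mat.shape} != ({d}, {q})")
    return FilterBank(mat)


@dataclass
class RunConfig:
    """Structured description of a full experiment run."""

    task: dict
    noise: dict = field(default_factory=dict)
    cost: dict = field(default_factory=lambda: {"kind": "L0_KL"})
    optimizer: dict = field(default_factory=dict)
    landscape: dict | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()

    def noise_model(self) -> NoiseModel:
        return NoiseModel(**self.noise) if self.noise else NoiseModel()

    def stimulus_set(self) -> LabeledStimulusSet:
        if "file" in self.task:
            return read_stimulus_set(self.task["file"])
        gen = dict(self.task.get("generator", {}))
        gen.setdefault("seed", self.seed)
        if "level_range" in gen:
            gen["level_range"] = tuple(gen["level_range"])
        training = generate_energy_task_set(EnergyTaskConfig(**gen))
        weights = self.task.get("prior_weights")
        if weights is not None:
            training = apply_prior_by_culling(
                training, np.asarray(weights, dtype=float), self.seed
            )
        return training


def _library_versions() -> dict:
    import scipy
    import sklearn

    return {"numpy": np.__version__, "scipy": scipy.__version__,
            "scikit-learn": sklearn.__version__}


def run_experiment(config: RunConfig, out_dir) -> dict:
    """Run generate -> train -> evaluate (-> landscape) and write artifacts.

    Writes ``filters.txt``, ``trace.csv``, ``costs.txt``, optionally
    ``landscape.txt``, and ``manifest.json`` to ``out_dir``; returns the
    manifest. Any stage failure aborts with a stage-tagged error."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def stage(name):
        log.info("stage %s", name)
        return name

    try:
        stage("generate")
        training = config.stimulus_set()
    except Exception as exc:
        raise RuntimeError(f"[generate] {exc}") from exc

    try:
        stage("train")
        model = AMA.from_stimulus_set(
            training, noise=config.noise_model(),
            cost=config.cost.get("kind", "L0_KL"),
        )
        opt = dict(config.optimizer)
        opt.setdefault("seed", config.seed)
        results = model.fit(**opt)
    except Exception as exc:
        raise RuntimeError(f"[train] {exc}") from exc

    try:
        stage("evaluate")
        write_filters(results.filters, out / "filters.txt")
        trace = results.trace
        with open(out / "trace.csv", "w") as fh:
            fh.write("iteration,batch_cost,post_step_cost,accepted,step_size\n")
            for i in range(trace.n_iterations):
                fh.write(
                    f"{i},{trace.batch_costs[i]:.17g},"
                    f"{trace.post_step_costs[i]:.17g},"
                    f"{int(trace.accepted[i])},{trace.step_sizes[i]:.17g}\n"
                )
                log.debug(
                    "iter %d cost %.6g accepted %s eps %.4g", i,
                    trace.batch_costs[i], bool(trace.accepted[i]),
                    trace.step_sizes[i],
                )
        per_stim = _per_stimulus_costs(
            training, results.filters, model.noise, model.cost.kind
        )
        np.savetxt(out / "costs.txt", per_stim, fmt="%.17g",
                   header=f"per-stimulus {model.cost.kind} cost; "
                          f"total {results.cost:.17g}")
    except Exception as exc:
        raise RuntimeError(f"[evaluate] {exc}") from exc

    if config.landscape is not None:
        try:
            stage("landscape")
            theta = np.arange(0.0, 360.0,
                              float(config.landscape.get("theta_step", 5.0)))
            land = results.rotation_landscape(theta_grid=theta)
            np.savetxt(out / "landscape.txt",
                       np.column_stack([theta, land.cost]),
                       header="theta_deg cost", fmt="%.17g")
        except Exception as exc:
            raise RuntimeError(f"[landscape] {exc}") from exc

    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "final_cost": results.cost,
        "initial_cost": results.trace.initial_cost,
        "versions": _library_versions(),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    log.info("final cost %.6g (initial %.6g)", results.cost,
             results.trace.initial_cost)
    return manifest
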