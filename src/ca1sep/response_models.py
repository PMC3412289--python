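"""Single-neuron response models: active synapses in, binary spike decision out.

The contract abstracts what a detailed compartmental CA1 model does within
one gamma window: given the set of activated synapse slots on a cell, decide
whether the cell fires (1) or not (0).  The shipped implementation is a
deterministic random-weight threshold unit — each slot carries a fixed
positive weight drawn once at construction, and the cell fires when the
summed weight of its active slots reaches a threshold theta.

Heterogeneous weights are essential: with identical weights, every cell with
the same active-slot *count* would make the same decision and the population
would carry no cell-specific information.  The default is i.i.d.
lognormal(mu=0, sigma=0.5) per slot, a standard choice for excitatory
synaptic efficacies.

Adapter contract for a compartmental backend
--------------------------------------------
A biophysical simulator satisfies :class:`ResponseModel` by implementing
``respond`` as: instantiate the cell model in its reset state, activate the
excitatory synapses named by ``active_slots_by_pathway`` (plus the model's
standing feedforward inhibition) at t = 0, integrate for a 20 ms window, and
return 1 iff the somatic membrane potential crosses the action-potential
threshold (10 mV) within the window.  Such a backend is intentionally not
implemented here.
"""

from __future__ import annotations

import json
from abc import ABC, abstractmethod
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .connectivity import ProjectionMap, _active_mask
from .patterns import BinaryPattern

__all__ = ["ResponseModel", "ThresholdSurrogate", "population_response"]


class ResponseModel(ABC):
    """Contract: a frozen, deterministic map from active synapses to {0, 1}."""

    @abstractmethod
    def respond(
        self, cell_id: int, active_slots_by_pathway: Mapping[str, Sequence[int]]
    ) -> int:
        """Binary spike decision for one cell and one gamma window."""

    @property
    @abstractmethod
    def metadata(self) -> dict:
        """Model name, parameters and calibration state."""


class ThresholdSurrogate(ResponseModel):
    """Random-weight threshold unit: spike iff summed active weight >= theta.

    Weights are drawn once per (cell, pathway, slot) and frozen; only the
    scalar threshold ``theta`` is adjusted during calibration.  Positive
    weights make the decision monotone in the active set.
    """

    DISTRIBUTIONS = ("constant", "uniform", "lognormal")

    def __init__(
        self,
        pathway_shapes: Mapping[str, tuple[int, int]],
        theta: float = 1.0,
        weight_distribution: tuple = ("lognormal", 0.0, 0.5),
        seed: int = 0,
    ):
        kind = weight_distribution[0]
        if kind not in self.DISTRIBUTIONS:
            raise ValueError(f"unknown weight distribution {kind!r}")
        self.pathway_shapes = dict(pathway_shapes)
        self.weight_distribution = tuple(weight_distribution)
        self.seed = int(seed)
        self.theta = float(theta)
        rng = np.random.default_rng(self.seed)
        self.weights: dict[str, np.ndarray] = {}
        for name in sorted(self.pathway_shapes):
            shape = self.pathway_shapes[name]
            if kind == "constant":
                w = np.full(shape, float(weight_distribution[1]))
            elif kind == "uniform":
                w = rng.uniform(weight_distribution[1], weight_distribution[2], size=shape)
            else:
                w = rng.lognormal(weight_distribution[1], weight_distribution[2], size=shape)
            if (w <= 0).any():
                raise ValueError("synaptic weights must be positive")
            w.setflags(write=False)
            self.weights[name] = w

    def respond(self, cell_id, active_slots_by_pathway) -> int:
        drive = 0.0
        for name, slots in active_slots_by_pathway.items():
            w = self.weights.get(name)
            if w is None:
                raise KeyError(f"unknown pathway {name!r}")
            if not 0 <= cell_id < w.shape[0]:
                raise IndexError(f"unknown cell {cell_id}")
            slots = np.asarray(slots, dtype=np.int64)
            drive += w[cell_id, slots].sum()
        return int(drive >= self.theta)

    def drive(self, maps: Mapping[str, ProjectionMap], inputs: Mapping[str, BinaryPattern]) -> np.ndarray:
        """Summed active synaptic weight per postsynaptic cell (vectorized)."""
        if not inputs:
            raise ValueError("no pathway inputs supplied")
        total = None
        for name, pattern in inputs.items():
            if name not in self.weights:
                raise KeyError(f"unknown pathway {name!r}")
            mask = _active_mask(maps[name], pattern)
            contrib = (self.weights[name] * mask).sum(axis=1)
            total = contrib if total is None else total + contrib
        return total

    @property
    def metadata(self) -> dict:
        return {
            "model": "threshold_surrogate",
            "theta": self.theta,
            "weight_distribution": list(self.weight_distribution),
            "seed": self.seed,
            "pathway_shapes": {k: list(v) for k, v in self.pathway_shapes.items()},
        }

    # state file: JSON parameters; weights regenerate from the recorded seed
    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.metadata, indent=2))

    @classmethod
    def load(cls, path) -> "ThresholdSurrogate":
        meta = json.loads(Path(path).read_text())
        return cls(
            pathway_shapes={k: tuple(v) for k, v in meta["pathway_shapes"].items()},
            theta=meta["theta"],
            weight_distribution=tuple(meta["weight_distribution"]),
            seed=meta["seed"],
        )


def population_response(
    model: ThresholdSurrogate,
    maps: Mapping[str, ProjectionMap],
    inputs: Mapping[str, BinaryPattern],
) -> BinaryPattern:
    """CA1 output pattern for one gamma window.

    Drives the supplied pathway(s) with their input patterns and thresholds
    every cell; the output is a binary pattern over the n_post CA1 cells.
    Pathways may be driven singly (the usual experimental condition) or
    jointly.
    """
    n_posts = {maps[name].n_post for name in inputs}
    if len(n_posts) != 1:
        raise ValueError(f"inconsistent n_post across driven pathways: {n_posts}")
    n_post = n_posts.pop()
    drive = model.drive(maps, inputs)
    spikes = np.flatnonzero(drive >= model.theta)
    return BinaryPattern.from_indices(n_post, spikes)
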