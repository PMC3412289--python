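"""Random feedforward projections from CA3/EC populations onto CA1 synapse slots.

Each model CA1 cell carries a fixed number of anonymous synapse slots per
pathway (4407 CA3 slots on apical/oblique dendrites, 1918 EC slots on the
tuft at full scale).  Wiring is drawn per postsynaptic cell: its slots are
assigned distinct presynaptic cells uniformly at random (at most one contact
per pre-post pair), and the map is frozen afterwards.

The fan-out of a presynaptic cell (how many CA1 cells it contacts) is then
emergent with mean n_post x synapses_per_post / n_pre; a "regularized"
builder with exact per-presynaptic fan-out is provided for sensitivity
checks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .patterns import BinaryPattern

__all__ = [
    "PathwaySpec",
    "ProjectionMap",
    "presyn_count",
    "fanout_of",
    "build_projection",
    "build_projection_regular",
    "active_synapses",
    "active_counts",
    "save_projection",
    "load_projection",
]


def presyn_count(n_post: int, synapses_per_post: int, fanout: int) -> int:
    """Presynaptic population size implied by slot count and fan-out.

    n_post x synapses_per_post total contacts, divided among presynaptic
    cells each making ``fanout`` of them; the integer part is returned
    (e.g. 23500 x 1918 / 1000 = 45073 EC cells).
    """
    if n_post <= 0 or synapses_per_post <= 0 or fanout <= 0:
        raise ValueError("all arguments must be positive")
    return (n_post * synapses_per_post) // fanout


def fanout_of(n_post: int, synapses_per_post: int, n_pre: int) -> int:
    """Mean CA1 targets per presynaptic cell implied by the contact budget.

    Integer part of n_post x synapses_per_post / n_pre (a partial target is
    not a target): 23500 x 4407 / 28009 -> 3697 for CA3,
    23500 x 1918 / 45073 -> 1000 for EC.
    """
    if n_post <= 0 or synapses_per_post <= 0 or n_pre <= 0:
        raise ValueError("all arguments must be positive")
    return (n_post * synapses_per_post) // n_pre


@dataclass(frozen=True)
class PathwaySpec:
    """Anatomical parameters of one feedforward pathway (CA3 or EC)."""

    name: str
    n_pre: int
    synapses_per_post: int
    fanout: int

    def check_consistency(self, n_post: int) -> None:
        """Contact-budget consistency: n_pre x fanout == n_post x S within
        rounding (tolerance one contact per presynaptic cell)."""
        lhs = self.n_pre * self.fanout
        rhs = n_post * self.synapses_per_post
        if abs(lhs - rhs) > self.n_pre:
            raise ValueError(
                f"{self.name}: n_pre*fanout={lhs} vs n_post*S={rhs} "
                f"differ by more than one contact per presynaptic cell"
            )


class ProjectionMap:
    """Frozen wiring of one pathway onto a CA1 patch.

    ``assignment[post, slot]`` is the presynaptic cell ID wired to that slot;
    per postsynaptic cell the IDs are distinct.
    """

    def __init__(self, spec: PathwaySpec, n_post: int, assignment: np.ndarray):
        assignment = np.asarray(assignment, dtype=np.int64)
        if assignment.shape != (n_post, spec.synapses_per_post):
            raise ValueError(
                f"assignment shape {assignment.shape} != "
                f"({n_post}, {spec.synapses_per_post})"
            )
        if assignment.size and (assignment.min() < 0 or assignment.max() >= spec.n_pre):
            raise ValueError("presynaptic IDs outside [0, n_pre)")
        # at most one contact per (pre, post) pair
        for post in range(n_post):
            row = assignment[post]
            if np.unique(row).size != row.size:
                raise ValueError(f"duplicate presynaptic ID on postsynaptic cell {post}")
        assignment.setflags(write=False)
        self.spec = spec
        self.n_post = n_post
        self.assignment = assignment

    def realized_fanout(self) -> np.ndarray:
        """Per-presynaptic-cell number of CA1 targets actually wired."""
        return np.bincount(self.assignment.ravel(), minlength=self.spec.n_pre)

    def __eq__(self, other):
        return (
            isinstance(other, ProjectionMap)
            and self.spec == other.spec
            and self.n_post == other.n_post
            and np.array_equal(self.assignment, other.assignment)
        )


def build_projection(
    spec: PathwaySpec, n_post: int, rng: np.random.Generator
) -> ProjectionMap:
    """Draw the wiring: per CA1 cell, S distinct presynaptic IDs uniformly
    without replacement, independently across cells."""
    s = spec.synapses_per_post
    if s > spec.n_pre:
        raise ValueError(
            f"synapses_per_post={s} exceeds n_pre={spec.n_pre}; "
            "the one-contact-per-pair rule is infeasible"
        )
    assignment = np.empty((n_post, s), dtype=np.int64)
    for post in range(n_post):
        assignment[post] = rng.choice(spec.n_pre, size=s, replace=False)
    return ProjectionMap(spec, n_post, assignment)


def build_projection_regular(
    spec: PathwaySpec, n_post: int, rng: np.random.Generator, max_rounds: int = 1000
) -> ProjectionMap:
    """Wiring with *exact* per-presynaptic fan-out (random bipartite
    near-regular graph), for sensitivity checks against the emergent-fanout
    default.

    Builds a shuffled pool in which each presynaptic cell appears as close to
    n_post*S/n_pre times as the contact budget allows, deals it into slots,
    then repairs within-row duplicates by random swaps.
    """
    s = spec.synapses_per_post
    if s > spec.n_pre:
        raise ValueError("synapses_per_post exceeds n_pre")
    total = n_post * s
    base, extra = divmod(total, spec.n_pre)
    counts = np.full(spec.n_pre, base, dtype=np.int64)
    if extra:
        counts[rng.choice(spec.n_pre, size=extra, replace=False)] += 1
    pool = np.repeat(np.arange(spec.n_pre), counts)
    rng.shuffle(pool)
    assignment = pool.reshape(n_post, s).copy()
    for _ in range(max_rounds):
        dup_rows = []
        for post in range(n_post):
            row = assignment[post]
            uniq, first = np.unique(row, return_index=True)
            if uniq.size != row.size:
                mask = np.ones(row.size, dtype=bool)
                mask[first] = False
                dup_rows.append((post, np.flatnonzero(mask)))
        if not dup_rows:
            return ProjectionMap(spec, n_post, assignment)
        for post, slots in dup_rows:
            for slot in slots:
                o_post = int(rng.integers(n_post))
                o_slot = int(rng.integers(s))
                a, b = assignment[post, slot], assignment[o_post, o_slot]
                # swap only if it removes the duplicate without creating new ones
                if b not in assignment[post] and a not in assignment[o_post]:
                    assignment[post, slot], assignment[o_post, o_slot] = b, a
    raise RuntimeError("could not regularize wiring within the repair budget")


def active_synapses(pmap: ProjectionMap, pattern: BinaryPattern) -> list[np.ndarray]:
    """Per postsynaptic cell, the slot indices whose presynaptic cell is
    active in ``pattern``."""
    hits = _active_mask(pmap, pattern)
    return [np.flatnonzero(row) for row in hits]


def active_counts(pmap: ProjectionMap, pattern: BinaryPattern) -> np.ndarray:
    """Per postsynaptic cell, the number of active synapse slots."""
    return _active_mask(pmap, pattern).sum(axis=1)


def _active_mask(pmap: ProjectionMap, pattern: BinaryPattern) -> np.ndarray:
    if pattern.length != pmap.spec.n_pre:
        raise ValueError(
            f"pattern length {pattern.length} != n_pre {pmap.spec.n_pre}"
        )
    return pattern.to_bool()[pmap.assignment]


# ---------------------------------------------------------------------------
# edge-list TSV (post_id, slot, pre_id) + JSON sidecar with the PathwaySpec

def save_projection(pmap: ProjectionMap, tsv_path, json_path, seed=None) -> None:
    with open(tsv_path, "w") as fh:
        fh.write("post_id\tslot\tpre_id\n")
        for post in range(pmap.n_post):
            for slot in range(pmap.spec.synapses_per_post):
                fh.write(f"{post}\t{slot}\t{pmap.assignment[post, slot]}\n")
    sidecar = {
        "pathway": pmap.spec.name,
        "n_pre": pmap.spec.n_pre,
        "synapses_per_post": pmap.spec.synapses_per_post,
        "fanout": pmap.spec.fanout,
        "n_post": pmap.n_post,
        "seed": seed,
    }
    Path(json_path).write_text(json.dumps(sidecar, indent=2))


def load_projection(tsv_path, json_path) -> ProjectionMap:
    meta = json.loads(Path(json_path).read_text())
    spec = PathwaySpec(
        name=meta["pathway"],
        n_pre=meta["n_pre"],
        synapses_per_post=meta["synapses_per_post"],
        fanout=meta["fanout"],
    )
    assignment = np.full((meta["n_post"], meta["synapses_per_post"]), -1, dtype=np.int64)
    with open(tsv_path) as fh:
        header = fh.readline()
        if header.strip() != "post_id\tslot\tpre_id":
            raise ValueError(f"unexpected edge-list header in {tsv_path}")
        for line in fh:
            post, slot, pre = (int(t) for t in line.split())
            assignment[post, slot] = pre
    if (assignment < 0).any():
        raise ValueError("edge list does not cover every (post, slot)")
    return ProjectionMap(spec, meta["n_post"], assignment)
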