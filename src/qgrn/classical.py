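"""Exhaustive classical dynamics of synchronous Boolean networks.

This is the ground-truth engine: it enumerates the full state transition
graph (all 2**n states), finds every attractor with its basin, and computes
the pre-analysis metrics (transient time, basin entropy, state-space
diameter) that indicate whether exhaustive search is even the right tool.
It also provides the fast classical subroutines the quantum search relies
on: verifying that a measured state is an attractor state and unrolling the
full cycle from any one of its members.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .bn_io import BooleanNetwork, rule_truth_table, state_to_string

__all__ = [
    "EXHAUSTIVE_GUARD",
    "TransitionMap",
    "Attractor",
    "NetworkSummary",
    "synchronous_step",
    "build_transition_map",
    "find_attractors",
    "transient_time",
    "is_attractor_state",
    "unroll_cycle",
    "basin_entropy",
    "state_space_diameter",
    "chain_attractor_probability",
]

#: Largest gene count for which we enumerate all 2**n states explicitly.
EXHAUSTIVE_GUARD = 24


class CapacityError(ValueError):
    """Network too large for exhaustive state-space enumeration."""


@dataclass
class TransitionMap:
    """successor[s] = state index after one synchronous update of state s."""

    n: int
    successor: np.ndarray

    def __post_init__(self):
        self.successor = np.asarray(self.successor, dtype=np.int64)
        if self.successor.shape != (self.N,):
            raise ValueError(f"successor array must have length 2**n = {self.N}")
        if self.successor.min() < 0 or self.successor.max() >= self.N:
            raise ValueError("successor entries must lie in [0, 2**n)")

    @property
    def N(self) -> int:
        return 1 << self.n

    def iterate(self, steps: int) -> np.ndarray:
        """The map composed with itself ``steps`` times, as an index array."""
        arr = np.arange(self.N)
        f = self.successor
        # binary exponentiation on the functional graph
        k = steps
        while k:
            if k & 1:
                arr = f[arr]
            f = f[f]
            k >>= 1
        return arr


@dataclass(frozen=True)
class Attractor:
    """A canonical attractor cycle plus the size of its basin.

    ``states`` is the cycle in dynamical order, rotated so the smallest
    state index leads; ``basin_size`` counts every state (cycle included)
    whose trajectory reaches this cycle.
    """

    states: tuple[int, ...]
    basin_size: int

    @property
    def length(self) -> int:
        return len(self.states)

    def labels(self, n: int) -> tuple[str, ...]:
        return tuple(state_to_string(s, n) for s in self.states)


@dataclass
class NetworkSummary:
    """Pre-analysis bundle: attractors plus the complexity metrics."""

    n: int
    attractors: list[Attractor]
    transient_time: int
    basin_entropy: float
    state_space_diameter: int

    @property
    def attractor_count(self) -> int:
        return len(self.attractors)

    @property
    def max_basin_fraction(self) -> float:
        return max(a.basin_size for a in self.attractors) / (1 << self.n)

    def to_json(self, genes: list[str] | None = None) -> str:
        obj = {
            "genes": genes if genes is not None else [f"g{i}" for i in range(self.n)],
            "attractors": [
                {"states": list(a.labels(self.n)), "basin_size": a.basin_size}
                for a in self.attractors
            ],
            "transient_time": self.transient_time,
            "basin_entropy": self.basin_entropy,
            "state_space_diameter": self.state_space_diameter,
        }
        return json.dumps(obj, indent=2)


def synchronous_step(net: BooleanNetwork, state: int) -> int:
    """One synchronous update: every gene's rule evaluated on ``state``."""
    if not 0 <= state < (1 << net.n):
        raise ValueError(f"state {state} out of range for n={net.n}")
    env = {
        g: (state >> (net.n - 1 - i)) & 1 for i, g in enumerate(net.genes)
    }
    out = 0
    for i, rule in enumerate(net.rules):
        out |= int(rule.evaluate(env)) << (net.n - 1 - i)
    return out


def build_transition_map(net: BooleanNetwork) -> TransitionMap:
    """Tabulate the synchronous dynamics over all 2**n states."""
    if net.n > EXHAUSTIVE_GUARD:
        raise CapacityError(
            f"n={net.n} exceeds the exhaustive guard of {EXHAUSTIVE_GUARD} genes "
            f"(2**{net.n} states)"
        )
    succ = np.zeros(1 << net.n, dtype=np.int64)
    for i in range(net.n):
        succ |= rule_truth_table(net, i).astype(np.int64) << (net.n - 1 - i)
    return TransitionMap(net.n, succ)


def _cycle_detection(tmap: TransitionMap) -> tuple[np.ndarray, list[tuple[int, ...]]]:
    """Assign every state to its attractor; return (attr_id per state, cycles).

    Classic functional-graph traversal: walk forward colouring the current
    path; hitting the path again closes a new cycle, hitting a finished
    state inherits its attractor.
    """
    N = tmap.N
    succ = tmap.successor
    attr_id = np.full(N, -1, dtype=np.int64)
    # 0 = white, 1 = on current path, 2 = finished
    color = np.zeros(N, dtype=np.uint8)
    cycles: list[tuple[int, ...]] = []
    for start in range(N):
        if color[start] == 2:
            continue
        path = []
        s = start
        while color[s] == 0:
            color[s] = 1
            path.append(s)
            s = int(succ[s])
        if color[s] == 1:
            # s is on the current path: the tail from s is a new cycle
            cut = path.index(s)
            cycle = tuple(path[cut:])
            cid = len(cycles)
            cycles.append(cycle)
            owner = cid
        else:
            owner = int(attr_id[s])
        for v in path:
            attr_id[v] = owner
            color[v] = 2
    return attr_id, cycles


def _canonicalize(cycle: tuple[int, ...]) -> tuple[int, ...]:
    """Rotate the cycle so the smallest state index leads."""
    k = cycle.index(min(cycle))
    return cycle[k:] + cycle[:k]


def find_attractors(tmap: TransitionMap) -> list[Attractor]:
    """Every attractor of the map, canonical and sorted by smallest member.

    Basin sizes partition the state space: they sum to 2**n.
    """
    attr_id, cycles = _cycle_detection(tmap)
    basin = np.bincount(attr_id, minlength=len(cycles))
    attrs = [
        Attractor(_canonicalize(cyc), int(basin[cid]))
        for cid, cyc in enumerate(cycles)
    ]
    attrs.sort(key=lambda a: a.states[0])
    return attrs


def _distance_to_cycle(tmap: TransitionMap) -> np.ndarray:
    """Steps each state needs to first land on an attractor cycle."""
    N = tmap.N
    succ = tmap.successor
    _, cycles = _cycle_detection(tmap)
    dist = np.full(N, -1, dtype=np.int64)
    for cyc in cycles:
        for s in cyc:
            dist[s] = 0
    for start in range(N):
        if dist[start] >= 0:
            continue
        path = []
        s = start
        while dist[s] < 0:
            path.append(s)
            s = int(succ[s])
        d = int(dist[s])
        for v in reversed(path):
            d += 1
            dist[v] = d
    return dist


def transient_time(tmap: TransitionMap) -> int:
    """Smallest T after which every state has reached its attractor cycle."""
    return int(_distance_to_cycle(tmap).max())


def state_space_diameter(tmap: TransitionMap) -> int:
    """Longest transient: the maximum distance from any state to a cycle."""
    return transient_time(tmap)


def is_attractor_state(tmap: TransitionMap, state: int) -> tuple[bool, Attractor | None]:
    """Is ``state`` on an attractor cycle?  If so, also return the attractor.

    This is the fast classical check the hybrid quantum-classical loop uses
    to validate each measured outcome.
    """
    if not 0 <= state < tmap.N:
        raise ValueError(f"state {state} out of range")
    succ = tmap.successor
    s = int(succ[state])
    for _ in range(tmap.N):
        if s == state:
            return True, unroll_cycle(tmap, state)
        s = int(succ[s])
    return False, None


def unroll_cycle(tmap: TransitionMap, attractor_state: int) -> Attractor:
    """Full canonical attractor containing ``attractor_state``.

    A single measured cycle member is enough: iterating the synchronous map
    walks the whole cycle.  Raises if the state is not on a cycle.
    """
    succ = tmap.successor
    cycle = [attractor_state]
    s = int(succ[attractor_state])
    while s != attractor_state:
        if len(cycle) > tmap.N:
            raise ValueError(f"state {attractor_state} is not an attractor state")
        cycle.append(s)
        s = int(succ[s])
    # confirm it is really a cycle (the walk above assumes it closes)
    canon = _canonicalize(tuple(cycle))
    for a in find_attractors(tmap):
        if a.states == canon:
            return a
    raise ValueError(f"state {attractor_state} is not an attractor state")


def basin_entropy(tmap: TransitionMap) -> float:
    """Shannon entropy (bits) of the basin-size distribution.

    -sum_i p_i log2 p_i with p_i = basin_size_i / 2**n; zero when a single
    attractor drains the whole state space, at most log2(#attractors).
    """
    attrs = find_attractors(tmap)
    p = np.array([a.basin_size for a in attrs], dtype=float) / tmap.N
    return float(-(p * np.log2(p)).sum())


def chain_attractor_probability(T_t: int, n: int) -> float:
    """Uniform-start probability of sitting on an attractor after T_t steps
    of a maximal linear chain over 2**n states: (T_t + 1) / 2**n, capped at 1.
    """
    if T_t < 0 or n < 1:
        raise ValueError("T_t must be >= 0 and n >= 1")
    return min(1.0, (T_t + 1) / (1 << n))


def summarize(tmap: TransitionMap) -> NetworkSummary:
    """Bundle attractors and complexity metrics for pre-analysis."""
    attrs = find_attractors(tmap)
    dist = _distance_to_cycle(tmap)
    tt = int(dist.max())
    p = np.array([a.basin_size for a in attrs], dtype=float) / tmap.N
    h = float(-(p * np.log2(p)).sum())
    return NetworkSummary(
        n=tmap.n,
        attractors=attrs,
        transient_time=tt,
        basin_entropy=h,
        state_space_diameter=tt,
    )
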