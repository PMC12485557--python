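"""The iterative outer loop: one run per attractor.

Each run builds a suppression plan from the attractors found so far,
executes the algorithm (structured emulation, or the noisy Monte-Carlo
backend), draws one measurement outcome, classically verifies that it is a
new attractor state, and unrolls its full cycle.  Noiselessly, the exact
suppression of every previously-found basin guarantees that each run yields
a new attractor, so the loop terminates in exactly (#attractors) runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .bn_io import BooleanNetwork
from .classical import (
    Attractor,
    NetworkSummary,
    build_transition_map,
    is_attractor_state,
    summarize,
    transient_time,
    unroll_cycle,
)
from .emulator import NoiseModel, OutcomeDistribution, run_noisy, run_structured, sample_shots
from .suppression import SuppressionPlan, plan_suppression

__all__ = ["RunRecord", "SearchResult", "find_all_attractors_quantum", "precheck_complexity"]

logger = logging.getLogger(__name__)

#: Bounded behaviour under heavy noise: redraw this many outcomes per run
#: before re-running, and re-run this many times before giving up.
MAX_REDRAWS = 100
MAX_RERUNS = 10


@dataclass
class RunRecord:
    """Everything one run produced."""

    plan: SuppressionPlan
    distribution: OutcomeDistribution
    outcome: int
    verified: bool
    draws: int


@dataclass
class SearchResult:
    """Outcome of the full search: attractors in discovery order."""

    n: int
    attractors: list[Attractor] = field(default_factory=list)
    runs: list[RunRecord] = field(default_factory=list)

    @property
    def total_runs(self) -> int:
        return len(self.runs)


class VerificationError(RuntimeError):
    """No verifiable attractor outcome within the retry budget (heavy noise)."""

    def __init__(self, dist: OutcomeDistribution):
        super().__init__(
            "could not draw a verifiable new attractor state within the retry "
            "budget; the run's outcome distribution is attached"
        )
        self.distribution = dist


def _draw_outcome(dist: OutcomeDistribution, rng: np.random.Generator) -> int:
    return int(rng.choice(len(dist.probs), p=dist.probs / dist.probs.sum()))


def find_all_attractors_quantum(
    net: BooleanNetwork,
    T: int | str = "auto",
    shots: int = 1,
    seed: int = 0,
    noise: NoiseModel | None = None,
    m_source: str = "exact",
    noise_trajectories: int = 200,
) -> SearchResult:
    """Find every attractor, one per run, by cumulative basin suppression.

    Parameters
    ----------
    net : the Boolean network (within the exhaustive guard).
    T : evolution depth; ``"auto"`` uses the classical transient time.
    shots : outcomes drawn per run record (the first verifiable one is kept).
    seed : seeds both the outcome draws and the noisy backend.
    noise : optional bit-flip noise model; selects the Monte-Carlo backend
        on the assembled gate-level circuit.
    m_source : ``"exact"`` basin counting or ``"counting"`` for the emulated
        quantum-counting estimate.
    """
    tmap = build_transition_map(net)
    depth = transient_time(tmap) if T == "auto" else int(T)
    rng = np.random.default_rng(seed)
    result = SearchResult(n=net.n)
    covered = 0
    while covered < tmap.N:
        plan = plan_suppression(result.attractors, tmap, depth, m_source=m_source)
        attr, record = _one_run(net, tmap, plan, rng, noise, noise_trajectories, result)
        result.attractors.append(attr)
        result.runs.append(record)
        covered += attr.basin_size
        logger.info(
            "run %d: found attractor %s (basin %d/%d)",
            result.total_runs,
            attr.states,
            attr.basin_size,
            tmap.N,
        )
    return result


def _one_run(
    net: BooleanNetwork,
    tmap,
    plan: SuppressionPlan,
    rng: np.random.Generator,
    noise: NoiseModel | None,
    noise_trajectories: int,
    result: SearchResult,
) -> tuple[Attractor, RunRecord]:
    found_states = {s for a in result.attractors for s in a.states}
    for rerun in range(MAX_RERUNS + 1):
        if noise is None:
            dist = run_structured(tmap, plan)
        else:
            from .circuits import assemble_suppression_circuit

            circuit = assemble_suppression_circuit(net, plan)
            dist = run_noisy(
                circuit, noise, trajectories=noise_trajectories, seed=rng
            )
        draws = 0
        for _ in range(MAX_REDRAWS):
            outcome = _draw_outcome(dist, rng)
            draws += 1
            ok, attr = is_attractor_state(tmap, outcome)
            if ok and outcome not in found_states:
                record = RunRecord(plan, dist, outcome, True, draws)
                return unroll_cycle(tmap, outcome), record
        if noise is None:  # exact backend cannot produce an invalid outcome twice
            break
    raise VerificationError(dist)


def precheck_complexity(net: BooleanNetwork) -> NetworkSummary:
    """Classical pre-analysis: attractor count, transient time, basin
    entropy and state-space diameter — the metrics that indicate whether
    the suppression search (short transients, few attractors) or a plain
    classical enumeration is the better tool."""
    return summarize(build_transition_map(net))
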