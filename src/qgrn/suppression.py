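"""Closed-form parameters of exact amplitude suppression.

The search deletes the basins of already-found attractors from the uniform
superposition using a Grover-style iteration with tailored phases: a phase
of -phi on the marked basin states (propagated from the attractor cycle
states through forward/reverse time evolution) followed by a generalized
diffusion that phases the all-zero state by +phi.  With

    beta = arcsin(sqrt(M/N)),
    J    = ceil(pi / (2*pi - 4*beta) - 1/2),
    phi  = 2 * arcsin(sin(pi / (4*J + 2)) / cos(beta)),

J applications drive the amplitude of all M marked states exactly to zero,
leaving a uniform superposition over the N - M survivors.  A single
application suffices whenever M/N <= 3/4; at the boundary M/N = 3/4 the
phase reaches phi = pi, the ordinary Grover phase flip.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

from .classical import Attractor, TransitionMap, transient_time

__all__ = [
    "SuppressionPlan",
    "beta",
    "iterations_J",
    "phase_phi",
    "plan_suppression",
]

_EPS = 1e-12


def beta(M: int | float, N: int) -> float:
    """Grover angle beta = arcsin(sqrt(M/N)), in [0, pi/2]."""
    if N < 1:
        raise ValueError("N must be >= 1")
    if not 0 <= M <= N:
        raise ValueError(f"need 0 <= M <= N, got M={M}, N={N}")
    return math.asin(math.sqrt(M / N))


def iterations_J(M: int | float, N: int) -> int:
    """Optimal iteration count J = ceil(pi/(2*pi - 4*beta) - 1/2).

    J = 0 iff nothing is marked; J = 1 for 0 < M/N <= 3/4; monotone
    non-decreasing in M/N.  Suppressing every state (M = N) is refused:
    no superposition would remain.
    """
    if M == N:
        raise ValueError("M = N: no states would remain after suppression")
    if M == 0:
        return 0
    b = beta(M, N)
    raw = math.pi / (2 * math.pi - 4 * b) - 0.5
    return max(1, math.ceil(raw - _EPS))


def phase_phi(J: int, b: float) -> float:
    """Tailored phase phi = 2*arcsin(sin(pi/(4J+2)) / cos(beta)).

    Feasible whenever sin(pi/(4J+2)) <= cos(beta), which the choice of J
    guarantees.  For J = 1 this is equivalent to the exact-deletion
    condition cos(phi) = (1 - 2*mu) / (2*(1 - mu)) with mu = sin^2(beta).
    """
    if J < 1:
        raise ValueError("phase_phi requires J >= 1")
    num = math.sin(math.pi / (4 * J + 2))
    den = math.cos(b)
    if den <= 0 or num > den * (1 + 1e-9):
        raise ValueError(
            f"infeasible phase: sin(pi/(4J+2))={num:.6g} exceeds cos(beta)="
            f"{den:.6g}; increase J"
        )
    return 2 * math.asin(min(1.0, num / den))


@dataclass(frozen=True)
class SuppressionPlan:
    """Everything one suppression run needs: which attractor states to mark
    (tau), how many basin states that suppresses (M out of N), the angles
    beta/phi, the iteration count J, and the evolution depth T."""

    tau: frozenset[int]
    M: int
    N: int
    beta: float
    J: int
    phi: float
    T: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "tau": sorted(self.tau),
                "M": self.M,
                "N": self.N,
                "beta": self.beta,
                "J": self.J,
                "phi": self.phi,
                "T": self.T,
            },
            indent=2,
        )


def plan_suppression(
    found: list[Attractor],
    tmap: TransitionMap,
    T: int,
    m_source: str = "exact",
    counting_bits: int | None = None,
) -> SuppressionPlan:
    """Assemble the per-run plan from the attractors found so far.

    tau collects every cycle state of every found attractor; M is the total
    basin mass to suppress — either the exact classical count or, with
    ``m_source="counting"``, the analytically emulated quantum-counting
    estimate rounded to the nearest integer.  An empty ``found`` yields the
    trivial first-run plan (M = 0, J = 0, phi = 0).
    """
    N = tmap.N
    tau = frozenset(s for a in found for s in a.states)
    M_exact = sum(a.basin_size for a in found)
    if M_exact >= N and found:
        raise ValueError("all attractors already found: nothing left to search")
    if m_source == "exact":
        M = M_exact
    elif m_source == "counting":
        from .emulator import counting_distribution

        t = counting_bits if counting_bits is not None else tmap.n + 3
        M = int(round(counting_distribution(M_exact, N, t).m_estimate))
        M = min(M, N - 1)
    else:
        raise ValueError(f"unknown m_source {m_source!r}")
    if M == 0:
        return SuppressionPlan(tau, 0, N, 0.0, 0, 0.0, T)
    b = beta(M, N)
    J = iterations_J(M, N)
    phi = phase_phi(J, b)
    return SuppressionPlan(tau, M, N, b, J, phi, T)
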