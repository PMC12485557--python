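"""Gate-level compilation of the basin-suppression search.

The circuit acts on (T+1) registers of n qubits; register ``r_t`` holds the
network state at time t.  The single-step evolution operator is synthesized
from the algebraic normal form (ANF) of each update rule: every XOR monomial
becomes one multi-controlled X from the time-t register onto the time-(t+1)
wire of its gene, so the transition block maps |x>|0> to |x>|f(x)>.  Phase
marking applies one multi-controlled phase per attractor state, with X
conjugation realizing the 0-bits; the generalized diffusion is the same
construction on the all-zero pattern of the t=0 register, sandwiched in
Hadamard layers.  Circuits export to OpenQASM 3.0.

Global phases (the overall minus sign of the suppression operator and the
uniform e^{i*phi} shifts factored out of the marking operators) are dropped
throughout: all correctness statements are about measurement distributions,
which cannot see them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .bn_io import BooleanNetwork, rule_truth_table, state_bits
from .suppression import SuppressionPlan

__all__ = [
    "Gate",
    "CircuitIR",
    "anf_monomials",
    "build_transition_operator",
    "build_reverse_evolution",
    "build_phase_marking",
    "build_zero_phase",
    "assemble_suppression_circuit",
    "export_qasm",
]


@dataclass(frozen=True)
class Gate:
    """One gate: H, X, multi-controlled X or multi-controlled phase.

    ``controls`` pairs each control wire with its polarity (True = trigger
    on |1>).  ``phase`` is set only for MCP gates.
    """

    kind: str  # "h" | "x" | "mcx" | "mcp"
    target: int
    controls: tuple[tuple[int, bool], ...] = ()
    phase: float | None = None

    def __post_init__(self):
        if self.kind not in ("h", "x", "mcx", "mcp"):
            raise ValueError(f"unknown gate kind {self.kind!r}")
        if (self.phase is not None) != (self.kind == "mcp"):
            raise ValueError("phase is set iff the gate is an MCP")
        wires = [w for w, _ in self.controls]
        if self.target in wires or len(set(wires)) != len(wires):
            raise ValueError("control and target wires must be disjoint")
        if self.kind in ("h", "x") and self.controls:
            raise ValueError(f"{self.kind} takes no controls")

    @property
    def wires(self) -> tuple[int, ...]:
        return tuple(w for w, _ in self.controls) + (self.target,)


@dataclass
class CircuitIR:
    """A (T+1)*n-wide circuit; wire t*n + i is qubit i of register r_t."""

    n: int
    T: int
    gates: list[Gate] = field(default_factory=list)
    measured: tuple[int, ...] = ()

    @property
    def width(self) -> int:
        return (self.T + 1) * self.n

    def register(self, t: int) -> tuple[int, ...]:
        if not 0 <= t <= self.T:
            raise IndexError(f"register index {t} out of range")
        return tuple(range(t * self.n, (t + 1) * self.n))

    def validate(self) -> None:
        for g in self.gates:
            if max(g.wires) >= self.width or min(g.wires) < 0:
                raise ValueError(f"gate {g} touches a wire outside width {self.width}")


def anf_monomials(truth_table: Sequence[int] | np.ndarray) -> frozenset[frozenset[int]]:
    """Algebraic normal form of a Boolean function given as a truth table.

    The table is indexed MSB-first: row ``s`` is the function on the
    assignment where variable 0 is the top bit of ``s``.  Returns the set of
    monomials (subsets of variable indices; the empty set is the constant-1
    term) whose XOR of ANDs reproduces the table — the Möbius/Reed-Muller
    transform.  Each monomial later compiles to one multi-controlled X.
    """
    tt = np.asarray(truth_table, dtype=np.uint8).copy()
    L = len(tt)
    k = L.bit_length() - 1
    if L != 1 << k:
        raise ValueError(f"truth table length {L} is not a power of two")
    for bit in range(k):
        step = 1 << bit
        idx = (np.arange(L) & step).astype(bool)
        tt[idx] ^= tt[np.arange(L)[idx] ^ step]
    monomials = set()
    for s in np.nonzero(tt)[0]:
        # bit position p (0 = LSB) holds variable k-1-p
        mono = frozenset(k - 1 - p for p in range(k) if (int(s) >> p) & 1)
        monomials.add(mono)
    return frozenset(monomials)


def build_transition_operator(
    net: BooleanNetwork, from_register: Sequence[int], to_register: Sequence[int]
) -> list[Gate]:
    """Gate list computing one synchronous step into a fresh |0...0> register.

    For each gene the rule's ANF is taken over its support variables only,
    so the gate count equals the total monomial count across rules.
    """
    if set(from_register) & set(to_register):
        raise ValueError("from/to registers must be disjoint")
    n = net.n
    gates: list[Gate] = []
    for i, rule in enumerate(net.rules):
        support = sorted(net.gene_index(v) for v in rule.variables())
        k = len(support)
        if k == 0:
            table = [int(rule.evaluate({}))]
            monos = anf_monomials(table) if table[0] else frozenset()
        else:
            # truth table over the support assignment, MSB-first
            bits = state_bits(k)
            env = {net.genes[g]: bits[:, j] for j, g in enumerate(support)}
            table = np.asarray(rule.evaluate(env), dtype=np.uint8)
            if table.ndim == 0:
                table = np.full(1 << k, int(table), dtype=np.uint8)
            monos = anf_monomials(table)
        target = to_register[i]
        for mono in sorted(monos, key=lambda m: (len(m), sorted(m))):
            if not mono:
                gates.append(Gate("x", target))
            else:
                ctrls = tuple((from_register[support[j]], True) for j in sorted(mono))
                gates.append(Gate("mcx", target, ctrls))
    return gates


def build_reverse_evolution(forward: list[Gate]) -> list[Gate]:
    """Uncomputation: the reversed gate list (X/MCX are self-inverse)."""
    for g in forward:
        if g.kind not in ("x", "mcx"):
            raise ValueError(f"cannot reverse non-self-inverse gate kind {g.kind!r}")
    return list(reversed(forward))


def build_phase_marking(
    tau: Iterable[int],
    register: Sequence[int],
    phi: float,
    sign: int = 1,
) -> list[Gate]:
    """Phase e^{i*sign*phi} on each basis pattern in ``tau`` of a register.

    One multi-controlled phase per pattern; 0-bits are realized by X
    conjugation of their wires.  An empty ``tau`` emits nothing.
    """
    patterns = list(tau)
    if len(set(patterns)) != len(patterns):
        raise ValueError("duplicate patterns in tau")
    n = len(register)
    gates: list[Gate] = []
    for pat in patterns:
        if not 0 <= pat < (1 << n):
            raise ValueError(f"pattern {pat} does not fit in {n} bits")
        zeros = [register[i] for i in range(n) if not (pat >> (n - 1 - i)) & 1]
        for w in zeros:
            gates.append(Gate("x", w))
        ctrls = tuple((w, True) for w in register[:-1])
        gates.append(Gate("mcp", register[-1], ctrls, phase=sign * phi))
        for w in zeros:
            gates.append(Gate("x", w))
    return gates


def build_zero_phase(register: Sequence[int], phi: float) -> list[Gate]:
    """Phase e^{+i*phi} on the all-zero pattern (the diffusion core)."""
    return build_phase_marking([0], register, phi, sign=+1)


def assemble_suppression_circuit(
    net: BooleanNetwork, plan: SuppressionPlan
) -> CircuitIR:
    """The full one-run circuit on (T+1)*n qubits.

    Hadamards on r_0; then J repetitions of [forward evolution r_0 -> r_T,
    -phi marking of the attractor states on r_T, reverse evolution,
    H layer, +phi on |0...0> of r_0, H layer]; then a final forward
    evolution and measurement of r_T.  Uncomputation returns the ancilla
    registers to |0...0> after every iteration, which is what allows their
    reuse across iterations and the final evolution.
    """
    n = net.n
    T = plan.T
    circ = CircuitIR(n=n, T=T)
    r0 = circ.register(0)
    rT = circ.register(T)

    forward: list[Gate] = []
    for t in range(T):
        forward += build_transition_operator(net, circ.register(t), circ.register(t + 1))
    h_layer = [Gate("h", w) for w in r0]

    circ.gates += h_layer
    for _ in range(plan.J):
        circ.gates += forward
        circ.gates += build_phase_marking(sorted(plan.tau), rT, plan.phi, sign=-1)
        circ.gates += build_reverse_evolution(forward)
        circ.gates += h_layer
        circ.gates += build_zero_phase(r0, plan.phi)
        circ.gates += h_layer
    circ.gates += forward
    circ.measured = rT
    circ.validate()
    return circ


# --------------------------------------------------------------------------
# OpenQASM 3.0 export


def _wire_name(w: int, n: int) -> str:
    return f"r{w // n}[{w % n}]"


def _format_gate(g: Gate, n: int) -> str:
    if g.kind == "h":
        return f"h {_wire_name(g.target, n)};"
    if g.kind == "x":
        return f"x {_wire_name(g.target, n)};"
    pos = [w for w, p in g.controls if p]
    neg = [w for w, p in g.controls if not p]
    mods = []
    if pos:
        mods.append(f"ctrl({len(pos)}) @" if len(pos) > 1 else "ctrl @")
    if neg:
        mods.append(f"negctrl({len(neg)}) @" if len(neg) > 1 else "negctrl @")
    base = "x" if g.kind == "mcx" else f"p({g.phase:.12g})"
    operands = ", ".join(_wire_name(w, n) for w in pos + neg + [g.target])
    if not mods:
        return f"{base} {operands};"
    return f"{' '.join(mods)} {base} {operands};"


def export_qasm(circuit: CircuitIR) -> str:
    """OpenQASM 3.0 text with one ``qubit[n] r{t}`` register per time step.

    Multi-controlled gates are emitted un-decomposed via ctrl/negctrl
    modifiers; decomposition to a native gate set is left to the device
    toolchain.
    """
    n = circuit.n
    lines = ['OPENQASM 3.0;', 'include "stdgates.inc";']
    for t in range(circuit.T + 1):
        lines.append(f"qubit[{n}] r{t};")
    if circuit.measured:
        lines.append(f"bit[{len(circuit.measured)}] c;")
    for g in circuit.gates:
        lines.append(_format_gate(g, n))
    for i, w in enumerate(circuit.measured):
        lines.append(f"c[{i}] = measure {_wire_name(w, n)};")
    return "\n".join(lines) + "\n"
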