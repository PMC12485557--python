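"""Exact and noisy execution backends for the suppression search.

Two backends implement the same algorithm:

* ``run_structured`` exploits the circuit's structure.  Because every
  iteration uncomputes the ancilla registers, the joint state is always a
  superposition of basis products |x>|map(x)>...|map^T(x)>, so it suffices
  to track one complex amplitude per t=0 basis state (2**n numbers instead
  of 2**((T+1)n)).  Marking multiplies a[x] by e^{-i*phi} when map^T(x) is
  a marked attractor state; the diffusion is a rank-one phase in the
  Walsh-Hadamard domain.
* ``run_dense`` is the independent oracle: a plain statevector simulation
  of the assembled gate list, gate by gate, with no knowledge of the
  structure above.

Quantum counting is emulated analytically through the textbook
phase-estimation outcome law for the Grover rotation angle
theta = 2*arcsin(sqrt(M/N)); gate noise is a two-parameter Monte-Carlo
bit-flip model (per-gate X errors plus readout flips), a generic stand-in
for device calibration data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .bn_io import state_to_string
from .circuits import CircuitIR, Gate
from .classical import TransitionMap
from .suppression import SuppressionPlan

__all__ = [
    "DENSE_WIDTH_GUARD",
    "OutcomeDistribution",
    "NoiseModel",
    "CountingOutcome",
    "suppressed_amplitudes",
    "run_structured",
    "run_dense",
    "sample_shots",
    "run_noisy",
    "error_probability",
    "counting_distribution",
]

DENSE_WIDTH_GUARD = 20


@dataclass
class OutcomeDistribution:
    """Probability of each n-bit outcome on the measured register."""

    n: int
    probs: np.ndarray

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != (1 << self.n,):
            raise ValueError("probs must have length 2**n")
        if self.probs.min() < -1e-12:
            raise ValueError("negative probability")
        if abs(self.probs.sum() - 1.0) > 1e-10:
            raise ValueError(f"probabilities sum to {self.probs.sum()}, not 1")

    def as_labels(self, tol: float = 1e-12) -> dict[str, float]:
        """Nonzero outcomes keyed by their printed state label; numerical
        dust below ``tol`` is dropped."""
        return {
            state_to_string(s, self.n): float(p)
            for s, p in enumerate(self.probs)
            if p > tol
        }

    def total_variation(self, other: "OutcomeDistribution") -> float:
        return 0.5 * float(np.abs(self.probs - other.probs).sum())


@dataclass(frozen=True)
class NoiseModel:
    """Generic gate-level noise: independent X errors with probability
    ``p_gate`` on every wire a gate touches, plus readout flips with
    probability ``p_read`` per measured bit."""

    p_gate: float = 0.0
    p_read: float = 0.0

    def __post_init__(self):
        if not (0 <= self.p_gate <= 1 and 0 <= self.p_read <= 1):
            raise ValueError("noise probabilities must lie in [0, 1]")


# --------------------------------------------------------------------------
# Structured backend


def _fwht(a: np.ndarray) -> np.ndarray:
    """In-place fast Walsh-Hadamard transform (unnormalized)."""
    h = 1
    n = len(a)
    while h < n:
        a = a.reshape(-1, 2, h)
        x = a[:, 0, :].copy()
        a[:, 0, :] = x + a[:, 1, :]
        a[:, 1, :] = x - a[:, 1, :]
        a = a.reshape(n)
        h *= 2
    return a


def suppressed_amplitudes(
    tmap: TransitionMap, plan: SuppressionPlan, T: int | None = None
) -> np.ndarray:
    """Amplitudes over t=0 basis states after the suppression stage
    (before the final forward evolution).

    Starting uniform, each of the J iterations phases the marked basin
    (states whose T-step image lies in tau) by e^{-i*phi} and then applies
    the diffusion H^(x)n diag(e^{+i*phi}, 1, ..., 1) H^(x)n.
    """
    if T is None:
        T = plan.T
    N = tmap.N
    if plan.N != N:
        raise ValueError("plan was built for a different state-space size")
    img = tmap.iterate(T)
    tau = np.fromiter(plan.tau, dtype=np.int64) if plan.tau else np.empty(0, np.int64)
    marked = np.isin(img, tau)
    a = np.full(N, 1 / math.sqrt(N), dtype=complex)
    mark_phase = np.exp(-1j * plan.phi)
    zero_phase = np.exp(+1j * plan.phi)
    for _ in range(plan.J):
        a[marked] *= mark_phase
        a = _fwht(a) / math.sqrt(N)
        a[0] *= zero_phase
        a = _fwht(a) / math.sqrt(N)
    return a


def run_structured(
    tmap: TransitionMap, plan: SuppressionPlan, T: int | None = None
) -> OutcomeDistribution:
    """Exact outcome distribution of one run (suppression + final evolution).

    The final measurement sees map^T(x), so outcome y collects the
    probability of every t=0 state that evolves to y.
    """
    if T is None:
        T = plan.T
    a = suppressed_amplitudes(tmap, plan, T)
    img = tmap.iterate(T)
    probs = np.bincount(img, weights=np.abs(a) ** 2, minlength=tmap.N)
    return OutcomeDistribution(tmap.n, probs / probs.sum())


# --------------------------------------------------------------------------
# Dense statevector oracle


def _apply_gate(psi: np.ndarray, g: Gate, width: int) -> np.ndarray:
    """Apply one gate to a statevector shaped (2,)*width (wire 0 = axis 0)."""
    t = g.target
    if g.kind == "h":
        a0 = np.take(psi, 0, axis=t)
        a1 = np.take(psi, 1, axis=t)
        s = 1 / math.sqrt(2)
        psi = np.stack(((a0 + a1) * s, (a0 - a1) * s), axis=t)
        return psi
    if g.kind == "x":
        return np.flip(psi, axis=t)
    sel: list[object] = [slice(None)] * width
    for w, pol in g.controls:
        sel[w] = 1 if pol else 0
    if g.kind == "mcp":
        sel[t] = 1
        psi[tuple(sel)] = psi[tuple(sel)] * np.exp(1j * g.phase)
        return psi
    if g.kind == "mcx":
        s0 = sel.copy()
        s1 = sel.copy()
        s0[t] = 0
        s1[t] = 1
        tmp = psi[tuple(s0)].copy()
        psi[tuple(s0)] = psi[tuple(s1)]
        psi[tuple(s1)] = tmp
        return psi
    raise ValueError(f"unknown gate kind {g.kind!r}")


def _simulate(circuit: CircuitIR, extra_x: dict[int, list[int]] | None = None) -> np.ndarray:
    """Statevector after the gate list; optional X errors inserted after
    gate k on the wires listed in ``extra_x[k]``."""
    width = circuit.width
    if width > DENSE_WIDTH_GUARD:
        raise ValueError(
            f"dense simulation of {width} qubits exceeds the guard of "
            f"{DENSE_WIDTH_GUARD}"
        )
    psi = np.zeros((2,) * width, dtype=complex)
    psi[(0,) * width] = 1.0
    for k, g in enumerate(circuit.gates):
        psi = _apply_gate(psi, g, width)
        if extra_x:
            for w in extra_x.get(k, ()):
                psi = np.flip(psi, axis=w)
    return psi


def _measure(psi: np.ndarray, circuit: CircuitIR) -> np.ndarray:
    """Marginal outcome distribution over the measured wires (MSB first)."""
    width = circuit.width
    p = np.abs(psi) ** 2
    keep = list(circuit.measured)
    drop = tuple(w for w in range(width) if w not in keep)
    marg = p.sum(axis=drop)
    # axes of marg follow increasing wire order; permute into the declared
    # measurement order (first measured wire = outcome MSB)
    in_order = sorted(keep)
    marg = np.transpose(marg, axes=[in_order.index(w) for w in keep])
    return marg.reshape(-1)


def run_dense(circuit: CircuitIR) -> OutcomeDistribution:
    """Gate-by-gate statevector simulation; the independent test oracle."""
    psi = _simulate(circuit)
    probs = _measure(psi, circuit)
    return OutcomeDistribution(len(circuit.measured), probs / probs.sum())


# --------------------------------------------------------------------------
# Shots, noise, counting


def sample_shots(
    dist: OutcomeDistribution, shots: int, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Multinomial shot counts per outcome, reproducible under ``seed``."""
    if shots < 1:
        raise ValueError("shots must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.multinomial(shots, dist.probs / dist.probs.sum())


def _readout_channel(probs: np.ndarray, n: int, p_read: float) -> np.ndarray:
    """Push an outcome distribution through independent per-bit flips."""
    if p_read == 0:
        return probs
    p = probs.reshape((2,) * n)
    for axis in range(n):
        p = (1 - p_read) * p + p_read * np.flip(p, axis=axis)
    return p.reshape(-1)


def run_noisy(
    circuit: CircuitIR,
    noise: NoiseModel,
    trajectories: int = 100,
    seed: int | np.random.Generator = 0,
) -> OutcomeDistribution:
    """Monte-Carlo bit-flip noise: average the outcome distributions of
    ``trajectories`` runs, each inserting an X error with probability
    ``p_gate`` on every wire touched by every gate, then applying the
    readout-flip channel.  Converges to :func:`run_dense` as the error
    probabilities vanish."""
    if trajectories < 1:
        raise ValueError("trajectories must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_out = len(circuit.measured)
    acc = np.zeros(1 << n_out)
    for _ in range(trajectories):
        extra: dict[int, list[int]] = {}
        if noise.p_gate > 0:
            for k, g in enumerate(circuit.gates):
                flips = [w for w in g.wires if rng.random() < noise.p_gate]
                if flips:
                    extra[k] = flips
        psi = _simulate(circuit, extra or None)
        acc += _measure(psi, circuit)
    probs = _readout_channel(acc / trajectories, n_out, noise.p_read)
    return OutcomeDistribution(n_out, probs / probs.sum())


def error_probability(
    dist: OutcomeDistribution, remaining_attractor_states: set[int]
) -> float:
    """Probability of measuring anything outside the attractor states still
    to be found: 1 - sum of their outcome probabilities."""
    idx = np.fromiter(remaining_attractor_states, dtype=np.int64)
    good = float(dist.probs[idx].sum()) if len(idx) else 0.0
    return max(0.0, 1.0 - good)


@dataclass
class CountingOutcome:
    """Quantum-counting emulation: the t-bit phase-estimation outcome
    distribution and the modal estimate of the marked-state count."""

    precision_bits: int
    probs: np.ndarray
    m_star: int
    m_estimate: float

    def __post_init__(self):
        assert abs(self.probs.sum() - 1.0) < 1e-9


def counting_distribution(M: int, N: int, precision_bits: int) -> CountingOutcome:
    """Exact outcome law of quantum counting with t precision bits.

    Phase estimation on the Grover iterate for M of N marked states sees the
    eigenphases +/- theta/(2*pi) with theta = 2*arcsin(sqrt(M/N)), each with
    weight 1/2; a t-bit register returns m with the Fejér-kernel law
    |sin(2^t pi d)/(2^t sin(pi d))|^2 at offset d = omega - m/2^t.  The
    count estimate is M_hat = N * sin^2(pi * m / 2^t), identical for the two
    branches."""
    t = precision_bits
    if t < 1:
        raise ValueError("precision_bits must be >= 1")
    if not 0 <= M <= N:
        raise ValueError("need 0 <= M <= N")
    L = 1 << t
    theta = 2 * math.asin(math.sqrt(M / N))
    omega = theta / (2 * math.pi)
    m = np.arange(L)

    def branch(w: float) -> np.ndarray:
        d = (w - m / L) % 1.0
        exact = np.isclose(d, 0.0, atol=1e-15) | np.isclose(d, 1.0, atol=1e-15)
        num = np.sin(L * np.pi * d)
        den = L * np.sin(np.pi * d)
        with np.errstate(divide="ignore", invalid="ignore"):
            amp = np.where(exact, 1.0, np.where(den != 0, num / np.where(den == 0, 1, den), 1.0))
        return amp**2

    probs = 0.5 * branch(omega) + 0.5 * branch(-omega)
    probs = probs / probs.sum()
    m_star = int(np.argmax(probs))
    m_hat = N * math.sin(math.pi * m_star / L) ** 2
    return CountingOutcome(t, probs, m_star, m_hat)
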