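# Methods

## Model and problem

A synchronous Boolean network over genes g₁…gₙ assigns each gene one
Boolean update rule; a state is an n-bit vector updated all at once, so
the dynamics is a function on the N = 2ⁿ states.  Every trajectory ends on
an attractor — a fixed point or cycle — and the set of states draining
into an attractor is its basin; basins partition the state space.
Attractors are the biologically meaningful objects (stable expression
patterns), and the task is to enumerate all of them.

**State encoding.**  A state string is written g₁…gₙ left to right and its
integer index treats g₁ as the most significant bit, so the printed label
`1011` of a 4-gene network is state index 11.  This one convention is used
by the parser, the classical engine, circuit wire order and measurement
read-out alike.

## The suppression search

Each run prepares the uniform superposition, deletes the basins of the
attractors already found, applies the time evolution T̂ᵀ and measures.
The deletion operator is

    Ŝ = (Ĥ⊗ⁿ Î₀ Ĥ⊗ⁿ) · (T̂ᵀ† Îc T̂ᵀ)

iterated J times, where Îc phases the found attractor states by e^{−iϕ}
at the final-time register (the forward/reverse evolution conjugation
propagates that phase to every basin state at t = 0) and Î₀ phases |0…0⟩
by e^{+iϕ}.  Overall phases are dropped everywhere: measurement
distributions cannot see them, and the tests assert on distributions.

With μ = M/N the marked fraction,

* β = arcsin(√μ) — the usual Grover angle;
* J = ⌈π/(2π − 4β) − ½⌉ — so J = 1 exactly for 0 < μ ≤ 3/4, and J grows
  as μ → 1 (J = 0 when nothing is marked; μ = 1 is refused, since nothing
  would remain);
* ϕ = 2·arcsin( sin(π/(4J+2)) / cos β ) — the phase-matching condition.
  For J = 1 it is equivalent to cos ϕ = (1−2μ)/(2(1−μ)), which is exactly
  the zero-amplitude condition of one iteration; the 2-dimensional
  invariant-subspace recursion shows the same choice zeroes the marked
  amplitude after J iterations with ϕ held constant across iterations.

Both conventions embedded here (β as arcsin of the *square root*, and the
*quotient* sin/cos in ϕ) were chosen because only they reproduce the
single-application bound μ ≤ 3/4 with ϕ(μ=3/4) = π, and both are verified
against the dense unitary oracle over randomized instances
(`test_acceptance.py`), not assumed.

After Ŝᴶ the surviving amplitudes are uniform (1/√(N−M)), so the final
measurement is uniform over the unsuppressed basins; in particular each
yet-unfound attractor is measured with probability proportional to its
basin size, and nothing else can be measured.  Hence: one new attractor
per run, #runs = #attractors.

**Evolution depth T.**  Any T at least the transient time T_t (the longest
distance from a state to its attractor cycle) works; the driver's
`T="auto"` computes T_t classically.  Measuring a cycle member is enough —
`unroll_cycle` recovers the whole cycle classically in O(N).

**Quantum counting.**  The number M to suppress is classically exact by
default.  `m_source="counting"` instead emulates quantum counting
analytically: t-bit phase estimation on the Grover iterate has eigenphases
±θ/2π with θ = 2β, each of weight ½, and outcome m follows the Fejér
kernel law; the modal estimate M̂ = N·sin²(πm/2ᵗ) is rounded to the
nearest integer before β/J/ϕ are computed.  Default precision t = n + 3
bits.  No QPE circuit is built: the outcome law is identical and the
controlled-Grover machinery adds nothing testable at these sizes.

## Circuits

The circuit uses (T+1)·n qubits: register r_t holds the state at time t.
Each rule is synthesized from its algebraic normal form (ANF, computed by
the Möbius/Reed-Muller butterfly over the rule's support variables): each
XOR monomial becomes one multi-controlled X from r_t onto the gene's wire
in r_{t+1}, the empty monomial a plain X.  The transition block therefore
costs exactly (total ANF monomials) gates — an interpretable, deterministic
cost metric.  Phase marking emits one multi-controlled phase per marked
pattern, X-conjugating the wires where the pattern bit is 0; the diffusion
is the same construction on the all-zero pattern of r₀ between Hadamard
layers.

Because X/MCX are self-inverse, reversing the forward gate list uncomputes
the ancilla registers exactly: after every mark-and-reverse the registers
r₁…r_T are |0…0⟩ again on every basis input.  Two consequences: the same
ancillas serve all J iterations and the final evolution (width stays
(T+1)·n), and the joint state is always a superposition of the product
states |x⟩|f(x)⟩…|fᵀ(x)⟩ — which is what licenses the structured emulator
below.

Export is OpenQASM 3.0 with one `qubit[n] r{t}` register per time step and
un-decomposed `ctrl`/`negctrl` modifiers for multi-controlled gates;
decomposition into a native gate set is device-specific and out of scope.

## Emulation

* **Structured backend** (default): tracks one complex amplitude per t=0
  basis state.  Marking multiplies a[x] by e^{−iϕ} iff map^T(x) is a
  marked attractor state; the diffusion is a fast Walsh-Hadamard
  transform, a phase on index 0, and a second transform.  Cost
  O(J·n·2ⁿ) — the 5-gene example with T = 4 runs in microseconds where a
  dense simulation of its 25 qubits would be hopeless.
* **Dense oracle**: a plain gate-by-gate statevector simulation of the
  assembled circuit (guarded at 20 qubits), kept deliberately ignorant of
  the structure argument; agreement within 1e−9 total variation across
  randomized small instances is asserted in the acceptance tests.
* **Noise**: a two-parameter Monte-Carlo model — after every gate each
  touched wire suffers an X error with probability `p_gate`, and each read
  bit flips with probability `p_read`.  This is a generic NISQ stand-in,
  *not* a calibration of any particular device: published device-snapshot
  error percentages are irreproducible by construction, so the tests
  assert the model's qualitative laws instead (error probability → 0 as
  p → 0; monotone growth with p; uniform outcomes at p_read = ½).
  The hybrid loop survives noise by classically verifying every measured
  outcome (`is_attractor_state` is O(N) worst case) and redrawing/
  re-running on failure, capped at 100 redraws and 10 reruns.

## Fixtures and what the tests show

* The **5-gene cortical network** (Fgf8, Emx2, Pax6, Coup_tfi, Sp8) is
  transcribed from the published consensus model of cortical area
  development; the package's self-test enforces its published facts —
  exactly two attractors, basins 4 and 28 of 32 — so a transcription error
  fails loudly.
* The **4-gene network** is a synthetic stand-in (see its file header)
  constructed so that its attractor set is exactly the five fixed points
  0000, 1011, 0011, 1111, 1101 with basins 4/4/3/3/2 and transient time 2.
  The demonstration it supports — suppress four basins in the order
  0000→1011→0011→1111 and the final run returns 1101 with probability 1 —
  depends only on that attractor set, not on the transient details.
* **Random networks** draw k distinct regulators per gene and an
  independent random truth table with P(1) = 0.5 (bias adjustable),
  seeded and reproducible.  They emulate the combinatorics of small
  regulatory logic, not the degree distributions or canalization of real
  GRNs, so passing the randomized suites shows algorithmic exactness —
  not biological realism.
* The **chain network** (saturating binary counter) realizes the
  pathological worst case: one attractor, transient time 2ⁿ−1, where the
  uniform-start hit probability after T steps is (T+1)/2ⁿ — the regime
  where a classical approach is preferable, which is why the pre-analysis
  metrics (transient time, basin entropy, state-space diameter) are
  exposed.

## Numerical choices

* Attractor canonicalization: cycles rotate so the smallest state index
  leads; attractor lists sort by that index.  Deterministic comparisons.
* Exhaustive guard: n ≤ 24 (arrays of 2ⁿ int64); beyond it the engine
  refuses rather than thrash.
* Basin entropy uses −Σ p log₂ p over basin-size fractions; the
  state-space diameter is defined as the longest transient
  (garden-of-Eden state to its cycle), which coincides with T_t.  Other
  diameter definitions exist; this one is documented, not claimed
  universal.
* iterations_J subtracts 1e−12 before the ceiling so the exact boundary
  μ = 3/4 yields J = 1 under floating-point arithmetic; phase_phi clips
  its arcsin argument at 1 with a 1e−9 feasibility tolerance.
* Probability vectors are validated to sum to 1 within 1e−10; the dense
  simulator's norm is preserved to machine precision (asserted at 1e−12).
* All stochastic operations (shot sampling, noise trajectories, outcome
  draws) take explicit integer seeds or numpy Generators.

Problem sizes in the shipped tests and the acceptance script (n ≤ 6
networks, ≤ 9-qubit dense simulations, 200-network sweeps, 250-300 noise
trajectories) were chosen so the whole suite completes in seconds while
still exercising every exactness property at full precision.

## Known limitations

* Exhaustive classical ground truth caps at n ≤ 24; the quantum circuit
  description itself scales to any n, but the package's verification
  pipeline (and T = auto) needs the classical map.
* The noise model is bit-flip + readout only — no amplitude damping,
  dephasing or correlated errors, and no device calibration data.
* Asynchronous and probabilistic update schemes are out of scope; the
  BoolNet parser deliberately rejects those extensions.
* Quantum counting is emulated at the distribution level; no gate-level
  QPE circuit is produced.
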