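# qgrn — quantum basin-suppression attractor search for Boolean networks

Gene regulatory networks are routinely modelled as synchronous Boolean
networks: *n* genes, each with one Boolean update rule, all updated at
once.  The stable behaviours of such a network — its **attractors** (fixed
points and cycles of the state transition graph) — are identified with
cellular phenotypes, so finding *all* of them matters, and the state space
has 2^n states.

`qgrn` implements a quantum search strategy for this problem that finds
**one new attractor per run**.  Starting from the uniform superposition
over all 2^n states, each run *deletes* the basins of attraction of every
attractor found so far, evolves the network dynamics T steps, and
measures — so the measurement can only return an attractor not yet seen.
The deletion is a Grover-style iteration with tailored phases: mark the
found attractor states with a phase −ϕ at the final-time register
(propagated through the whole basin by forward-then-reverse time
evolution, T̂ᵗ † Îc T̂ᵗ), then apply a generalized diffusion
−Ĥ⊗ⁿ Î₀ Ĥ⊗ⁿ that phases |0…0⟩ by +ϕ.  With

    β = arcsin(√(M/N)),   J = ⌈π/(2π − 4β) − ½⌉,
    ϕ = 2 arcsin( sin(π/(4J+2)) / cos β ),

J applications drive the amplitude of all M basin states *exactly* to
zero (a single application suffices whenever M/N ≤ 3/4), leaving a uniform
superposition over the N − M survivors.  The package provides:

* `bn_io` — BoolNet-dialect text parsing/writing and truth-table
  compilation of rules;
* `classical` — the exhaustive classical engine (ground truth): attractors
  with basins, transient time, basin entropy, state-space diameter, plus
  the fast cycle checks the hybrid quantum-classical loop uses;
* `suppression` — the closed-form β/J/ϕ plan for each run;
* `circuits` — reversible synthesis of the time-evolution operator from
  the algebraic normal form of each rule (one multi-controlled X per XOR
  monomial), phase marking, diffusion, full circuit assembly on (T+1)·n
  qubits, and OpenQASM 3.0 export;
* `emulator` — an exact structured emulator that tracks only 2^n
  amplitudes (valid because every iteration uncomputes its ancillas), a
  dense statevector oracle, shot sampling, an analytic quantum-counting
  emulation, and a generic Monte-Carlo bit-flip noise model;
* `driver` — the iterative outer loop (one run per attractor) with
  classical verification of every measured outcome, and the `qgrn` CLI;
* `fixtures` — packaged example networks and seeded synthetic generators.

## Worked example

The packaged 5-gene cortical-area-development network (genes Fgf8, Emx2,
Pax6, Coup_tfi, Sp8) has exactly two fixed-point attractors: the posterior
expression pattern `01010` (basin 28 of 32 states) and the anterior
pattern `10101` (basin 4 of 32).

```python
>>> import qgrn
>>> net = qgrn.giacomantonio_fixture()
>>> tmap = qgrn.build_transition_map(net)
>>> T = qgrn.transient_time(tmap)          # 4 synchronous steps
>>> plan = qgrn.plan_suppression([], tmap, T)   # first run: no suppression
>>> qgrn.run_structured(tmap, plan).as_labels()
{'01010': 0.875, '10101': 0.12499999999999999}
```

The first run measures an attractor with probability proportional to its
basin (28/32 = 0.875 vs 4/32 = 0.125).  Suppose it returned the big
attractor; the second run suppresses its entire basin:

```python
>>> big = qgrn.find_attractors(tmap)[0]         # state 01010, basin 28
>>> plan2 = qgrn.plan_suppression([big], tmap, T)
>>> (plan2.M, plan2.N, plan2.J)
(28, 32, 2)
>>> qgrn.run_structured(tmap, plan2).as_labels()
{'10101': 1.0}
```

With 28 of 32 states suppressed (M/N > 3/4) the plan needs J = 2
iterations, after which the small attractor is measured with certainty —
two runs, two attractors.  The full loop does this automatically:

```python
>>> result = qgrn.find_all_attractors_quantum(net, seed=1)
>>> result.total_runs
2
```

The same works from the shell:

```sh
qgrn analyze net.bn                    # classical pre-analysis (JSON)
qgrn attractors net.bn --seed 1        # the full iterative search
qgrn suppress net.bn --found 01010     # one run's exact distribution
qgrn circuit net.bn --found 01010 --qasm run2.qasm   # OpenQASM 3.0 export
qgrn synth --chain 4 -o chain4.bn      # pathological chain fixture
```

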