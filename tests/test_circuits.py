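import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from qgrn import (
    CircuitIR,
    Gate,
    anf_monomials,
    assemble_suppression_circuit,
    build_phase_marking,
    build_reverse_evolution,
    build_transition_operator,
    build_zero_phase,
    export_qasm,
    build_transition_map,
    find_attractors,
    parse_boolnet,
    plan_suppression,
)
from qgrn.emulator import _measure, _simulate
from qgrn.fixtures import random_network


def eval_anf(monomials, k, s):
    """Evaluate an ANF monomial set on the assignment encoded by s (MSB first)."""
    bits = [(s >> (k - 1 - j)) & 1 for j in range(k)]
    val = 0
    for mono in monomials:
        val ^= int(all(bits[j] for j in mono)) if mono else 1
    return val


class TestANF:
    def test_xor_of_two_inputs(self):
        assert anf_monomials([0, 1, 1, 0]) == frozenset(
            {frozenset({0}), frozenset({1})}
        )

    def test_and_of_two_inputs(self):
        assert anf_monomials([0, 0, 0, 1]) == frozenset({frozenset({0, 1})})

    def test_constants(self):
        assert anf_monomials([0, 0, 0, 0]) == frozenset()
        assert anf_monomials([1, 1, 1, 1]) == frozenset({frozenset()})

    def test_bad_length(self):
        with pytest.raises(ValueError):
            anf_monomials([0, 1, 1])

    @settings(max_examples=60, derandomize=True)
    @given(st.integers(min_value=1, max_value=4), st.data())
    def test_xor_of_monomials_reconstructs_table(self, k, data):
        table = data.draw(
            st.lists(st.integers(0, 1), min_size=1 << k, max_size=1 << k)
        )
        monos = anf_monomials(table)
        for s in range(1 << k):
            assert eval_anf(monos, k, s) == table[s]


def circuit_from_gates(n, T, gates, measured=()):
    return CircuitIR(n=n, T=T, gates=list(gates), measured=tuple(measured))


class TestTransitionOperator:
    def test_swap_network_is_two_cnots(self, swap_net):
        gates = build_transition_operator(swap_net, (0, 1), (2, 3))
        kinds = sorted((g.kind, g.controls, g.target) for g in gates)
        assert kinds == [
            ("mcx", ((0, True),), 3),
            ("mcx", ((1, True),), 2),
        ]

    def test_constant_one_rule_is_plain_x(self):
        net = parse_boolnet("targets, factors\nA, 1\nB, A")
        gates = build_transition_operator(net, (0, 1), (2, 3))
        assert ("x", 2) in [(g.kind, g.target) for g in gates]

    def test_overlapping_registers_rejected(self, swap_net):
        with pytest.raises(ValueError):
            build_transition_operator(swap_net, (0, 1), (1, 2))

    @pytest.mark.parametrize("seed", range(4))
    def test_maps_basis_to_image_n3(self, seed):
        net = random_network(3, 2, seed)
        tmap = build_transition_map(net)
        forward = build_transition_operator(net, (0, 1, 2), (3, 4, 5))
        for x in range(8):
            prep = [Gate("x", w) for w in range(3) if (x >> (2 - w)) & 1]
            circ = circuit_from_gates(3, 1, prep + forward)
            psi = _simulate(circ).reshape(-1)
            expect = (x << 3) | int(tmap.successor[x])
            assert abs(psi[expect]) == pytest.approx(1.0)


class TestReverseEvolution:
    def test_forward_then_reverse_is_identity(self, swap_net):
        fwd = build_transition_operator(swap_net, (0, 1), (2, 3))
        rev = build_reverse_evolution(fwd)
        for x in range(4):
            prep = [Gate("x", w) for w in range(2) if (x >> (1 - w)) & 1]
            circ = circuit_from_gates(2, 1, prep + fwd + rev)
            psi = _simulate(circ).reshape(-1)
            assert abs(psi[x << 2]) == pytest.approx(1.0)

    def test_reverse_of_reverse(self, swap_net):
        fwd = build_transition_operator(swap_net, (0, 1), (2, 3))
        assert build_reverse_evolution(build_reverse_evolution(fwd)) == fwd

    def test_non_self_inverse_rejected(self):
        with pytest.raises(ValueError):
            build_reverse_evolution([Gate("h", 0)])


class TestPhaseMarking:
    def run_phases(self, gates, n):
        """Phase picked up by each basis state of an n-wire register."""
        out = []
        for x in range(1 << n):
            prep = [Gate("x", w) for w in range(n) if (x >> (n - 1 - w)) & 1]
            circ = circuit_from_gates(n, 0, prep + gates)
            psi = _simulate(circ).reshape(-1)
            out.append(psi[x])
        return np.array(out)

    def test_all_ones_pattern_is_controlled_z(self):
        gates = build_phase_marking([0b11], (0, 1), math.pi, sign=1)
        phases = self.run_phases(gates, 2)
        assert np.allclose(phases, [1, 1, 1, -1])

    def test_all_zeros_pattern_lands_on_00(self):
        gates = build_phase_marking([0b00], (0, 1), math.pi / 2, sign=-1)
        phases = self.run_phases(gates, 2)
        assert phases[0] == pytest.approx(np.exp(-1j * math.pi / 2))
        assert np.allclose(phases[1:], 1)

    def test_disjoint_patterns_compose(self):
        gates = build_phase_marking([0b00, 0b11], (0, 1), 0.7, sign=1)
        phases = self.run_phases(gates, 2)
        assert phases[0] == pytest.approx(np.exp(0.7j))
        assert phases[3] == pytest.approx(np.exp(0.7j))
        assert np.allclose(phases[1:3], 1)

    def test_empty_tau_emits_nothing(self):
        assert build_phase_marking([], (0, 1), 1.0) == []

    def test_duplicates_rejected(self):
        with pytest.raises(ValueError):
            build_phase_marking([1, 1], (0, 1), 1.0)

    def test_zero_phase_projector_form(self):
        # build_zero_phase == I + (e^{i phi} - 1)|0><0| on the register
        phi = 1.1
        gates = build_zero_phase((0, 1), phi)
        phases = self.run_phases(gates, 2)
        expect = np.ones(4, dtype=complex)
        expect[0] = np.exp(1j * phi)
        assert np.allclose(phases, expect)

    def test_zero_phi_is_identity(self):
        phases = self.run_phases(build_zero_phase((0, 1), 0.0), 2)
        assert np.allclose(phases, 1)

    def test_negative_polarity_gate_in_simulator(self):
        # a negctrl MCP phases |01> (control wire 0 low, target wire 1 high)
        g = Gate("mcp", 1, ((0, False),), phase=math.pi)
        phases = self.run_phases([g], 2)
        assert np.allclose(phases, [1, -1, 1, 1])


class TestAssembledCircuit:
    def test_j0_plan_structure(self, swap_net, swap_tmap):
        plan = plan_suppression([], swap_tmap, T=1)
        circ = assemble_suppression_circuit(swap_net, plan)
        assert circ.width == 4  # (T+1) * n
        kinds = [g.kind for g in circ.gates]
        assert kinds == ["h", "h", "mcx", "mcx"]
        assert circ.measured == (2, 3)

    def test_width_scales_with_depth(self, swap_net, swap_tmap):
        plan = plan_suppression([], swap_tmap, T=3)
        assert assemble_suppression_circuit(swap_net, plan).width == 8

    def test_unitarity_and_uncomputation(self, swap_net, swap_tmap, swap_attractors):
        plan = plan_suppression([swap_attractors[0]], swap_tmap, T=1)
        circ = assemble_suppression_circuit(swap_net, plan)
        # drop the final forward evolution to inspect the suppressed state
        n_final = 2  # two CNOTs of the final forward block
        probe = CircuitIR(
            n=circ.n, T=circ.T, gates=circ.gates[:-n_final], measured=circ.measured
        )
        psi = _simulate(probe).reshape(4, 4)
        assert np.linalg.norm(psi) == pytest.approx(1.0, abs=1e-12)
        # ancilla register r1 is exactly |00> for every r0 basis state
        assert np.allclose(psi[:, 1:], 0, atol=1e-12)


class TestQasmExport:
    def test_swap_j0_program(self, swap_net, swap_tmap):
        plan = plan_suppression([], swap_tmap, T=1)
        qasm = export_qasm(assemble_suppression_circuit(swap_net, plan))
        assert qasm.startswith("OPENQASM 3.0;")
        assert "qubit[2] r0;" in qasm and "qubit[2] r1;" in qasm
        assert qasm.count("\nh r0[") == 2
        assert "ctrl @ x r0[1], r1[0];" in qasm
        assert "c[0] = measure r1[0];" in qasm

    def test_mcp_uses_ctrl_modifier(self, swap_net, swap_tmap, swap_attractors):
        plan = plan_suppression([swap_attractors[2]], swap_tmap, T=1)
        qasm = export_qasm(assemble_suppression_circuit(swap_net, plan))
        assert "ctrl @ p(" in qasm

    def test_negctrl_modifier(self):
        circ = CircuitIR(
            n=2, T=0, gates=[Gate("mcp", 1, ((0, False),), phase=0.5)], measured=(0, 1)
        )
        assert "negctrl @ p(0.5) r0[0], r0[1];" in export_qasm(circ)

    def test_empty_circuit_header_only(self):
        qasm = export_qasm(CircuitIR(n=1, T=0))
        assert qasm.splitlines()[0] == "OPENQASM 3.0;"
        assert "measure" not in qasm


class TestGateInvariants:
    def test_control_target_disjoint(self):
        with pytest.raises(ValueError):
            Gate("mcx", 0, ((0, True),))

    def test_phase_only_on_mcp(self):
        with pytest.raises(ValueError):
            Gate("x", 0, phase=1.0)
        with pytest.raises(ValueError):
            Gate("mcp", 0)

    def test_gate_count_equals_monomial_total(self):
        net = random_network(4, 3, 9)
        from qgrn.circuits import anf_monomials as anf
        from qgrn.bn_io import rule_truth_table

        gates = build_transition_operator(net, range(4), range(4, 8))
        total = sum(len(anf(rule_truth_table(net, i)[: 1 << 4])) for i in range(4))
        # per-rule ANF over the full assignment equals ANF over the support
        assert len(gates) == total
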