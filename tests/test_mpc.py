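import itertools
import random

import pytest

from privseq.channel import Channel, ProtocolAbort
from privseq.circuits import (
    BooleanCircuit,
    CircuitBuilder,
    CircuitError,
    Gate,
    bits_to_int,
    compile_banded_ed_circuit,
    evaluate_plain,
    sequence_to_bits,
    write_circuit,
)
from privseq.distance import banded_edit_distance, edit_distance
from privseq.mpc import (
    IntegrityError,
    SecureDistanceOutput,
    evaluate,
    garble,
    oblivious_transfer,
    secure_banded_distance,
)


def garble_and_evaluate(circuit, inputs, seed=0, free_xor=False, audit=None):
    """Run the garbling scheme locally: generator-side labels for every input."""
    g = garble(circuit, seed=seed, free_xor=free_xor)
    initial = {}
    for role, wires in circuit.input_map.items():
        for w, bit in zip(wires, inputs[role], strict=True):
            initial[w] = g.input_labels[w][bit]
    for w, bit in circuit.const_map.items():
        initial[w] = g.input_labels[w][bit]
    return evaluate(
        g.garbled_gates, initial, circuit.output_wires, g.output_decode,
        free_xor=free_xor, audit=audit,
    )


def single_gate_circuit(kind):
    bd = CircuitBuilder()
    a, b = bd.inputs("generator", 1)[0], bd.inputs("evaluator", 1)[0]
    bd.circuit.output_wires = [bd.gate(kind, a, -1 if kind == "NOT" else b)]
    bd.circuit.validate()
    return bd.circuit


class TestGarbledGates:
    @pytest.mark.parametrize("kind", ["AND", "OR", "XOR"])
    def test_binary_gate_truth_table(self, kind):
        circ = single_gate_circuit(kind)
        op = {"AND": lambda a, b: a & b, "OR": lambda a, b: a | b,
              "XOR": lambda a, b: a ^ b}[kind]
        for va, vb in itertools.product((0, 1), repeat=2):
            out = garble_and_evaluate(
                circ, {"generator": [va], "evaluator": [vb]}, seed=va * 2 + vb
            )
            assert out == [op(va, vb)]

    def test_not_gate(self):
        bd = CircuitBuilder()
        a = bd.inputs("generator", 1)[0]
        bd.circuit.output_wires = [bd.not_(a)]
        for v in (0, 1):
            out = garble_and_evaluate(bd.circuit, {"generator": [v]}, seed=v)
            assert out == [1 - v]

    def test_table_sizes(self):
        g = garble(single_gate_circuit("AND"), seed=1)
        assert len(g.garbled_gates[0].table) == 4
        bd = CircuitBuilder()
        a = bd.inputs("generator", 1)[0]
        bd.circuit.output_wires = [bd.not_(a)]
        g = garble(bd.circuit, seed=1)
        assert len(g.garbled_gates[0].table) == 2

    def test_wire_label_pair_structure(self):
        g = garble(single_gate_circuit("AND"), seed=2)
        for l0, l1 in g.input_labels.values():
            assert l0.key != l1.key
            assert l0.permute_bit == 1 - l1.permute_bit

    def test_random_circuits_match_plaintext_oracle(self):
        """Seeded random 8-gate circuits on 4 inputs: garbled evaluation equals
        plaintext boolean evaluation over all 2^4 assignments."""
        rng = random.Random(3)
        for trial in range(10):
            bd = CircuitBuilder()
            gen = bd.inputs("generator", 2)
            ev = bd.inputs("evaluator", 2)
            wires = gen + ev
            for _ in range(8):
                kind = rng.choice(["AND", "OR", "XOR", "NOT"])
                a = rng.choice(wires)
                b = rng.choice(wires) if kind != "NOT" else -1
                wires.append(bd.gate(kind, a, b))
            bd.circuit.output_wires = wires[-3:]
            bd.circuit.validate()
            for bits in itertools.product((0, 1), repeat=4):
                inputs = {"generator": list(bits[:2]), "evaluator": list(bits[2:])}
                assert garble_and_evaluate(bd.circuit, inputs, seed=trial) == \
                    evaluate_plain(bd.circuit, inputs)

    def test_exactly_one_row_decrypts_per_gate(self):
        audit = {}
        garble_and_evaluate(
            single_gate_circuit("AND"), {"generator": [1], "evaluator": [1]},
            seed=4, audit=audit,
        )
        assert audit["rows_valid_per_gate"] == [1]
        assert audit["wires_single_label"] is True

    def test_corrupted_table_detected(self):
        circ = single_gate_circuit("AND")
        g = garble(circ, seed=5)
        gate = g.garbled_gates[0]
        corrupted = gate.__class__(
            gate.gate_kind, gate.input_wires, gate.output_wire,
            tuple(bytes(len(r)) for r in gate.table),
        )
        initial = {
            w: g.input_labels[w][1] for ws in circ.input_map.values() for w in ws
        }
        with pytest.raises(IntegrityError):
            evaluate([corrupted], initial, circ.output_wires, g.output_decode)

    def test_cyclic_circuit_rejected(self):
        circ = BooleanCircuit(
            gates=[Gate(0, "AND", 0, 2, 1), Gate(1, "AND", 1, 0, 2)],
            input_map={"generator": [0]},
            output_wires=[2],
        )
        with pytest.raises(CircuitError, match="before definition"):
            garble(circ, seed=0)


class TestCircuitGadgets:
    def test_four_bit_adder(self):
        """4-bit ripple-carry adder inside the garbling scheme: 5 + 9 = 14."""
        bd = CircuitBuilder()
        a = bd.inputs("generator", 4)
        b = bd.inputs("evaluator", 4)
        bd.circuit.output_wires = bd.add_vec(a, b, width=5)
        bd.circuit.validate()
        to_bits = lambda v: [(v >> i) & 1 for i in range(4)]
        out = garble_and_evaluate(
            bd.circuit, {"generator": to_bits(5), "evaluator": to_bits(9)}, seed=6
        )
        assert bits_to_int(out) == 14

    def test_adder_exhaustive_plaintext(self):
        bd = CircuitBuilder()
        a = bd.inputs("generator", 3)
        b = bd.inputs("evaluator", 3)
        bd.circuit.output_wires = bd.add_vec(a, b, width=4)
        for x in range(8):
            for y in range(8):
                out = evaluate_plain(
                    bd.circuit,
                    {
                        "generator": [(x >> i) & 1 for i in range(3)],
                        "evaluator": [(y >> i) & 1 for i in range(3)],
                    },
                )
                assert bits_to_int(out) == x + y


class TestObliviousTransfer:
    def test_choice_selects_message(self):
        m0, m1 = b"\x01" * 17, b"\x02" * 17
        assert oblivious_transfer((m0, m1), 0, seed=1) == m0
        assert oblivious_transfer((m0, m1), 1, seed=1) == m1

    def test_sender_view_independent_of_choice(self):
        m0, m1 = b"left-msg-0123456", b"rght-msg-0123456"
        ch0, ch1 = Channel(), Channel()
        out0 = oblivious_transfer((m0, m1), 0, ch0, seed=2)
        out1 = oblivious_transfer((m0, m1), 1, ch1, seed=2)
        assert out0 != out1
        sizes0 = [len(p) for s, p in ch0.transcript if s == "data_owner"]
        sizes1 = [len(p) for s, p in ch1.transcript if s == "data_owner"]
        assert sizes0 == sizes1
        assert len(ch0.transcript) == len(ch1.transcript)

    def test_length_mismatch_aborts(self):
        with pytest.raises(ProtocolAbort, match="equal length"):
            oblivious_transfer((b"ab", b"abc"), 0, seed=3)


class TestBandedCircuit:
    def test_worked_pair_through_garbled_circuit(self):
        circ = compile_banded_ed_circuit(4, 4, 1, bit_width=3)
        out = garble_and_evaluate(
            circ,
            {
                "generator": sequence_to_bits("ATGC"),
                "evaluator": sequence_to_bits("ATGG"),
            },
            seed=7,
        )
        assert bits_to_int(out) == 1

    def test_identical_inputs_zero(self):
        circ = compile_banded_ed_circuit(3, 3, 0)
        out = evaluate_plain(
            circ,
            {"generator": sequence_to_bits("AAA"), "evaluator": sequence_to_bits("AAA")},
        )
        assert bits_to_int(out) == 0

    def test_full_band_equals_exact_distance(self):
        rng = random.Random(8)
        for _ in range(50):
            x = "".join(rng.choice("ACGT") for _ in range(5))
            y = "".join(rng.choice("ACGT") for _ in range(5))
            circ = compile_banded_ed_circuit(5, 5, 5)
            out = evaluate_plain(
                circ,
                {
                    "generator": sequence_to_bits(x),
                    "evaluator": sequence_to_bits(y),
                },
            )
            assert bits_to_int(out) == edit_distance(x, y)

    def test_plaintext_circuit_matches_banded_kernel(self):
        rng = random.Random(9)
        for _ in range(40):
            lx, ly = rng.randint(0, 9), rng.randint(0, 9)
            x = "".join(rng.choice("ACGT") for _ in range(lx))
            y = "".join(rng.choice("ACGT") for _ in range(ly))
            b = rng.choice([0, 1, 3])
            circ = compile_banded_ed_circuit(lx, ly, b)
            out = evaluate_plain(
                circ,
                {
                    "generator": sequence_to_bits(x),
                    "evaluator": sequence_to_bits(y),
                },
            )
            assert bits_to_int(out) == banded_edit_distance(x, y, b)

    def test_bit_width_too_small_rejected(self):
        with pytest.raises(CircuitError, match="bit_width"):
            compile_banded_ed_circuit(10, 10, 2, bit_width=3)

    def test_circuit_ir_dump(self, tmp_path):
        circ = compile_banded_ed_circuit(2, 2, 1)
        p = tmp_path / "circ.txt"
        write_circuit(circ, p)
        lines = [l for l in p.read_text().splitlines() if not l.startswith("#")]
        assert len(lines) == len(circ.gates)


class TestSecureBandedDistance:
    def test_worked_pair(self):
        out = secure_banded_distance("ATGC", "ATGG", 1, seed=10)
        assert out.distance == 1

    def test_equal_sequences_any_band(self):
        for b in (0, 2):
            assert secure_banded_distance("CAGT", "CAGT", b, seed=b).distance == 0

    def test_matches_plaintext_banded_oracle(self):
        rng = random.Random(11)
        for i in range(8):
            lx, ly = rng.randint(0, 12), rng.randint(0, 12)
            x = "".join(rng.choice("ACGT") for _ in range(lx))
            y = "".join(rng.choice("ACGT") for _ in range(ly))
            b = rng.choice([0, 1, 3])
            out = secure_banded_distance(x, y, b, seed=i)
            assert out.distance == banded_edit_distance(x, y, b)

    def test_free_xor_changes_no_output(self):
        x, y = "CAACAT", "AACATG"
        base = secure_banded_distance(x, y, 2, seed=12)
        fx = secure_banded_distance(x, y, 2, seed=12, free_xor=True)
        assert base.distance == fx.distance

    def test_audit_confirms_one_valid_row_per_gate(self):
        audit = {}
        secure_banded_distance("ACGT", "AGGT", 1, seed=13, audit=audit)
        assert set(audit["rows_valid_per_gate"]) == {1}
        assert audit["wires_single_label"] is True

    def test_output_range_validation(self):
        with pytest.raises(ValueError):
            SecureDistanceOutput(distance=8, bit_width=3)
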