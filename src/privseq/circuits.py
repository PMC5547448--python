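"""Boolean-circuit IR and the compiler turning banded edit distance into gates.

The entire banded dynamic programme is expressed as one circuit — the secure
protocol later evaluates it in a single garbled execution so that nothing but
the final distance is revealed (per-cell comparisons leaked individually would
let either party probe residues position by position, since each position has
only four possible values).

Conventions, fixed for bit-exact interoperability:

* nucleotides are 2 bits each, A=00, C=01, G=10, T=11 (high bit first in the
  input wire order);
* DP values are unsigned, ``bit_width`` bits, least-significant wire first;
* out-of-band neighbours are the all-ones constant 2^bit_width - 1, and the
  +1 / +cost additions saturate at all-ones, realising the +infinity
  convention in finite width;
* the data owner's sequence feeds the "generator" input wires and the
  researcher's the "evaluator" input wires; only the final DP cell is output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .distance import BandSpec

GATE_KINDS = ("AND", "XOR", "OR", "NOT")

NUC_BITS = {"A": (0, 0), "C": (0, 1), "G": (1, 0), "T": (1, 1)}


class CircuitError(ValueError):
    """Structural problem in a boolean circuit (cycle, undefined wire, ...)."""


@dataclass(frozen=True)
class Gate:
    gate_id: int
    kind: str
    in1: int
    in2: int  # ignored for NOT (set to -1)
    out: int


@dataclass
class BooleanCircuit:
    """Topologically ordered gate list with role-tagged inputs and constants."""

    gates: list[Gate] = field(default_factory=list)
    input_map: dict[str, list[int]] = field(default_factory=dict)
    const_map: dict[int, int] = field(default_factory=dict)  # wire -> fixed bit
    output_wires: list[int] = field(default_factory=list)
    n_wires: int = 0

    def validate(self) -> None:
        defined = set(self.const_map)
        for wires in self.input_map.values():
            defined.update(wires)
        for g in self.gates:
            if g.kind not in GATE_KINDS:
                raise CircuitError(f"gate {g.gate_id}: unknown kind {g.kind}")
            ins = (g.in1,) if g.kind == "NOT" else (g.in1, g.in2)
            for w in ins:
                if w not in defined:
                    raise CircuitError(
                        f"gate {g.gate_id}: input wire {w} used before definition "
                        "(cycle or dangling wire)"
                    )
            if g.out in defined:
                raise CircuitError(f"gate {g.gate_id}: wire {g.out} defined twice")
            defined.add(g.out)
        for w in self.output_wires:
            if w not in defined:
                raise CircuitError(f"output wire {w} never defined")

    def all_input_wires(self) -> list[int]:
        wires = list(self.const_map)
        for ws in self.input_map.values():
            wires.extend(ws)
        return wires


def evaluate_plain(circuit: BooleanCircuit, inputs: dict[str, list[int]]) -> list[int]:
    """Reference plaintext evaluation of the circuit; oracle for the garbled path."""
    values: dict[int, int] = dict(circuit.const_map)
    for role, wires in circuit.input_map.items():
        bits = inputs[role]
        if len(bits) != len(wires):
            raise ValueError(
                f"{role}: expected {len(wires)} input bits, got {len(bits)}"
            )
        values.update(zip(wires, bits))
    for g in circuit.gates:
        a = values[g.in1]
        if g.kind == "NOT":
            values[g.out] = 1 - a
            continue
        b = values[g.in2]
        if g.kind == "AND":
            values[g.out] = a & b
        elif g.kind == "OR":
            values[g.out] = a | b
        else:  # XOR
            values[g.out] = a ^ b
    return [values[w] for w in circuit.output_wires]


class CircuitBuilder:
    """Emits gates in topological order; numbers are LSB-first wire vectors."""

    def __init__(self):
        self.circuit = BooleanCircuit()
        self._const_cache: dict[int, int] = {}

    def new_wire(self) -> int:
        w = self.circuit.n_wires
        self.circuit.n_wires += 1
        return w

    def inputs(self, role: str, n: int) -> list[int]:
        wires = [self.new_wire() for _ in range(n)]
        self.circuit.input_map.setdefault(role, []).extend(wires)
        return wires

    def const(self, bit: int) -> int:
        if bit not in self._const_cache:
            w = self.new_wire()
            self.circuit.const_map[w] = bit
            self._const_cache[bit] = w
        return self._const_cache[bit]

    def const_vec(self, value: int, width: int) -> list[int]:
        return [self.const((value >> i) & 1) for i in range(width)]

    def gate(self, kind: str, a: int, b: int = -1) -> int:
        out = self.new_wire()
        self.circuit.gates.append(
            Gate(gate_id=len(self.circuit.gates), kind=kind, in1=a, in2=b, out=out)
        )
        return out

    def xor(self, a: int, b: int) -> int:
        return self.gate("XOR", a, b)

    def and_(self, a: int, b: int) -> int:
        return self.gate("AND", a, b)

    def or_(self, a: int, b: int) -> int:
        return self.gate("OR", a, b)

    def not_(self, a: int) -> int:
        return self.gate("NOT", a)

    # ---------------------------------------------------------------- gadgets

    def mismatch(self, x: tuple[int, int], y: tuple[int, int]) -> int:
        """Cost bit for one DP cell: 1 iff the two 2-bit nucleotides differ."""
        return self.or_(self.xor(x[0], y[0]), self.xor(x[1], y[1]))

    def add_bit_saturating(self, a: list[int], d: int) -> list[int]:
        """a + d (d a single bit), saturating at all-ones so +inf stays +inf."""
        out, carry = [], d
        for bit in a:
            out.append(self.xor(bit, carry))
            carry = self.and_(bit, carry)
        return [self.or_(s, carry) for s in out]

    def add_vec(self, a: list[int], b: list[int], width: int | None = None) -> list[int]:
        """Ripple-carry adder a + b; result has ``width`` bits (default len(a)+1)."""
        if width is None:
            width = len(a) + 1
        out, carry = [], self.const(0)
        for ai, bi in zip(a, b, strict=True):
            axb = self.xor(ai, bi)
            out.append(self.xor(axb, carry))
            carry = self.or_(self.and_(ai, bi), self.and_(carry, axb))
        out.append(carry)
        return out[:width]

    def less_than(self, a: list[int], b: list[int]) -> int:
        """Unsigned a < b, LSB-first ripple comparison."""
        lt = self.const(0)
        for ai, bi in zip(a, b, strict=True):
            x = self.xor(ai, bi)
            t = self.xor(bi, lt)
            lt = self.xor(lt, self.and_(x, t))  # mux(x, bi, lt)
        return lt

    def mux_vec(self, sel: int, a: list[int], b: list[int]) -> list[int]:
        """sel ? a : b, per bit as b XOR (sel AND (a XOR b))."""
        return [
            self.xor(bi, self.and_(sel, self.xor(ai, bi)))
            for ai, bi in zip(a, b, strict=True)
        ]

    def min_vec(self, a: list[int], b: list[int]) -> list[int]:
        return self.mux_vec(self.less_than(a, b), a, b)


def min_bit_width(len_x: int, len_y: int) -> int:
    """Width holding any real distance plus one headroom bit for the sentinel."""
    return max(1, (max(len_x, len_y)).bit_length()) + 1


def compile_banded_ed_circuit(
    len_x: int,
    len_y: int,
    band: BandSpec | int,
    bit_width: int | None = None,
) -> BooleanCircuit:
    """Compile the banded edit-distance DP over sequences of the given lengths.

    ``x`` (length ``len_x``) is the generator/data-owner input, ``y`` the
    evaluator/researcher input; both enter as 2 bits per nucleotide, high bit
    first.  The returned circuit's single output is the final DP cell, LSB
    first, ``bit_width`` wires wide.
    """
    if isinstance(band, int):
        band = BandSpec(band)
    needed = max(1, max(len_x, len_y).bit_length())
    if bit_width is None:
        bit_width = min_bit_width(len_x, len_y)
    if bit_width < needed:
        raise CircuitError(
            f"bit_width={bit_width} cannot hold distances up to "
            f"{max(len_x, len_y)} (need >= {needed})"
        )
    beff = band.effective(len_x, len_y)
    bd = CircuitBuilder()
    gen_wires = bd.inputs("generator", 2 * len_x)
    ev_wires = bd.inputs("evaluator", 2 * len_y)
    x = [(gen_wires[2 * i], gen_wires[2 * i + 1]) for i in range(len_x)]
    y = [(ev_wires[2 * j], ev_wires[2 * j + 1]) for j in range(len_y)]
    maxvec = bd.const_vec((1 << bit_width) - 1, bit_width)
    one = bd.const(1)

    def in_band(i: int, j: int) -> bool:
        return abs(i - j) <= beff

    # D[(i, j)] -> LSB-first wire vector, only for in-band cells
    D: dict[tuple[int, int], list[int]] = {}
    for j in range(0, min(len_y, beff) + 1):
        D[(0, j)] = bd.const_vec(j, bit_width)
    for i in range(1, len_x + 1):
        if in_band(i, 0):
            D[(i, 0)] = bd.const_vec(i, bit_width)
        for j in range(max(1, i - beff), min(len_y, i + beff) + 1):
            up = D[(i - 1, j)] if in_band(i - 1, j) else maxvec
            left = D[(i, j - 1)] if in_band(i, j - 1) else maxvec
            diag = D[(i - 1, j - 1)]  # always in-band when (i, j) is
            cost = bd.mismatch(x[i - 1], y[j - 1])
            cand = bd.min_vec(
                bd.add_bit_saturating(up, one), bd.add_bit_saturating(left, one)
            )
            D[(i, j)] = bd.min_vec(cand, bd.add_bit_saturating(diag, cost))
    bd.circuit.output_wires = list(D[(len_x, len_y)])
    bd.circuit.validate()
    return bd.circuit


def sequence_to_bits(residues: str) -> list[int]:
    """Flatten an ACGT string to circuit input bits, 2 per base, high bit first."""
    bits: list[int] = []
    for ch in residues:
        bits.extend(NUC_BITS[ch])
    return bits


def bits_to_int(bits: list[int]) -> int:
    """LSB-first bit list to integer (decoding of DP output wires)."""
    return sum(b << i for i, b in enumerate(bits))


def write_circuit(circuit: BooleanCircuit, path) -> None:
    """Text IR dump: one gate per line ``gate_id kind in1 in2 out``."""
    with open(path, "w") as fh:
        for role, wires in sorted(circuit.input_map.items()):
            fh.write(f"# input {role}: {' '.join(map(str, wires))}\n")
        for w, b in sorted(circuit.const_map.items()):
            fh.write(f"# const {w} = {b}\n")
        fh.write(f"# outputs: {' '.join(map(str, circuit.output_wires))}\n")
        for g in circuit.gates:
            fh.write(f"{g.gate_id} {g.kind} {g.in1} {g.in2} {g.out}\n")
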