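"""Yao garbled-circuit engine with oblivious transfer.

The data owner acts as circuit *generator*: it draws two random 128-bit labels
per wire (one meaning 0, one meaning 1), encrypts every row of every gate's
truth table under the pair of input labels that selects it, and sends the
garbled tables plus the labels for its own input bits.  The researcher acts as
*evaluator*: it obtains the labels for its own input bits through 1-out-of-2
oblivious transfer (so the generator never sees those bits), then walks the
circuit decrypting exactly one row per gate, and finally decodes the output
wires.  Row encryption is the textbook construction

    ciphertext = H(label_A || label_B || gate_id) XOR (output_label || 0^16)

with H = SHAKE-256; the 16 zero bytes are an explicit validity tag, and
point-and-permute (a random permute bit carried on every label) tells the
evaluator which single row to decrypt.  Free-XOR is available behind a flag
(default off): XOR gates then cost no table at all, all wire label pairs
differing by one global offset.

Oblivious transfer is the Diffie-Hellman construction of Bellare-Micali: the
receiver can form a valid public key for only one of the two branches, so it
can decrypt exactly one message while its single transmitted key is
statistically independent of the choice bit.
"""

from __future__ import annotations

import hashlib
import pickle
from dataclasses import dataclass

from . import _crypto
from ._crypto import Drbg, G2048, P2048
from .channel import Channel, DATA_OWNER, ProtocolAbort, RESEARCHER
from .circuits import (
    BooleanCircuit,
    CircuitError,
    bits_to_int,
    compile_banded_ed_circuit,
    min_bit_width,
    sequence_to_bits,
)
from .distance import BandSpec

KEY_BYTES = 16
LABEL_BYTES = KEY_BYTES + 1  # key || permute bit
TAG_BYTES = 16
ROW_BYTES = LABEL_BYTES + TAG_BYTES
_ZERO_TAG = b"\x00" * TAG_BYTES


class IntegrityError(RuntimeError):
    """No garbled row decrypted to a valid label (corrupted table or labels)."""


@dataclass(frozen=True)
class WireLabel:
    """One of the two random labels of a wire: 128-bit key plus permute bit."""

    key: bytes
    permute_bit: int

    def to_bytes(self) -> bytes:
        return self.key + bytes([self.permute_bit])

    @classmethod
    def from_bytes(cls, data: bytes) -> "WireLabel":
        if len(data) != LABEL_BYTES:
            raise ValueError("bad label encoding")
        return cls(key=data[:KEY_BYTES], permute_bit=data[KEY_BYTES])


@dataclass(frozen=True)
class GarbledGate:
    gate_kind: str
    input_wires: tuple[int, ...]
    output_wire: int
    table: tuple[bytes, ...]  # permuted ciphertexts; empty under free-XOR


@dataclass
class GarblingResult:
    garbled_gates: list[GarbledGate]
    input_labels: dict[int, tuple[WireLabel, WireLabel]]  # all input+const wires
    output_decode: dict[int, int]  # output wire -> permute bit of its 0-label
    free_xor: bool


def _row_pad(kind: str, gate_id: int, la: WireLabel, lb: WireLabel | None) -> bytes:
    material = la.key if lb is None else la.key + lb.key
    return hashlib.shake_256(
        b"privseq-gc\x00" + kind.encode() + gate_id.to_bytes(8, "big") + material
    ).digest(ROW_BYTES)


def _xor(a: bytes, b: bytes) -> bytes:
    return (int.from_bytes(a, "big") ^ int.from_bytes(b, "big")).to_bytes(
        len(a), "big"
    )


_OPS = {
    "AND": lambda a, b: a & b,
    "OR": lambda a, b: a | b,
    "XOR": lambda a, b: a ^ b,
}


def garble(
    circuit: BooleanCircuit, seed: int | None = None, free_xor: bool = False
) -> GarblingResult:
    """Garble a circuit: seeded label sampling, point-and-permute row order."""
    circuit.validate()
    rng = Drbg(seed, domain=b"garble")

    if free_xor:
        delta_key = rng.randbytes(KEY_BYTES)

    def fresh_pair() -> tuple[WireLabel, WireLabel]:
        k0 = rng.randbytes(KEY_BYTES)
        p0 = rng.randbit()
        if free_xor:
            return (
                WireLabel(k0, p0),
                WireLabel(_xor(k0, delta_key), p0 ^ 1),
            )
        return (WireLabel(k0, p0), WireLabel(rng.randbytes(KEY_BYTES), p0 ^ 1))

    labels: dict[int, tuple[WireLabel, WireLabel]] = {}
    for w in circuit.all_input_wires():
        labels[w] = fresh_pair()

    garbled: list[GarbledGate] = []
    for g in circuit.gates:
        if g.kind == "NOT":
            out_pair = fresh_pair()
            labels[g.out] = out_pair
            rows: list[bytes | None] = [None, None]
            for va in (0, 1):
                la = labels[g.in1][va]
                pad = _row_pad("NOT", g.gate_id, la, None)
                rows[la.permute_bit] = _xor(
                    pad, out_pair[1 - va].to_bytes() + _ZERO_TAG
                )
            garbled.append(GarbledGate("NOT", (g.in1,), g.out, tuple(rows)))
            continue
        if g.kind == "XOR" and free_xor:
            a0, _ = labels[g.in1]
            b0, _ = labels[g.in2]
            o0 = WireLabel(_xor(a0.key, b0.key), a0.permute_bit ^ b0.permute_bit)
            o1 = WireLabel(_xor(o0.key, delta_key), o0.permute_bit ^ 1)
            labels[g.out] = (o0, o1)
            garbled.append(GarbledGate("XOR", (g.in1, g.in2), g.out, ()))
            continue
        out_pair = fresh_pair()
        labels[g.out] = out_pair
        rows: list[bytes | None] = [None] * 4
        for va in (0, 1):
            for vb in (0, 1):
                la = labels[g.in1][va]
                lb = labels[g.in2][vb]
                out_label = out_pair[_OPS[g.kind](va, vb)]
                pad = _row_pad(g.kind, g.gate_id, la, lb)
                idx = 2 * la.permute_bit + lb.permute_bit
                rows[idx] = _xor(pad, out_label.to_bytes() + _ZERO_TAG)
        garbled.append(GarbledGate(g.kind, (g.in1, g.in2), g.out, tuple(rows)))

    input_labels = {w: labels[w] for w in circuit.all_input_wires()}
    output_decode = {w: labels[w][0].permute_bit for w in circuit.output_wires}
    return GarblingResult(garbled, input_labels, output_decode, free_xor)


def _decrypt_row(
    gate: GarbledGate, gate_id: int, la: WireLabel, lb: WireLabel | None, idx: int
) -> WireLabel | None:
    """Try one table row; None if the validity tag does not check out."""
    plain = _xor(_row_pad(gate.gate_kind, gate_id, la, lb), gate.table[idx])
    if plain[LABEL_BYTES:] != _ZERO_TAG:
        return None
    return WireLabel.from_bytes(plain[:LABEL_BYTES])


def evaluate(
    garbled_gates: list[GarbledGate],
    initial_labels: dict[int, WireLabel],
    output_wires: list[int],
    output_decode: dict[int, int],
    free_xor: bool = False,
    audit: dict | None = None,
) -> list[int]:
    """Evaluate a garbled circuit given one label per input wire.

    Decrypts the single row selected by the permute bits of the held labels and
    checks its validity tag.  With ``audit`` (a dict, mutated in place) it also
    counts, for every garbled gate, how many of the table rows decrypt validly
    with the held labels — the structural security property is that this count
    is exactly one — and records that no wire ever received two distinct labels.
    """
    wire_labels: dict[int, WireLabel] = {}

    def assign(wire: int, label: WireLabel) -> None:
        prev = wire_labels.get(wire)
        if prev is not None and prev != label:
            raise IntegrityError(f"wire {wire} received two distinct labels")
        wire_labels[wire] = label

    for w, lab in initial_labels.items():
        assign(w, lab)

    for gate_id, gate in enumerate(garbled_gates):
        if gate.gate_kind == "NOT":
            la = wire_labels[gate.input_wires[0]]
            out = _decrypt_row(gate, gate_id, la, None, la.permute_bit)
            if out is None:
                raise IntegrityError(
                    f"gate {gate_id} (NOT): selected row failed its validity tag"
                )
            if audit is not None:
                valid = sum(
                    _decrypt_row(gate, gate_id, la, None, i) is not None
                    for i in range(2)
                )
                audit.setdefault("rows_valid_per_gate", []).append(valid)
            assign(gate.output_wire, out)
            continue
        if gate.gate_kind == "XOR" and free_xor and not gate.table:
            la = wire_labels[gate.input_wires[0]]
            lb = wire_labels[gate.input_wires[1]]
            assign(
                gate.output_wire,
                WireLabel(_xor(la.key, lb.key), la.permute_bit ^ lb.permute_bit),
            )
            continue
        la = wire_labels[gate.input_wires[0]]
        lb = wire_labels[gate.input_wires[1]]
        idx = 2 * la.permute_bit + lb.permute_bit
        out = _decrypt_row(gate, gate_id, la, lb, idx)
        if out is None:
            raise IntegrityError(
                f"gate {gate_id} ({gate.gate_kind}): selected row failed its "
                "validity tag — corrupted table"
            )
        if audit is not None:
            valid = sum(
                _decrypt_row(gate, gate_id, la, lb, i) is not None for i in range(4)
            )
            audit.setdefault("rows_valid_per_gate", []).append(valid)
        assign(gate.output_wire, out)

    if audit is not None:
        audit["wires_single_label"] = True  # assign() would have raised otherwise
    return [
        wire_labels[w].permute_bit ^ output_decode[w] for w in output_wires
    ]


# ------------------------------------------------------------ oblivious transfer


def _batch_ot_send_recv(
    pairs: list[tuple[bytes, bytes]],
    choice_bits: list[int],
    channel: Channel,
    sender_rng: Drbg,
    receiver_rng: Drbg,
    sender_role: str = DATA_OWNER,
) -> list[bytes]:
    """Run n independent 1-out-of-2 OTs over the channel (both roles in-process)."""
    receiver_role = RESEARCHER if sender_role == DATA_OWNER else DATA_OWNER
    for m0, m1 in pairs:
        if len(m0) != len(m1):
            raise ProtocolAbort("OT messages must have equal length")
    # sender: one random group element c, reused across the batch
    c = pow(G2048, _crypto.rand_scalar(sender_rng), P2048)
    channel.send(sender_role, _crypto.element_to_bytes(c))
    c = _crypto.bytes_to_element(channel.recv(receiver_role))

    # receiver: one keypair per OT; the other branch's key is c / g^k
    ks = [_crypto.rand_scalar(receiver_rng) for _ in pairs]
    pk0s = []
    for k, sigma in zip(ks, choice_bits):
        pk_sigma = pow(G2048, k, P2048)
        pk0 = pk_sigma if sigma == 0 else (c * _crypto.mod_inverse(pk_sigma)) % P2048
        pk0s.append(_crypto.element_to_bytes(pk0))
    channel.send(receiver_role, b"".join(pk0s))

    # sender: encrypt each branch under an ephemeral DH with the branch key
    blob = channel.recv(sender_role)
    if len(blob) != len(pairs) * _crypto.ELEMENT_BYTES:
        raise ProtocolAbort("OT receiver keys malformed", len(channel.transcript))
    out_parts = []
    for i, (m0, m1) in enumerate(pairs):
        pk0 = _crypto.bytes_to_element(
            blob[i * _crypto.ELEMENT_BYTES : (i + 1) * _crypto.ELEMENT_BYTES]
        )
        pk1 = (c * _crypto.mod_inverse(pk0)) % P2048
        for b, (pk, m) in enumerate(((pk0, m0), (pk1, m1))):
            r = _crypto.rand_scalar(sender_rng)
            gr = pow(G2048, r, P2048)
            pad = _crypto.kdf(
                _crypto.element_to_bytes(pow(pk, r, P2048))
                + i.to_bytes(4, "big")
                + bytes([b]),
                len(m),
                domain=b"ot",
            )
            out_parts.append(_crypto.element_to_bytes(gr))
            out_parts.append(len(m).to_bytes(4, "big"))
            out_parts.append(_crypto.xor_bytes(pad, m))
    channel.send(sender_role, b"".join(out_parts))

    # receiver: decrypt the chosen branch of each OT
    blob = channel.recv(receiver_role)
    results = []
    off = 0
    for i, sigma in enumerate(choice_bits):
        branches = []
        for b in range(2):
            gr = _crypto.bytes_to_element(blob[off : off + _crypto.ELEMENT_BYTES])
            off += _crypto.ELEMENT_BYTES
            ln = int.from_bytes(blob[off : off + 4], "big")
            off += 4
            ct = blob[off : off + ln]
            off += ln
            branches.append((gr, ct))
        gr, ct = branches[sigma]
        pad = _crypto.kdf(
            _crypto.element_to_bytes(pow(gr, ks[i], P2048))
            + i.to_bytes(4, "big")
            + bytes([sigma]),
            len(ct),
            domain=b"ot",
        )
        results.append(_crypto.xor_bytes(pad, ct))
    return results


def oblivious_transfer(
    sender_msgs: tuple[bytes, bytes],
    choice_bit: int,
    channel: Channel | None = None,
    seed: int | None = None,
) -> bytes:
    """1-out-of-2 OT: the receiver obtains exactly ``sender_msgs[choice_bit]``;
    the sender's transcript is independent of the choice bit."""
    if choice_bit not in (0, 1):
        raise ValueError("choice bit must be 0 or 1")
    if channel is None:
        channel = Channel()
    root = Drbg(seed, domain=b"ot")
    return _batch_ot_send_recv(
        [tuple(sender_msgs)],
        [choice_bit],
        channel,
        root.spawn(b"sender"),
        root.spawn(b"receiver"),
    )[0]


# ------------------------------------------------------ secure banded distance


@dataclass(frozen=True)
class SecureDistanceOutput:
    """Distance decoded from the circuit's output wires."""

    distance: int
    bit_width: int

    def __post_init__(self):
        if not (0 <= self.distance < 2**self.bit_width):
            raise ValueError("decoded distance out of range for bit width")


def secure_banded_distance(
    owner_seq: str,
    researcher_seq: str,
    band: BandSpec | int,
    channel: Channel | None = None,
    seed: int | None = None,
    bit_width: int | None = None,
    free_xor: bool = False,
    audit: dict | None = None,
) -> SecureDistanceOutput:
    """Banded edit distance computed entirely inside one garbled circuit.

    Sequence lengths and the band are public protocol parameters (the circuit
    topology necessarily reveals them); only the residues are private.  The
    data owner garbles, the researcher evaluates after fetching its input
    labels by oblivious transfer, and the decoded distance equals
    :func:`privseq.distance.banded_edit_distance` on the same inputs.
    """
    if isinstance(band, int):
        band = BandSpec(band)
    if channel is None:
        channel = Channel()
    if bit_width is None:
        bit_width = min_bit_width(len(owner_seq), len(researcher_seq))
    circuit = compile_banded_ed_circuit(
        len(owner_seq), len(researcher_seq), band, bit_width
    )
    root = Drbg(seed, domain=b"secure-banded")

    # --- generator (data owner) side
    garbling = garble(circuit, seed=seed, free_xor=free_xor)
    gen_bits = sequence_to_bits(owner_seq)
    gen_wires = circuit.input_map.get("generator", [])
    active = {
        w: garbling.input_labels[w][bit].to_bytes()
        for w, bit in zip(gen_wires, gen_bits, strict=True)
    }
    for w, bit in circuit.const_map.items():
        active[w] = garbling.input_labels[w][bit].to_bytes()
    gates_wire = [
        (g.gate_kind, g.input_wires, g.output_wire, g.table)
        for g in garbling.garbled_gates
    ]

    # --- evaluator (researcher) obtains its labels by OT first
    ev_bits = sequence_to_bits(researcher_seq)
    ev_wires = circuit.input_map.get("evaluator", [])
    if len(ev_bits) != len(ev_wires):
        raise CircuitError("evaluator input width mismatch")
    pairs = [
        (
            garbling.input_labels[w][0].to_bytes(),
            garbling.input_labels[w][1].to_bytes(),
        )
        for w in ev_wires
    ]
    ot_results = (
        _batch_ot_send_recv(
            pairs,
            ev_bits,
            channel,
            root.spawn(b"ot-sender"),
            root.spawn(b"ot-receiver"),
        )
        if pairs
        else []
    )

    # --- generator ships tables, its active input labels, and the decode map
    channel.send(
        DATA_OWNER,
        pickle.dumps(
            (gates_wire, active, circuit.output_wires, garbling.output_decode),
            protocol=pickle.HIGHEST_PROTOCOL,
        ),
    )

    # --- evaluator decrypts gate by gate and decodes
    payload = pickle.loads(channel.recv(RESEARCHER))
    gates_raw, active_raw, output_wires, output_decode = payload
    ggates = [GarbledGate(*g) for g in gates_raw]
    initial = {w: WireLabel.from_bytes(lb) for w, lb in active_raw.items()}
    for w, lab in zip(ev_wires, ot_results):
        initial[w] = WireLabel.from_bytes(lab)
    out_bits = evaluate(
        ggates, initial, output_wires, output_decode, free_xor=free_xor, audit=audit
    )
    distance = bits_to_int(out_bits)
    channel.send(RESEARCHER, distance.to_bytes(8, "big"))  # owner learns it too
    return SecureDistanceOutput(distance=distance, bit_width=bit_width)
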