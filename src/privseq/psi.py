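"""Two-party private set intersection over shingle sets.

Two instantiations with the same interface and output contract:

* :func:`psi_dh` — Diffie-Hellman commutative blinding.  Each element is hashed
  to a group element which both parties exponentiate with their secret scalar;
  equality of the doubly-blinded values reveals membership and nothing else
  (one-more-DH style, semi-honest).  The data owner learns the intersection.

* :func:`psi_naive_hash` — salted-hash exchange.  Functionally identical output
  but insecure for a small element space: an adversary who knows the salt can
  enumerate all 4^w shingles and invert the hashes.
  :func:`brute_force_hashed_set` demonstrates exactly that attack.

Both run over a :class:`~privseq.channel.Channel` so tests can audit the
transcript: the researcher's messages in the DH protocol never contain any
plaintext shingle.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

from . import _crypto
from ._crypto import Drbg, P2048
from .channel import Channel, DATA_OWNER, ProtocolAbort, RESEARCHER
from .shingles import ShingleSet


@dataclass(frozen=True)
class PsiResult:
    """Outcome of a PSI run: the intersection, learned by the data owner."""

    intersection: ShingleSet
    learned_by: str
    metadata: dict = field(default_factory=dict)


def _check_widths(researcher_set: ShingleSet, owner_set: ShingleSet) -> None:
    if researcher_set.w != owner_set.w:
        raise ProtocolAbort(
            f"shingle width mismatch: researcher w={researcher_set.w}, "
            f"owner w={owner_set.w}"
        )


def _pack(elements: list[bytes]) -> bytes:
    out = [len(elements).to_bytes(4, "big")]
    for e in elements:
        out.append(len(e).to_bytes(4, "big"))
        out.append(e)
    return b"".join(out)


def _unpack(payload: bytes, position: int) -> list[bytes]:
    try:
        count = int.from_bytes(payload[:4], "big")
        off = 4
        items = []
        for _ in range(count):
            ln = int.from_bytes(payload[off : off + 4], "big")
            off += 4
            if off + ln > len(payload):
                raise ValueError("truncated element")
            items.append(payload[off : off + ln])
            off += ln
        if off != len(payload):
            raise ValueError("trailing bytes")
        return items
    except Exception as exc:
        raise ProtocolAbort(f"malformed PSI message: {exc}", position) from exc


def psi_dh(
    researcher_set: ShingleSet,
    owner_set: ShingleSet,
    channel: Channel | None = None,
    seed: int | None = None,
) -> PsiResult:
    """DH-based PSI: the data owner learns exactly the plaintext intersection.

    Flow (all elements as group members g^H(x) mod p):

    1. researcher blinds its elements with secret a and sends them shuffled;
    2. owner raises them to its secret b, keeping the set {g^{H(x)ab}};
    3. owner sends its own elements blinded with b, in an order it remembers;
    4. researcher raises those to a and returns them in the same order;
    5. owner marks element j as shared iff its doubly-blinded value landed in
       the set from step 2.

    ``seed`` drives both parties' secret scalars and the shuffle (tests);
    ``seed=None`` uses OS entropy.
    """
    _check_widths(researcher_set, owner_set)
    if channel is None:
        channel = Channel()
    root = Drbg(seed, domain=b"psi-dh")
    r_rng, o_rng = root.spawn(b"researcher"), root.spawn(b"owner")

    # researcher
    a = _crypto.rand_scalar(r_rng)
    r_elems = sorted(researcher_set.items)
    r_rng.shuffle(r_elems)
    blinded = [
        _crypto.element_to_bytes(pow(_crypto.hash_to_element(e.encode()), a, P2048))
        for e in r_elems
    ]
    channel.send(RESEARCHER, _pack(blinded))

    # owner: double-blind the researcher's elements
    b = _crypto.rand_scalar(o_rng)
    pos = len(channel.transcript)
    researcher_ab = {
        _crypto.element_to_bytes(pow(_crypto.bytes_to_element(x), b, P2048))
        for x in _unpack(channel.recv(DATA_OWNER), pos)
    }
    # owner blinds its own elements (order retained locally)
    o_elems = sorted(owner_set.items)
    owner_b = [
        _crypto.element_to_bytes(pow(_crypto.hash_to_element(e.encode()), b, P2048))
        for e in o_elems
    ]
    channel.send(DATA_OWNER, _pack(owner_b))

    # researcher raises the owner's blinded elements to a, same order
    pos = len(channel.transcript)
    owner_ab = [
        _crypto.element_to_bytes(pow(_crypto.bytes_to_element(x), a, P2048))
        for x in _unpack(channel.recv(RESEARCHER), pos)
    ]
    channel.send(RESEARCHER, _pack(owner_ab))

    # owner matches doubly-blinded values
    pos = len(channel.transcript)
    owner_ab_recv = _unpack(channel.recv(DATA_OWNER), pos)
    if len(owner_ab_recv) != len(o_elems):
        raise ProtocolAbort("owner element count changed in transit", pos)
    intersection = {
        e for e, xab in zip(o_elems, owner_ab_recv) if xab in researcher_ab
    }
    return PsiResult(
        intersection=ShingleSet(owner_set.w, intersection),
        learned_by=DATA_OWNER,
        metadata={"protocol": "dh", "secure": True},
    )


def _salted_hash(salt: bytes, element: str) -> bytes:
    return hashlib.sha256(salt + element.encode()).digest()


def psi_naive_hash(
    researcher_set: ShingleSet,
    owner_set: ShingleSet,
    channel: Channel | None = None,
    seed: int | None = None,
) -> PsiResult:
    """Salted-hash PSI baseline: correct but brute-forceable over small w.

    The result metadata carries ``secure: False`` — over a w-shingle universe of
    size 4^w anyone holding the salt can enumerate every candidate shingle and
    recover the hashed set (see :func:`brute_force_hashed_set`).
    """
    _check_widths(researcher_set, owner_set)
    if channel is None:
        channel = Channel()
    rng = Drbg(seed, domain=b"psi-naive")
    salt = rng.randbytes(16)
    hashed = sorted(_salted_hash(salt, e) for e in researcher_set.items)
    channel.send(RESEARCHER, _pack([salt]) + _pack(hashed))

    pos = len(channel.transcript)
    payload = channel.recv(DATA_OWNER)
    salt_part = _unpack(payload[: 4 + 4 + 16], pos)
    if len(salt_part) != 1 or len(salt_part[0]) != 16:
        raise ProtocolAbort("malformed salt", pos)
    recv_salt = salt_part[0]
    recv_hashes = set(_unpack(payload[4 + 4 + 16 :], pos))
    intersection = {
        e for e in owner_set.items if _salted_hash(recv_salt, e) in recv_hashes
    }
    return PsiResult(
        intersection=ShingleSet(owner_set.w, intersection),
        learned_by=DATA_OWNER,
        metadata={
            "protocol": "naive_hash",
            "secure": False,
            "warning": "salted-hash PSI is brute-forceable over the 4^w shingle space",
        },
    )


def brute_force_hashed_set(salt: bytes, hashed_set: set[bytes], w: int) -> ShingleSet:
    """Recover a salted-hashed shingle set by enumerating all 4^w candidates.

    This is the attack that rules the naive-hash protocol out: with the salt
    public on the wire, the whole shingle universe is searchable.
    """
    alphabet = "ACGT"
    recovered = set()

    def rec(prefix: str):
        if len(prefix) == w:
            if _salted_hash(salt, prefix) in hashed_set:
                recovered.add(prefix)
            return
        for c in alphabet:
            rec(prefix + c)

    rec("")
    return ShingleSet(w, recovered)
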