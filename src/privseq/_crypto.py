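"""Low-level cryptographic primitives shared by the PSI and garbled-circuit protocols.

Everything here is built from the standard library: SHA-256 / SHAKE-256 from
:mod:`hashlib`, OS entropy from :mod:`secrets`, and modular exponentiation via
:func:`pow`.  The group is the 2048-bit MODP safe-prime group from RFC 3526
(group 14); protocol elements live in its prime-order subgroup of quadratic
residues, reached by hashing set elements to exponents of the generator.
"""

from __future__ import annotations

import hashlib
import secrets

# RFC 3526, 2048-bit MODP group (group 14): p = 2^2048 - 2^1984 - 1 + 2^64 * ( [2^1918 pi] + 124476 )
P2048 = int(
    "FFFFFFFFFFFFFFFFC90FDAA22168C234C4C6628B80DC1CD129024E088A67CC74"
    "020BBEA63B139B22514A08798E3404DDEF9519B3CD3A431B302B0A6DF25F1437"
    "4FE1356D6D51C245E485B576625E7EC6F44C42E9A637ED6B0BFF5CB6F406B7ED"
    "EE386BFB5A899FA5AE9F24117C4B1FE649286651ECE45B3DC2007CB8A163BF05"
    "98DA48361C55D39A69163FA8FD24CF5F83655D23DCA3AD961C62F356208552BB"
    "9ED529077096966D670C354E4ABC9804F1746C08CA18217C32905E462E36CE3B"
    "E39E772C180E86039B2783A2EC07A28FB5C55DF06F4C52C9DE2BCBF695581718"
    "3995497CEA956AE515D2261898FA051015728E5A8AACAA68FFFFFFFFFFFFFFFF",
    16,
)
G2048 = 2
# order of the quadratic-residue subgroup of a safe prime
Q2048 = (P2048 - 1) // 2

ELEMENT_BYTES = 256  # fixed wire encoding of a group element
SCALAR_BITS = 256  # short-exponent DH; standard for 2048-bit MODP


class Drbg:
    """Deterministic byte generator: SHA-256 in counter mode over a seed.

    Used wherever a protocol party needs reproducible randomness under an
    explicit test seed.  With ``seed=None`` it draws a fresh seed from the OS,
    so unseeded runs are indistinguishable from using :mod:`secrets` directly.
    """

    def __init__(self, seed: bytes | int | None = None, domain: bytes = b""):
        if seed is None:
            seed = secrets.token_bytes(32)
        elif isinstance(seed, int):
            seed = seed.to_bytes(16, "big", signed=True)
        self._key = hashlib.sha256(b"privseq-drbg\x00" + domain + b"\x00" + seed).digest()
        self._counter = 0
        self._buf = b""

    def randbytes(self, n: int) -> bytes:
        while len(self._buf) < n:
            block = hashlib.sha256(self._key + self._counter.to_bytes(8, "big")).digest()
            self._counter += 1
            self._buf += block
        out, self._buf = self._buf[:n], self._buf[n:]
        return out

    def randbits(self, k: int) -> int:
        nbytes = (k + 7) // 8
        val = int.from_bytes(self.randbytes(nbytes), "big")
        return val >> (nbytes * 8 - k)

    def randbelow(self, n: int) -> int:
        # rejection sampling, unbiased
        k = n.bit_length()
        while True:
            r = self.randbits(k)
            if r < n:
                return r

    def randbit(self) -> int:
        return self.randbytes(1)[0] & 1

    def shuffle(self, items: list) -> None:
        for i in range(len(items) - 1, 0, -1):
            j = self.randbelow(i + 1)
            items[i], items[j] = items[j], items[i]

    def spawn(self, domain: bytes) -> "Drbg":
        child = Drbg.__new__(Drbg)
        child._key = hashlib.sha256(self._key + b"\x00spawn\x00" + domain).digest()
        child._counter = 0
        child._buf = b""
        return child


def rand_scalar(rng: Drbg) -> int:
    """Random secret exponent in [1, 2^256): short-exponent DH in the QR subgroup."""
    return rng.randbits(SCALAR_BITS) | 1


def hash_to_exponent(data: bytes, domain: bytes = b"h2e") -> int:
    """Map arbitrary bytes to a 256-bit exponent, giving the element g^H(x).

    Short exponents (like the secret scalars) keep the per-element cost of the
    commutative blinding at a few hundred microseconds.
    """
    d = hashlib.shake_256(domain + b"\x00" + data).digest(SCALAR_BITS // 8)
    return int.from_bytes(d, "big")


def hash_to_element(data: bytes, domain: bytes = b"h2e") -> int:
    return pow(G2048, hash_to_exponent(data, domain), P2048)


def element_to_bytes(e: int) -> bytes:
    return e.to_bytes(ELEMENT_BYTES, "big")


def bytes_to_element(b: bytes) -> int:
    if len(b) != ELEMENT_BYTES:
        raise ValueError(f"group element must be {ELEMENT_BYTES} bytes, got {len(b)}")
    return int.from_bytes(b, "big")


def mod_inverse(x: int) -> int:
    return pow(x, P2048 - 2, P2048)


def kdf(key_material: bytes, n: int, domain: bytes = b"kdf") -> bytes:
    """Derive an n-byte one-time pad from DH shared material."""
    return hashlib.shake_256(domain + b"\x00" + key_material).digest(n)


def xor_bytes(a: bytes, b: bytes) -> bytes:
    return bytes(x ^ y for x, y in zip(a, b, strict=True))
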