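"""Plaintext edit-distance kernels: exact Wagner-Fischer and the banded variant.

The exact kernel is the unit-cost Levenshtein dynamic programme over the
(|x|+1) x (|y|+1) matrix.  The banded kernel restricts the DP to cells within a
half-width ``b`` of the main diagonal (the Ukkonen band); out-of-band cells are
treated as +infinity, which makes the banded value an upper bound on the exact
distance that collapses to equality once the band covers the whole matrix.

For unequal lengths the band is widened to ``b_eff = max(b, ||x|-|y||)`` so the
terminal cell is always reachable and every pair gets a finite, rankable value.

Both kernels keep only a rolling row (O(min length) memory) and vectorise the
row update with numpy.  The within-row dependency D[i][j-1] is resolved by a
prefix-minimum: D[i][j] = min_{j' <= j} (m[j'] + (j - j')) where m holds the
diagonal/vertical candidates, computed as a cumulative minimum of m[j'] - j'.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .seqdata import NucleotideSequence, SequenceDataset, encode_residues

_INF = np.int64(1) << 40


@dataclass(frozen=True)
class BandSpec:
    """Band half-width around the main diagonal; cells with |i-j| <= b are kept."""

    b: int

    def __post_init__(self):
        if self.b < 0:
            raise ValueError("band half-width must be >= 0")

    def effective(self, len_x: int, len_y: int) -> int:
        """Widen the band to the length difference so the end cell is in-band."""
        return max(self.b, abs(len_x - len_y))


@dataclass(frozen=True)
class DistanceResult:
    record_id: str
    distance: int
    method: str  # "exact" or "banded"

    def __post_init__(self):
        if self.distance < 0:
            raise ValueError("distance must be non-negative")
        if self.method not in ("exact", "banded"):
            raise ValueError(f"unknown method {self.method!r}")


def edit_distance(x: str, y: str) -> int:
    """Unit-cost Levenshtein distance between two ACGT strings (empty allowed)."""
    if len(x) == 0:
        return len(y)
    if len(y) == 0:
        return len(x)
    a = encode_residues(x)
    b = encode_residues(y)
    n = len(b)
    js = np.arange(n + 1, dtype=np.int64)
    prev = js.copy()
    f = np.empty(n + 1, dtype=np.int64)
    for i in range(1, len(a) + 1):
        np.minimum(prev[:-1] + (a[i - 1] != b), prev[1:] + 1, out=f[1:])
        f[0] = i
        f -= js
        np.minimum.accumulate(f, out=f)
        f += js
        prev, f = f, prev
    return int(prev[n])


def banded_edit_distance(x: str, y: str, band: BandSpec | int) -> int:
    """Edit distance restricted to the diagonal band |i-j| <= max(b, ||x|-|y||).

    Upper-bounds :func:`edit_distance` and equals it when the band covers the
    full matrix (b >= max(|x|, |y|)).
    """
    if isinstance(band, int):
        band = BandSpec(band)
    m, n = len(x), len(y)
    if m == 0:
        return n
    if n == 0:
        return m
    beff = band.effective(m, n)
    a = encode_residues(x)
    bb = encode_residues(y)
    # row i covers columns [max(0, i-beff), min(n, i+beff)]
    plo, phi = 0, min(n, beff)
    prev = np.arange(plo, phi + 1, dtype=np.int64)
    for i in range(1, m + 1):
        lo, hi = max(0, i - beff), min(n, i + beff)
        width = hi - lo + 1
        js = np.arange(lo, hi + 1, dtype=np.int64)
        up = np.full(width, _INF, dtype=np.int64)
        diag = np.full(width, _INF, dtype=np.int64)
        s, e = max(lo, plo), min(hi, phi)
        if s <= e:  # vertical neighbours prev[j]
            up[s - lo : e - lo + 1] = prev[s - plo : e - plo + 1]
        s, e = max(lo, plo + 1), min(hi, phi + 1)
        if s <= e:  # diagonal neighbours prev[j-1]
            diag[s - lo : e - lo + 1] = prev[s - 1 - plo : e - plo]
        f = np.full(width, _INF, dtype=np.int64)
        j0 = 1 if lo == 0 else 0  # position of the first j >= 1 cell
        cost = (bb[js[j0:] - 1] != a[i - 1]).astype(np.int64)
        f[j0:] = np.minimum(up[j0:] + 1, diag[j0:] + cost)
        if lo == 0:
            f[0] = i  # boundary D[i][0], in-band because i <= beff here
        f -= js
        np.minimum.accumulate(f, out=f)
        f += js
        prev, plo, phi = f, lo, hi
    return int(prev[-1])  # cell (m, n); in-band since beff >= |m-n|


def distance_matrix(
    dataset: SequenceDataset | Iterable[NucleotideSequence],
    query: NucleotideSequence | str,
    method: str = "exact",
    band: BandSpec | int | None = None,
) -> list[DistanceResult]:
    """Distance of the query to every record, order preserved."""
    if method not in ("exact", "banded"):
        raise ValueError(f"unknown method {method!r}")
    if method == "banded" and band is None:
        raise ValueError("banded method requires a band")
    q = query.residues if isinstance(query, NucleotideSequence) else query
    results = []
    for rec in dataset:
        if method == "exact":
            d = edit_distance(rec.residues, q)
        else:
            d = banded_edit_distance(rec.residues, q, band)
        results.append(DistanceResult(rec.id, d, method))
    return results
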