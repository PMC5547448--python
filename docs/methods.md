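# Methods

## Problem setting

A data owner holds n genomic sequences over Σ = {A, C, G, T}; a researcher
holds one query sequence. A top-k similar-patient query returns the k records
with the smallest unit-cost Levenshtein distance to the query. Both inputs are
private: the owner must not see the query, the researcher must not see the
collection beyond the answer. The threat model is semi-honest throughout —
both parties follow the protocols but may inspect their views.

## Exact and banded edit distance

The exact kernel is the Wagner–Fischer dynamic programme over the
(|x|+1)×(|y|+1) matrix with unit costs for insertion, deletion and
substitution and zero cost for a match. The banded kernel keeps only cells
within a half-width b of the main diagonal ("band" = half-width, the
convention of the banded-alignment literature); out-of-band cells are +∞. For
unequal lengths the band is widened to b_eff = max(b, ||x|−|y||), the minimal
band in which the terminal cell is reachable, so every pair receives a finite,
rankable value rather than a sentinel. Consequences used by the tests:
banded(x, y, b) ≥ d(x, y), monotone non-increasing in b, with equality once
b ≥ max(|x|, |y|).

Both kernels are numpy row-vectorised with O(min length) memory. The
within-row dependency D[i][j] = min(…, D[i][j−1]+1) is resolved by a prefix
minimum over m[j′] − j′ (then adding j back), which makes each row one
cumulative-minimum pass instead of a Python loop. The banded kernel carries
only the in-band window of each row; the window is contiguous, so horizontal
propagation never crosses an out-of-band cell. A dense DP with out-of-band
cells pinned to +∞ serves as the test oracle for the windowed code, and an
exhaustive memo-free recursion over all edit sequences serves as the oracle
for Wagner–Fischer at tiny lengths (edlib provides an additional independent
cross-check in the tests).

## Shingling

The w-shingle set of a sequence is the set of its distinct length-w substrings
(set, not bag, semantics: repeats carry no weight). Records shorter than w are
an error rather than an empty set — a silently empty set would zero the
record's similarity and corrupt the ranking. The default width is
w = ⌈log₄ l⌉ for query length l, computed in exact integer arithmetic;
rounding *up* because smaller widths make matches too common and inflate false
positives. The shingle space is bounded by 4^w, so the owner's union database
stores at most 4^w strings of w bytes; `shingle_space_stats` reports the
unique count, the 4^w bound and the byte cost, and the database is persisted
as sorted plain text so the accounting is auditable.

## Private set intersection

One PSI runs per query, between the query's shingle set and the owner's
*union* database; the owner then counts each record's matches with the
intersection locally. (Running PSI once against the union, rather than per
record, is what the global shingle-database accounting implies; per-record
counting is local to the owner either way.)

The secure instantiation is Diffie–Hellman commutative blinding in the
quadratic-residue subgroup of the RFC 3526 2048-bit safe prime: element x maps
to g^H(x), each party exponentiates with its secret scalar, and equality of
the doubly-blinded values reveals membership only. The owner learns the
intersection (it must rank its records); the researcher learns nothing but set
sizes. Secret scalars and hash exponents are 256-bit (standard short-exponent
DH), keeping each blinding at a few hundred microseconds. The insecure
baseline — a salted-hash exchange — is implemented for comparison and flagged
`secure: False`: over a 4^w universe anyone holding the salt can enumerate all
candidate shingles and invert the hashes, and `brute_force_hashed_set`
demonstrates exactly that attack. Both protocols run over an in-process
`Channel` whose append-only transcript lets tests assert that no plaintext
shingle ever crosses the wire.

## Garbled-circuit banded distance

The entire banded DP is compiled into one Boolean circuit and evaluated in a
single garbled execution, so nothing but the final distance is revealed.
Evaluating per-cell comparisons under separate secure computations would leak:
with only four residue values per position, either party could probe positions
exhaustively.

Circuit conventions (fixed for bit-exact interoperability):

- nucleotides enter as 2 bits, A=00, C=01, G=10, T=11, high bit first;
- DP values are unsigned, LSB-first, `bit_width = ⌈log₂(max_len+1)⌉ + 1` bits
  by default — one headroom bit above any real distance;
- out-of-band neighbours are the all-ones constant 2^bit_width − 1, and the
  +1/+cost adders *saturate* at all-ones, realising +∞ in finite width
  (all-ones + 1 would otherwise wrap to 0 and corrupt the minimum);
- per in-band cell: a 2-bit mismatch gadget, three saturating bit-serial
  adders, and two minimum gadgets (ripple comparator + XOR-mux);
- sequence lengths and the band are public protocol parameters — the circuit
  topology necessarily reveals them; only residues are private.

Garbling is the textbook scheme with point-and-permute: two random 128-bit
labels per wire carrying complementary permute bits; each truth-table row is
encrypted as `SHAKE-256(label_A ‖ label_B ‖ gate_id) XOR (output_label ‖ 0^16)`
with the 16 zero bytes as an explicit validity tag, rows ordered by the
permute bits. The evaluator decrypts exactly the indicated row; an audit mode
counts, per gate, how many rows decrypt validly (the structural invariant is
exactly one) and verifies no wire ever receives two distinct labels. Free-XOR
is available behind a flag (default off, since no particular optimisation
stack is assumed); the test suite checks it changes no output. The data owner
plays generator, the researcher evaluator; the researcher's input labels are
fetched with Bellare–Micali 1-out-of-2 oblivious transfer over the same MODP
group (the receiver can form a valid key for only one branch; its single
transmitted key is independent of the choice bit). The decoded distance equals
the plaintext banded kernel on all inputs — this equivalence, on randomised
suites, is the core correctness surface of the module.

## Joined cascade and ties

Stage 1 ranks by shingle matches and hands **exactly t = c·k** survivors to
stage 2 (ties at the rank-t boundary broken by record id); stage 2 ranks only
the survivors by banded distance and returns the final top-k. Truncating at t,
rather than tie-expanding, keeps the stage-2 cost at exactly t garbled
evaluations and makes the survivor count a checkable constant; the final
result is contained in the survivor set by construction. Final rankings —
exact, approx1, approx2 and joined — *do* tie-expand at rank k: every record
tied with the rank-k score is returned, with record id as deterministic
secondary order. Accuracy is recall against the tie-expanded exact truth set:
N_TP/(N_TP+N_FN) with the truth-set size as denominator.

The cascade factor c stays a user parameter (default 5, as in the benchmark
configuration k=10, c=5, w=10, b=5): no closed-form rule for it is claimed, it
trades accuracy against stage-2 cost.

## Synthetic data

`synthetic_frequency_table` emulates accumulated population allele
frequencies: each site is biallelic with a uniformly chosen major/minor pair
and minor-allele frequency ~ U(0.01, 0.5). `generate_dataset` draws every
sequence independently, site s from the site-s vector, at fixed length = table
size; `perturb_lengths` then applies U{0..max_indels} random single-base
indels per record. Separating sampling from length perturbation keeps the
sampler exactly i.i.d. per column. Two cohort profiles mirror the evaluation
settings this package targets: 500 records × length 3400–3500 with one query,
and 2000 records × length 9000–10000 with 50 held-out queries (9500 sites,
up to 500 indels, so lengths stay inside the stated range).

What the generator does *not* emulate: linkage disequilibrium between sites,
population substructure, genotyping error, and the long shared haplotype runs
of real cohorts. Real genomes repeat far more than i.i.d. draws, so real
shingle databases stay well below the 4^w bound while synthetic ones nearly
saturate it; passing accuracy tests on synthetic corpora therefore shows the
machinery ranks correctly under the stated model, not that shingle matching
attains any particular accuracy on real data.

## Problem sizes in the shipped checks

The randomised equivalence suites use lengths ≤ 20 with b ∈ {0, 1, 3} for the
garbled path (100 pairs), 200 pairs at lengths ≤ 30 for band/exact agreement,
and all 63² pairs of length ≤ 5 strings over a two-letter alphabet against the
exhaustive-recursion oracle. PSI correctness runs 1000 random set pairs
through both protocols. The accuracy properties use 20 seeded corpora of
n = 200 records × length 1000 with k = 10, w = 10, b = 5 and
c ∈ {1, 2, 5, 10} — large enough for the c-trend and the
full-band-equals-exact property to be stable, small enough to re-run routinely
— and the cascade arithmetic is additionally exercised once at the full
n = 2000 × length 9000–10000 profile.

## Known limitations

- Semi-honest security only; no malicious-model hardening (cut-and-choose,
  authenticated garbling) and no half-gates optimisation.
- The DH-PSI and OT run over a 2048-bit MODP group; an elliptic-curve group
  would shrink transcripts and cost but is not provided.
- Both parties run in one process over the `Channel` abstraction; correctness
  is transport-independent, a TCP transport would slot behind the same
  interface.
- The banded kernel widens the band to the length difference; pairs with very
  different lengths are effectively compared at a larger band than requested.
- Whether a protocol's returned top-k payload is identifiers only or includes
  residues is a policy choice; the CLI releases identifiers by default and
  sequences only behind `--release-sequences`.
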