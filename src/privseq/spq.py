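"""Similar Patients Query engine: exact baseline, both approximations, and the
joined cascade, plus the tie-aware recall metric used to score them.

A top-k query retrieves the k dataset records with the lowest edit distance to
the researcher's query sequence.  The exact baseline ranks by Wagner-Fischer
distance.  Approximation 1 ranks by shingle matches: the researcher's query
shingles are intersected (via PSI) with the owner's union shingle database
once, and the owner then counts, per record, how many of its shingles fall in
that intersection — more matches, more similar.  Approximation 2 ranks by
banded edit distance, evaluated either in plaintext or inside the garbled
circuit (identical results by construction).  The joined cascade runs
approximation 1 first to select t = c*k survivors, then re-ranks only those
with the banded distance, trading a little accuracy for a much smaller number
of expensive secure comparisons.

Ties: every ranked output includes all records tied with the rank-k score
(so the returned set can exceed k), with record id as the deterministic
secondary order.  Stage 1 of the cascade is the exception: it hands exactly t
survivors to stage 2, breaking boundary ties by record id, so the cascade's
cost is exactly t secure comparisons.

Accuracy is recall against the tie-expanded exact truth set:
N_TP / (N_TP + N_FN) where N_TP counts predicted records that appear in the
truth set and the denominator is the truth-set size.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .channel import Channel
from .distance import BandSpec, banded_edit_distance, edit_distance
from .mpc import secure_banded_distance
from .psi import PsiResult, psi_dh, psi_naive_hash
from .seqdata import NucleotideSequence, SequenceDataset
from .shingles import ShingleDB, build_shingle_db, optimal_w, shingle_set

PSI_PROTOCOLS: dict[str, Callable] = {"dh": psi_dh, "naive": psi_naive_hash}

MODES = ("exact", "approx1", "approx2", "joined")


@dataclass(frozen=True)
class QuerySpec:
    """Query parameters: top-k, cascade factor c (t = c*k), shingle width w, band."""

    k: int
    c: int = 5
    w: int | None = None
    band: BandSpec = BandSpec(5)
    mode: str = "exact"

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.c < 1:
            raise ValueError("c must be >= 1")
        if self.w is not None and self.w < 1:
            raise ValueError("w must be >= 1")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")

    @property
    def t(self) -> int:
        return self.c * self.k

    def effective_w(self, query_length: int) -> int:
        return self.w if self.w is not None else optimal_w(query_length)


@dataclass(frozen=True)
class RankedResult:
    """Ordered record ids with scores; ties at rank k are expanded."""

    ids: tuple[str, ...]
    scores: tuple[int, ...]
    score_kind: str  # "distance" (ascending) or "matches" (descending)
    tie_expanded: bool

    @property
    def returned_set(self) -> frozenset[str]:
        return frozenset(self.ids)

    def __len__(self) -> int:
        return len(self.ids)


@dataclass(frozen=True)
class AccuracyReport:
    n_tp: int
    n_fn: int

    @property
    def accuracy(self) -> float:
        return self.n_tp / (self.n_tp + self.n_fn)


def _rank(
    pairs: list[tuple[str, int]], k: int, ascending: bool, tie_expand: bool = True
) -> RankedResult:
    """Sort (id, score), cut at rank k, optionally keep everything tied with
    the rank-k score; record id breaks ties deterministically."""
    if not pairs:
        raise ValueError("cannot rank an empty dataset")
    key = (lambda p: (p[1], p[0])) if ascending else (lambda p: (-p[1], p[0]))
    ordered = sorted(pairs, key=key)
    k = min(k, len(ordered))
    cutoff = ordered[k - 1][1]
    if tie_expand:
        kept = [p for p in ordered if (p[1] <= cutoff if ascending else p[1] >= cutoff)]
    else:
        kept = ordered[:k]
    return RankedResult(
        ids=tuple(p[0] for p in kept),
        scores=tuple(p[1] for p in kept),
        score_kind="distance" if ascending else "matches",
        tie_expanded=len(kept) > k,
    )


def topk_exact(
    dataset: SequenceDataset, query: NucleotideSequence | str, spec: QuerySpec
) -> RankedResult:
    """Ground-truth ranking by exact edit distance, ties at rank k expanded."""
    q = query.residues if isinstance(query, NucleotideSequence) else query
    pairs = [(rec.id, edit_distance(rec.residues, q)) for rec in dataset]
    return _rank(pairs, spec.k, ascending=True)


def _match_counts(
    db: ShingleDB, intersection
) -> list[tuple[str, int]]:
    items = intersection.items if hasattr(intersection, "items") else intersection
    items = set(items)
    return [(rid, len(ss.items & items)) for rid, ss in db.per_record.items()]


def topk_approx1(
    dataset: SequenceDataset,
    query: NucleotideSequence | str,
    spec: QuerySpec,
    psi_protocol: str | Callable | None = "dh",
    channel: Channel | None = None,
    seed: int | None = None,
    shingle_db: ShingleDB | None = None,
    _k_override: int | None = None,
    _tie_expand: bool = True,
) -> RankedResult:
    """Approximation 1: rank by shingle matches with the PSI intersection.

    One PSI runs between the researcher's query shingle set and the owner's
    union shingle database; the owner then counts matches per record locally.
    ``psi_protocol`` is ``"dh"``, ``"naive"``, a callable with the same
    signature, or ``None`` for a plaintext set intersection (no protocol; for
    experiments — identical counts by the PSI correctness contract).
    """
    q = query.residues if isinstance(query, NucleotideSequence) else query
    w = spec.effective_w(len(q))
    db = shingle_db if shingle_db is not None and shingle_db.w == w else None
    if db is None:
        db = build_shingle_db(dataset, w)
    query_shingles = shingle_set(q, w)
    if psi_protocol is None:
        intersection = query_shingles.intersection(db.union)
    else:
        proto = (
            PSI_PROTOCOLS[psi_protocol]
            if isinstance(psi_protocol, str)
            else psi_protocol
        )
        result: PsiResult = proto(
            query_shingles, db.union, channel if channel is not None else Channel(),
            seed=seed,
        )
        intersection = result.intersection
    k = _k_override if _k_override is not None else spec.k
    return _rank(_match_counts(db, intersection), k, ascending=False,
                 tie_expand=_tie_expand)


def topk_approx2(
    dataset: SequenceDataset,
    query: NucleotideSequence | str,
    spec: QuerySpec,
    use_secure: bool = False,
    seed: int | None = None,
    restrict_ids: set[str] | None = None,
) -> RankedResult:
    """Approximation 2: rank by banded edit distance, ascending.

    With ``use_secure`` every pairwise distance is computed inside a garbled
    circuit; otherwise the plaintext banded kernel is used.  The two paths
    return identical rankings — the circuit computes the same recurrence.
    """
    q = query.residues if isinstance(query, NucleotideSequence) else query
    records = [
        r for r in dataset if restrict_ids is None or r.id in restrict_ids
    ]
    if not records:
        raise ValueError("no records to rank")
    pairs = []
    for i, rec in enumerate(records):
        if use_secure:
            out = secure_banded_distance(
                rec.residues, q, spec.band,
                seed=None if seed is None else seed + i,
            )
            d = out.distance
        else:
            d = banded_edit_distance(rec.residues, q, spec.band)
        pairs.append((rec.id, d))
    return _rank(pairs, spec.k, ascending=True)


def topk_joined(
    dataset: SequenceDataset,
    query: NucleotideSequence | str,
    spec: QuerySpec,
    psi_protocol: str | Callable | None = "dh",
    use_secure: bool = False,
    seed: int | None = None,
    shingle_db: ShingleDB | None = None,
) -> RankedResult:
    """Joined cascade: approximation 1 selects exactly t = c*k survivors, the
    banded stage re-ranks only those and returns the final top-k.

    The final returned set is contained in the stage-1 survivor set by
    construction.
    """
    if spec.t > dataset.n:
        raise ValueError(f"t = c*k = {spec.t} exceeds dataset size {dataset.n}")
    stage1 = topk_approx1(
        dataset, query, spec, psi_protocol=psi_protocol, seed=seed,
        shingle_db=shingle_db, _k_override=spec.t, _tie_expand=False,
    )
    return topk_approx2(
        dataset, query, spec, use_secure=use_secure, seed=seed,
        restrict_ids=set(stage1.ids),
    )


def stage1_survivors(
    dataset: SequenceDataset,
    query: NucleotideSequence | str,
    spec: QuerySpec,
    psi_protocol: str | Callable | None = "naive",
    seed: int | None = None,
    shingle_db: ShingleDB | None = None,
) -> RankedResult:
    """The top-t record set the cascade's first stage hands to the second."""
    return topk_approx1(
        dataset, query, spec, psi_protocol=psi_protocol, seed=seed,
        shingle_db=shingle_db, _k_override=spec.t, _tie_expand=False,
    )


def accuracy(truth: RankedResult, predicted: RankedResult) -> AccuracyReport:
    """Tie-aware recall: |predicted ∩ truth| / |truth|."""
    truth_set = truth.returned_set
    if not truth_set:
        raise ValueError("truth set is empty")
    n_tp = len(predicted.returned_set & truth_set)
    return AccuracyReport(n_tp=n_tp, n_fn=len(truth_set) - n_tp)


def run_query(
    dataset: SequenceDataset,
    query: NucleotideSequence | str,
    spec: QuerySpec,
    psi_protocol: str | Callable | None = "dh",
    use_secure: bool = False,
    seed: int | None = None,
    shingle_db: ShingleDB | None = None,
) -> RankedResult:
    """Dispatch on ``spec.mode``."""
    if spec.mode == "exact":
        return topk_exact(dataset, query, spec)
    if spec.mode == "approx1":
        return topk_approx1(
            dataset, query, spec, psi_protocol=psi_protocol, seed=seed,
            shingle_db=shingle_db,
        )
    if spec.mode == "approx2":
        return topk_approx2(dataset, query, spec, use_secure=use_secure, seed=seed)
    return topk_joined(
        dataset, query, spec, psi_protocol=psi_protocol, use_secure=use_secure,
        seed=seed, shingle_db=shingle_db,
    )


# ------------------------------------------------------------------ experiments


@dataclass
class ExperimentConfig:
    """Sweep configuration for the experiment harness (all sizes explicit)."""

    n_records: int = 200
    n_queries: int = 3
    n_sites: int = 1000
    max_indels: int = 0
    seed: int = 0
    k_values: tuple[int, ...] = (1, 5, 10)
    methods: tuple[str, ...] = ("approx1", "approx2", "joined")
    w: int | None = None
    b_values: tuple[int, ...] = (5,)
    c_values: tuple[int, ...] = (5,)

    @classmethod
    def from_file(cls, path) -> "ExperimentConfig":
        """Flat ``key = value`` text config; lists comma-separated."""
        cfg = cls()
        valid = set(cfg.__dataclass_fields__)
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{lineno}: expected 'key = value'")
                key, _, value = line.partition("=")
                key, value = key.strip(), value.strip()
                if key not in valid:
                    raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
                current = getattr(cfg, key)
                if key == "methods":
                    setattr(cfg, key, tuple(v.strip() for v in value.split(",")))
                elif isinstance(current, tuple):
                    setattr(cfg, key, tuple(int(v) for v in value.split(",")))
                elif key == "w":
                    setattr(cfg, key, None if value == "auto" else int(value))
                else:
                    setattr(cfg, key, int(value))
        return cfg


def run_experiment(
    config: ExperimentConfig,
    dataset: SequenceDataset | None = None,
    queries: SequenceDataset | None = None,
) -> pd.DataFrame:
    """Accuracy of each method against the exact baseline over a parameter sweep.

    Generates a synthetic corpus from the config unless an explicit dataset and
    query set are supplied.  Returns one row per (method, k, parameter, query),
    plus the accuracy; deterministic under the config seed.  Plaintext kernels
    are used throughout (secure variants return identical rankings; the
    equivalence is enforced by the protocol test suite).
    """
    from .seqdata import generate_dataset, perturb_lengths, synthetic_frequency_table

    if dataset is None or queries is None:
        freqs = synthetic_frequency_table(config.n_sites, config.seed)
        dataset, queries = generate_dataset(
            freqs, config.n_records, config.n_queries, config.seed + 1
        )
        if config.max_indels:
            dataset = perturb_lengths(dataset, config.max_indels, config.seed + 2)
            queries = perturb_lengths(queries, config.max_indels, config.seed + 3)
    rows = []
    db_cache: dict[int, ShingleDB] = {}
    for qi, query in enumerate(queries):
        w = config.w if config.w is not None else optimal_w(len(query))
        if w not in db_cache:
            db_cache[w] = build_shingle_db(dataset, w)
        db = db_cache[w]
        for k in config.k_values:
            truth = topk_exact(dataset, query, QuerySpec(k=k))
            for method in config.methods:
                if method == "approx1":
                    spec = QuerySpec(k=k, w=w, mode="approx1")
                    pred = topk_approx1(
                        dataset, query, spec, psi_protocol=None, shingle_db=db
                    )
                    rows.append((method, k, f"w={w}", qi, accuracy(truth, pred).accuracy))
                elif method == "approx2":
                    for b in config.b_values:
                        spec = QuerySpec(k=k, band=BandSpec(b), mode="approx2")
                        pred = topk_approx2(dataset, query, spec)
                        rows.append(
                            (method, k, f"b={b}", qi, accuracy(truth, pred).accuracy)
                        )
                elif method == "joined":
                    for c in config.c_values:
                        for b in config.b_values:
                            if c * k > dataset.n:
                                continue
                            spec = QuerySpec(
                                k=k, c=c, w=w, band=BandSpec(b), mode="joined"
                            )
                            pred = topk_joined(
                                dataset, query, spec, psi_protocol=None,
                                shingle_db=db,
                            )
                            rows.append(
                                (
                                    method, k, f"c={c},b={b}", qi,
                                    accuracy(truth, pred).accuracy,
                                )
                            )
                else:
                    raise ValueError(f"unknown method {method!r} in config")
    return pd.DataFrame(
        rows, columns=["method", "k", "param", "query_index", "accuracy"]
    )


# ----------------------------------------------------------------- result I/O


def write_ranked_result(result: RankedResult, path_or_buf) -> None:
    df = pd.DataFrame(
        {
            "rank": np.arange(1, len(result) + 1),
            "record_id": result.ids,
            "score": result.scores,
            "score_kind": result.score_kind,
        }
    )
    df.to_csv(path_or_buf, sep="\t", index=False)


def read_ranked_result(path) -> RankedResult:
    df = pd.read_csv(path, sep="\t", dtype={"record_id": str})
    kind = str(df["score_kind"].iloc[0]) if len(df) else "distance"
    return RankedResult(
        ids=tuple(df["record_id"]),
        scores=tuple(int(s) for s in df["score"]),
        score_kind=kind,
        tie_expanded=False,
    )


def ranked_result_tsv(result: RankedResult) -> str:
    buf = io.StringIO()
    write_ranked_result(result, buf)
    return buf.getvalue()
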