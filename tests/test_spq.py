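import pytest

from privseq.distance import BandSpec
from privseq.seqdata import NucleotideSequence, SequenceDataset
from privseq.spq import (
    ExperimentConfig,
    QuerySpec,
    RankedResult,
    accuracy,
    read_ranked_result,
    run_experiment,
    stage1_survivors,
    topk_approx1,
    topk_approx2,
    topk_exact,
    topk_joined,
    write_ranked_result,
)


def ranked(ids, scores, kind="distance"):
    return RankedResult(tuple(ids), tuple(scores), kind, tie_expanded=False)


class TestQuerySpec:
    def test_t_is_c_times_k(self):
        assert QuerySpec(k=10, c=5).t == 50
        assert QuerySpec(k=20, c=5).t == 100

    def test_validation(self):
        with pytest.raises(ValueError):
            QuerySpec(k=0)
        with pytest.raises(ValueError):
            QuerySpec(k=1, mode="fast")


class TestAccuracyMetric:
    def test_worked_example(self):
        """Top-3 query whose truth set has four records (two tied at 3rd):
        three of four predicted hits give 75% recall."""
        truth = ranked(["1000", "1010", "505", "1101"], [1, 2, 3, 3])
        pred = ranked(["1000", "1010", "505", "202"], [9, 8, 7, 7], "matches")
        rep = accuracy(truth, pred)
        assert (rep.n_tp, rep.n_fn) == (3, 1)
        assert rep.accuracy == 0.75

    def test_perfect_and_disjoint(self):
        truth = ranked(["a", "b"], [0, 1])
        assert accuracy(truth, truth).accuracy == 1.0
        assert accuracy(truth, ranked(["c", "d"], [0, 1])).accuracy == 0.0

    def test_empty_truth_rejected(self):
        empty = RankedResult((), (), "distance", False)
        with pytest.raises(ValueError):
            accuracy(empty, empty)


class TestTopkExact:
    def test_query_equal_to_record_ranks_first(self, toy_dataset):
        res = topk_exact(toy_dataset, "ATGCATGC", QuerySpec(k=1))
        assert res.ids[0] == "r1" and res.scores[0] == 0

    def test_tie_expansion_at_rank_k(self):
        ds = SequenceDataset(
            [
                NucleotideSequence("a", "AAAA"),
                NucleotideSequence("b", "AAAT"),
                NucleotideSequence("c", "AATT"),  # ties with d at distance 2
                NucleotideSequence("d", "TTAA"),
                NucleotideSequence("e", "TTTT"),
            ]
        )
        res = topk_exact(ds, "AAAA", QuerySpec(k=3))
        assert res.returned_set == {"a", "b", "c", "d"}
        assert res.tie_expanded
        assert len(res) == 4

    def test_record_order_invariance(self, small_corpus):
        data, queries = small_corpus
        q = queries[0]
        shuffled = SequenceDataset(list(data)[::-1])
        r1 = topk_exact(data, q, QuerySpec(k=5))
        r2 = topk_exact(shuffled, q, QuerySpec(k=5))
        assert r1.returned_set == r2.returned_set
        assert r1.ids == r2.ids  # id tie-break makes the order deterministic


class TestTopkApprox1:
    def test_more_matches_ranks_higher(self):
        ds = SequenceDataset(
            [
                NucleotideSequence("rec2", "ACGTACGTA"),  # fewer shared shingles
                NucleotideSequence("rec1", "CAACATAGCA"),  # more shared shingles
            ]
        )
        q = "CAACATAGCAAC"
        res = topk_approx1(ds, q, QuerySpec(k=2, w=4), psi_protocol=None)
        assert res.ids[0] == "rec1"
        assert res.scores[0] > res.scores[1]

    def test_identical_record_attains_max_matches(self, small_corpus):
        data, _ = small_corpus
        q = data[0].residues
        res = topk_approx1(data, q, QuerySpec(k=1, w=5), psi_protocol=None)
        from privseq.shingles import shingle_set

        assert res.ids[0] == data[0].id
        assert res.scores[0] == len(shingle_set(q, 5))

    def test_psi_and_plaintext_pipelines_agree(self, small_corpus):
        data, queries = small_corpus
        sub = SequenceDataset(
            [NucleotideSequence(r.id, r.residues[:100]) for r in list(data)[:8]]
        )
        q = NucleotideSequence("q", queries[0].residues[:100])
        spec = QuerySpec(k=3, w=6)
        plain = topk_approx1(sub, q, spec, psi_protocol=None)
        for proto in ("dh", "naive"):
            viaproto = topk_approx1(sub, q, spec, psi_protocol=proto, seed=1)
            assert viaproto.ids == plain.ids
            assert viaproto.scores == plain.scores


class TestTopkApprox2:
    def test_secure_equals_plaintext_on_toy_dataset(self):
        records = [
            NucleotideSequence(f"r{i}", s)
            for i, s in enumerate(
                ["ACGTACGTACGT", "ACGTACCTACGT", "TTGTACGAACGA", "ACATACGTACGA",
                 "GCGTACGTATGT"]
            )
        ]
        ds = SequenceDataset(records)
        spec = QuerySpec(k=2, band=BandSpec(2))
        q = "ACGTACGAACGT"
        secure = topk_approx2(ds, q, spec, use_secure=True, seed=21)
        plain = topk_approx2(ds, q, spec, use_secure=False)
        assert secure.ids == plain.ids
        assert secure.scores == plain.scores

    def test_wide_band_equals_exact(self, small_corpus):
        data, queries = small_corpus
        q = queries[0]
        spec = QuerySpec(k=4, band=BandSpec(500))
        assert (
            topk_approx2(data, q, spec).returned_set
            == topk_exact(data, q, spec).returned_set
        )

    def test_single_record_dataset(self):
        ds = SequenceDataset([NucleotideSequence("only", "ACGT")])
        res = topk_approx2(ds, "AGGT", QuerySpec(k=1, band=BandSpec(1)))
        assert res.ids == ("only",)


class TestTopkJoined:
    def test_stage1_survivor_counts(self, small_corpus):
        data, queries = small_corpus
        q = queries[0]
        s1 = stage1_survivors(data, q, QuerySpec(k=5, c=4, w=5), psi_protocol=None)
        assert len(s1) == 20

    def test_containment_in_stage1(self, small_corpus):
        data, queries = small_corpus
        q = queries[1]
        spec = QuerySpec(k=3, c=3, w=5, band=BandSpec(4))
        s1 = stage1_survivors(data, q, spec, psi_protocol=None)
        joined = topk_joined(data, q, spec, psi_protocol=None)
        assert joined.returned_set <= s1.returned_set

    def test_degenerate_cascade_equals_approx2(self, small_corpus):
        data, queries = small_corpus
        q = queries[0]
        spec = QuerySpec(k=4, c=10, w=5, band=BandSpec(3))  # t = n
        assert spec.t == data.n
        joined = topk_joined(data, q, spec, psi_protocol=None)
        direct = topk_approx2(data, q, spec)
        assert joined.ids == direct.ids

    def test_t_larger_than_dataset_rejected(self, small_corpus):
        data, queries = small_corpus
        with pytest.raises(ValueError, match="exceeds"):
            topk_joined(data, queries[0], QuerySpec(k=30, c=2), psi_protocol=None)


class TestExperimentHarness:
    def test_deterministic_under_seed(self):
        cfg = ExperimentConfig(
            n_records=25, n_queries=2, n_sites=150, seed=4,
            k_values=(1, 3), c_values=(2,), b_values=(2,),
        )
        assert run_experiment(cfg).equals(run_experiment(cfg))

    def test_single_record_all_accuracies_one(self):
        cfg = ExperimentConfig(
            n_records=1, n_queries=1, n_sites=100, seed=5,
            k_values=(1,), c_values=(1,), b_values=(2,),
        )
        df = run_experiment(cfg)
        assert (df["accuracy"] == 1.0).all()

    def test_config_file_parsing(self, tmp_path):
        p = tmp_path / "cfg.txt"
        p.write_text(
            "n_records = 30\nk_values = 1, 5\nmethods = approx1, joined\n"
            "w = auto\nseed = 2\n# comment line\n"
        )
        cfg = ExperimentConfig.from_file(p)
        assert cfg.n_records == 30
        assert cfg.k_values == (1, 5)
        assert cfg.methods == ("approx1", "joined")
        assert cfg.w is None

    def test_unknown_config_key_rejected(self, tmp_path):
        p = tmp_path / "cfg.txt"
        p.write_text("records = 30\n")
        with pytest.raises(ValueError, match="unknown config key"):
            ExperimentConfig.from_file(p)


class TestRankedResultIO:
    def test_tsv_roundtrip(self, tmp_path):
        res = ranked(["b", "a", "c"], [1, 2, 3])
        p = tmp_path / "r.tsv"
        write_ranked_result(res, p)
        back = read_ranked_result(p)
        assert back.ids == res.ids
        assert back.scores == res.scores
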