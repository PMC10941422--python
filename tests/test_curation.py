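"""Dataset curation: filters, identity clustering, fixpoint, split."""

import numpy as np
import pytest

from dbpstack import FixtureSpec, gen_benchmark
from dbpstack.curation import (PairwiseIdentity, cluster_by_identity,
                               cross_class_reduce, curate, filter_records,
                               reduce_to_fixpoint, split_80_20,
                               verify_identity_threshold)
from dbpstack.sequence_io import ProteinRecord


def _rec(rid, seq):
    return ProteinRecord(rid, seq)


def _long(base, n=60):
    return (base * (n // len(base) + 1))[:n]


class StubOracle:
    """Identity oracle driven by an explicit id-pair table (via sequences)."""

    def __init__(self, table, default=0.0):
        self.table = {frozenset(k): v for k, v in table.items()}
        self.default = default

    def __call__(self, a, b):
        if a == b:
            return 1.0
        return self.table.get(frozenset((a, b)), self.default)


class TestFilters:
    def test_length_50_dropped_51_kept(self):
        recs = [_rec("short", "A" * 50), _rec("ok", "A" * 51)]
        kept, dropped = filter_records(recs)
        assert [r.id for r in kept] == ["ok"]
        assert dropped[0][0] == "short" and "fragment" in dropped[0][1]

    def test_unknown_residue_dropped_with_reason(self):
        recs = [_rec("hasx", "AX" + "A" * 60), _rec("ok", "AC" * 30)]
        kept, dropped = filter_records(recs)
        assert [r.id for r in kept] == ["ok"]
        assert "unknown residue" in dropped[0][1]

    def test_idempotent(self):
        recs = [_rec("a", "AC" * 40), _rec("b", "A" * 10)]
        kept, _ = filter_records(recs)
        kept2, dropped2 = filter_records(kept)
        assert kept2 == kept and dropped2 == []


class TestPairwiseIdentity:
    def test_identical_sequences(self):
        ident = PairwiseIdentity()
        s = _long("ACDKW")
        assert ident(s, s) == 1.0

    def test_symmetric_and_bounded(self):
        ident = PairwiseIdentity()
        rng = np.random.default_rng(0)
        aas = "ACDEFGHIKLMNPQRSTVWY"
        for _ in range(5):
            a = "".join(rng.choice(list(aas), 60))
            b = "".join(rng.choice(list(aas), 80))
            v = ident(a, b)
            assert 0.0 <= v <= 1.0
            assert ident(b, a) == v

    def test_near_duplicate_scores_high(self):
        ident = PairwiseIdentity()
        a = _long("ACDEFGHIKLMNPQRSTVWY", 80)
        b = a[:40] + "W" + a[41:]  # single substitution
        assert ident(a, b) > 0.9

    def test_unrelated_sequences_score_low(self):
        ident = PairwiseIdentity()
        rng = np.random.default_rng(1)
        aas = "ACDEFGHIKLMNPQRSTVWY"
        vals = [ident("".join(rng.choice(list(aas), 70)),
                      "".join(rng.choice(list(aas), 70))) for _ in range(10)]
        assert np.mean(vals) < 0.25


class TestClustering:
    def test_identical_pair_single_cluster(self):
        s = _long("KR")
        recs = [_rec("b", s), _rec("a", s)]
        cs = cluster_by_identity(recs, threshold=0.25)
        assert len(cs.clusters) == 1
        # tie in length -> lexicographically smallest id represents
        assert cs.representatives == ("a",)

    def test_mutually_dissimilar_all_singletons(self):
        recs = [_rec(f"r{i}", _long("ACD", 60 + i)) for i in range(4)]
        cs = cluster_by_identity(recs, threshold=0.25,
                                 oracle=StubOracle({}, default=0.0))
        assert len(cs.clusters) == 4

    def test_five_sequence_greedy_hand_replay(self):
        # lengths force order e, d, c, b, a (decreasing); stub identities:
        seqs = {rid: _long(base, ln) for rid, base, ln in (
            ("a", "AC", 60), ("b", "DE", 61), ("c", "FG", 62),
            ("d", "HI", 63), ("e", "KL", 64))}
        table = {
            (seqs["e"], seqs["d"]): 0.1,   # d founds its own cluster
            (seqs["e"], seqs["c"]): 0.9,   # c joins e (first match)
            (seqs["d"], seqs["c"]): 0.9,   # ...even though d also matches
            (seqs["e"], seqs["b"]): 0.0,
            (seqs["d"], seqs["b"]): 0.8,   # b joins d
            (seqs["e"], seqs["a"]): 0.0,
            (seqs["d"], seqs["a"]): 0.0,
        }
        recs = [_rec(r, s) for r, s in seqs.items()]
        cs = cluster_by_identity(recs, 0.25, StubOracle(table))
        clusters = {frozenset(c) for c in cs.clusters}
        assert clusters == {frozenset({"e", "c"}), frozenset({"d", "b"}),
                            frozenset({"a"})}
        assert set(cs.representatives) == {"e", "d", "a"}


class TestFixpoint:
    def test_chain_resolved_in_one_round(self):
        # A~B, B~C, A!~C: greedy keeps A and C which do not match
        sa, sb, sc = _long("AC", 62), _long("DE", 61), _long("FG", 60)
        table = {(sa, sb): 0.9, (sb, sc): 0.9, (sa, sc): 0.0}
        recs = [_rec("A", sa), _rec("B", sb), _rec("C", sc)]
        out = reduce_to_fixpoint(recs, 0.25, StubOracle(table))
        assert {r.id for r in out} == {"A", "C"}

    def test_already_reduced_set_unchanged(self):
        recs = [_rec(f"r{i}", _long("ACDKW", 60 + i)) for i in range(3)]
        out = reduce_to_fixpoint(recs, 0.25, StubOracle({}, default=0.0))
        assert {r.id for r in out} == {r.id for r in recs}

    def test_survivors_always_verify_on_random_inputs(self):
        # the founder of every cluster is its representative (decreasing
        # length, ties by id), so one greedy pass already satisfies the
        # threshold; verification must find nothing
        ident = PairwiseIdentity()
        records, _ = gen_benchmark(FixtureSpec(n_pos=20, n_neg=20, seed=17,
                                               signal_strength=0.5))
        out = reduce_to_fixpoint(records, 0.25, ident)
        assert verify_identity_threshold(out, 0.25, ident) == []

    def test_max_rounds_validation(self):
        with pytest.raises(ValueError, match="max_rounds"):
            reduce_to_fixpoint([], 0.25, StubOracle({}), max_rounds=0)


class TestCrossClass:
    def test_negative_identical_to_positive_discarded(self):
        s = _long("KRH")
        pos = [_rec("p", s)]
        neg = [_rec("n", s), _rec("m", _long("ACD"))]
        kept = cross_class_reduce(pos, neg, 0.25, StubOracle({}, 0.0))
        assert [r.id for r in kept] == ["m"]

    def test_all_dissimilar_negatives_kept(self):
        pos = [_rec("p", _long("KR"))]
        neg = [_rec(f"n{i}", _long("AC", 60 + i)) for i in range(3)]
        kept = cross_class_reduce(pos, neg, 0.25, StubOracle({}, 0.0))
        assert len(kept) == 3

    def test_survivors_verified_exhaustively(self):
        ident = PairwiseIdentity()
        records, y = gen_benchmark(FixtureSpec(n_pos=15, n_neg=15, seed=21,
                                               signal_strength=0.3))
        pos = [r for r, lab in zip(records, y) if lab == 1]
        neg = [r for r, lab in zip(records, y) if lab == 0]
        # plant a near-duplicate of a positive in the negatives
        dup = ProteinRecord("neg_dup", pos[0].sequence[:-1] + "W")
        kept = cross_class_reduce(pos, neg + [dup], 0.25, ident)
        assert all(ident(n.sequence, p.sequence) < 0.25
                   for n in kept for p in pos)
        assert "neg_dup" not in {r.id for r in kept}


class TestSplit:
    def test_published_benchmark_sizes(self):
        pos = [f"p{i}" for i in range(890)]
        neg = [f"n{i}" for i in range(890)]
        split = split_80_20(pos, neg, seed=0)
        assert len(split.train_pos) == len(split.train_neg) == 712
        assert len(split.test_pos) == len(split.test_neg) == 178
        total = sum(map(len, (split.train_pos, split.train_neg,
                              split.test_pos, split.test_neg)))
        assert total == 1780

    def test_ten_per_class_gives_8_2(self):
        split = split_80_20([f"p{i}" for i in range(10)],
                            [f"n{i}" for i in range(10)], seed=1)
        assert len(split.train_pos) == 8 and len(split.test_pos) == 2

    def test_seeded_determinism_and_disjointness(self):
        pos = [f"p{i}" for i in range(37)]
        neg = [f"n{i}" for i in range(23)]
        a = split_80_20(pos, neg, seed=5)
        b = split_80_20(pos, neg, seed=5)
        assert a == b
        groups = [set(a.train_pos), set(a.train_neg), set(a.test_pos),
                  set(a.test_neg)]
        assert sum(map(len, groups)) == len(set().union(*groups)) == 60

    def test_tiny_class_warns(self):
        with pytest.warns(UserWarning, match="only"):
            split_80_20(["p1", "p2"], [f"n{i}" for i in range(10)], seed=0)


class TestEndToEndCuration:
    def test_planted_duplicates_removed_and_threshold_guaranteed(self):
        ident = PairwiseIdentity()
        records, y = gen_benchmark(FixtureSpec(n_pos=25, n_neg=25, seed=33,
                                               signal_strength=0.2))
        pos = [r for r, lab in zip(records, y) if lab == 1]
        neg = [r for r, lab in zip(records, y) if lab == 0]
        # adversarial planting: near-duplicates within and across classes
        pos.append(ProteinRecord("pos_dupA", pos[1].sequence[:-2] + "WW"))
        neg.append(ProteinRecord("neg_dupB", neg[2].sequence[:-2] + "WW"))
        neg.append(ProteinRecord("neg_dupP", pos[3].sequence[:-2] + "WW"))
        split, report = curate(pos, neg, threshold=0.25, seed=0,
                               oracle=ident)
        by_id = {r.id: r for r in pos + neg}
        survivors = [by_id[i] for i in (split.train_pos + split.train_neg
                                        + split.test_pos + split.test_neg)]
        assert verify_identity_threshold(survivors, 0.25, ident) == []
        assert report["filtered"]["pos"] == len(pos)
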