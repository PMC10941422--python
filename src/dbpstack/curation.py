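"""Benchmark-dataset curation: residue/length filters, sequence-identity
redundancy reduction within and between classes, and the stratified 80-20
split.

The identity oracle is the fraction of identical aligned residues in a
global pairwise alignment divided by the length of the shorter sequence
(the greedy-incremental clustering convention).  Clustering is greedy in
decreasing-length order: a sequence joins the first existing cluster whose
representative it matches at or above the threshold, else founds a new
cluster; the longest member (ties: lexicographically smallest id) represents
each cluster.  Because a single greedy pass can leave residual matching
pairs when representatives change, reduction iterates to a fixpoint and then
verifies the survivors exhaustively.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from Bio import Align

__all__ = ["PairwiseIdentity", "ClusterSet", "BenchmarkSplit",
           "filter_records", "cluster_by_identity", "reduce_to_fixpoint",
           "cross_class_reduce", "split_80_20", "verify_identity_threshold"]


class PairwiseIdentity:
    """Global-alignment sequence identity in [0, 1].

    identity(a, b) = identical aligned residues / min(len(a), len(b)).
    Affine gap penalties (open -10, extend -0.5) with match +5 / mismatch -4
    keep alignments of unrelated sequences gappy and low-identity.  Results
    are memoized per sequence pair.
    """

    def __init__(self, match=5, mismatch=-4, open_gap=-10, extend_gap=-0.5):
        self._aligner = Align.PairwiseAligner(
            mode="global", match_score=match, mismatch_score=mismatch,
            open_gap_score=open_gap, extend_gap_score=extend_gap)
        self._cache: dict = {}

    def __call__(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        key = (a, b) if a <= b else (b, a)
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        # composition bound: aligned matches cannot exceed the shared
        # residue multiset; skip alignment when the bound is tiny
        counts_a = {}
        for ch in a:
            counts_a[ch] = counts_a.get(ch, 0) + 1
        shared = 0
        counts_b = {}
        for ch in b:
            counts_b[ch] = counts_b.get(ch, 0) + 1
        for ch, na in counts_a.items():
            shared += min(na, counts_b.get(ch, 0))
        short = min(len(a), len(b))
        bound = shared / short
        if bound < 1e-9:
            self._cache[key] = 0.0
            return 0.0
        aln = self._aligner.align(a, b)[0]
        ident = aln.counts().identities / short
        ident = min(ident, bound)
        self._cache[key] = ident
        return ident


@dataclass(frozen=True)
class ClusterSet:
    """A partition of record ids into identity clusters."""

    clusters: tuple            # tuple of member-id tuples
    representatives: tuple     # one id per cluster (longest member)
    threshold: float

    @property
    def representative_ids(self) -> list:
        return list(self.representatives)


@dataclass(frozen=True)
class BenchmarkSplit:
    train_pos: tuple
    train_neg: tuple
    test_pos: tuple
    test_neg: tuple
    seed: int

    def __post_init__(self):
        groups = [set(self.train_pos), set(self.train_neg),
                  set(self.test_pos), set(self.test_neg)]
        total = sum(len(g) for g in groups)
        if len(set().union(*groups)) != total:
            raise ValueError("split lists are not disjoint")


def filter_records(records):
    """Length and residue filters: drop fragments (length <= 50) and records
    containing unknown/non-canonical residues.

    Returns ``(kept, dropped)`` with dropped a list of (id, reason).
    Idempotent: filtering the kept list again drops nothing.
    """
    kept, dropped = [], []
    for r in records:
        if r.length <= 50:
            dropped.append((r.id, f"fragment rule: length {r.length} <= 50"))
        elif not r.is_canonical:
            bad = sorted(set(r.sequence) - set("ACDEFGHIKLMNPQRSTVWY"))
            dropped.append((r.id, f"unknown residue: {','.join(bad)}"))
        else:
            kept.append(r)
    return kept, dropped


def _greedy_order(records):
    return sorted(records, key=lambda r: (-r.length, r.id))


def cluster_by_identity(records, threshold: float,
                        oracle=None) -> ClusterSet:
    """Greedy incremental clustering in decreasing-length order.

    Each sequence joins the FIRST existing cluster whose representative it
    matches at >= threshold, else founds a new cluster.  The representative
    is the longest member (ties: lexicographically smallest id).
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    oracle = oracle or PairwiseIdentity()
    by_id = {r.id: r for r in records}
    clusters: list = []      # list of lists of ids
    founders: list = []      # founder record per cluster
    for rec in _greedy_order(records):
        placed = False
        for ci, rep in enumerate(founders):
            if oracle(rec.sequence, rep.sequence) >= threshold:
                clusters[ci].append(rec.id)
                placed = True
                break
        if not placed:
            clusters.append([rec.id])
            founders.append(rec)
    reps = []
    for members in clusters:
        best = sorted(members, key=lambda i: (-by_id[i].length, i))[0]
        reps.append(best)
    return ClusterSet(tuple(tuple(m) for m in clusters), tuple(reps),
                      threshold)


def verify_identity_threshold(records, threshold: float, oracle=None) -> list:
    """Exhaustive pairwise check; returns the list of violating id pairs."""
    oracle = oracle or PairwiseIdentity()
    recs = list(records)
    if len(recs) > 2000:
        raise ValueError("exhaustive verification capped at 2000 sequences")
    bad = []
    for i in range(len(recs)):
        for j in range(i + 1, len(recs)):
            if oracle(recs[i].sequence, recs[j].sequence) >= threshold:
                bad.append((recs[i].id, recs[j].id))
    return bad


def reduce_to_fixpoint(records, threshold: float, oracle=None,
                       max_rounds: int = 5):
    """Repeat cluster-and-keep-representatives until no surviving pair
    matches at >= threshold (verified exhaustively), or error out listing the
    offending pairs once ``max_rounds`` is exhausted."""
    if max_rounds < 1:
        raise ValueError("max_rounds must be >= 1")
    oracle = oracle or PairwiseIdentity()
    current = list(records)
    by_id = {r.id: r for r in current}
    for _ in range(max_rounds):
        cs = cluster_by_identity(current, threshold, oracle)
        current = [by_id[i] for i in cs.representative_ids]
        if not verify_identity_threshold(current, threshold, oracle):
            return current
    bad = verify_identity_threshold(current, threshold, oracle)
    raise RuntimeError(
        f"identity reduction did not converge in {max_rounds} rounds; "
        f"violating pairs: {bad}"
    )


def cross_class_reduce(pos_records, neg_records, threshold: float,
                       oracle=None):
    """Between-class reduction retaining every positive.

    Keeps exactly the negatives whose identity to every positive is below
    the threshold (mixed clusters resolve by discarding negatives).
    """
    oracle = oracle or PairwiseIdentity()
    kept = []
    for neg in neg_records:
        if all(oracle(neg.sequence, pos.sequence) < threshold
               for pos in pos_records):
            kept.append(neg)
    return kept


def split_80_20(pos_ids, neg_ids, seed: int = 0) -> BenchmarkSplit:
    """Per-class seeded shuffle and 80-20 split (test size = round(0.2 n));
    e.g. 890 per class yields 712 train / 178 test per class."""
    pos_ids, neg_ids = list(pos_ids), list(neg_ids)
    if not pos_ids or not neg_ids:
        raise ValueError("both classes must be non-empty")
    out = {}
    for name, ids in (("pos", pos_ids), ("neg", neg_ids)):
        if len(ids) < 5:
            warnings.warn(f"{name} class has only {len(ids)} members; "
                          f"test side forced to at least 1")
        rng = np.random.default_rng((seed, name == "neg"))
        order = list(ids)
        rng.shuffle(order)
        n_test = max(1, int(round(0.2 * len(ids))))
        out[name] = (tuple(sorted(order[n_test:])),
                     tuple(sorted(order[:n_test])))
    return BenchmarkSplit(train_pos=out["pos"][0], train_neg=out["neg"][0],
                          test_pos=out["pos"][1], test_neg=out["neg"][1],
                          seed=seed)


def curate(pos_records, neg_records, threshold: float = 0.25, seed: int = 0,
           oracle=None, max_rounds: int = 5):
    """Full curation workflow.

    Filters both classes, reduces each within-class to the identity
    threshold, removes negatives matching any positive, and splits 80-20 per
    class.  Returns ``(split, report)`` where report maps stage names to
    counts and drop reasons.
    """
    oracle = oracle or PairwiseIdentity()
    report = {}
    pos_kept, pos_drop = filter_records(pos_records)
    neg_kept, neg_drop = filter_records(neg_records)
    report["filtered"] = {"pos": len(pos_kept), "neg": len(neg_kept),
                          "dropped": pos_drop + neg_drop}
    pos_red = reduce_to_fixpoint(pos_kept, threshold, oracle, max_rounds)
    neg_red = reduce_to_fixpoint(neg_kept, threshold, oracle, max_rounds)
    report["within_class"] = {"pos": len(pos_red), "neg": len(neg_red)}
    neg_final = cross_class_reduce(pos_red, neg_red, threshold, oracle)
    report["between_class"] = {"pos": len(pos_red), "neg": len(neg_final)}
    split = split_80_20([r.id for r in pos_red], [r.id for r in neg_final],
                        seed=seed)
    return split, report
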