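"""Seeded synthetic fixtures: sequences, PSSMs, structural profiles.

Stands in for curated benchmark sets so the whole pipeline is testable
offline.  Positive-class sequences mix a shared background residue
distribution with a class-specific composition (mass shifted toward the
K/R/H/S/T residues that dominate nucleic-acid-binding interfaces);
``signal_strength`` interpolates between indistinguishable classes (0) and a
fully class-specific composition (1).  Matched synthetic PSSMs elevate each
row at the query residue's column; structural profiles are drawn from simple
valid distributions.  Every generator is a pure function of its inputs and
seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np

from .physchem import AA_ALPHABET
from .sequence_io import ProteinRecord, PSSMProfile, StructProfile

__all__ = ["FixtureSpec", "gen_benchmark", "gen_pssm", "gen_struct_profile",
           "POSITIVE_COMPOSITION"]

#: Class-specific residue distribution of the positive class: uniform over the
#: basic/polar residues enriched at DNA contacts.
POSITIVE_COMPOSITION = np.array(
    [0.2 if a in "KRHST" else 0.0 for a in AA_ALPHABET]
)

_BACKGROUND = np.full(20, 0.05)


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic two-class benchmark.

    Minimum length defaults to 51 so the curation fragment filter (length
    <= 50) is not triggered accidentally.
    """

    n_pos: int = 200
    n_neg: int = 200
    length_range: tuple = (51, 120)
    seed: int = 0
    signal_strength: float = 1.0
    dipeptide_bias: dict | None = None

    def __post_init__(self):
        lo, hi = self.length_range
        if lo < 51:
            raise ValueError("minimum length must be >= 51")
        if hi < lo:
            raise ValueError("length_range must be (min, max) with max >= min")
        if not 0.0 <= self.signal_strength <= 1.0:
            raise ValueError("signal_strength must lie in [0, 1]")
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("class sizes must be positive")


def _sub_seed(seed: int, tag: str) -> int:
    return (int(seed) * 1_000_003 + zlib.crc32(tag.encode())) % (2**31 - 1)


def _sample_sequence(rng, length, comp, dipeptide_bias=None):
    letters = list(AA_ALPHABET)
    if not dipeptide_bias:
        idx = rng.choice(20, size=length, p=comp)
        return "".join(letters[i] for i in idx)
    # first-order tweak: after residue a, dipeptide (a, b) with excess
    # probability eps picks b directly; otherwise sample from comp.
    out = [letters[rng.choice(20, p=comp)]]
    by_first = {}
    for (pair, eps) in dipeptide_bias.items():
        by_first.setdefault(pair[0], []).append((pair[1], float(eps)))
    for _ in range(length - 1):
        prev = out[-1]
        choices = by_first.get(prev, [])
        total = sum(e for _, e in choices)
        u = rng.random()
        nxt = None
        if u < total:
            acc = 0.0
            for b, e in choices:
                acc += e
                if u < acc:
                    nxt = b
                    break
        if nxt is None:
            nxt = letters[rng.choice(20, p=comp)]
        out.append(nxt)
    return "".join(out)


def gen_benchmark(spec: FixtureSpec):
    """Generate a labeled two-class benchmark.

    Returns ``(records, labels)`` with labels a 0/1 integer array aligned with
    the record list (positives first).  Deterministic for a fixed spec.
    """
    rng = np.random.default_rng(_sub_seed(spec.seed, "benchmark"))
    s = spec.signal_strength
    pos_comp = (1.0 - s) * _BACKGROUND + s * POSITIVE_COMPOSITION
    records = []
    labels = []
    lo, hi = spec.length_range
    for k in range(spec.n_pos):
        L = int(rng.integers(lo, hi + 1))
        seq = _sample_sequence(rng, L, pos_comp, spec.dipeptide_bias)
        records.append(ProteinRecord(f"pos_{k:04d}", seq))
        labels.append(1)
    for k in range(spec.n_neg):
        L = int(rng.integers(lo, hi + 1))
        seq = _sample_sequence(rng, L, _BACKGROUND)
        records.append(ProteinRecord(f"neg_{k:04d}", seq))
        labels.append(0)
    return records, np.array(labels, dtype=int)


def gen_pssm(record: ProteinRecord, seed: int, strength: float = 1.0,
             noise: int = 3, elevation: int = 8) -> PSSMProfile:
    """Synthetic log-odds profile whose row maxima track the query residue.

    Row i gets ``round(strength * elevation)`` added at the column of residue
    R_i on top of integer noise drawn uniformly from [-noise, noise].
    Deterministic per (record, seed).
    """
    if not 0.0 <= strength <= 1.0:
        raise ValueError("strength must lie in [0, 1]")
    rng = np.random.default_rng(_sub_seed(seed, "pssm:" + record.id))
    L = record.length
    scores = rng.integers(-noise, noise + 1, size=(L, 20)) if noise > 0 \
        else np.zeros((L, 20), dtype=int)
    boost = int(round(strength * elevation))
    for i, a in enumerate(record.sequence):
        scores[i, AA_ALPHABET.index(a)] += boost
    return PSSMProfile(record.id, record.sequence, scores.astype(int))


def gen_struct_profile(record: ProteinRecord, seed: int) -> StructProfile:
    """Valid synthetic structural profile matched to a record's length."""
    rng = np.random.default_rng(_sub_seed(seed, "struct:" + record.id))
    L = record.length
    ss3 = rng.dirichlet(np.array([2.0, 1.5, 2.5]), size=L)
    asa = np.abs(rng.normal(60.0, 25.0, size=L))
    torsion = rng.uniform(-180.0, 180.0, size=(L, 4))
    hse = rng.poisson(8.0, size=(L, 2)).astype(float)
    return StructProfile(record.id, ss3, asa, torsion, hse)
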