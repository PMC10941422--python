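"""Sequence-origin feature encoders.

Fixed-length descriptor families computed from the primary sequence alone,
in the pseudo-amino-acid-composition tradition: a variable-length protein
``P = R1..RL`` is mapped to a vector ``[psi_1 .. psi_Omega]`` whose
construction preserves composition and sequence-order information.  Every
encoder is registered with its dimension formula, default parameters and
minimum sequence length; ``encode`` dispatches by :class:`EncoderSpec`.

Composition-family outputs (AAC, DPC, TPC, GAAC, GDPC, GTPC, CTDC) are
frequency-normalized and sum to 1.  Any division with a zero denominator
yields 0, never NaN.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import physchem as pc
from .physchem import AA_ALPHABET, AA_INDEX
from .sequence_io import ProteinRecord

__all__ = [
    "EncoderSpec", "FeatureVector", "list_encoders", "encode",
    "encode_records", "encode_knnpeptide", "feature_bank_dimension",
    "DEFAULT_BANK",
]


@dataclass(frozen=True)
class EncoderSpec:
    """A registered encoder name plus parameter overrides."""

    name: str
    params: dict = field(default_factory=dict)


@dataclass(frozen=True)
class FeatureVector:
    """Ordered feature labels (encoder-prefixed) and their values."""

    names: tuple
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if len(self.names) != v.shape[0]:
            raise ValueError("names/values length mismatch")
        if not np.isfinite(v).all():
            raise ValueError("non-finite feature values")
        object.__setattr__(self, "values", v)


def _safe_div(num, den):
    num = np.asarray(num, dtype=float)
    den = np.asarray(den, dtype=float)
    out = np.zeros(np.broadcast_shapes(num.shape, den.shape))
    np.divide(num, den, out=out, where=den != 0)
    return out


def _seq_indices(seq: str) -> np.ndarray:
    return np.fromiter((AA_INDEX[a] for a in seq), dtype=int, count=len(seq))


_PAIRS = ["".join(p) for p in itertools.product(AA_ALPHABET, repeat=2)]
_TRIPLES = ["".join(p) for p in itertools.product(AA_ALPHABET, repeat=3)]


# ---------------------------------------------------------------------------
# composition families
# ---------------------------------------------------------------------------

def _aac(seq):
    counts = np.bincount(_seq_indices(seq), minlength=20)
    return list(AA_ALPHABET), counts / len(seq)


def _kmer_freq(seq, k, offset=1):
    """Frequency of (s[i], s[i+offset], ...) k-tuples with stride ``offset``
    between consecutive members (offset 1 = contiguous k-mers)."""
    idx = _seq_indices(seq)
    n = len(seq) - (k - 1) * offset
    counts = np.zeros(20 ** k)
    if n > 0:
        code = np.zeros(n, dtype=int)
        for j in range(k):
            code = code * 20 + idx[j * offset: j * offset + n]
        np.add.at(counts, code, 1.0)
        counts /= n
    return counts


def _dpc(seq):
    return _PAIRS, _kmer_freq(seq, 2)


def _tpc(seq):
    return _TRIPLES, _kmer_freq(seq, 3)


def _ngdip(seq, gaps=(1, 2, 3, 4, 5)):
    names, vals = [], []
    for g in gaps:
        names += [f"g{g}.{p}" for p in _PAIRS]
        vals.append(_kmer_freq(seq, 2, offset=g + 1))
    return names, np.concatenate(vals)


_GROUP_NAMES = list(pc.GAAC_GROUPS)
_GROUP_OF = {}
for _gname, _members in pc.GAAC_GROUPS.items():
    for _a in _members:
        _GROUP_OF[_a] = _GROUP_NAMES.index(_gname)


def _group_indices(seq):
    return np.fromiter((_GROUP_OF[a] for a in seq), dtype=int, count=len(seq))


def _grouped_kmer(seq, k, offset=1, n_groups=5):
    idx = _group_indices(seq)
    n = len(seq) - (k - 1) * offset
    counts = np.zeros(n_groups ** k)
    if n > 0:
        code = np.zeros(n, dtype=int)
        for j in range(k):
            code = code * n_groups + idx[j * offset: j * offset + n]
        np.add.at(counts, code, 1.0)
        counts /= n
    return counts


def _gaac(seq):
    counts = np.bincount(_group_indices(seq), minlength=5)
    return _GROUP_NAMES, counts / len(seq)


def _gkmer_names(k):
    return [".".join(t) for t in itertools.product(_GROUP_NAMES, repeat=k)]


def _gdpc(seq):
    return _gkmer_names(2), _grouped_kmer(seq, 2)


def _gtpc(seq):
    return _gkmer_names(3), _grouped_kmer(seq, 3)


def _ngaagp(seq, gaps=(1, 2, 3, 4, 5)):
    names, vals = [], []
    pair_names = _gkmer_names(2)
    for g in gaps:
        names += [f"g{g}.{p}" for p in pair_names]
        vals.append(_grouped_kmer(seq, 2, offset=g + 1))
    return names, np.concatenate(vals)


# ---------------------------------------------------------------------------
# positional / segmented families
# ---------------------------------------------------------------------------

def _psn(seq, window=5, ns=(1, 2)):
    """Position-specific n-grams: n-gram composition of the N-terminal and
    C-terminal windows."""
    names, vals = [], []
    for side, sub in (("nt", seq[:window]), ("ct", seq[-window:])):
        for n in ns:
            grams = _PAIRS if n == 2 else list(AA_ALPHABET)
            names += [f"{side}.n{n}.{g}" for g in grams]
            vals.append(_kmer_freq(sub, n) if len(sub) >= n
                        else np.zeros(20 ** n))
    return names, np.concatenate(vals)


def _segments(seq, n_bins):
    return [s for s in np.array_split(list(seq), n_bins)]


def _mps(seq, n_bins=4):
    """Monogram percentile separation: residue composition per percentile
    segment of the sequence."""
    names, vals = [], []
    for b, seg in enumerate(_segments(seq, n_bins)):
        names += [f"q{b + 1}.{a}" for a in AA_ALPHABET]
        sub = "".join(seg)
        vals.append(_aac(sub)[1] if sub else np.zeros(20))
    return names, np.concatenate(vals)


def _bps(seq, n_bins=4):
    """Bigram percentile separation: bigram composition per percentile
    segment."""
    names, vals = [], []
    for b, seg in enumerate(_segments(seq, n_bins)):
        names += [f"q{b + 1}.{p}" for p in _PAIRS]
        sub = "".join(seg)
        vals.append(_kmer_freq(sub, 2) if len(sub) >= 2 else np.zeros(400))
    return names, np.concatenate(vals)


def _nnb(seq):
    """Nearest-neighbor bigram: for each ordered residue pair (a, b), the mean
    over occurrences of a of the inverse distance to the nearest b."""
    positions = {a: [] for a in AA_ALPHABET}
    for i, a in enumerate(seq):
        positions[a].append(i)
    pos_arrays = {a: np.array(p) for a, p in positions.items() if p}
    vals = np.zeros(400)
    for ai, a in enumerate(AA_ALPHABET):
        pa = pos_arrays.get(a)
        if pa is None:
            continue
        for bi, b in enumerate(AA_ALPHABET):
            pb = pos_arrays.get(b)
            if pb is None:
                continue
            total = 0.0
            cnt = 0
            for i in pa:
                d = np.abs(pb - i)
                d = d[d > 0]
                if d.size:
                    total += 1.0 / d.min()
                    cnt += 1
            if cnt:
                vals[ai * 20 + bi] = total / cnt
    return [f"{p}" for p in _PAIRS], vals


# ---------------------------------------------------------------------------
# CTD families
# ---------------------------------------------------------------------------

def _partition_indices(seq, groups):
    gmap = {}
    for gi, members in enumerate(groups):
        for a in members:
            gmap[a] = gi
    return np.fromiter((gmap[a] for a in seq), dtype=int, count=len(seq))


def _ctd_c(idx):
    return np.bincount(idx, minlength=3) / idx.size


def _ctd_t(idx):
    out = np.zeros(3)
    if idx.size < 2:
        return out
    a, b = idx[:-1], idx[1:]
    for k, (g1, g2) in enumerate(((0, 1), (0, 2), (1, 2))):
        out[k] = np.sum(((a == g1) & (b == g2)) | ((a == g2) & (b == g1)))
    return out / (idx.size - 1)


def _ctd_d(idx):
    """Distribution: relative positions of the first / 25% / 50% / 75% / last
    occurrence of each group (0 if absent)."""
    L = idx.size
    out = np.zeros(15)
    for g in range(3):
        where = np.flatnonzero(idx == g)
        if where.size == 0:
            continue
        n = where.size
        for qi, q in enumerate((0.0, 0.25, 0.5, 0.75, 1.0)):
            k = max(1, int(np.ceil(q * n)))
            out[g * 5 + qi] = (where[k - 1] + 1) / L
    return out


def _ctdc(seq, partitions=None):
    partitions = partitions or pc.CTD_PARTITIONS
    names, vals = [], []
    for pname, groups in partitions.items():
        idx = _partition_indices(seq, groups)
        names += [f"{pname}.g{g + 1}" for g in range(3)]
        vals.append(_ctd_c(idx))
    return names, np.concatenate(vals)


def _ctdt(seq, partitions=None):
    partitions = partitions or pc.CTD_PARTITIONS
    names, vals = [], []
    for pname, groups in partitions.items():
        idx = _partition_indices(seq, groups)
        names += [f"{pname}.t{k}" for k in ("12", "13", "23")]
        vals.append(_ctd_t(idx))
    return names, np.concatenate(vals)


def _dubchak(seq, partitions=None):
    """Full composition/transition/distribution descriptor over the seven
    canonical attribute partitions (21 values each)."""
    partitions = partitions or pc.CTD_CANONICAL_PARTITIONS
    names, vals = [], []
    for pname, groups in partitions.items():
        idx = _partition_indices(seq, groups)
        names += [f"{pname}.c{g + 1}" for g in range(3)]
        names += [f"{pname}.t{k}" for k in ("12", "13", "23")]
        names += [f"{pname}.d.g{g + 1}.q{q}" for g in range(3)
                  for q in (0, 25, 50, 75, 100)]
        vals += [_ctd_c(idx), _ctd_t(idx), _ctd_d(idx)]
    return names, np.concatenate(vals)


# ---------------------------------------------------------------------------
# conjoint triads
# ---------------------------------------------------------------------------

_CT_OF = {}
for _ci, _members in enumerate(pc.CTRIAD_GROUPS):
    for _a in _members:
        _CT_OF[_a] = _ci
_CT_NAMES = [f"{i + 1}.{j + 1}.{k + 1}"
             for i in range(7) for j in range(7) for k in range(7)]


def _ctriad_counts(seq, spacing=0):
    idx = np.fromiter((_CT_OF[a] for a in seq), dtype=int, count=len(seq))
    step = spacing + 1
    n = len(seq) - 2 * step
    counts = np.zeros(343)
    if n > 0:
        code = idx[:n] * 49 + idx[step: step + n] * 7 + idx[2 * step: 2 * step + n]
        np.add.at(counts, code, 1.0)
        counts /= n
    return counts


def _ctriad(seq):
    return _CT_NAMES, _ctriad_counts(seq, 0)


def _ksctriad(seq, ks=(0, 1, 2, 3)):
    names, vals = [], []
    for k in ks:
        names += [f"k{k}.{n}" for n in _CT_NAMES]
        vals.append(_ctriad_counts(seq, k))
    return names, np.concatenate(vals)


# ---------------------------------------------------------------------------
# DDE
# ---------------------------------------------------------------------------

def _dde(seq):
    """Dipeptide deviation from the expected mean under codon usage:
    (observed - theoretical mean) / theoretical standard deviation."""
    L = len(seq)
    dc = _kmer_freq(seq, 2)
    ca = np.array([pc.CODON_COUNTS[a] for a in AA_ALPHABET]) / pc.N_SENSE_CODONS
    tm = np.outer(ca, ca).ravel()
    tv = tm * (1.0 - tm) / (L - 1)
    return _PAIRS, _safe_div(dc - tm, np.sqrt(tv))


# ---------------------------------------------------------------------------
# sequence-order-coupling families
# ---------------------------------------------------------------------------

def _coupling_sums(seq, matrix, lam):
    idx = _seq_indices(seq)
    L = len(seq)
    return np.array([
        float(np.sum(matrix[idx[:L - d], idx[d:]] ** 2)) for d in range(1, lam + 1)
    ])


def _socnumber(seq, lam=8, matrices=None):
    matrices = matrices or pc.DISTANCE_MATRICES
    names, vals = [], []
    for mname, m in matrices.items():
        names += [f"{mname}.d{d}" for d in range(1, lam + 1)]
        vals.append(_coupling_sums(seq, m, lam))
    return names, np.concatenate(vals)


def _qsorder(seq, lam=8, w=0.1, matrices=None):
    matrices = matrices or pc.DISTANCE_MATRICES
    freqs = _aac(seq)[1] * len(seq)  # raw counts
    names, vals = [], []
    for mname, m in matrices.items():
        tau = _coupling_sums(seq, m, lam)
        den = freqs.sum() + w * tau.sum()
        names += [f"{mname}.f.{a}" for a in AA_ALPHABET]
        vals.append(_safe_div(freqs, den))
        names += [f"{mname}.tau{d}" for d in range(1, lam + 1)]
        vals.append(_safe_div(w * tau, den))
    return names, np.concatenate(vals)


_PAAC_PROPS = [pc.HYDROPHOBICITY_PSE, pc.HYDROPHILICITY, pc.SIDE_CHAIN_MASS]


def _paac(seq, lam=8, w=0.05):
    props = np.stack([pc.scale_vector(s, standardize=True)
                      for s in _PAAC_PROPS])
    idx = _seq_indices(seq)
    L = len(seq)
    theta = np.array([
        np.mean((props[:, idx[d:]] - props[:, idx[:L - d]]) ** 2)
        for d in range(1, lam + 1)
    ])
    f = np.bincount(idx, minlength=20) / L
    den = f.sum() + w * theta.sum()
    names = [f"f.{a}" for a in AA_ALPHABET] + [f"theta{d}" for d in range(1, lam + 1)]
    return names, np.concatenate([_safe_div(f, den), _safe_div(w * theta, den)])


def _apaac(seq, lam=8, w=0.05):
    props = np.stack([pc.scale_vector(s, standardize=True)
                      for s in (pc.HYDROPHOBICITY_PSE, pc.HYDROPHILICITY)])
    idx = _seq_indices(seq)
    L = len(seq)
    taus = []
    for d in range(1, lam + 1):
        for p in range(2):
            taus.append(np.mean(props[p, idx[:L - d]] * props[p, idx[d:]]))
    taus = np.array(taus)
    f = np.bincount(idx, minlength=20) / L
    den = f.sum() + w * taus.sum()
    names = [f"f.{a}" for a in AA_ALPHABET] + [
        f"tau{d}.p{p + 1}" for d in range(1, lam + 1) for p in range(2)
    ]
    return names, np.concatenate([_safe_div(f, den), _safe_div(w * taus, den)])


# ---------------------------------------------------------------------------
# autocorrelation families
# ---------------------------------------------------------------------------

def _autocorr(seq, kind, scales=None, max_lag=8):
    scales = scales or pc.AUTOCORR_SCALES
    idx = _seq_indices(seq)
    L = len(seq)
    names, vals = [], []
    for sname, scale in scales.items():
        p = pc.scale_vector(scale, standardize=True)[idx]
        pbar = p.mean()
        dev = p - pbar
        denom_var = np.sum(dev ** 2)
        if denom_var < 1e-12:  # zero-variance sequence: normalized kinds -> 0
            denom_var = 0.0
            dev = np.zeros_like(dev)
        for d in range(1, max_lag + 1):
            names.append(f"{sname}.lag{d}")
            if kind == "Moran":
                num = np.sum(dev[:L - d] * dev[d:]) / (L - d)
                vals.append(float(_safe_div(num, denom_var / L)))
            elif kind == "Geary":
                num = np.sum((p[:L - d] - p[d:]) ** 2) / (2 * (L - d))
                vals.append(float(_safe_div(num, denom_var / (L - 1))))
            elif kind == "NMBroto":
                vals.append(float(np.sum(p[:L - d] * p[d:]) / (L - d)))
            else:
                raise ValueError(f"unknown autocorrelation kind {kind!r}")
    return names, np.array(vals)


def encode_autocorrelation(record: ProteinRecord, kind: str,
                           properties=None, max_lag: int = 8) -> FeatureVector:
    """Moran / Geary / normalized Moreau-Broto autocorrelation descriptors.

    Property scales are standardized over the 20 residues before use.  A
    zero-variance sequence (homopolymer) yields 0 by convention for the
    normalized kinds.
    """
    if record.length <= max_lag:
        raise ValueError(
            f"{kind}: sequence {record.id!r} of length {record.length} "
            f"is too short for max_lag={max_lag}"
        )
    names, vals = _autocorr(record.sequence, kind, properties, max_lag)
    return FeatureVector(tuple(f"{kind}.{n}" for n in names), vals)


# ---------------------------------------------------------------------------
# KNNpeptide
# ---------------------------------------------------------------------------

def encode_knnpeptide(record: ProteinRecord, train_records, train_labels,
                      k_fracs=(0.02, 0.05, 0.1, 0.2, 0.3),
                      identity_fn=None) -> FeatureVector:
    """For each k fraction, the proportion of positive labels among the top-k
    training sequences most similar to the query (global-alignment identity).

    The training pool must be fold-internal during cross-validation; the
    query itself is excluded when present in the pool.
    """
    if len(train_records) == 0:
        raise ValueError("KNNpeptide: empty training pool")
    if identity_fn is None:
        from .curation import PairwiseIdentity
        identity_fn = PairwiseIdentity()
    pool = [(r, y) for r, y in zip(train_records, train_labels)
            if r.id != record.id]
    if not pool:
        raise ValueError("KNNpeptide: pool contains only the query")
    sims = np.array([identity_fn(record.sequence, r.sequence) for r, _ in pool])
    ys = np.array([y for _, y in pool], dtype=float)
    order = np.argsort(-sims, kind="stable")
    names, vals = [], []
    for f in k_fracs:
        k = max(1, int(round(f * len(pool))))
        names.append(f"KNNpeptide.top{f:g}")
        vals.append(float(ys[order[:k]].mean()))
    return FeatureVector(tuple(names), np.array(vals))


def encode_dde(record: ProteinRecord) -> FeatureVector:
    """Dipeptide deviation from expected mean (codon-usage null model)."""
    if record.length < 2:
        raise ValueError(f"DDE: sequence {record.id!r} shorter than 2")
    names, vals = _dde(record.sequence)
    return FeatureVector(tuple(f"DDE.{n}" for n in names), vals)


# ---------------------------------------------------------------------------
# registry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _Entry:
    func: object
    dim: object          # params -> int
    defaults: dict
    min_length: object   # params -> int
    doc: str


def _const(n):
    return lambda p: n


_REGISTRY = {
    "AAC": _Entry(lambda s, **p: _aac(s), _const(20), {}, _const(1),
                  "amino-acid composition"),
    "DPC": _Entry(lambda s, **p: _dpc(s), _const(400), {}, _const(2),
                  "dipeptide composition"),
    "TPC": _Entry(lambda s, **p: _tpc(s), _const(8000), {}, _const(3),
                  "tripeptide composition"),
    "nGDip": _Entry(lambda s, **p: _ngdip(s, **p),
                    lambda p: 400 * len(p.get("gaps", (1, 2, 3, 4, 5))),
                    {"gaps": (1, 2, 3, 4, 5)},
                    lambda p: max(p.get("gaps", (1, 2, 3, 4, 5))) + 2,
                    "n-gapped dipeptide composition"),
    "PSN": _Entry(lambda s, **p: _psn(s, **p), _const(840), {},
                  _const(10), "terminal-window position-specific n-grams"),
    "MPS": _Entry(lambda s, **p: _mps(s, **p),
                  lambda p: 20 * p.get("n_bins", 4), {"n_bins": 4},
                  lambda p: p.get("n_bins", 4),
                  "monogram percentile separation"),
    "BPS": _Entry(lambda s, **p: _bps(s, **p),
                  lambda p: 400 * p.get("n_bins", 4), {"n_bins": 4},
                  lambda p: 2 * p.get("n_bins", 4),
                  "bigram percentile separation"),
    "NNB": _Entry(lambda s, **p: _nnb(s), _const(400), {}, _const(2),
                  "nearest-neighbor bigram"),
    "Dubchak": _Entry(lambda s, **p: _dubchak(s), _const(147), {}, _const(2),
                      "CTD over the 7 canonical attribute partitions"),
    "DDE": _Entry(lambda s, **p: _dde(s), _const(400), {}, _const(2),
                  "dipeptide deviation from expected mean"),
    "GAAC": _Entry(lambda s, **p: _gaac(s), _const(5), {}, _const(1),
                   "grouped amino-acid composition"),
    "GDPC": _Entry(lambda s, **p: _gdpc(s), _const(25), {}, _const(2),
                   "grouped dipeptide composition"),
    "GTPC": _Entry(lambda s, **p: _gtpc(s), _const(125), {}, _const(3),
                   "grouped tripeptide composition"),
    "nGAAGP": _Entry(lambda s, **p: _ngaagp(s, **p),
                     lambda p: 25 * len(p.get("gaps", (1, 2, 3, 4, 5))),
                     {"gaps": (1, 2, 3, 4, 5)},
                     lambda p: max(p.get("gaps", (1, 2, 3, 4, 5))) + 2,
                     "n-gapped amino-acid group pairs"),
    "CTDC": _Entry(lambda s, **p: _ctdc(s), _const(39), {}, _const(1),
                   "composition descriptor, 13 attribute partitions"),
    "CTDT": _Entry(lambda s, **p: _ctdt(s), _const(39), {}, _const(2),
                   "transition descriptor, 13 attribute partitions"),
    "CTriad": _Entry(lambda s, **p: _ctriad(s), _const(343), {}, _const(3),
                     "conjoint triad"),
    "KSCTriad": _Entry(lambda s, **p: _ksctriad(s, **p),
                       lambda p: 343 * len(p.get("ks", (0, 1, 2, 3))),
                       {"ks": (0, 1, 2, 3)},
                       lambda p: 2 * max(p.get("ks", (0, 1, 2, 3))) + 3,
                       "k-spaced conjoint triad"),
    "SOCNumber": _Entry(lambda s, **p: _socnumber(s, **p),
                        lambda p: p.get("lam", 8) * 2, {"lam": 8},
                        lambda p: p.get("lam", 8) + 1,
                        "sequence-order-coupling numbers"),
    "QSOrder": _Entry(lambda s, **p: _qsorder(s, **p),
                      lambda p: (20 + p.get("lam", 8)) * 2,
                      {"lam": 8, "w": 0.1},
                      lambda p: p.get("lam", 8) + 1,
                      "quasi-sequence-order"),
    "PAAC": _Entry(lambda s, **p: _paac(s, **p),
                   lambda p: 20 + p.get("lam", 8), {"lam": 8, "w": 0.05},
                   lambda p: p.get("lam", 8) + 1,
                   "pseudo amino-acid composition"),
    "APAAC": _Entry(lambda s, **p: _apaac(s, **p),
                    lambda p: 20 + 2 * p.get("lam", 8), {"lam": 8, "w": 0.05},
                    lambda p: p.get("lam", 8) + 1,
                    "amphiphilic pseudo amino-acid composition"),
    "Moran": _Entry(lambda s, **p: _autocorr(s, "Moran", **p),
                    lambda p: len(p.get("scales") or pc.AUTOCORR_SCALES)
                    * p.get("max_lag", 8),
                    {"max_lag": 8},
                    lambda p: p.get("max_lag", 8) + 1,
                    "Moran autocorrelation"),
    "Geary": _Entry(lambda s, **p: _autocorr(s, "Geary", **p),
                    lambda p: len(p.get("scales") or pc.AUTOCORR_SCALES)
                    * p.get("max_lag", 8),
                    {"max_lag": 8},
                    lambda p: p.get("max_lag", 8) + 1,
                    "Geary autocorrelation"),
    "NMBroto": _Entry(lambda s, **p: _autocorr(s, "NMBroto", **p),
                      lambda p: len(p.get("scales") or pc.AUTOCORR_SCALES)
                      * p.get("max_lag", 8),
                      {"max_lag": 8},
                      lambda p: p.get("max_lag", 8) + 1,
                      "normalized Moreau-Broto autocorrelation"),
    "KNNpeptide": _Entry(None, lambda p: len(p.get("k_fracs",
                                                   (0.02, 0.05, 0.1, 0.2, 0.3))),
                         {"k_fracs": (0.02, 0.05, 0.1, 0.2, 0.3)},
                         _const(1),
                         "positive fraction among most-similar pool members "
                         "(requires a labeled training pool)"),
}

#: Encoders included in batch encoding by default.  KNNpeptide is excluded:
#: it needs a labeled pool and must be computed fold-internally during CV.
DEFAULT_BANK = [n for n in _REGISTRY if n != "KNNpeptide"]


def list_encoders() -> pd.DataFrame:
    """Registry table: encoder name, default dimension, defaults, summary."""
    rows = []
    for name, e in _REGISTRY.items():
        rows.append({
            "name": name,
            "dimension": e.dim(e.defaults),
            "default_params": dict(e.defaults),
            "min_length": e.min_length(e.defaults),
            "description": e.doc,
        })
    return pd.DataFrame(rows).set_index("name")


def encode(record: ProteinRecord, spec: EncoderSpec) -> FeatureVector:
    """Encode one record with one registered encoder."""
    if spec.name not in _REGISTRY:
        raise KeyError(f"unknown encoder {spec.name!r}")
    if spec.name == "KNNpeptide":
        raise ValueError("KNNpeptide requires a pool; use encode_knnpeptide")
    entry = _REGISTRY[spec.name]
    params = {**entry.defaults, **spec.params}
    min_len = entry.min_length(params)
    if record.length < min_len:
        raise ValueError(
            f"{spec.name}: sequence {record.id!r} of length {record.length} "
            f"is shorter than the encoder minimum {min_len}"
        )
    if not record.is_canonical:
        raise ValueError(
            f"{spec.name}: sequence {record.id!r} contains non-canonical "
            f"residues; filter before encoding"
        )
    names, vals = entry.func(record.sequence, **params)
    vec = FeatureVector(tuple(f"{spec.name}.{n}" for n in names),
                        np.asarray(vals, dtype=float))
    expect = entry.dim(params)
    if len(vec.names) != expect:
        raise AssertionError(
            f"{spec.name}: produced {len(vec.names)} features, "
            f"registered dimension is {expect}"
        )
    return vec


def encode_records(records, specs=None) -> pd.DataFrame:
    """Batch-encode records into a feature matrix (rows = record ids).

    ``specs`` is a list of EncoderSpec or encoder names; defaults to the full
    default bank.  Encoding a batch equals encoding each record independently.
    """
    if specs is None:
        specs = DEFAULT_BANK
    specs = [s if isinstance(s, EncoderSpec) else EncoderSpec(s) for s in specs]
    rows, index = [], []
    columns = None
    for rec in records:
        parts = [encode(rec, s) for s in specs]
        names = tuple(n for p in parts for n in p.names)
        if columns is None:
            columns = names
        elif names != columns:
            raise AssertionError("inconsistent feature names across records")
        rows.append(np.concatenate([p.values for p in parts]))
        index.append(rec.id)
    return pd.DataFrame(np.vstack(rows), index=index, columns=list(columns))


def feature_bank_dimension(specs=None) -> int:
    """Total dimensionality of the (default) encoder bank."""
    if specs is None:
        specs = DEFAULT_BANK
    total = 0
    for s in specs:
        s = s if isinstance(s, EncoderSpec) else EncoderSpec(s)
        entry = _REGISTRY[s.name]
        total += entry.dim({**entry.defaults, **s.params})
    return total


def write_feature_table(df: pd.DataFrame, path) -> None:
    """Tab-separated feature table: header = feature names, first column id."""
    df.to_csv(path, sep="\t", index_label="id")


def read_feature_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="id")
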