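"""PSSM-origin descriptors.

All encoders operate on the logistic-normalized score matrix
``N = 1 / (1 + exp(-S))`` (values in (0, 1)); the raw integer log-odds matrix
comes from :class:`~dbpstack.sequence_io.PSSMProfile`.  Column order is
alphabetical everywhere (remapped once at parse time), so these encoders are
invariant to trailing non-score columns in the source file.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .physchem import AA_ALPHABET, AA_INDEX
from .sequence_io import PSSMProfile
from .features_sequence import FeatureVector

__all__ = [
    "normalize_pssm", "encode_local_pse_pssm", "encode_pssm_bigram",
    "encode_pssm_composition", "encode_pssm_autocov",
    "encode_pssm_segmented_distribution", "encode_pssm_bank",
    "encode_pssm_records",
]

_CLAMP = 30.0


def normalize_pssm(profile: PSSMProfile) -> np.ndarray:
    """Elementwise logistic transform of the log-odds scores.

    Scores are clamped to [-30, 30] first (real log-odds rarely leave
    [-16, 16]) so the output is always finite and strictly inside (0, 1) in
    float64; the transform is monotone.
    """
    x = np.clip(profile.scores.astype(float), -_CLAMP, _CLAMP)
    return 1.0 / (1.0 + np.exp(-x))


def _pse_block(N: np.ndarray, lam: int, prefix: str):
    """20 column means + 20*lam averaged squared lag-differences."""
    L = N.shape[0]
    if L <= lam:
        raise ValueError(
            f"segment of length {L} too short for lag {lam}"
        )
    names = [f"{prefix}mean.{a}" for a in AA_ALPHABET]
    vals = [N.mean(axis=0)]
    for g in range(1, lam + 1):
        names += [f"{prefix}lag{g}.{a}" for a in AA_ALPHABET]
        vals.append(((N[:-g] - N[g:]) ** 2).mean(axis=0))
    return names, np.concatenate(vals)


def encode_local_pse_pssm(profile: PSSMProfile, n: int = 1,
                          lam: int = 8) -> FeatureVector:
    """Segment-local pseudo-PSSM: per contiguous segment, the 20 column means
    of the normalized matrix plus 20*lam averaged squared lag-differences.

    Segments are equal splits of the rows; the last segment absorbs the
    remainder.  Dimension n * (20 + 20*lam).  n = 1 is the global form.
    """
    if n < 1 or lam < 1:
        raise ValueError("n and lam must be >= 1")
    N = normalize_pssm(profile)
    L = N.shape[0]
    base = L // n
    if base <= lam:
        raise ValueError(
            f"profile {profile.record_id!r}: segments of length {base} "
            f"(L={L}, n={n}) must be longer than lag {lam}"
        )
    names, vals = [], []
    for s in range(n):
        start = s * base
        stop = (s + 1) * base if s < n - 1 else L
        bn, bv = _pse_block(N[start:stop], lam, prefix=f"seg{s + 1}.")
        names += bn
        vals.append(bv)
    return FeatureVector(tuple(f"LPsePSSM.n{n}.{x}" for x in names),
                         np.concatenate(vals))


def encode_pssm_bigram(profile: PSSMProfile, lead: int = 0) -> FeatureVector:
    """PSSM bigram: B[j,k] = mean over i of N[i,j] * N[i+1+lead,k].

    ``lead`` 0 is the adjacent-row bigram, 1 the one-lead bigram.
    Dimension 400.
    """
    if lead not in (0, 1):
        raise ValueError("lead must be 0 or 1")
    N = normalize_pssm(profile)
    L = N.shape[0]
    step = 1 + lead
    if L <= step:
        raise ValueError(
            f"profile {profile.record_id!r}: too short (L={L}) for lead {lead}"
        )
    B = N[:-step].T @ N[step:] / (L - step)
    tag = "biPSSM" if lead == 0 else "1biPSSM"
    names = tuple(f"{tag}.{a}.{b}" for a in AA_ALPHABET for b in AA_ALPHABET)
    return FeatureVector(names, B.ravel())


def encode_pssm_composition(profile: PSSMProfile) -> FeatureVector:
    """Rows grouped by query residue identity; group-wise column means.

    Groups absent from the sequence contribute zeros.  Dimension 400.
    """
    N = normalize_pssm(profile)
    out = np.zeros((20, 20))
    idx = np.fromiter((AA_INDEX[a] for a in profile.residues), dtype=int)
    for g in range(20):
        rows = N[idx == g]
        if rows.size:
            out[g] = rows.mean(axis=0)
    names = tuple(f"compPSSM.{a}.{b}" for a in AA_ALPHABET for b in AA_ALPHABET)
    return FeatureVector(names, out.ravel())


def encode_pssm_autocov(profile: PSSMProfile, lam: int = 8) -> FeatureVector:
    """Per-column lagged auto-covariance of the normalized matrix.

    For column j and lag g: mean over i of
    (N[i,j] - mean_j)(N[i+g,j] - mean_j).  Dimension 20*lam.
    """
    N = normalize_pssm(profile)
    L = N.shape[0]
    if L <= lam:
        raise ValueError(
            f"profile {profile.record_id!r}: lag {lam} >= length {L}"
        )
    mu = N.mean(axis=0)
    D = N - mu
    vals, names = [], []
    for g in range(1, lam + 1):
        names += [f"aCovPSSM.lag{g}.{a}" for a in AA_ALPHABET]
        vals.append((D[:-g] * D[g:]).mean(axis=0))
    return FeatureVector(tuple(names), np.concatenate(vals))


def encode_pssm_segmented_distribution(profile: PSSMProfile,
                                       n_segments: int = 4) -> FeatureVector:
    """Per column, the fractional positions at which the running column sum
    first reaches k/n_segments of the column total (k = 1..n_segments).

    A zero-total column reports 0 for all its breakpoints.  Dimension
    20 * n_segments.
    """
    if n_segments < 2:
        raise ValueError("n_segments must be >= 2")
    N = normalize_pssm(profile)
    L = N.shape[0]
    csum = np.cumsum(N, axis=0)
    totals = csum[-1]
    vals = np.zeros((n_segments, 20))
    for k in range(1, n_segments + 1):
        target = totals * k / n_segments
        # first row index where cumulative sum reaches the target
        reached = csum >= target[None, :] - 1e-12
        first = np.argmax(reached, axis=0)
        vals[k - 1] = np.where(totals > 0, (first + 1) / L, 0.0)
    names = tuple(f"segDPSSM.p{k}.{a}" for k in range(1, n_segments + 1)
                  for a in AA_ALPHABET)
    return FeatureVector(names, vals.ravel())


def encode_pssm_bank(profile: PSSMProfile, ns=(1, 2, 3, 4, 5), lam: int = 8,
                     n_segments: int = 4) -> FeatureVector:
    """Default PSSM feature bank: local pseudo-PSSM for each segment count,
    bigram, one-lead bigram, composition, auto-covariance and segmented
    distribution, concatenated."""
    parts = [encode_local_pse_pssm(profile, n=n, lam=lam) for n in ns]
    parts += [
        encode_pssm_bigram(profile, lead=0),
        encode_pssm_bigram(profile, lead=1),
        encode_pssm_composition(profile),
        encode_pssm_autocov(profile, lam=lam),
        encode_pssm_segmented_distribution(profile, n_segments=n_segments),
    ]
    names = tuple(n for p in parts for n in p.names)
    return FeatureVector(names, np.concatenate([p.values for p in parts]))


def encode_pssm_records(profiles, **kwargs) -> pd.DataFrame:
    """Batch-encode PSSM profiles into a feature matrix keyed by record id."""
    rows, index = [], []
    columns = None
    for p in profiles:
        fv = encode_pssm_bank(p, **kwargs)
        if columns is None:
            columns = fv.names
        elif fv.names != columns:
            raise AssertionError("inconsistent PSSM feature names")
        rows.append(fv.values)
        index.append(p.record_id)
    return pd.DataFrame(np.vstack(rows), index=index, columns=list(columns))
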