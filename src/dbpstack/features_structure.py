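"""Structure-profile descriptors.

Computed from per-residue structural predictions (:class:`StructProfile`):
3-state secondary-structure probabilities, accessible surface area, backbone
torsion angles and half-sphere exposure.  Torsion angles enter every
statistic as (sin, cos) pairs so the -180/180 wraparound is seamless.
Output dimension depends only on (channel, statistic, lag), never on L.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .sequence_io import StructProfile
from .features_sequence import FeatureVector

__all__ = ["encode_ss", "encode_continuous", "encode_struct_bank",
           "encode_struct_records", "channel_matrix"]

_SS_STATES = ("H", "E", "C")


def channel_matrix(profile: StructProfile, channel: str,
                   normalize_asa: bool = False) -> tuple:
    """Return (column names, L x C matrix) for a named channel.

    ``torsion`` expands each of (phi, psi, theta, tau) into sin/cos columns
    (C = 8); ``asa`` is raw by default with an optional max-normalization
    flag; ``ss_probs`` C = 3; ``hse`` C = 2.
    """
    if channel == "asa":
        a = profile.asa[:, None].astype(float)
        if normalize_asa and a.max() > 0:
            a = a / a.max()
        return ["asa"], a
    if channel == "ss_probs":
        return [f"p{t}" for t in _SS_STATES], profile.ss3_probs
    if channel == "hse":
        return ["up", "down"], profile.hse
    if channel == "torsion":
        rad = np.deg2rad(profile.torsion)
        cols, names = [], []
        for j, ang in enumerate(("phi", "psi", "theta", "tau")):
            cols += [np.sin(rad[:, j]), np.cos(rad[:, j])]
            names += [f"sin_{ang}", f"cos_{ang}"]
        return names, np.stack(cols, axis=1)
    raise ValueError(f"unknown channel {channel!r}")


def encode_ss(profile: StructProfile, mode: str = "composition") -> FeatureVector:
    """Secondary-structure occurrence or composition over argmax states.

    occurrence: binary indicator that any residue's most likely state is H/E/C;
    composition: fraction of residues per argmax state (sums to 1).
    """
    states = profile.ss3_probs.argmax(axis=1)
    counts = np.bincount(states, minlength=3).astype(float)
    if mode == "occurrence":
        vals = (counts > 0).astype(float)
        tag = "occSS"
    elif mode == "composition":
        vals = counts / counts.sum()
        tag = "compSS"
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return FeatureVector(tuple(f"{tag}.{s}" for s in _SS_STATES), vals)


def encode_continuous(profile: StructProfile, channel: str,
                      stat: str = "composition", lam: int = 8,
                      normalize_asa: bool = False) -> FeatureVector:
    """Composition / bigram / auto-covariance statistics of a channel.

    composition: per-column means (dimension C); bigram: mean lag-1 outer
    products (C^2); auto_covariance: per-column lagged covariances for lags
    1..lam (C*lam).
    """
    names, M = channel_matrix(profile, channel, normalize_asa=normalize_asa)
    L, C = M.shape
    if stat == "composition":
        return FeatureVector(
            tuple(f"comp.{channel}.{n}" for n in names), M.mean(axis=0))
    if stat == "bigram":
        if L < 2:
            raise ValueError(f"profile {profile.record_id!r}: too short for bigram")
        B = M[:-1].T @ M[1:] / (L - 1)
        out_names = tuple(f"bi.{channel}.{a}.{b}" for a in names for b in names)
        return FeatureVector(out_names, B.ravel())
    if stat == "auto_covariance":
        if L <= lam:
            raise ValueError(
                f"profile {profile.record_id!r}: lag {lam} >= length {L}")
        mu = M.mean(axis=0)
        D = M - mu
        vals, out_names = [], []
        for g in range(1, lam + 1):
            out_names += [f"aCov.{channel}.lag{g}.{n}" for n in names]
            vals.append((D[:-g] * D[g:]).mean(axis=0))
        return FeatureVector(tuple(out_names), np.concatenate(vals))
    raise ValueError(f"unknown stat {stat!r}")


def encode_struct_bank(profile: StructProfile, lam: int = 8) -> FeatureVector:
    """Default structure feature bank: SS occurrence + composition, ASA
    composition, torsion/SS-probability composition, bigram and
    auto-covariance, and HSE composition."""
    parts = [
        encode_ss(profile, "occurrence"),
        encode_ss(profile, "composition"),
        encode_continuous(profile, "asa", "composition"),
        encode_continuous(profile, "torsion", "composition"),
        encode_continuous(profile, "ss_probs", "composition"),
        encode_continuous(profile, "torsion", "bigram"),
        encode_continuous(profile, "ss_probs", "bigram"),
        encode_continuous(profile, "torsion", "auto_covariance", lam=lam),
        encode_continuous(profile, "ss_probs", "auto_covariance", lam=lam),
        encode_continuous(profile, "hse", "composition"),
    ]
    names = tuple(n for p in parts for n in p.names)
    return FeatureVector(names, np.concatenate([p.values for p in parts]))


def encode_struct_records(profiles, **kwargs) -> pd.DataFrame:
    rows, index = [], []
    columns = None
    for p in profiles:
        fv = encode_struct_bank(p, **kwargs)
        if columns is None:
            columns = fv.names
        elif fv.names != columns:
            raise AssertionError("inconsistent structure feature names")
        rows.append(fv.values)
        index.append(p.record_id)
    return pd.DataFrame(np.vstack(rows), index=index, columns=list(columns))
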