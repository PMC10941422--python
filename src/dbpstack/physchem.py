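"""Amino-acid alphabets, physicochemical property scales and group partitions.

All residue-indexed tables use the alphabetical 20-letter order
``ACDEFGHIKLMNPQRSTVWY``.  PSSM files on disk use the PSI-BLAST column order
``ARNDCQEGHILKMFPSTWYV``; that remapping happens once, at parse time.
"""

from __future__ import annotations

import numpy as np

#: Canonical residues, alphabetical order — the internal column order everywhere.
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AA_ALPHABET)}

#: PSI-BLAST ASCII PSSM column order.
PSSM_FILE_ORDER = "ARNDCQEGHILKMFPSTWYV"

#: Residues treated as non-canonical (unknown or rare): flagged at parse time,
#: removed by the curation residue filter.
NON_CANONICAL = set("XBZUOJ")


def _scale(d: dict) -> dict:
    missing = set(AA_ALPHABET) - set(d)
    if missing:
        raise ValueError(f"scale missing residues {sorted(missing)}")
    return d


# Kyte-Doolittle hydropathy.
HYDROPATHY_KD = _scale({
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5, "E": -3.5,
    "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8,
    "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
})

# Hopp-Woods hydrophilicity.
HYDROPHILICITY = _scale({
    "A": -0.5, "R": 3.0, "N": 0.2, "D": 3.0, "C": -1.0, "Q": 0.2, "E": 3.0,
    "G": 0.0, "H": -0.5, "I": -1.8, "L": -1.8, "K": 3.0, "M": -1.3, "F": -2.5,
    "P": 0.0, "S": 0.3, "T": -0.4, "W": -3.4, "Y": -2.3, "V": -1.5,
})

# Consensus hydrophobicity scale used in the classic pseudo-composition encoders.
HYDROPHOBICITY_PSE = _scale({
    "A": 0.62, "R": -2.53, "N": -0.78, "D": -0.90, "C": 0.29, "Q": -0.85,
    "E": -0.74, "G": 0.48, "H": -0.40, "I": 1.38, "L": 1.06, "K": -1.50,
    "M": 0.64, "F": 1.19, "P": 0.12, "S": -0.18, "T": -0.05, "W": 0.81,
    "Y": 0.26, "V": 1.08,
})

# Side-chain mass (Da).
SIDE_CHAIN_MASS = _scale({
    "A": 15.0, "R": 101.0, "N": 58.0, "D": 59.0, "C": 47.0, "Q": 72.0,
    "E": 73.0, "G": 1.0, "H": 82.0, "I": 57.0, "L": 57.0, "K": 73.0,
    "M": 75.0, "F": 91.0, "P": 42.0, "S": 31.0, "T": 45.0, "W": 130.0,
    "Y": 107.0, "V": 43.0,
})

# Residue volume (A^3, Zamyatnin).
VOLUME = _scale({
    "A": 88.6, "R": 173.4, "N": 114.1, "D": 111.1, "C": 108.5, "Q": 143.8,
    "E": 138.4, "G": 60.1, "H": 153.2, "I": 166.7, "L": 166.7, "K": 168.6,
    "M": 162.9, "F": 189.9, "P": 112.7, "S": 89.0, "T": 116.1, "W": 227.8,
    "Y": 193.6, "V": 140.0,
})

# Isoelectric point of the free amino acid.
ISOELECTRIC_POINT = _scale({
    "A": 6.00, "R": 10.76, "N": 5.41, "D": 2.77, "C": 5.07, "Q": 5.65,
    "E": 3.22, "G": 5.97, "H": 7.59, "I": 6.02, "L": 5.98, "K": 9.74,
    "M": 5.74, "F": 5.48, "P": 6.30, "S": 5.68, "T": 5.60, "W": 5.89,
    "Y": 5.66, "V": 5.96,
})

# Net side-chain charge at physiological pH.
NET_CHARGE = _scale({
    "A": 0.0, "R": 1.0, "N": 0.0, "D": -1.0, "C": 0.0, "Q": 0.0, "E": -1.0,
    "G": 0.0, "H": 0.1, "I": 0.0, "L": 0.0, "K": 1.0, "M": 0.0, "F": 0.0,
    "P": 0.0, "S": 0.0, "T": 0.0, "W": 0.0, "Y": 0.0, "V": 0.0,
})

# Aromaticity indicator.
AROMATICITY = _scale({a: (1.0 if a in "FWYH" else 0.0) for a in AA_ALPHABET})

#: Default property scales for the autocorrelation encoders (Moran / Geary /
#: normalized Moreau-Broto).  Eight scales, standardized before use.
AUTOCORR_SCALES = {
    "hydropathy": HYDROPATHY_KD,
    "hydrophilicity": HYDROPHILICITY,
    "hydrophobicity": HYDROPHOBICITY_PSE,
    "side_chain_mass": SIDE_CHAIN_MASS,
    "volume": VOLUME,
    "isoelectric_point": ISOELECTRIC_POINT,
    "net_charge": NET_CHARGE,
    "aromaticity": AROMATICITY,
}


def scale_vector(scale: dict, standardize: bool = False) -> np.ndarray:
    """Scale as a length-20 vector in alphabetical residue order.

    With ``standardize`` the 20 values are shifted/scaled to zero mean and unit
    (population) variance, the convention for autocorrelation descriptors.
    """
    v = np.array([float(scale[a]) for a in AA_ALPHABET])
    if standardize:
        sd = v.std()
        v = (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)
    return v


# ---------------------------------------------------------------------------
# Group partitions
# ---------------------------------------------------------------------------

#: Five-class grouping for GAAC/GDPC/GTPC/nGAAGP: aliphatic, aromatic,
#: positively charged, negatively charged, uncharged polar.
GAAC_GROUPS = {
    "aliphatic": "GAVLMI",
    "aromatic": "FYW",
    "positive": "KRH",
    "negative": "DE",
    "uncharged": "STCPNQ",
}

#: Seven-class grouping for the conjoint-triad encoders.
CTRIAD_GROUPS = ["AGV", "ILFP", "YMTS", "HNQW", "RK", "DE", "C"]

# Seven canonical composition/transition/distribution attribute partitions
# (hydrophobicity, normalized van der Waals volume, polarity, polarizability,
# charge, secondary-structure propensity, solvent accessibility).
_CTD_CANONICAL = {
    "hydrophobicity": ("RKEDQN", "GASTPHY", "CLVIMFW"),
    "vdw_volume": ("GASTPDC", "NVEQIL", "MHKFRYW"),
    "polarity": ("LIFWCMVY", "PATGS", "HQRKNED"),
    "polarizability": ("GASDT", "CPNVEQIL", "KMHFRYW"),
    "charge": ("KR", "ANCQGHILMFPSTWYV", "DE"),
    "secondary_structure": ("EALMQKRH", "VIYCWFT", "GNPSD"),
    "solvent_accessibility": ("ALFCGIVW", "RKQEND", "MSPTHY"),
}


def _tertile_partition(scale: dict) -> tuple:
    """Three near-equal groups of residues ordered by a property scale."""
    order = sorted(AA_ALPHABET, key=lambda a: (scale[a], a))
    return ("".join(order[:7]), "".join(order[7:13]), "".join(order[13:]))


# Six additional hydrophobicity-variant partitions derived by tertile-splitting
# shipped hydrophobicity-related scales, completing the conventional 13
# attributes of the composition/transition/distribution descriptor family.
_CTD_DERIVED = {
    "hydropathy_kd": _tertile_partition(HYDROPATHY_KD),
    "hydrophilicity_hw": _tertile_partition(HYDROPHILICITY),
    "hydrophobicity_pse": _tertile_partition(HYDROPHOBICITY_PSE),
    "buriability": _tertile_partition({a: -HYDROPATHY_KD[a] for a in AA_ALPHABET}),
    "transfer_energy": _tertile_partition(
        {a: HYDROPHOBICITY_PSE[a] - 0.5 * NET_CHARGE[a] for a in AA_ALPHABET}
    ),
    "amphipathicity": _tertile_partition(
        {a: HYDROPHILICITY[a] * abs(HYDROPATHY_KD[a]) for a in AA_ALPHABET}
    ),
}

#: The 13 three-group partitions used by CTDC/CTDT (39 = 13 x 3 features each).
CTD_PARTITIONS = {**_CTD_CANONICAL, **_CTD_DERIVED}

#: The 7 canonical partitions used by the full CTD (Dubchak-style) encoder.
CTD_CANONICAL_PARTITIONS = dict(_CTD_CANONICAL)

#: Sense-codon counts per residue in the standard genetic code (61 total).
CODON_COUNTS = {
    "A": 4, "C": 2, "D": 2, "E": 2, "F": 2, "G": 4, "H": 2, "I": 3, "K": 2,
    "L": 6, "M": 1, "N": 2, "P": 4, "Q": 2, "R": 6, "S": 6, "T": 4, "V": 4,
    "W": 1, "Y": 2,
}
N_SENSE_CODONS = 61


def _distance_matrix(scales: list, name_weights=None) -> np.ndarray:
    """Symmetric 20x20 Euclidean distance over standardized property scales."""
    cols = np.stack([scale_vector(s, standardize=True) for s in scales], axis=1)
    d = np.sqrt(((cols[:, None, :] - cols[None, :, :]) ** 2).sum(axis=2))
    return d / d.max()


#: Two physicochemical residue-pair distance matrices (normalized to [0, 1])
#: used by the sequence-order-coupling encoders.  Built from packaged property
#: scales; any literature matrix can be passed instead.
DISTANCE_MATRICES = {
    "physchem_hydro": _distance_matrix(
        [HYDROPATHY_KD, HYDROPHILICITY, SIDE_CHAIN_MASS]
    ),
    "physchem_steric": _distance_matrix(
        [VOLUME, ISOELECTRIC_POINT, NET_CHARGE, AROMATICITY]
    ),
}
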