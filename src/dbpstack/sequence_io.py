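"""FASTA, PSSM and structural-profile I/O with residue validation.

Typed records:

* :class:`ProteinRecord` — a validated primary sequence ``P = R1..RL``.
* :class:`PSSMProfile` — an L x 20 integer log-odds matrix from iterative
  homology search (PSI-BLAST ASCII dialect on disk).
* :class:`StructProfile` — per-residue structural predictions (3-state
  secondary-structure probabilities, accessible surface area, backbone torsion
  angles, half-sphere exposure), the tabular layout emitted by per-residue
  structure predictors.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .physchem import AA_ALPHABET, NON_CANONICAL, PSSM_FILE_ORDER

__all__ = [
    "ProteinRecord",
    "PSSMProfile",
    "StructProfile",
    "read_fasta",
    "write_fasta",
    "parse_pssm",
    "write_pssm",
    "parse_struct_profile",
    "write_struct_profile",
]

_CANONICAL = set(AA_ALPHABET)
# column permutation: PSSM file order -> alphabetical order
_FILE_TO_ALPHA = np.array([PSSM_FILE_ORDER.index(a) for a in AA_ALPHABET])

STRUCT_COLUMNS = ["ss_h", "ss_e", "ss_c", "asa", "phi", "psi", "theta", "tau",
                  "hse_u", "hse_d"]


@dataclass(frozen=True)
class ProteinRecord:
    """A protein primary sequence with a unique identifier.

    ``sequence`` is uppercased at construction.  ``is_canonical`` is False when
    any residue falls outside the 20-letter alphabet (e.g. 'X', 'B', 'Z', 'U',
    'O'); such records survive non-strict parsing but are flagged so the
    curation residue filter can drop them.
    """

    id: str
    sequence: str

    def __post_init__(self):
        if not self.id:
            raise ValueError("record id must be non-empty")
        object.__setattr__(self, "sequence", self.sequence.upper())
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - _CANONICAL - NON_CANONICAL
        if bad:
            raise ValueError(
                f"record {self.id!r}: unrecognized characters {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def is_canonical(self) -> bool:
        return not (set(self.sequence) & NON_CANONICAL)


@dataclass(frozen=True)
class PSSMProfile:
    """L x 20 integer log-odds scores, columns in alphabetical residue order."""

    record_id: str
    residues: str
    scores: np.ndarray  # (L, 20), int

    def __post_init__(self):
        scores = np.asarray(self.scores)
        if scores.ndim != 2 or scores.shape[1] != 20:
            raise ValueError("scores must be an L x 20 matrix")
        if scores.shape[0] != len(self.residues):
            raise ValueError(
                f"PSSM {self.record_id!r}: {scores.shape[0]} score rows for "
                f"{len(self.residues)} residues"
            )
        if not np.isfinite(scores).all():
            raise ValueError(f"PSSM {self.record_id!r}: non-finite scores")
        object.__setattr__(self, "scores", scores)

    @property
    def length(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class StructProfile:
    """Per-residue structural predictions for one protein.

    ss3_probs rows (helix, strand, coil) sum to 1; asa and hse are
    non-negative; torsion columns are (phi, psi, theta, tau) in degrees.
    """

    record_id: str
    ss3_probs: np.ndarray  # (L, 3)
    asa: np.ndarray        # (L,)
    torsion: np.ndarray    # (L, 4) degrees
    hse: np.ndarray        # (L, 2)

    def __post_init__(self):
        ss3 = np.atleast_2d(np.asarray(self.ss3_probs, dtype=float))
        asa = np.asarray(self.asa, dtype=float).ravel()
        tor = np.atleast_2d(np.asarray(self.torsion, dtype=float))
        hse = np.atleast_2d(np.asarray(self.hse, dtype=float))
        L = ss3.shape[0]
        if not (asa.shape[0] == tor.shape[0] == hse.shape[0] == L) or L == 0:
            raise ValueError(f"profile {self.record_id!r}: array lengths differ")
        if ss3.shape[1] != 3 or tor.shape[1] != 4 or hse.shape[1] != 2:
            raise ValueError(f"profile {self.record_id!r}: wrong column counts")
        if np.abs(ss3.sum(axis=1) - 1.0).max() > 1e-6:
            raise ValueError(
                f"profile {self.record_id!r}: unnormalized SS probabilities"
            )
        if (asa < 0).any() or (hse < 0).any():
            raise ValueError(f"profile {self.record_id!r}: negative ASA/HSE")
        for name, arr in (("ss3_probs", ss3), ("asa", asa), ("torsion", tor),
                          ("hse", hse)):
            object.__setattr__(self, name, arr)

    @property
    def length(self) -> int:
        return self.ss3_probs.shape[0]


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path, strict: bool = True) -> list:
    """Read a FASTA file into an order-preserving list of ProteinRecord.

    With ``strict`` any residue outside the canonical alphabet raises,
    naming the residue and its 1-based position.  Without it, records with
    unknown residues are kept but flagged (``is_canonical`` False).
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    records = []
    seen = set()
    for sr in SeqIO.parse(str(path), "fasta"):
        if not sr.id:
            raise ValueError(f"{path}: record with empty header")
        if sr.id in seen:
            raise ValueError(f"{path}: duplicate record id {sr.id!r}")
        seen.add(sr.id)
        rec = ProteinRecord(sr.id, str(sr.seq))
        if strict and not rec.is_canonical:
            pos = next(i for i, a in enumerate(rec.sequence)
                       if a in NON_CANONICAL)
            raise ValueError(
                f"record {rec.id!r}: non-canonical residue "
                f"{rec.sequence[pos]!r} at position {pos + 1}"
            )
        records.append(rec)
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_fasta(records, path, width: int = 60) -> None:
    seqrecs = [SeqRecord(Seq(r.sequence), id=r.id, description="")
               for r in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqrecs)


# ---------------------------------------------------------------------------
# PSI-BLAST ASCII PSSM
# ---------------------------------------------------------------------------

def parse_pssm(path, record_id: str | None = None) -> PSSMProfile:
    """Parse a PSI-BLAST ASCII PSSM (``-out_ascii_pssm``) file.

    Data rows look like ``  12 K  -1 0 ... (20 log-odds) (20 pct) info gapless``.
    Only the residue column and the first 20 numeric columns (log-odds) are
    used; trailing weighted-percentage and information columns are ignored.
    Columns are remapped from PSI-BLAST order to alphabetical order here, once.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    residues = []
    rows = []
    expected_index = 0
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) < 22 or not parts[0].isdigit():
                continue  # header / footer / blank
            if len(parts[1]) != 1 or not parts[1].isalpha():
                continue
            expected_index += 1
            if int(parts[0]) != expected_index:
                raise ValueError(
                    f"{path}: PSSM row index {parts[0]} out of order "
                    f"(expected {expected_index})"
                )
            try:
                row = [int(x) for x in parts[2:22]]
            except ValueError as exc:
                raise ValueError(
                    f"{path}: non-integer log-odds in row {parts[0]}: {exc}"
                ) from None
            residues.append(parts[1].upper())
            rows.append(row)
    if not rows:
        raise ValueError(f"{path}: no PSSM rows")
    scores = np.array(rows, dtype=int)[:, _FILE_TO_ALPHA]
    rid = record_id or os.path.splitext(os.path.basename(str(path)))[0]
    return PSSMProfile(rid, "".join(residues), scores)


def write_pssm(profile: PSSMProfile, path) -> None:
    """Write a PSSMProfile in the PSI-BLAST ASCII layout (log-odds columns in
    PSI-BLAST order, zero-filled trailing percentage/information columns)."""
    alpha_to_file = np.array([AA_ALPHABET.index(a) for a in PSSM_FILE_ORDER])
    with open(path, "w") as fh:
        fh.write("\nLast position-specific scoring matrix computed\n")
        fh.write(" " * 11 + "  ".join(PSSM_FILE_ORDER) + "   "
                 + "  ".join(PSSM_FILE_ORDER) + "\n")
        for i, (res, row) in enumerate(zip(profile.residues, profile.scores)):
            file_row = row[alpha_to_file]
            cells = " ".join(f"{int(v):3d}" for v in file_row)
            pct = " ".join("0" for _ in range(20))
            fh.write(f"{i + 1:5d} {res} {cells}  {pct}  0.00 0.00\n")


# ---------------------------------------------------------------------------
# Structural-profile table
# ---------------------------------------------------------------------------

def parse_struct_profile(path, record_id: str | None = None) -> StructProfile:
    """Parse a whitespace-delimited per-residue structural-profile table.

    The first non-blank line is a header naming the columns (order free);
    required names: ``ss_h ss_e ss_c asa phi psi theta tau hse_u hse_d``.
    SS probability rows whose sum falls within [0.99, 1.01] are renormalized;
    anything further from 1 is an error.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty profile table")
    header = lines[0].lstrip("#").split()
    col = {name: i for i, name in enumerate(header)}
    missing = [c for c in STRUCT_COLUMNS if c not in col]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    data = []
    for ln in lines[1:]:
        parts = ln.split()
        data.append([float(parts[col[c]]) for c in STRUCT_COLUMNS])
    if not data:
        raise ValueError(f"{path}: length-0 table")
    arr = np.array(data)
    ss3 = arr[:, 0:3]
    sums = ss3.sum(axis=1)
    if ((sums < 0.99) | (sums > 1.01)).any():
        bad = int(np.argmax((sums < 0.99) | (sums > 1.01)))
        raise ValueError(
            f"{path}: unnormalized SS probabilities in row {bad + 1} "
            f"(sum {sums[bad]:.4f})"
        )
    ss3 = ss3 / sums[:, None]
    rid = record_id or os.path.splitext(os.path.basename(str(path)))[0]
    return StructProfile(rid, ss3, arr[:, 3], arr[:, 4:8], arr[:, 8:10])


def write_struct_profile(profile: StructProfile, path) -> None:
    with open(path, "w") as fh:
        fh.write("# " + " ".join(STRUCT_COLUMNS) + "\n")
        for i in range(profile.length):
            row = (list(profile.ss3_probs[i]) + [profile.asa[i]]
                   + list(profile.torsion[i]) + list(profile.hse[i]))
            fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")
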