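"""Aligned locus container and FASTA round-tripping.

A :class:`LocusAlignment` is the unit every stage of the curation pipeline
operates on: one capture locus as an aligned taxon -> gapped-DNA table.
Sequences are stored as plain strings; numeric code paths convert to a
``numpy`` byte matrix via :meth:`LocusAlignment.to_array`.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: Residue alphabet accepted in alignments. ``-`` is an alignment gap,
#: ``?`` missing data, ``N`` an ambiguous base.
ALPHABET = frozenset("ACGTN-?")

# byte codes used by to_array(): A,C,G,T -> 0..3, everything else -> 255
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
_DECODE = np.frombuffer(b"ACGT", dtype=np.uint8)

MISSING_CODE = 255


@dataclass
class LocusAlignment:
    """One UCE locus as an aligned taxon -> sequence table.

    Parameters
    ----------
    locus_id:
        Stable locus identifier (e.g. ``uce-0042``).
    taxa:
        Ordered taxon labels; must be unique.
    rows:
        Mapping taxon -> gapped DNA sequence. All rows must have equal
        length and use only :data:`ALPHABET`.
    """

    locus_id: str
    taxa: list[str] = field(default_factory=list)
    rows: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError(f"{self.locus_id}: duplicate taxon labels")
        if set(self.taxa) != set(self.rows):
            raise ValueError(f"{self.locus_id}: taxa and rows disagree")
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError(f"{self.locus_id}: ragged alignment {lengths}")
        for taxon, seq in self.rows.items():
            bad = set(seq) - ALPHABET
            if bad:
                raise ValueError(
                    f"{self.locus_id}/{taxon}: illegal characters {sorted(bad)}"
                )

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_cols(self) -> int:
        if not self.taxa:
            return 0
        return len(self.rows[self.taxa[0]])

    def to_array(self) -> np.ndarray:
        """Return an (n_taxa, n_cols) uint8 matrix; A,C,G,T -> 0..3,
        gap/missing/ambiguous -> 255."""
        if not self.taxa:
            return np.zeros((0, 0), dtype=np.uint8)
        raw = np.frombuffer(
            "".join(self.rows[t] for t in self.taxa).encode("ascii"), dtype=np.uint8
        )
        return _CODE[raw].reshape(self.n_taxa, self.n_cols)

    @classmethod
    def from_array(
        cls, locus_id: str, taxa: list[str], arr: np.ndarray, missing: str = "-"
    ) -> "LocusAlignment":
        """Inverse of :meth:`to_array`; code 255 becomes ``missing``."""
        out = np.where(arr == MISSING_CODE, ord(missing), _DECODE[np.minimum(arr, 3)])
        rows = {
            t: out[i].tobytes().decode("ascii") for i, t in enumerate(taxa)
        }
        return cls(locus_id=locus_id, taxa=list(taxa), rows=rows)

    def subset_columns(self, cols: np.ndarray | list[int]) -> "LocusAlignment":
        """New alignment keeping 0-based columns ``cols`` in the given order."""
        idx = np.asarray(cols, dtype=int)
        rows = {
            t: "".join(self.rows[t][j] for j in idx) for t in self.taxa
        }
        return LocusAlignment(self.locus_id, list(self.taxa), rows)

    def subset_taxa(self, taxa: list[str]) -> "LocusAlignment":
        missing = [t for t in taxa if t not in self.rows]
        if missing:
            raise KeyError(f"{self.locus_id}: unknown taxa {missing}")
        return LocusAlignment(
            self.locus_id, list(taxa), {t: self.rows[t] for t in taxa}
        )


def read_fasta_alignment(path: str | os.PathLike, locus_id: str | None = None) -> LocusAlignment:
    """Read one aligned FASTA file as a :class:`LocusAlignment`.

    ``locus_id`` defaults to the file stem.
    """
    path = os.fspath(path)
    if locus_id is None:
        locus_id = os.path.splitext(os.path.basename(path))[0]
    taxa: list[str] = []
    rows: dict[str, str] = {}
    for rec in SeqIO.parse(path, "fasta"):
        taxa.append(rec.id)
        rows[rec.id] = str(rec.seq).upper()
    return LocusAlignment(locus_id, taxa, rows)


def write_fasta_alignment(aln: LocusAlignment, path: str | os.PathLike) -> None:
    records = [
        SeqRecord(Seq(aln.rows[t]), id=t, description="") for t in aln.taxa
    ]
    SeqIO.write(records, os.fspath(path), "fasta")


def read_locus_dir(path: str | os.PathLike) -> dict[str, LocusAlignment]:
    """Read every ``*.fasta`` in a directory, keyed by locus id (file stem)."""
    path = os.fspath(path)
    if not os.path.isdir(path):
        raise FileNotFoundError(f"locus directory not found: {path}")
    out: dict[str, LocusAlignment] = {}
    for name in sorted(os.listdir(path)):
        if name.endswith((".fasta", ".fa")):
            aln = read_fasta_alignment(os.path.join(path, name))
            out[aln.locus_id] = aln
    return out


def pdistance_matrix(aln: LocusAlignment) -> np.ndarray:
    """Pairwise p-distances over columns where both sequences are A/C/G/T.

    Returns an (n, n) matrix in taxon order; entries with zero comparable
    sites are ``nan``.
    """
    arr = aln.to_array()
    valid = arr != MISSING_CODE
    n = aln.n_taxa
    d = np.zeros((n, n))
    for i in range(n):
        both = valid[i] & valid[i + 1:]
        diff = (arr[i] != arr[i + 1:]) & both
        comp = both.sum(axis=1)
        with np.errstate(invalid="ignore"):
            row = np.where(comp > 0, diff.sum(axis=1) / np.maximum(comp, 1), np.nan)
        d[i, i + 1:] = row
        d[i + 1:, i] = row
    return d
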