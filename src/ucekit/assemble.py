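"""Conserved-block trimming, intron excision, occupancy filtering and
supermatrix assembly.

Trimming follows the Gblocks-style conserved-block algorithm with the
b1–b4 parameters: b1/b2 are the fractions of sequences a column's most
frequent base must reach to count as conserved / highly conserved, b3 is
the longest run of contiguous nonconserved columns tolerated inside a
block, b4 the minimum block length. Three matrix variants mirror the
standard curation ladder: (1) all loci, relaxed trimming; (2) curated loci,
relaxed trimming; (3) curated loci, introns excised, stricter trimming.
Occupancy is computed after trimming.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field

import numpy as np

from .alignment import LocusAlignment, MISSING_CODE
from .annotate import LocusAnnotation

GAP, NONCONSERVED, CONSERVED, HIGHLY_CONSERVED = "gap", "nonconserved", "conserved", "highly_conserved"


@dataclass
class TrimSettings:
    """Conserved-block trimming parameters (Gblocks b1–b4 convention)."""

    b1: float = 0.5
    b2: float = 0.5
    b3: int = 6
    b4: int = 6
    gap_policy: str = "half"  # none | half | all

    def __post_init__(self) -> None:
        if self.b3 < 1 or self.b4 < 2:
            raise ValueError("b3 must be >= 1 and b4 >= 2")
        if self.gap_policy not in ("none", "half", "all"):
            raise ValueError(f"unknown gap_policy {self.gap_policy!r}")


#: the two trimming regimes used for the matrix variants
TRIM_RELAXED = TrimSettings(b1=0.5, b2=0.5, b3=6, b4=6)
TRIM_STRICT = TrimSettings(b1=0.5, b2=0.85, b3=4, b4=8)


@dataclass
class AssembleConfig:
    min_occupancy: float = 0.70
    missing_char: str = "?"

    def __post_init__(self) -> None:
        if not 0 < self.min_occupancy <= 1:
            raise ValueError("min_occupancy must be in (0, 1]")


@dataclass
class SuperMatrix:
    """Concatenated matrix with per-locus partition bookkeeping."""

    taxa: list[str]
    rows: dict[str, str]
    partitions: list[tuple[str, int, int]]  # (locus_id, start, end) 1-based

    @property
    def n_loci(self) -> int:
        return len(self.partitions)

    @property
    def n_sites(self) -> int:
        return self.partitions[-1][2] if self.partitions else 0

    def extract(self, locus_id: str) -> dict[str, str]:
        """Per-taxon block for one partition (for bookkeeping checks)."""
        for lid, s, e in self.partitions:
            if lid == locus_id:
                return {t: self.rows[t][s - 1:e] for t in self.taxa}
        raise KeyError(locus_id)


# ---------------------------------------------------------------------------
# Column classification and block trimming
# ---------------------------------------------------------------------------

def classify_columns(aln: LocusAlignment, settings: TrimSettings) -> list[str]:
    """Per-column conservation label.

    The identity count is the number of occurrences of the most frequent
    non-gap base. Columns violating the gap policy are labelled ``gap``;
    otherwise ``nonconserved`` below ceil(b1*N), ``highly_conserved`` at or
    above ceil(b2*N), ``conserved`` in between. N is the number of
    sequences in the alignment.
    """
    if aln.n_taxa == 0 or aln.n_cols == 0:
        return []
    arr = aln.to_array()
    n = aln.n_taxa
    counts = np.stack([(arr == b).sum(axis=0) for b in range(4)]).max(axis=0)
    gaps = (arr == MISSING_CODE).sum(axis=0)
    t1 = math.ceil(settings.b1 * n)
    t2 = math.ceil(settings.b2 * n)
    labels = []
    for c in range(aln.n_cols):
        if settings.gap_policy == "half" and gaps[c] > n / 2:
            labels.append(GAP)
        elif settings.gap_policy == "all" and gaps[c] > 0:
            labels.append(GAP)
        elif counts[c] < t1:
            labels.append(NONCONSERVED)
        elif counts[c] >= t2:
            labels.append(HIGHLY_CONSERVED)
        else:
            labels.append(CONSERVED)
    return labels


def _trim_labels(labels: list[str], settings: TrimSettings) -> list[tuple[int, int]]:
    """Kept column spans (0-based inclusive) for a label sequence.

    Removal set: runs of more than b3 contiguous nonconserved columns, gap
    columns, and nonconserved columns contiguous with a gap column. The
    remaining segments are shrunk until both ends are highly conserved and
    segments shorter than b4 are dropped.
    """
    n = len(labels)
    remove = np.zeros(n, dtype=bool)
    # runs of nonconserved longer than b3
    i = 0
    while i < n:
        if labels[i] == NONCONSERVED:
            j = i
            while j < n and labels[j] == NONCONSERVED:
                j += 1
            if j - i > settings.b3:
                remove[i:j] = True
            i = j
        else:
            i += 1
    # gap columns plus adjacent nonconserved stretches
    for c in range(n):
        if labels[c] == GAP:
            remove[c] = True
            j = c - 1
            while j >= 0 and labels[j] == NONCONSERVED:
                remove[j] = True
                j -= 1
            j = c + 1
            while j < n and labels[j] == NONCONSERVED:
                remove[j] = True
                j += 1
    spans = []
    i = 0
    while i < n:
        if remove[i]:
            i += 1
            continue
        j = i
        while j < n and not remove[j]:
            j += 1
        # shrink segment ends to highly conserved flanks
        s, e = i, j - 1
        while s <= e and labels[s] != HIGHLY_CONSERVED:
            s += 1
        while e >= s and labels[e] != HIGHLY_CONSERVED:
            e -= 1
        if s <= e and e - s + 1 >= settings.b4:
            spans.append((s, e))
        i = j
    return spans


def trim_conserved_blocks(
    aln: LocusAlignment, settings: TrimSettings
) -> tuple[LocusAlignment, list[tuple[int, int]]]:
    """Trim an alignment to its conserved blocks.

    Returns the trimmed alignment and the kept column spans as 1-based
    inclusive coordinates of the input. The operation is idempotent and
    never reorders or edits residues.
    """
    labels = classify_columns(aln, settings)
    spans0 = _trim_labels(labels, settings)
    cols = [c for s, e in spans0 for c in range(s, e + 1)]
    return aln.subset_columns(cols), [(s + 1, e + 1) for s, e in spans0]


def excise_introns(
    aln: LocusAlignment, exon_spans: list[tuple[int, int]]
) -> LocusAlignment:
    """Keep only the union of exon spans (1-based inclusive), in order."""
    cols: list[int] = []
    for s, e in sorted(exon_spans):
        if s < 1 or e > aln.n_cols or s > e:
            raise IndexError(f"{aln.locus_id}: span [{s},{e}] outside 1..{aln.n_cols}")
        cols.extend(range(s - 1, e))
    cols = sorted(set(cols))
    return aln.subset_columns(cols)


# ---------------------------------------------------------------------------
# Occupancy and concatenation
# ---------------------------------------------------------------------------

_MISSINGISH = frozenset("-?N")


def occupancy(aln: LocusAlignment, full_taxon_set: list[str]) -> float:
    """Fraction of the full taxon set with at least one non-missing
    character in this locus."""
    if not full_taxon_set:
        raise ValueError("full taxon set is empty")
    present = 0
    for t in full_taxon_set:
        seq = aln.rows.get(t)
        if seq and any(ch not in _MISSINGISH for ch in seq):
            present += 1
    return present / len(full_taxon_set)


def filter_by_occupancy(
    loci: dict[str, LocusAlignment],
    full_taxon_set: list[str],
    cfg: AssembleConfig | None = None,
) -> dict[str, LocusAlignment]:
    """Keep loci whose occupancy is at least ``min_occupancy`` (a locus at
    exactly the threshold is kept)."""
    cfg = cfg or AssembleConfig()
    return {
        lid: aln
        for lid, aln in loci.items()
        if aln.n_cols > 0 and occupancy(aln, full_taxon_set) >= cfg.min_occupancy
    }


def concatenate(
    loci: dict[str, LocusAlignment],
    full_taxon_set: list[str],
    cfg: AssembleConfig | None = None,
) -> SuperMatrix:
    """Concatenate loci (lexicographic by id) padding absent taxa with the
    missing character; records partitions."""
    cfg = cfg or AssembleConfig()
    if not loci:
        raise ValueError("no loci to concatenate")
    if len(set(full_taxon_set)) != len(full_taxon_set):
        raise ValueError("duplicate taxon labels in full taxon set")
    order = sorted(loci)
    parts: list[tuple[str, int, int]] = []
    chunks: dict[str, list[str]] = {t: [] for t in full_taxon_set}
    pos = 0
    for lid in order:
        aln = loci[lid]
        L = aln.n_cols
        parts.append((lid, pos + 1, pos + L))
        pos += L
        for t in full_taxon_set:
            chunks[t].append(aln.rows.get(t, cfg.missing_char * L))
    rows = {t: "".join(chunks[t]) for t in full_taxon_set}
    return SuperMatrix(list(full_taxon_set), rows, parts)


# ---------------------------------------------------------------------------
# Matrix variants
# ---------------------------------------------------------------------------

VARIANTS = ("unfiltered", "filtered_exon_intron", "filtered_exon_only")


def build_matrices(
    loci: dict[str, LocusAlignment],
    kept_loci: list[str],
    annotations: dict[str, LocusAnnotation],
    full_taxon_set: list[str],
    cfg: AssembleConfig | None = None,
    trim_relaxed: TrimSettings = TRIM_RELAXED,
    trim_strict: TrimSettings = TRIM_STRICT,
) -> tuple[dict[str, SuperMatrix], dict[str, dict], dict[str, dict[str, list[int]]]]:
    """Assemble the three matrix variants.

    Variant 1 (``unfiltered``): every locus, relaxed trimming. Variant 2
    (``filtered_exon_intron``): curated loci only, relaxed trimming.
    Variant 3 (``filtered_exon_only``): curated loci, annotated introns
    excised, then stricter trimming. All variants are occupancy-filtered
    after trimming.

    Returns (matrices, summary, kept_columns) where ``kept_columns`` maps
    variant -> locus -> 0-based original column indices retained (used for
    exon-purity audits).
    """
    cfg = cfg or AssembleConfig()
    kept_set = set(kept_loci)
    matrices: dict[str, SuperMatrix] = {}
    summary: dict[str, dict] = {}
    kept_columns: dict[str, dict[str, list[int]]] = {}

    def trimmed_set(ids, excise: bool, settings: TrimSettings):
        out: dict[str, LocusAlignment] = {}
        cols_out: dict[str, list[int]] = {}
        for lid in sorted(ids):
            aln = loci[lid]
            orig_cols = np.arange(aln.n_cols)
            if excise:
                spans = annotations[lid].exon_spans if lid in annotations else []
                if not spans:
                    continue
                keep = sorted({c for s, e in spans for c in range(s - 1, e)})
                aln = aln.subset_columns(keep)
                orig_cols = orig_cols[keep]
            trimmed, spans_kept = trim_conserved_blocks(aln, settings)
            cols = [c for s, e in spans_kept for c in range(s - 1, e)]
            if trimmed.n_cols == 0:
                continue
            out[lid] = trimmed
            cols_out[lid] = [int(orig_cols[c]) for c in cols]
        return out, cols_out

    specs = {
        "unfiltered": (set(loci), False, trim_relaxed),
        "filtered_exon_intron": (kept_set, False, trim_relaxed),
        "filtered_exon_only": (kept_set, True, trim_strict),
    }
    for name, (ids, excise, settings) in specs.items():
        trimmed, cols = trimmed_set(ids, excise, settings)
        passing = filter_by_occupancy(trimmed, full_taxon_set, cfg)
        kept_columns[name] = {lid: cols[lid] for lid in passing}
        if passing:
            sm = concatenate(passing, full_taxon_set, cfg)
        else:
            sm = SuperMatrix(list(full_taxon_set), {t: "" for t in full_taxon_set}, [])
        matrices[name] = sm
        summary[name] = {"n_loci": sm.n_loci, "n_sites": sm.n_sites}
    return matrices, summary, kept_columns


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_phylip(sm: SuperMatrix, path: str | os.PathLike) -> None:
    """Relaxed sequential PHYLIP."""
    with open(os.fspath(path), "w") as fh:
        fh.write(f"{len(sm.taxa)} {sm.n_sites}\n")
        for t in sm.taxa:
            fh.write(f"{t}  {sm.rows[t]}\n")


def write_fasta(sm: SuperMatrix, path: str | os.PathLike) -> None:
    with open(os.fspath(path), "w") as fh:
        for t in sm.taxa:
            fh.write(f">{t}\n{sm.rows[t]}\n")


def write_partitions(sm: SuperMatrix, path: str | os.PathLike) -> None:
    """RAxML-style partition file: ``DNA, locus = start-end``."""
    with open(os.fspath(path), "w") as fh:
        for lid, s, e in sm.partitions:
            fh.write(f"DNA, {lid} = {s}-{e}\n")


def write_nexus_charsets(sm: SuperMatrix, path: str | os.PathLike) -> None:
    with open(os.fspath(path), "w") as fh:
        fh.write("#NEXUS\nbegin sets;\n")
        for lid, s, e in sm.partitions:
            fh.write(f"    charset {lid} = {s}-{e};\n")
        fh.write("end;\n")


def write_matrix_outputs(
    matrices: dict[str, SuperMatrix], summary: dict[str, dict], outdir: str | os.PathLike
) -> None:
    import pandas as pd

    outdir = os.fspath(outdir)
    os.makedirs(outdir, exist_ok=True)
    for name, sm in matrices.items():
        write_phylip(sm, os.path.join(outdir, f"{name}.phy"))
        write_fasta(sm, os.path.join(outdir, f"{name}.fasta"))
        write_partitions(sm, os.path.join(outdir, f"{name}.partitions"))
        write_nexus_charsets(sm, os.path.join(outdir, f"{name}.charsets.nex"))
    pd.DataFrame(
        [
            {"variant": name, "n_loci": s["n_loci"], "n_sites": s["n_sites"]}
            for name, s in summary.items()
        ]
    ).to_csv(os.path.join(outdir, "summary.tsv"), sep="\t", index=False)
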