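"""Locus annotation: consensus building, hit filtering, classification.

A per-locus consensus sequence is queried against a protein set (in real
use, the output of a translated homology search in 12-column tabular
format); the filtered hits classify each locus as entirely exonic, an exon
with flanking introns, or hit-less (with or without an open reading
frame), and map exon/intron boundaries back into alignment columns.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .alignment import LocusAlignment

BLAST6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]

STATUSES = ("exonic", "exon_plus_intron", "no_hit_orf", "no_hit")


class EmptyConsensusError(ValueError):
    """Raised when every alignment column is majority-gap."""


class HitTableParseError(ValueError):
    """Raised on a malformed row in a tabular hit file."""


@dataclass
class AnnotationConfig:
    """Thresholds for hit filtering and locus classification.

    ``max_evalue`` is the expectation cutoff for retaining hits (1e-10 by
    default). A locus is "exonic" when merged hit coverage of the ungapped
    consensus reaches ``exon_coverage_threshold``. Hit-less loci are
    scanned in six frames for open reading frames of at least
    ``orf_min_len`` amino acids (a start codon is not required: capture
    cores may begin mid-exon).
    """

    max_evalue: float = 1e-10
    exon_coverage_threshold: float = 0.90
    orf_min_len: int = 50

    def __post_init__(self) -> None:
        if not 0 < self.exon_coverage_threshold <= 1:
            raise ValueError("exon_coverage_threshold must be in (0, 1]")


@dataclass
class LocusAnnotation:
    """Classification and exon geometry for one locus."""

    locus_id: str
    status: str
    best_protein: str | None
    candidate_hits: list[tuple[str, float]]   # (protein_id, bitscore), desc
    exon_spans: list[tuple[int, int]]          # 1-based alignment columns
    flags: set[str] = field(default_factory=set)


def build_consensus(
    aln: LocusAlignment, max_gap_fraction: float = 0.5
) -> tuple[str, list[int]]:
    """Majority-rule consensus of an alignment.

    Each retained column contributes its most frequent A/C/G/T base (ties
    broken alphabetically); columns whose gap/missing fraction exceeds
    ``max_gap_fraction`` are dropped from the consensus but recorded via
    the returned column map.

    Returns
    -------
    consensus, column_map
        ``column_map[i]`` is the 1-based alignment column behind consensus
        position ``i`` (0-based); it is strictly increasing.
    """
    if aln.n_taxa == 0 or aln.n_cols == 0:
        raise EmptyConsensusError(f"{aln.locus_id}: empty alignment")
    arr = aln.to_array()
    counts = np.stack([(arr == b).sum(axis=0) for b in range(4)])  # (4, n_cols)
    gap_frac = (arr == 255).mean(axis=0)
    keep = gap_frac <= max_gap_fraction
    if not keep.any():
        raise EmptyConsensusError(f"{aln.locus_id}: all columns majority-gap")
    best = counts.argmax(axis=0)  # argmax takes the first max -> alphabetical
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)[best]
    consensus = bases[keep].tobytes().decode("ascii")
    column_map = [int(c) + 1 for c in np.nonzero(keep)[0]]
    return consensus, column_map


def load_hits(path: str | os.PathLike, cfg: AnnotationConfig | None = None) -> pd.DataFrame:
    """Load a 12-column tabular hit file, filter by e-value, sort by score.

    Rows with e-value above ``cfg.max_evalue`` are dropped; surviving rows
    are grouped by query locus and sorted by descending bitscore within
    each locus. An empty file yields an empty table.
    """
    cfg = cfg or AnnotationConfig()
    path = os.fspath(path)
    if os.path.getsize(path) == 0:
        return pd.DataFrame(columns=BLAST6_COLUMNS)
    try:
        df = pd.read_csv(
            path, sep="\t", names=BLAST6_COLUMNS, header=None, comment="#",
            dtype={"qseqid": str, "sseqid": str},
        )
    except Exception as exc:  # pandas raises various parse errors
        raise HitTableParseError(str(exc)) from exc
    if df.shape[1] != 12:
        raise HitTableParseError(f"{path}: expected 12 columns, got {df.shape[1]}")
    for col in ("qstart", "qend", "sstart", "send", "evalue", "bitscore"):
        converted = pd.to_numeric(df[col], errors="coerce")
        if converted.isna().any():
            line = int(converted.isna().idxmax()) + 1
            raise HitTableParseError(f"{path}: malformed value in column {col!r}, line {line}")
        df[col] = converted
    df = df[df["evalue"] <= cfg.max_evalue]
    df = df.sort_values(
        ["qseqid", "bitscore"], ascending=[True, False], kind="mergesort"
    ).reset_index(drop=True)
    return df


def hits_for_locus(hits: pd.DataFrame, locus_id: str) -> pd.DataFrame:
    return hits[hits["qseqid"] == locus_id]


def map_exon_spans(
    hits: pd.DataFrame, column_map: list[int]
) -> list[tuple[int, int]]:
    """Translate HSP consensus coordinates to merged alignment-column spans.

    Overlapping or directly adjacent spans are merged; output is disjoint
    and ascending.
    """
    spans = []
    n = len(column_map)
    for _, row in hits.iterrows():
        q1, q2 = int(row["qstart"]), int(row["qend"])
        if not (1 <= q1 <= q2 <= n):
            raise IndexError(
                f"hit coordinates [{q1},{q2}] outside consensus of length {n}"
            )
        spans.append((column_map[q1 - 1], column_map[q2 - 1]))
    spans.sort()
    merged: list[list[int]] = []
    for s, e in spans:
        if merged and s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def _merged_coverage(hits: pd.DataFrame, consensus_len: int) -> float:
    """Fraction of the consensus covered by the union of HSP q-intervals."""
    if hits.empty or consensus_len == 0:
        return 0.0
    ivals = sorted(
        (int(r["qstart"]), int(r["qend"])) for _, r in hits.iterrows()
    )
    covered, cur_s, cur_e = 0, None, None
    for s, e in ivals:
        if cur_e is None or s > cur_e + 1:
            if cur_e is not None:
                covered += cur_e - cur_s + 1
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    covered += cur_e - cur_s + 1
    return covered / consensus_len


def longest_orf(consensus: str, min_aa: int = 50) -> int:
    """Longest stop-free translated stretch over six frames, in aa.

    ``min_aa`` is unused for the scan itself; callers compare the return
    value against their threshold.
    """
    best = 0
    seqs = [consensus, str(Seq(consensus).reverse_complement())]
    for seq in seqs:
        for frame in range(3):
            sub = seq[frame:]
            sub = sub[: len(sub) - len(sub) % 3]
            if not sub:
                continue
            aa = str(Seq(sub).translate())
            for run in aa.split("*"):
                best = max(best, len(run))
    return best


def classify_locus(
    aln: LocusAlignment, hits: pd.DataFrame, cfg: AnnotationConfig | None = None
) -> LocusAnnotation:
    """Classify one locus from its filtered hits.

    ``exonic`` when merged hit coverage of the ungapped consensus reaches
    ``exon_coverage_threshold``; ``exon_plus_intron`` with any hit below
    that; otherwise ``no_hit_orf``/``no_hit`` depending on a six-frame ORF
    scan.
    """
    cfg = cfg or AnnotationConfig()
    consensus, column_map = build_consensus(aln)
    lhits = hits_for_locus(hits, aln.locus_id) if not hits.empty else hits
    if lhits.empty:
        if longest_orf(consensus) >= cfg.orf_min_len:
            status = "no_hit_orf"
        else:
            status = "no_hit"
        return LocusAnnotation(aln.locus_id, status, None, [], [])
    coverage = _merged_coverage(lhits, len(consensus))
    status = "exonic" if coverage >= cfg.exon_coverage_threshold else "exon_plus_intron"
    # best score per distinct protein, descending
    per_protein = (
        lhits.groupby("sseqid")["bitscore"].max().sort_values(ascending=False)
    )
    candidates = [(pid, float(s)) for pid, s in per_protein.items()]
    spans = map_exon_spans(lhits, column_map)
    return LocusAnnotation(aln.locus_id, status, candidates[0][0], candidates, spans)


def annotate_all(
    loci: dict[str, LocusAlignment], hits: pd.DataFrame, cfg: AnnotationConfig | None = None
) -> dict[str, LocusAnnotation]:
    return {lid: classify_locus(loci[lid], hits, cfg) for lid in sorted(loci)}


# ---------------------------------------------------------------------------
# annotations.tsv round trip
# ---------------------------------------------------------------------------

def write_annotations(
    annotations: dict[str, LocusAnnotation], path: str | os.PathLike
) -> None:
    rows = []
    for lid in sorted(annotations):
        a = annotations[lid]
        rows.append({
            "locus_id": a.locus_id,
            "status": a.status,
            "best_protein": a.best_protein or "",
            "candidate_hits": ";".join(f"{p}:{s:g}" for p, s in a.candidate_hits),
            "exon_spans": ";".join(f"{s}-{e}" for s, e in a.exon_spans),
            "flags": ",".join(sorted(a.flags)),
        })
    pd.DataFrame(
        rows,
        columns=["locus_id", "status", "best_protein", "candidate_hits", "exon_spans", "flags"],
    ).to_csv(os.fspath(path), sep="\t", index=False)


def read_annotations(path: str | os.PathLike) -> dict[str, LocusAnnotation]:
    df = pd.read_csv(os.fspath(path), sep="\t", keep_default_na=False)
    out: dict[str, LocusAnnotation] = {}
    for _, r in df.iterrows():
        cands = []
        if r["candidate_hits"]:
            for tok in str(r["candidate_hits"]).split(";"):
                pid, s = tok.rsplit(":", 1)
                cands.append((pid, float(s)))
        spans = []
        if r["exon_spans"]:
            for tok in str(r["exon_spans"]).split(";"):
                s, e = tok.split("-")
                spans.append((int(s), int(e)))
        flags = set(str(r["flags"]).split(",")) - {""} if r["flags"] else set()
        out[r["locus_id"]] = LocusAnnotation(
            r["locus_id"], r["status"], r["best_protein"] or None, cands, spans, flags
        )
    return out
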