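"""Duplicate-exon grouping and orthology curation.

Capture loci that hit the same protein are different exons of one gene and
are collapsed to a single representative (most sequences; longest
alignment when taxon counts are comparable). Loci carrying non-orthologous
(paralogous) sequences are flagged by two lines of evidence: hits to two
or more distinct proteins at similar bitscores, and congeneric taxa with
divergent sequences, confirmed by a neighbor-joining gene tree when
needed. A locus is excluded only when the congeneric signal is corroborated
(multi-protein hits, or failed genus monophyly), which limits false
positives.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np

from .alignment import LocusAlignment, pdistance_matrix
from .annotate import LocusAnnotation


@dataclass
class CurationConfig:
    """Numeric operationalisation of the curation rules.

    ``ratio_threshold``: second/top distinct-protein bitscore ratio at or
    above which a locus is treated as hitting two proteins "at similar"
    scores. ``taxa_tolerance``: sequence-count difference within which two
    duplicate loci count as having "approximately the same" number of taxa.
    A congeneric pair is divergent when its p-distance exceeds
    ``max(pdist_abs_threshold, pdist_rel_factor x median pairwise
    p-distance in the locus)``.
    """

    ratio_threshold: float = 0.9
    taxa_tolerance: int = 1
    pdist_abs_threshold: float = 0.10
    pdist_rel_factor: float = 2.0

    def __post_init__(self) -> None:
        if not 0 < self.ratio_threshold <= 1:
            raise ValueError("ratio_threshold must be in (0, 1]")
        if self.taxa_tolerance < 0:
            raise ValueError("taxa_tolerance must be >= 0")


@dataclass
class DuplicateGroup:
    protein_id: str
    locus_ids: list[str]
    representative: str | None = None


@dataclass
class ParalogReport:
    locus_id: str
    multi_hit_flag: bool
    bitscore_ratio: float | None
    congeneric_flag: bool
    max_congeneric_pdist: float | None
    nj_monophyly_ok: bool | None
    decision: str  # keep | exclude


def group_duplicates(annotations: list[LocusAnnotation]) -> list[DuplicateGroup]:
    """One group per protein that is the best hit of two or more loci."""
    by_protein: dict[str, list[str]] = {}
    for a in annotations:
        if a.best_protein:
            by_protein.setdefault(a.best_protein, []).append(a.locus_id)
    groups = [
        DuplicateGroup(pid, sorted(lids))
        for pid, lids in sorted(by_protein.items())
        if len(lids) >= 2
    ]
    return groups


def choose_representative(
    group: DuplicateGroup,
    alignments: dict[str, LocusAlignment],
    cfg: CurationConfig | None = None,
) -> str:
    """Representative of a duplicate group.

    The locus with the most sequences wins; loci within ``taxa_tolerance``
    of the top count compete on alignment length instead; remaining ties
    fall to the lexicographically smallest locus id.
    """
    cfg = cfg or CurationConfig()
    if not group.locus_ids:
        raise ValueError("empty duplicate group")
    counts = {lid: alignments[lid].n_taxa for lid in group.locus_ids}
    top = max(counts.values())
    candidates = [lid for lid in group.locus_ids if counts[lid] >= top - cfg.taxa_tolerance]
    candidates.sort(key=lambda lid: (-alignments[lid].n_cols, lid))
    return candidates[0]


def flag_multi_protein(
    annotation: LocusAnnotation, cfg: CurationConfig | None = None
) -> tuple[bool, float | None]:
    """Two-or-more distinct proteins at similar bitscores?

    Returns (flag, second/top bitscore ratio) — ratio is None with fewer
    than two distinct protein hits.
    """
    cfg = cfg or CurationConfig()
    if len(annotation.candidate_hits) < 2:
        return False, None
    top = annotation.candidate_hits[0][1]
    second = annotation.candidate_hits[1][1]
    if top <= 0:
        return False, None
    ratio = second / top
    return ratio >= cfg.ratio_threshold, ratio


def _congeneric_pairs(taxa: list[str], genus_map: dict[str, str]) -> list[tuple[int, int]]:
    by_genus: dict[str, list[int]] = {}
    for i, t in enumerate(taxa):
        g = genus_map.get(t)
        if g is not None:
            by_genus.setdefault(g, []).append(i)
    pairs = []
    for members in by_genus.values():
        for a in range(len(members)):
            for b in range(a + 1, len(members)):
                pairs.append((members[a], members[b]))
    return pairs


def congeneric_divergence(
    aln: LocusAlignment,
    genus_map: dict[str, str],
    cfg: CurationConfig | None = None,
) -> tuple[bool, float | None]:
    """Divergent congeneric sequences — the primary non-orthology signal.

    The flag is raised when the maximum congeneric p-distance exceeds
    ``max(pdist_abs_threshold, pdist_rel_factor x median of all pairwise
    p-distances in the locus)``. Pairs with zero comparable sites are
    skipped; with no usable pair the result is (False, None).
    """
    cfg = cfg or CurationConfig()
    pairs = _congeneric_pairs(aln.taxa, genus_map)
    if not pairs:
        return False, None
    d = pdistance_matrix(aln)
    vals = [d[i, j] for i, j in pairs if np.isfinite(d[i, j])]
    if not vals:
        return False, None
    max_pd = float(max(vals))
    tri = d[np.triu_indices(aln.n_taxa, k=1)]
    tri = tri[np.isfinite(tri)]
    median_all = float(np.median(tri)) if tri.size else 0.0
    threshold = max(cfg.pdist_abs_threshold, cfg.pdist_rel_factor * median_all)
    return max_pd > threshold, max_pd


def nj_gene_tree_check(
    aln: LocusAlignment, genus_map: dict[str, str]
) -> bool | None:
    """Genus monophyly on a neighbor-joining p-distance gene tree.

    Returns True when every genus with >= 2 sampled taxa forms a clade on
    some rooting of the unrooted NJ tree, False otherwise; None with fewer
    than four taxa or no multiply-sampled genus. Degenerate all-zero
    distances count as monophyletic.
    """
    if aln.n_taxa < 4:
        return None
    genera: dict[str, set[str]] = {}
    for t in aln.taxa:
        g = genus_map.get(t)
        if g is not None:
            genera.setdefault(g, set()).add(t)
    multi = {g: s for g, s in genera.items() if len(s) >= 2}
    if not multi:
        return None
    d = pdistance_matrix(aln)
    d = np.where(np.isfinite(d), d, 0.75)  # incomparable pairs -> saturated
    np.fill_diagonal(d, 0.0)
    if not d.any():
        return True
    from skbio import DistanceMatrix
    from skbio.tree import nj

    tree = nj(DistanceMatrix((d + d.T) / 2.0, ids=list(aln.taxa)))
    all_tips = frozenset(aln.taxa)
    splits = set()
    for node in tree.traverse(include_self=False):
        if not node.is_tip():
            tips = frozenset(t.name for t in node.tips())
            splits.add(tips)
            splits.add(all_tips - tips)
    for genus_tips in multi.values():
        fs = frozenset(genus_tips)
        if fs == all_tips:
            continue
        if fs not in splits:
            return False
    return True


def build_paralog_report(
    annotation: LocusAnnotation,
    aln: LocusAlignment,
    genus_map: dict[str, str],
    cfg: CurationConfig | None = None,
) -> ParalogReport:
    """All paralogy evidence and the keep/exclude decision for one locus.

    Exclusion requires the congeneric-divergence flag corroborated by
    either similar-bitscore multi-protein hits or failed genus monophyly
    on the NJ gene tree. The NJ check is computed lazily — only when the
    congeneric flag is raised and could change the decision.
    """
    cfg = cfg or CurationConfig()
    multi, ratio = flag_multi_protein(annotation, cfg)
    cong, max_pd = congeneric_divergence(aln, genus_map, cfg)
    nj_ok: bool | None = None
    if cong:
        nj_ok = nj_gene_tree_check(aln, genus_map)
    exclude = (multi and cong) or (cong and nj_ok is False)
    return ParalogReport(
        locus_id=annotation.locus_id,
        multi_hit_flag=multi,
        bitscore_ratio=ratio,
        congeneric_flag=cong,
        max_congeneric_pdist=max_pd,
        nj_monophyly_ok=nj_ok,
        decision="exclude" if exclude else "keep",
    )


def apply_curation(
    annotations: dict[str, LocusAnnotation],
    groups: list[DuplicateGroup],
    reports: dict[str, ParalogReport],
) -> list[str]:
    """Final kept locus list: drop excluded paralogs and non-representative
    duplicates; output sorted."""
    excluded = {lid for lid, r in reports.items() if r.decision == "exclude"}
    for g in groups:
        if g.representative is None:
            raise ValueError(f"group {g.protein_id} has no representative")
        excluded.update(set(g.locus_ids) - {g.representative})
    return sorted(lid for lid in annotations if lid not in excluded)


def curate_all(
    annotations: dict[str, LocusAnnotation],
    loci: dict[str, LocusAlignment],
    genus_map: dict[str, str],
    cfg: CurationConfig | None = None,
) -> tuple[list[str], list[DuplicateGroup], dict[str, ParalogReport]]:
    """Run the full curation stage; returns (kept, groups, reports)."""
    cfg = cfg or CurationConfig()
    groups = group_duplicates([annotations[k] for k in sorted(annotations)])
    for g in groups:
        g.representative = choose_representative(g, loci, cfg)
    reports = {
        lid: build_paralog_report(annotations[lid], loci[lid], genus_map, cfg)
        for lid in sorted(annotations)
    }
    kept = apply_curation(annotations, groups, reports)
    return kept, groups, reports


# ---------------------------------------------------------------------------
# File IO
# ---------------------------------------------------------------------------

def read_genus_map(path: str | os.PathLike) -> dict[str, str]:
    """Two-column TSV (taxon, genus), with or without a header line."""
    out: dict[str, str] = {}
    with open(os.fspath(path)) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            taxon, genus = line.split("\t")[:2]
            if taxon.lower() == "taxon" and genus.lower() == "genus":
                continue
            out[taxon] = genus
    return out


def write_curation_outputs(
    outdir: str | os.PathLike,
    kept: list[str],
    groups: list[DuplicateGroup],
    reports: dict[str, ParalogReport],
) -> None:
    import pandas as pd

    outdir = os.fspath(outdir)
    os.makedirs(outdir, exist_ok=True)
    with open(os.path.join(outdir, "kept_loci.txt"), "w") as fh:
        fh.write("\n".join(kept) + ("\n" if kept else ""))
    pd.DataFrame(
        [
            {
                "protein_id": g.protein_id,
                "locus_ids": ",".join(g.locus_ids),
                "representative": g.representative,
            }
            for g in groups
        ],
        columns=["protein_id", "locus_ids", "representative"],
    ).to_csv(os.path.join(outdir, "duplicate_groups.tsv"), sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "locus_id": r.locus_id,
                "multi_hit_flag": r.multi_hit_flag,
                "bitscore_ratio": "" if r.bitscore_ratio is None else f"{r.bitscore_ratio:.4f}",
                "congeneric_flag": r.congeneric_flag,
                "max_congeneric_pdist": ""
                if r.max_congeneric_pdist is None
                else f"{r.max_congeneric_pdist:.4f}",
                "nj_monophyly_ok": "" if r.nj_monophyly_ok is None else r.nj_monophyly_ok,
                "decision": r.decision,
            }
            for _, r in sorted(reports.items())
        ],
    ).to_csv(os.path.join(outdir, "curation_report.tsv"), sep="\t", index=False)
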