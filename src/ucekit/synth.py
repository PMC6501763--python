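"""Seeded synthetic UCE-capture datasets with known truth.

Emulates the statistical structure the curation pipeline assumes for a
sequence-capture phylogenomic study: a pure-birth species tree whose tips
include congeneric pairs, multi-exon protein gene models, per-locus
alignments consisting of a conserved exon core flanked by faster-evolving
intron sequence (indels only in introns, so loci are born aligned),
injected paralogous sequences for a taxon subset of some loci, an emulated
translated-homology hit table, and a discrete trait simulated under the
Mk model for ancestral-state tests.

All randomness flows from a single ``numpy`` generator seeded by
``SimConfig.seed``; identical configs produce byte-identical output trees.
"""

from __future__ import annotations

import dataclasses
import os
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
import yaml
from Bio.Seq import Seq

from .alignment import LocusAlignment, write_fasta_alignment

__all__ = [
    "SimConfig",
    "TruthRow",
    "SyntheticDataset",
    "simulate_tree",
    "evolve_sequences",
    "make_locus",
    "inject_paralog",
    "emit_hits",
    "simulate_discrete",
    "generate_dataset",
    "write_dataset",
]

BLAST6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


@dataclass
class SimConfig:
    """Conditions for one synthetic dataset.

    Defaults describe the reference study conditions: 20 taxa with
    congeneric pairs, ~300 loci, ~15% of loci being different exons of one
    protein, ~15% of loci carrying a paralogous sequence in one taxon, and
    70% mean taxon occupancy. Rates are substitutions per site per unit
    branch length; intron flanks evolve faster than the exon core.
    """

    n_taxa: int = 20
    birth_rate: float = 2.5
    n_proteins: int = 270
    exons_per_protein: tuple[int, int] = (2, 3)  # for multi-exon proteins
    exon_len: tuple[int, int] = (120, 300)       # nt, multiples of 3
    intron_flank_len: tuple[int, int] = (60, 150)  # nt, each side
    exon_sub_rate: float = 0.05
    intron_sub_rate: float = 0.25
    dup_fraction: float = 0.15
    paralog_fraction: float = 0.15
    paralog_depth: float = 0.5
    occupancy_mean: float = 0.70
    intron_del_prob: float = 0.02      # per intron site, per tip
    intron_del_mean_len: float = 3.0   # geometric mean deletion length
    n_states: int = 7                  # discrete trait states for ASR tests
    trait_rate: float = 0.3
    search_space: float = 1e9          # m*n in the e-value model E = m*n*2^-S
    seed: int = 0

    def validate(self) -> None:
        if self.n_taxa < 2:
            raise ValueError("n_taxa must be >= 2")
        for name in ("dup_fraction", "paralog_fraction", "occupancy_mean"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a proportion, got {v}")
        if self.intron_sub_rate < self.exon_sub_rate:
            raise ValueError("intron_sub_rate must be >= exon_sub_rate")
        lo, hi = self.exon_len
        if lo % 3 or hi % 3:
            raise ValueError("exon_len bounds must be multiples of 3")
        if self.birth_rate <= 0:
            raise ValueError("birth_rate must be positive")
        if self.n_states < 2:
            raise ValueError("n_states must be >= 2")


@dataclass
class TruthRow:
    """Ground truth for one simulated locus."""

    locus_id: str
    source_protein_id: str
    exon_index: int
    exon_aa_len: int
    exon_span: tuple[int, int]          # 1-based inclusive alignment columns
    duplicate_group_id: str | None
    contaminated_taxa: list[str]
    paralog_source_id: str | None
    present_taxa: list[str]


@dataclass
class SyntheticDataset:
    config: SimConfig
    tree: dendropy.Tree
    genus_map: dict[str, str]
    loci: dict[str, LocusAlignment]
    truth: list[TruthRow]
    hits: pd.DataFrame
    traits: dict[str, int]
    proteins: dict[tuple[str, int], str] = field(default_factory=dict)

    @property
    def newick(self) -> str:
        return self.tree.as_string(
            schema="newick", suppress_rooting=True, unquoted_underscores=True
        ).strip()

    def truth_by_locus(self) -> dict[str, TruthRow]:
        return {row.locus_id: row for row in self.truth}


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Tree simulation
# ---------------------------------------------------------------------------

def simulate_tree(n_taxa: int, birth_rate: float, seed) -> dendropy.Tree:
    """Pure-birth (Yule) tree with ``n_taxa`` tips.

    Waiting times between speciation events are Exponential(k * birth_rate)
    with k extant lineages; the tree is sampled one extra waiting time after
    the last split so terminal branches are never zero. Tip labels carry
    genus prefixes (``gen01_a`` etc.); congeneric pairs are placed on
    cherries (or the closest remaining tip pairs) so at least two pairs
    exist whenever ``n_taxa >= 6``.
    """
    if n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    rng = _as_rng(seed)
    taxon_ns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxon_ns)
    tree.seed_node.edge.length = 0.0
    left = tree.seed_node.new_child(edge_length=0.0)
    right = tree.seed_node.new_child(edge_length=0.0)
    tips = [left, right]
    while len(tips) < n_taxa:
        wait = rng.exponential(1.0 / (len(tips) * birth_rate))
        for tip in tips:
            tip.edge.length += wait
        parent = tips.pop(int(rng.integers(len(tips))))
        tips.append(parent.new_child(edge_length=0.0))
        tips.append(parent.new_child(edge_length=0.0))
    wait = rng.exponential(1.0 / (len(tips) * birth_rate))
    for tip in tips:
        tip.edge.length += wait

    _assign_genus_labels(tree, n_taxa, rng, taxon_ns)
    return tree


def _assign_genus_labels(tree, n_taxa, rng, taxon_ns) -> None:
    """Label tips so congeneric pairs sit on cherries / nearest tip pairs."""
    leaves = list(tree.leaf_node_iter())
    if n_taxa >= 6:
        n_pairs = max(2, n_taxa // 5)
    else:
        n_pairs = 1 if n_taxa >= 4 else 0

    # depth of every node (time from root)
    depth: dict[int, float] = {}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        depth[id(node)] = (depth[id(parent)] if parent else 0.0) + (node.edge.length or 0.0)

    pairs: list[tuple] = []
    used: set[int] = set()
    # cherries first, youngest (shallowest pair divergence) first
    cherries = [
        node for node in tree.preorder_internal_node_iter()
        if all(ch.is_leaf() for ch in node.child_nodes())
    ]
    cherries.sort(key=lambda nd: depth[id(nd)], reverse=True)
    for node in cherries:
        if len(pairs) >= n_pairs:
            break
        a, b = node.child_nodes()
        pairs.append((a, b))
        used.update((id(a), id(b)))
    # fall back to closest remaining tips (patristic) if cherries ran out
    if len(pairs) < n_pairs:
        free = [lf for lf in leaves if id(lf) not in used]
        # patristic distance via MRCA depth on an ultrametric tree
        anc = {id(lf): set() for lf in free}
        for lf in free:
            node = lf
            while node is not None:
                anc[id(lf)].add(id(node))
                node = node.parent_node
        while len(pairs) < n_pairs and len(free) >= 2:
            best = None
            for i in range(len(free)):
                for j in range(i + 1, len(free)):
                    a, b = free[i], free[j]
                    # deepest common ancestor
                    node, mrca_depth = b, 0.0
                    while node is not None:
                        if id(node) in anc[id(a)]:
                            mrca_depth = depth[id(node)]
                            break
                        node = node.parent_node
                    dist = (depth[id(a)] - mrca_depth) + (depth[id(b)] - mrca_depth)
                    if best is None or dist < best[0]:
                        best = (dist, i, j)
            _, i, j = best
            a, b = free[i], free[j]
            pairs.append((a, b))
            free = [lf for k, lf in enumerate(free) if k not in (i, j)]

    genus_idx = 0
    for a, b in pairs:
        genus_idx += 1
        g = f"gen{genus_idx:02d}"
        for leaf, suffix in ((a, "a"), (b, "b")):
            leaf.taxon = taxon_ns.new_taxon(label=f"{g}_{suffix}")
            used.add(id(leaf))
    for leaf in leaves:
        if leaf.taxon is None:
            genus_idx += 1
            leaf.taxon = taxon_ns.new_taxon(label=f"gen{genus_idx:02d}_a")


def genus_of(taxon: str) -> str:
    """Genus label encoded in a synthetic tip name (prefix before ``_``)."""
    return taxon.rsplit("_", 1)[0]


def genus_map_of(tree: dendropy.Tree) -> dict[str, str]:
    return {lf.taxon.label: genus_of(lf.taxon.label) for lf in tree.leaf_node_iter()}


# ---------------------------------------------------------------------------
# Sequence evolution (Jukes-Cantor)
# ---------------------------------------------------------------------------

def _jc_evolve_child(parent: np.ndarray, d: np.ndarray, rng) -> np.ndarray:
    """One branch of JC69: per-site distance ``d`` in expected subs/site.

    P(site differs) = 3/4 (1 - exp(-4 d / 3)); given change, the new base is
    uniform over the other three.
    """
    p_diff = 0.75 * (1.0 - np.exp(-4.0 * d / 3.0))
    mask = rng.random(parent.shape[0]) < p_diff
    child = parent.copy()
    n = int(mask.sum())
    if n:
        child[mask] = (parent[mask] + 1 + rng.integers(0, 3, n)) % 4
    return child


def _evolve_along_tree(
    tree: dendropy.Tree, root_states: np.ndarray, site_rates: np.ndarray, rng
) -> dict[str, np.ndarray]:
    """Evolve integer-coded states down the tree; returns tip arrays."""
    states = {id(tree.seed_node): root_states}
    out: dict[str, np.ndarray] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            pass
        else:
            parent = states[id(node.parent_node)]
            d = site_rates * (node.edge.length or 0.0)
            states[id(node)] = _jc_evolve_child(parent, d, rng)
        if node.is_leaf():
            out[node.taxon.label] = states[id(node)]
    return out


def random_dna(length: int, rng) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, length))


def evolve_sequences(tree: dendropy.Tree, root_seq: str, rate: float, seed) -> dict[str, str]:
    """Evolve ``root_seq`` along ``tree`` under single-rate JC69.

    Returns one ungapped sequence per tip, same length as the root.
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    if not root_seq:
        raise ValueError("root_seq must be non-empty")
    rng = _as_rng(seed)
    codes = np.frombuffer(root_seq.encode("ascii"), dtype=np.uint8)
    lut = np.zeros(256, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        lut[b] = i
    root = lut[codes]
    rates = np.full(len(root_seq), float(rate))
    tips = _evolve_along_tree(tree, root, rates, rng)
    return {t: "".join("ACGT"[i] for i in arr) for t, arr in tips.items()}


# ---------------------------------------------------------------------------
# Locus construction
# ---------------------------------------------------------------------------

def _draw_exon_len(cfg: SimConfig, rng) -> int:
    lo, hi = cfg.exon_len
    return 3 * int(rng.integers(lo // 3, hi // 3 + 1))


def _simulate_locus(
    locus_id: str,
    protein_id: str,
    exon_index: int,
    tree: dendropy.Tree,
    cfg: SimConfig,
    rng,
    duplicate_group_id: str | None,
) -> tuple[LocusAlignment, TruthRow, dict]:
    """Core generator; returns (alignment, truth, meta) where meta carries
    the root sequence and per-site rates needed for paralog injection."""
    exon_len = _draw_exon_len(cfg, rng)
    ilo, ihi = cfg.intron_flank_len
    left = int(rng.integers(ilo, ihi + 1))
    right = int(rng.integers(ilo, ihi + 1))
    total = left + exon_len + right
    root = rng.integers(0, 4, total).astype(np.uint8)
    site_rates = np.full(total, cfg.intron_sub_rate)
    site_rates[left:left + exon_len] = cfg.exon_sub_rate

    tips = _evolve_along_tree(tree, root, site_rates, rng)
    taxa = sorted(tips)

    # intron deletions, geometric length (mean intron_del_mean_len)
    p_geo = 1.0 / max(cfg.intron_del_mean_len, 1.0)
    intron_cols = np.r_[np.arange(left), np.arange(left + exon_len, total)]
    gap_mask: dict[str, np.ndarray] = {}
    for t in taxa:
        mask = np.zeros(total, dtype=bool)
        starts = intron_cols[rng.random(intron_cols.size) < cfg.intron_del_prob]
        for s in starts:
            ln = int(rng.geometric(p_geo))
            stop = min(s + ln, total)
            # deletions never eat into the exon core
            span = np.arange(s, stop)
            span = span[(span < left) | (span >= left + exon_len)]
            mask[span] = True
        gap_mask[t] = mask

    # occupancy: drop taxa uniformly at random, keep at least 4
    present = [t for t in taxa if rng.random() < cfg.occupancy_mean]
    if len(present) < min(4, len(taxa)):
        extra = [t for t in taxa if t not in present]
        rng.shuffle(extra)
        present = sorted(present + extra[: min(4, len(taxa)) - len(present)])

    rows = {}
    for t in present:
        arr = np.frombuffer(b"ACGT", dtype=np.uint8)[tips[t]].copy()
        arr[gap_mask[t]] = ord("-")
        rows[t] = arr.tobytes().decode("ascii")
    aln = LocusAlignment(locus_id, present, rows)
    truth = TruthRow(
        locus_id=locus_id,
        source_protein_id=protein_id,
        exon_index=exon_index,
        exon_aa_len=exon_len // 3,
        exon_span=(left + 1, left + exon_len),
        duplicate_group_id=duplicate_group_id,
        contaminated_taxa=[],
        paralog_source_id=None,
        present_taxa=list(present),
    )
    meta = {"root": root, "site_rates": site_rates, "left": left, "exon_len": exon_len}
    return aln, truth, meta


def make_locus(
    protein_id: str,
    exon_index: int,
    tree: dendropy.Tree,
    config: SimConfig,
    seed,
    locus_id: str | None = None,
    duplicate_group_id: str | None = None,
) -> tuple[LocusAlignment, TruthRow]:
    """Simulate one capture locus: conserved exon core with intron flanks.

    The exon span is recorded in the truth row in 1-based alignment
    columns; a random taxon subset is dropped to hit the configured mean
    occupancy.
    """
    rng = _as_rng(seed)
    if locus_id is None:
        locus_id = f"{protein_id}-e{exon_index}"
    aln, truth, _ = _simulate_locus(
        locus_id, protein_id, exon_index, tree, config, rng, duplicate_group_id
    )
    return aln, truth


def inject_paralog(
    locus: LocusAlignment,
    tree: dendropy.Tree,
    taxa: list[str],
    paralog_depth: float,
    seed,
    *,
    root_seq: np.ndarray,
    site_rates: np.ndarray,
    exon_sub_rate: float,
) -> LocusAlignment:
    """Replace the listed taxa's sequences with paralogous copies.

    The paralogous root diverges from the locus root by ``paralog_depth``
    substitutions/site on the exon core (introns proportionally faster, per
    ``site_rates``), then evolves down the tree under the same process.
    Original gap positions are preserved so the alignment stays consistent.
    """
    unknown = [t for t in taxa if t not in locus.rows]
    if unknown:
        raise ValueError(f"unknown taxa: {unknown}")
    if not taxa:
        return locus
    rng = _as_rng(seed)
    rel = site_rates / max(exon_sub_rate, 1e-12)
    paralog_root = _jc_evolve_child(root_seq, paralog_depth * rel, rng)
    tips = _evolve_along_tree(tree, paralog_root, site_rates, rng)
    rows = dict(locus.rows)
    for t in taxa:
        new = np.frombuffer(b"ACGT", dtype=np.uint8)[tips[t]].copy()
        old = np.frombuffer(rows[t].encode("ascii"), dtype=np.uint8)
        new[old == ord("-")] = ord("-")
        rows[t] = new.tobytes().decode("ascii")
    return LocusAlignment(locus.locus_id, list(locus.taxa), rows)


# ---------------------------------------------------------------------------
# Hit-table emulation
# ---------------------------------------------------------------------------

def evalue_from_bitscore(bitscore: float, search_space: float = 1e9) -> float:
    """Karlin-Altschul style expectation: E = m*n * 2^(-S)."""
    return search_space * 2.0 ** (-bitscore)


def _consensus_and_map(aln: LocusAlignment) -> tuple[str, list[int]]:
    # local import: annotate also imports alignment, avoid cycles at module load
    from .annotate import build_consensus

    return build_consensus(aln)


def emit_hits(
    truth: list[TruthRow],
    loci: dict[str, LocusAlignment],
    config: SimConfig,
    proteins: dict[tuple[str, int], str],
    seed,
) -> pd.DataFrame:
    """Emulated translated-homology hit table (12-column tabular format).

    Each locus gets one hit from its consensus exon region to its source
    protein, with bitscore S = 2 x (identical translated residues) and
    e-value E = m*n*2^(-S). Paralog-contaminated loci get a second hit to a
    distinct protein with a bitscore ratio >= 0.9; uncontaminated loci
    occasionally get a weak decoy second hit (ratio < 0.9 by construction).
    Query coordinates equal the truth exon spans mapped into consensus
    coordinates; subject coordinates follow the protein's exon layout.
    """
    rng = _as_rng(seed)
    # subject aa offsets per (protein, exon_index)
    by_protein: dict[str, list[TruthRow]] = {}
    for row in truth:
        by_protein.setdefault(row.source_protein_id, []).append(row)
    offsets: dict[tuple[str, int], int] = {}
    protein_len: dict[str, int] = {}
    for pid, rows in by_protein.items():
        pos = 0
        for row in sorted(rows, key=lambda r: r.exon_index):
            offsets[(pid, row.exon_index)] = pos
            pos += row.exon_aa_len
        protein_len[pid] = pos
    all_proteins = sorted(protein_len)

    records = []
    for row in sorted(truth, key=lambda r: r.locus_id):
        aln = loci[row.locus_id]
        consensus, column_map = _consensus_and_map(aln)
        col_to_cons = {c: i + 1 for i, c in enumerate(column_map)}  # 1-based
        q_start = col_to_cons[row.exon_span[0]]
        q_end = col_to_cons[row.exon_span[1]]
        cons_exon = consensus[q_start - 1:q_end]
        aa = str(Seq(cons_exon).translate())
        target = proteins[(row.source_protein_id, row.exon_index)]
        ident = sum(1 for a, b in zip(aa, target) if a == b)
        bitscore = 2.0 * ident
        s_off = offsets[(row.source_protein_id, row.exon_index)]
        records.append({
            "qseqid": row.locus_id,
            "sseqid": row.source_protein_id,
            "pident": round(100.0 * ident / max(len(target), 1), 2),
            "length": len(target),
            "mismatch": len(target) - ident,
            "gapopen": 0,
            "qstart": q_start,
            "qend": q_end,
            "sstart": s_off + 1,
            "send": s_off + len(target),
            "evalue": evalue_from_bitscore(bitscore, config.search_space),
            "bitscore": bitscore,
        })
        second_pid, ratio = None, None
        if row.contaminated_taxa:
            second_pid = row.paralog_source_id
            ratio = rng.uniform(0.90, 0.98)
        elif rng.random() < 0.10 and len(all_proteins) > 1:
            choices = [p for p in all_proteins if p != row.source_protein_id]
            second_pid = choices[int(rng.integers(len(choices)))]
            ratio = rng.uniform(0.30, 0.70)
        if second_pid is not None:
            s2 = bitscore * ratio
            ident2 = int(round(s2 / 2.0))
            slen = min(len(target), protein_len.get(second_pid, len(target)))
            records.append({
                "qseqid": row.locus_id,
                "sseqid": second_pid,
                "pident": round(100.0 * ident2 / max(len(target), 1), 2),
                "length": len(target),
                "mismatch": len(target) - ident2,
                "gapopen": 0,
                "qstart": q_start,
                "qend": q_end,
                "sstart": 1,
                "send": max(slen, 1),
                "evalue": evalue_from_bitscore(s2, config.search_space),
                "bitscore": round(s2, 1),
            })
    return pd.DataFrame.from_records(records, columns=BLAST6_COLUMNS)


# ---------------------------------------------------------------------------
# Discrete trait simulation (Mk)
# ---------------------------------------------------------------------------

def simulate_discrete(
    tree: dendropy.Tree, k: int, rate: float, seed, n_chars: int = 1
) -> dict[str, np.ndarray]:
    """Simulate ``n_chars`` independent Mk(k) characters on the tree.

    Root states uniform; along a branch of length t the state changes to a
    specific other state with probability (1/k)(1 - exp(-k*rate*t)).
    Returns taxon -> int array of length ``n_chars``.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = _as_rng(seed)
    states = {id(tree.seed_node): rng.integers(0, k, n_chars)}
    out: dict[str, np.ndarray] = {}
    for node in tree.preorder_node_iter():
        if node is not tree.seed_node:
            parent = states[id(node.parent_node)]
            t = node.edge.length or 0.0
            p_change = (k - 1) / k * (1.0 - np.exp(-k * rate * t))
            mask = rng.random(n_chars) < p_change
            child = parent.copy()
            n = int(mask.sum())
            if n:
                child[mask] = (parent[mask] + 1 + rng.integers(0, k - 1, n)) % k
            states[id(node)] = child
        if node.is_leaf():
            out[node.taxon.label] = states[id(node)]
    return out


# ---------------------------------------------------------------------------
# Dataset assembly and IO
# ---------------------------------------------------------------------------

def _gene_models(cfg: SimConfig, rng) -> list[tuple[str, int]]:
    """Per-protein exon counts honouring ``dup_fraction``.

    A protein is multi-exon with probability p chosen so the expected
    fraction of loci that belong to multi-exon proteins equals
    ``dup_fraction``; multi-exon counts are uniform on
    ``exons_per_protein``.
    """
    lo, hi = cfg.exons_per_protein
    lo = max(lo, 2)
    if cfg.dup_fraction <= 0 or hi < 2:
        return [(f"prot{i:04d}", 1) for i in range(1, cfg.n_proteins + 1)]
    m = (lo + hi) / 2.0
    f = cfg.dup_fraction
    p_multi = f / (m * (1.0 - f) + f)
    out = []
    for i in range(1, cfg.n_proteins + 1):
        if rng.random() < p_multi:
            n_exons = int(rng.integers(lo, hi + 1))
        else:
            n_exons = 1
        out.append((f"prot{i:04d}", n_exons))
    return out


def generate_dataset(config: SimConfig) -> SyntheticDataset:
    """Full generator: tree, loci, paralog injection, hits, truth, traits."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    tree = simulate_tree(config.n_taxa, config.birth_rate, rng)
    genus_map = genus_map_of(tree)

    models = _gene_models(config, rng)
    loci: dict[str, LocusAlignment] = {}
    truth: list[TruthRow] = []
    metas: dict[str, dict] = {}
    proteins: dict[tuple[str, int], str] = {}
    idx = 0
    for pid, n_exons in models:
        group = f"dup-{pid}" if n_exons >= 2 else None
        for e in range(1, n_exons + 1):
            idx += 1
            locus_id = f"uce-{idx:04d}"
            aln, row, meta = _simulate_locus(locus_id, pid, e, tree, config, rng, group)
            loci[locus_id] = aln
            truth.append(row)
            metas[locus_id] = meta
            # the "protein database" entry is the translated root exon
            exon_nt = "".join(
                "ACGT"[b] for b in meta["root"][meta["left"]:meta["left"] + meta["exon_len"]]
            )
            proteins[(pid, e)] = str(Seq(exon_nt).translate())

    # paralog injection: contaminate one member of a congeneric pair
    genera_pairs = {}
    for t, g in genus_map.items():
        genera_pairs.setdefault(g, []).append(t)
    pairs = [sorted(v) for v in genera_pairs.values() if len(v) >= 2]
    n_paralog = int(round(config.paralog_fraction * len(truth)))
    if n_paralog and not pairs:
        warnings.warn("no congeneric pairs available; skipping paralog injection")
        n_paralog = 0
    all_ids = sorted(loci)
    chosen = rng.choice(len(all_ids), size=n_paralog, replace=False) if n_paralog else []
    all_pids = sorted({r.source_protein_id for r in truth})
    truth_map = {r.locus_id: r for r in truth}
    for ci in sorted(int(c) for c in chosen):
        locus_id = all_ids[ci]
        row = truth_map[locus_id]
        aln = loci[locus_id]
        pair = pairs[int(rng.integers(len(pairs)))]
        # force the pair present so congeneric evidence exists
        meta = metas[locus_id]
        for t in pair[:2]:
            if t not in aln.rows:
                # re-materialise the dropped taxon from a fresh tree pass is
                # not possible deterministically here; instead copy its
                # congener's row and let the paralog replacement overwrite
                # the contaminated member. The uncontaminated member keeps a
                # plausible congeneric sequence.
                donor = pair[0] if t == pair[1] else pair[1]
                if donor not in aln.rows:
                    donor = aln.taxa[0]
                taxa = sorted(aln.taxa + [t])
                rows = dict(aln.rows)
                rows[t] = rows[donor]
                aln = LocusAlignment(locus_id, taxa, rows)
        contaminated = pair[int(rng.integers(2))]
        aln = inject_paralog(
            aln, tree, [contaminated], config.paralog_depth, rng,
            root_seq=meta["root"], site_rates=meta["site_rates"],
            exon_sub_rate=config.exon_sub_rate,
        )
        loci[locus_id] = aln
        row.contaminated_taxa = [contaminated]
        row.present_taxa = list(aln.taxa)
        others = [p for p in all_pids if p != row.source_protein_id]
        row.paralog_source_id = others[int(rng.integers(len(others)))] if others else None

    hits = emit_hits(truth, loci, config, proteins, rng)
    trait_arrays = simulate_discrete(tree, config.n_states, config.trait_rate, rng, 1)
    traits = {t: int(v[0]) for t, v in sorted(trait_arrays.items())}
    return SyntheticDataset(
        config=config, tree=tree, genus_map=genus_map, loci=loci,
        truth=truth, hits=hits, traits=traits, proteins=proteins,
    )


def write_dataset(ds: SyntheticDataset, outdir: str | os.PathLike) -> None:
    """Write the dataset as plain-text files readable by downstream stages.

    Layout: ``loci/*.fasta``, ``hits.tsv`` (12-column, headerless),
    ``truth.tsv``, ``tree.nwk``, ``traits.tsv``, ``genera.tsv``,
    ``config.yaml``.
    """
    outdir = os.fspath(outdir)
    os.makedirs(os.path.join(outdir, "loci"), exist_ok=True)
    for locus_id in sorted(ds.loci):
        write_fasta_alignment(ds.loci[locus_id], os.path.join(outdir, "loci", f"{locus_id}.fasta"))
    ds.hits.to_csv(os.path.join(outdir, "hits.tsv"), sep="\t", header=False, index=False)
    rows = []
    for r in sorted(ds.truth, key=lambda r: r.locus_id):
        rows.append({
            "locus_id": r.locus_id,
            "source_protein_id": r.source_protein_id,
            "exon_index": r.exon_index,
            "exon_aa_len": r.exon_aa_len,
            "exon_start": r.exon_span[0],
            "exon_end": r.exon_span[1],
            "duplicate_group_id": r.duplicate_group_id or "",
            "contaminated_taxa": ",".join(r.contaminated_taxa),
            "paralog_source_id": r.paralog_source_id or "",
            "present_taxa": ",".join(r.present_taxa),
        })
    pd.DataFrame(rows).to_csv(os.path.join(outdir, "truth.tsv"), sep="\t", index=False)
    with open(os.path.join(outdir, "tree.nwk"), "w") as fh:
        fh.write(ds.newick + "\n")
    with open(os.path.join(outdir, "traits.tsv"), "w") as fh:
        fh.write("taxon\tstate\n")
        for t in sorted(ds.traits):
            fh.write(f"{t}\t{ds.traits[t]}\n")
    with open(os.path.join(outdir, "genera.tsv"), "w") as fh:
        fh.write("taxon\tgenus\n")
        for t in sorted(ds.genus_map):
            fh.write(f"{t}\t{ds.genus_map[t]}\n")
    with open(os.path.join(outdir, "config.yaml"), "w") as fh:
        yaml.safe_dump(dataclasses.asdict(ds.config), fh, sort_keys=True)


def read_truth(path: str | os.PathLike) -> list[TruthRow]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    out = []
    for _, r in df.iterrows():
        out.append(TruthRow(
            locus_id=r["locus_id"],
            source_protein_id=r["source_protein_id"],
            exon_index=int(r["exon_index"]),
            exon_aa_len=int(r["exon_aa_len"]),
            exon_span=(int(r["exon_start"]), int(r["exon_end"])),
            duplicate_group_id=r["duplicate_group_id"] or None,
            contaminated_taxa=[t for t in str(r["contaminated_taxa"]).split(",") if t],
            paralog_source_id=r["paralog_source_id"] or None,
            present_taxa=[t for t in str(r["present_taxa"]).split(",") if t],
        ))
    return out
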