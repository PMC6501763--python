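# ucekit

Curation of ultraconserved-element (UCE) capture loci for phylogenomics,
plus Mk-model ancestral state reconstruction on a fixed tree.

## The problem

Arthropod UCE bait sets largely target exons: a captured "locus" is a
conserved exon core with faster-evolving intron flanks. Two artifacts
follow that standard capture pipelines do not remove:

- **Duplicate loci** — distinct capture loci that are different exons of
  the same (often large) protein, separated by introns. Harmless for
  concatenation, but they violate the independence assumptions of
  coalescent and SNP-based analyses.
- **Non-orthologs ("paralogs")** — alignments in which a subset of taxa
  carry a paralogous copy rather than the ortholog. The tell-tale signals
  are hits to two or more different proteins at similar bitscores, and
  congeneric taxa with conspicuously divergent sequences.

`ucekit` implements the annotation/curation ladder that turns raw per-locus
alignments into analysis-ready supermatrices, and the downstream
discrete-character reconstruction:

1. **annotate** — majority-rule consensus per locus, translated-search hit
   ingestion (12-column tabular format, e-value ≤ 10⁻¹⁰), locus
   classification (`exonic` / `exon_plus_intron` / `no_hit_orf` /
   `no_hit`), and exon/intron boundary mapping into alignment columns.
2. **curate** — duplicate-exon groups (loci sharing a best-hit protein)
   collapsed to one representative (most sequences; longest alignment when
   taxon counts are within tolerance); paralog flagging from the
   bitscore-ratio signal (second/top ≥ 0.9) and congeneric p-distance
   divergence, confirmed by neighbor-joining gene-tree genus monophyly.
3. **assemble** — Gblocks-style conserved-block trimming (`b1 b2 b3 b4`
   parameters; relaxed `0.5/0.5/6/6` and strict `0.5/0.85/4/8` presets),
   intron excision from the annotated boundaries, ≥ 70% taxon-occupancy
   filtering, and concatenation into three matrix variants with partition
   bookkeeping (PHYLIP/FASTA/RAxML partitions/NEXUS charsets).
4. **mkasr** — the one-parameter Markov k-state model:
   `P(same) = 1/k + (k−1)/k·e^(−kαt)`, `P(diff) = (1/k)(1 − e^(−kαt))`,
   Felsenstein pruning with per-node scaling, bounded ML estimation of α,
   and marginal ("proportional likelihood") ancestral states per node.
5. **synth** — a seeded generator producing datasets with known truth
   (pure-birth tree with congeneric pairs, multi-exon gene models, JC69
   sequence evolution with conserved exon cores, injected paralogs,
   emulated hit tables with `E = m·n·2^(−S)`, Mk-simulated traits) used to
   validate every curation rule against labels.
6. **pipeline** — one-config orchestration with a checksummed manifest.

## Worked example

```bash
ucekit simulate --out ds --seed 2
ucekit annotate --loci ds/loci --hits ds/hits.tsv --out annotations.tsv
ucekit curate --annotations annotations.tsv --loci ds/loci --genera ds/genera.tsv --out curation
ucekit assemble --loci ds/loci --kept curation/kept_loci.txt \
    --annotations annotations.tsv --genera ds/genera.tsv --out matrices
ucekit asr --tree ds/tree.nwk --traits ds/traits.tsv --k 7 --out asr.tsv
```

prints

```
annotated 310 loci -> annotations.tsv
kept 231/310 loci; 23 duplicate groups
unfiltered: 191 loci, 80511 sites
filtered_exon_intron: 144 loci, 61699 sites
filtered_exon_only: 144 loci, 30608 sites
rate=0.258883 logL=-28.9908 -> asr.tsv
```

Reading: of 310 simulated loci, curation removed duplicate-group
non-representatives and paralog-flagged loci, leaving 231. After trimming
and 70% occupancy filtering, the unfiltered variant keeps 191 loci
(80,511 sites); the curated exon+intron variant keeps 144 loci; excising
introns and trimming strictly roughly halves the matrix (30,608 sites),
as expected when intron flanks make up about half of each locus. The ASR
line reports the fitted Mk rate and log-likelihood for the simulated
7-state trait; `asr.tsv` holds one row per internal node with proportional
likelihoods summing to one.

The same run is available as a library call
(`ucekit.pipeline.run_pipeline`) or via `ucekit run --config cfg.yaml`,
which also writes a `manifest.json` with input checksums and per-stage
counts for auditability.

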