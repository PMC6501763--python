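# Methods

This note records the models, the numeric choices behind every curation
rule, and what the synthetic benchmark does and does not establish.

## Locus model and synthetic data generator

The generator emulates the data a UCE capture experiment delivers after
assembly and alignment, with truth labels attached.

**Species tree.** Pure-birth (Yule) process: with k extant lineages the
next speciation waits Exponential(k·λ); the tree is sampled one extra
waiting time after the n-th tip appears so terminal branches are never
zero. Default λ = 2.5 per lineage with n = 20 tips gives an expected
root-to-tip depth of ≈ 1.0 time unit, so at the default exon substitution
rate the conserved core diverges by ≈ 0.05 substitutions/site tip to tip —
the level of conservation that makes a locus a UCE in the first place.
Congeneric pairs are required by the curation rules, and congeners must be
phylogenetically close for their divergence to carry orthology
information; tips are therefore labelled so pairs sit on cherries
(youngest first), falling back to the closest remaining tip pairs by
patristic distance. For n ≥ 6 at least two pairs exist.

**Loci.** Each protein carries 1 exon, or 2–3 exons with a probability
chosen so the expected fraction of loci belonging to multi-exon proteins
equals `dup_fraction` (default 0.15); all exons of one protein form one
duplicate group. A locus is a random exon core (120–300 nt, multiple of
3) flanked by intron sequence (60–150 nt each side). Evolution is JC69:
on a branch of length t at rate r a site changes with probability
¾(1 − e^(−4rt)), the replacement uniform over the other three bases.
Exon sites use rate 0.05, intron sites 0.25 (5× faster flanks — flanking
variation is what makes UCE loci informative at shallow depths). Indels
occur only in introns (start probability 0.02/site/tip, geometric length
with mean 3) and are realised as gaps at generation time, so loci are born
aligned and no aligner enters the pipeline. Taxa are dropped uniformly at
random per locus to a mean occupancy of 0.70 (at least four kept).

**Paralogs.** For `paralog_fraction` (default 0.15) of loci, one member of
a congeneric pair (the pair forced present) is replaced by a sequence
evolved from a paralogous root that diverged from the locus root by
`paralog_depth` (default 0.5) substitutions/site on the exon, scaled by
the intron/exon rate ratio on the flanks — paralogous introns are
effectively saturated, as in real data. Original gap positions are kept.

**Hit tables.** Rather than running a translated search, hits are emitted
from truth: each locus hits its source protein over exactly its exon span
(mapped into consensus coordinates) with bitscore S = 2 × (identical
translated residues between the consensus exon and the protein) and
expectation E = m·n·2^(−S) with m·n = 10⁹. Paralog-contaminated loci
receive a second hit to a distinct protein at a bitscore ratio drawn from
[0.90, 0.98); clean loci occasionally (10%) receive a weak decoy second
hit at ratio [0.30, 0.70), which by construction never crosses the 0.9
flagging bar. Because coordinates are truth-derived, downstream span
recovery is exact by design; what the benchmark tests is the *decision
logic*, not a search engine.

**Traits.** One discrete character simulated under Mk with k = 7 states
(rate 0.3) on the same tree, for the reconstruction stage.

All randomness flows from a single seeded generator; identical configs
give byte-identical file trees.

**What passing tests do not show.** The generator has no alignment error,
no assembly chimeras, no rate heterogeneity across loci beyond exon vs
intron, no base-composition bias, no correlated missingness (real capture
drops taxa by library quality, not uniformly), and paralogs always arrive
with a detectable second protein hit. Sensitivity/specificity estimates
are therefore upper bounds on real-data performance; thresholds are
calibrated only in this synthetic regime.

## Annotation

The consensus is majority rule over A/C/G/T per column (ties broken
alphabetically — deterministic and documented; ambiguity codes would
overstate certainty for a search query), with majority-gap columns
(gap fraction > 0.5) dropped but recorded in a strictly increasing column
map so hit coordinates can be projected back into alignment columns.
Hits with e-value above 10⁻¹⁰ are discarded. A locus is `exonic` when the
union of HSP query intervals covers ≥ 90% of the consensus (the source
pipeline never states its boundary between "entirely exonic" and "exon
with flanking introns"; 0.90 is the package's configurable
operationalisation), `exon_plus_intron` with any hit below that, and
otherwise classified by a six-frame ORF scan (≥ 50 aa, no start codon
required since capture cores can begin mid-exon). Exon spans are merged
when overlapping or directly adjacent. Coordinates are 1-based inclusive
everywhere, matching the tabular search convention.

## Curation

- **Duplicates.** Loci sharing a best-hit protein form a group; the
  representative is the locus with the most sequences, except that loci
  within `taxa_tolerance = 1` sequence of the top count compete on
  alignment length (the "approximately same number of taxa" rule made
  numeric), with a lexicographic final tie-break.
- **Multi-protein signal.** Flag when the best bitscores of the top two
  distinct proteins have ratio ≥ 0.9. The ratio is scale-free, so the
  threshold does not depend on locus length.
- **Congeneric divergence.** p-distance (mismatches over sites where both
  sequences are unambiguous bases) for every congeneric pair; flag when
  the maximum exceeds max(0.10, 2 × median of all pairwise p-distances in
  the locus). The relative term adapts to per-locus rate variation; the
  absolute floor stops near-invariant loci from flagging on trivial
  differences.
- **Gene-tree check.** Neighbor-joining (scikit-bio) on the p-distance
  matrix; the check passes when every genus with ≥ 2 sampled taxa is a
  split of the unrooted tree. NJ replaces ML gene trees deliberately:
  for a yes/no monophyly question on one locus it is orders of magnitude
  faster and needs no model choice. It is computed lazily — only when the
  congeneric flag is raised, since the decision rule never consults it
  otherwise.
- **Decision.** Exclude a whole locus iff congeneric divergence is
  corroborated (multi-protein flag, or failed monophyly). The conjunction
  deliberately trades a little sensitivity for a low false-positive rate;
  hit-less loci are retained unless congeneric-flagged.

## Trimming and matrices

Column labels: with N sequences, the identity count is the most frequent
non-gap base's count; `gap` when the gap fraction exceeds ½ (policy
`half`; `none`/`all` available), `nonconserved` below ceil(b1·N),
`highly_conserved` at or above ceil(b2·N), else `conserved`. Trimming
removes runs of more than b3 contiguous nonconserved columns, gap columns
together with nonconserved columns contiguous to them, shrinks the
remaining segments until both ends are highly conserved, and drops
segments shorter than b4. End-shrinking is applied after the gap step so
the operation is idempotent; kept columns are a subset of the input in
original order, never edited.

Variants: (1) all loci with the relaxed preset (0.5/0.5/6/6); (2) curated
loci, same trimming; (3) curated loci with annotated introns excised
first, then the strict preset (0.5/0.85/4/8) — excision and stricter
trimming are combined because each addresses a different residue class.
Occupancy (fraction of the full taxon set with ≥ 1 non-missing character)
is computed after trimming — trimming can empty a taxon's row, and an
occupancy promise should hold for the matrix actually analysed. The
boundary is inclusive (a locus at exactly 0.70 is kept) and count
thresholds use ceiling, both dialect choices the upstream tools leave
implicit. Missing data is `?`; `-` is reserved for alignment gaps.

## Mk ancestral reconstruction

Closed-form transitions (k-state symmetric model), uniform 1/k root
prior, Felsenstein pruning with per-node rescaling (max-normalisation;
log factors accumulated), marginal states from an inside–outside pass
normalised per node. Reconstruction is marginal, not joint, matching the
proportional-likelihood convention for reporting per-node state support.
The rate is fitted on [10⁻⁸, 100] to tolerance 10⁻⁸; because the profile
can pair an interior peak with a high-rate plateau (where all transitions
approach 1/k), the optimum is first bracketed on a 40-point log grid and
then refined by bounded minimisation. Invariant characters return the
lower bound with a warning. Polytomies and single-child roots are
rejected at parse time rather than silently resolved. k defaults to 7
(web-construct coding of the motivating application) and is fully
configurable; the shipped trait files are synthetic examples, not an
asserted empirical coding.

## Problem sizes used in validation

The test suite validates against enumeration oracles on trees of ≤ 9 tips
with k ≤ 4 (exact to 10⁻⁸), and runs the curation benchmark on ten seeded
datasets at the reference conditions (20 taxa, ~300 loci each). Rate
recovery uses 12 replicates of 100 Mk characters on a 50-tip tree
(relative bias of the mean ≤ 10%). These sizes were chosen so the entire
suite completes in well under a minute while keeping every check exact or
statistically well-powered.

## Known limitations

- Curation excludes whole loci, never individual sequences; a locus with
  one detectable paralog among many clean sequences is lost entirely.
- The paralog detector requires congeneric sampling; datasets without
  multiply-sampled genera fall back to the multi-protein signal only,
  which alone never excludes.
- NJ monophyly uses uncorrected distances; at saturation it can fail to
  confirm true non-orthology (conservative direction).
- The e-value/bitscore emulation is monotone in identity but not a
  Karlin–Altschul calibrated statistic; real search output should be
  supplied for real data.
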