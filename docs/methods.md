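# Methods

## The integration model

txweave treats annotation consolidation as a constrained selection
problem. Candidate transcripts are first grouped into **superloci** —
transitive clusters of models whose genomic spans, extended by a flank
(default 200 bp), overlap on compatible strands (`+` with `+`/`.`, `-`
with `-`/`.`, unknown strand joins either). Within a superlocus,
**subloci** group multiexonic models sharing at least one identical intron
and, separately, monoexonic models by exonic overlap; the two kinds never
co-group, since intron-chain evidence and pure overlap are not comparable.
Each sublocus elects a winner by score; the winners then compete in a
greedy iterative selection: take the highest-scoring remaining transcript
as a locus primary, remove everything that directly intersects it (exonic
overlap on a compatible strand), repeat. The iteration — rather than
one-winner-per-cluster — prevents an unresolved read-through model from
suppressing both of its neighbour loci. All ties anywhere in the pipeline
break by (score, cDNA length, id), which makes runs bit-reproducible.

Assumptions: inputs are genome-anchored transcript structures (no
expression or coverage values are used — scoring is purely structural plus
external evidence); one primary transcript adequately represents a locus;
the scoring configuration expresses what a "good" transcript looks like
for the genome at hand. There is no automated weight training.

## Scoring

Metrics are either intrinsic (cDNA length, exon count, CDS fraction, UTR
geometry, ORF completeness) or locus-relative (fraction of the group's
exons/introns carried, retained introns, which change as grouping
changes). Evidence metrics come from the store: verified-junction counts
against trusted introns, best homology bit score, and the query coverage
of the best (lowest e-value) hit. The full registry is the 26 metrics in
`scoring.METRIC_NAMES`; configurations referencing any other name fail at
load time rather than silently scoring zero, and `EXTRA_METRICS` lets a
user bind new callables.

Per metric the group is rescaled to [0, multiplier] (`max`, `min`, or
distance-to-`target`); a degenerate metric (all values equal) awards the
full multiplier to everyone, because an uninformative metric should not
penalise. A per-metric filter atom zeroes the contribution of failing
transcripts and removes them from the rescaling range. An ε of 1e-9
guards the target denominator. Booleans are cast to {0, 1}.

Definitions that needed fixing where common usage is loose:

- **retained intron**: an exon of transcript *t* fully containing an
  intron of another group member whose two flanking exons both overlap
  that exon; `retained_fraction` is the summed length of such exons over
  the cDNA length.
- **end_distance_from_junction**: cDNA distance from the stop codon to the
  final splice junction (0 for monoexonic models) — a proxy for
  nonsense-mediated-decay susceptibility.
- **canonical_intron_proportion** is taken from the preparation stage's
  per-model tagging; monoexonic models score 0 (they present no splicing
  evidence).

The default configuration prioritises complete protein-coding models:
CDS length (w=3), completeness (w=2), verified junctions (w=2), one
internal ORF as target (w=2), plus cDNA length, canonical splicing, locus
fractions, homology, and a penalty on retained introns. The default
`not_fragmentary` exemption is "multiexonic or complete": a spliced model
is never purged as a neighbour's fragment, which protects real gene
pairs in compact genomes from the proximity filter.

## Chimera resolution

A transcript with two or more cDNA-disjoint ORF clusters is a fusion
candidate. Homology can rescue it: if any single target protein's HSPs
cover at least 20% (configurable) of two clusters, those clusters are
treated as one gene. Remaining clusters each yield a part; exons are cut
at the cDNA midpoint between consecutive clusters (UTR bases between ORFs
go to the nearer part — deterministic and symmetric), and each part's CDS
is its cluster's longest ORF projected to the genome. Split parts then
compete in selection like any other model, so a clean single-gene model
from another input normally outranks them.

## Comparison

The reference is indexed per chromosome in an interval tree; each
prediction is evaluated against every overlapping reference transcript for
nucleotide, junction (= intron) and exon recall/precision, and the best
match maximises junction F1 (ties: nucleotide F1). The class-code decision
table is a re-derivation of the cuffcompare/gffcompare family with every
predicate explicit in `compare.classify_pair`; notable choices:

- `n` (extension) requires the reference chain to be a contiguous
  subchain of the prediction's *and* all extra introns to lie outside the
  reference span — a novel intron inside a reference exon is `j` (or `h`
  when all CDS junctions still agree).
- monoexonic "full match" is ≥80% reciprocal nucleotide overlap, since
  intron-chain identity is undefined for single exons.
- a prediction is a fusion (`f,` prefix) when it intersects transcripts of
  two or more genes, each with a shared junction or exonic overlap
  strictly above 10% of the shorter model's cDNA.

Run statistics count features at six levels; base/exon/intron features are
keyed by (chromosome, strand), so a strand-stripped model does not claim
the stranded reference bases. Transcript-level matches use intron-chain
identity (or the monoexonic rule); a gene matches when any of its
transcripts does. z-scores across methods use the population standard
deviation (zero deviation gives z = 0), so per level they sum to zero.

The UTR-trimming utility shortens terminal exons' UTR portions from the
outer end to a cap (default 50 bp) without crossing the CDS; the
reconstructability filter then keeps reference transcripts whose every
junction is in the detected set and every remaining exonic base has read
depth ≥ 1.

## Synthetic data

The generator builds 20 genes (default) over two chromosomes: 60–150 bp
UTRs, 80–180 codon CDSs with no internal stops, 1–5 exons with GT–AG
introns of 80–400 bp, genes on both strands separated by 0.5–1.5 kb
spacers. Corruptions are drawn independently per transcript and assembler
(three assemblers by default) from one seeded stream: fusions chain the
next same-strand gene — with the artifactual junction placed on canonical
dinucleotides found in the intergenic gap, as spliced aligners would —
fragments keep a random exon subchain, retained introns merge adjacent
exons, strand errors flip the label, duplicates copy a model into another
assembler's set, terminal extensions widen outer exons. The evidence
bundle derives trusted junctions and a depth-1 coverage track from the
truth, scans each (post-preparation-oriented) cDNA for ORFs of ≥200 nt in
the manner of an ORF caller, and links each ORF to a synthetic protein id
per truth gene whose CDS its genomic footprint overlaps — so a fused
model hits two distinct proteins and triggers the split path.

What the generator does not emulate: expression-dependent coverage,
alignment noise, soft-clipped or misassembled exon boundaries beyond the
listed corruption classes, paralogy between genes, and genomes with N
bases. Passing end-to-end tests therefore demonstrates the selection
logic under a controlled error spectrum, not performance on real
libraries.

## Problem sizes and numerical choices

Test and reproduction runs use 20-gene genomes (~40 kb) with three input
sets — large enough that every corruption class occurs at the default
rates, while a full pipeline run takes well under a second. The
brute-force oracles enumerate every overlap graph on up to six
transcripts for primary selection and use 50-transcript random fixtures
for the comparison statistics. Seeds fix all randomness; two runs with
the same seed produce byte-identical outputs (sorted writers, no hash
iteration order anywhere).

Known limitations: requirements are evaluated on intrinsic metrics before
grouping, so a locus-relative requirement atom sees singleton-group
values; alternative-splicing candidates are scored once in the context of
their locus's candidate group rather than re-scored after each admission;
`J`-coded truncations that reach half the primary's score can be admitted
as isoforms (faithful to the defaults, at some precision cost); and the
external-merge sort bounds memory per run but the dedup table is still
in-memory per chromosome-scale batch.
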