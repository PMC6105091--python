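# txweave

**txweave** consolidates transcript models from multiple genome-guided
assemblers, samples or sequencing technologies into a single coherent gene
annotation. RNA-seq assemblers have idiosyncratic strengths: each one
correctly reconstructs transcripts the others miss, while also producing
artifacts — read-through fusions chaining neighbouring genes, fragmented
models, retained introns, mislabelled strands and duplicates. Rather than
naively pooling assemblies (which maximises recall but destroys
precision), txweave scores every candidate transcript against its
competitors at the same locus and selects, per locus, the model that best
fits user-defined criteria, plus any valid splice variants.

It is aimed at genome-annotation groups and anyone producing an
evidence-based gene set from heterogeneous transcript assemblies.

## Method

The pipeline has three stages, plus a comparison tool:

1. **prepare** — reads GTF/GFF3/BED12 inputs, discards models shorter than
   200 bp (default), checks each intron for canonical splice dinucleotides
   (GT–AG, GC–AG, AT–AC), flips multiexonic models whose introns are
   canonical only on the opposite strand, discards models with canonical
   introns on both strands, strips the strand of monoexonic models from
   non-strand-specific assemblies, removes exact duplicates, and emits a
   coordinate-sorted GTF plus the matching cDNA FASTA.
2. **evidence** — loads trusted splice junctions (genomic BED), ORFs called
   on the prepared cDNAs (transcript-space BED12/GFF3) and protein-homology
   hits (a tabular BLASTX/DIAMOND digest) into a single SQLite store.
3. **pick** — clusters transcripts into superloci (flanked span overlap)
   and subloci (shared introns, or exonic overlap for monoexonic models),
   splits candidate chimeras (two or more cDNA-disjoint ORFs whose homology
   does not tie them to one protein), computes ~26 per-transcript metrics,
   turns a scoring configuration into hard filters and a numeric score, and
   greedily selects non-intersecting locus primaries in descending score
   order. Each metric *m* with group minimum *lo* and maximum *hi*
   contributes, for a transcript with value *v*,

   - `max` rescaling: `w · (v − lo)/(hi − lo)`
   - `min` rescaling: `w · (hi − v)/(hi − lo)`
   - `target t`: `w · (1 − |v − t| / max(|hi − t|, |lo − t|))`

   with weight *w* > 0. After primaries are fixed, alternative-splicing
   candidates are admitted when their class code against the primary is a
   valid event (default `j`, `J`, `h`, `G`), their intron chain is novel in
   the locus, and their score is at least 50% of the primary's (default),
   up to an isoform cap. Loci that look like fragments of a higher-scoring
   neighbour (intronic, proximal or antisense codes) are purged.

**compare** measures any annotation against a reference: each prediction
is matched through an interval-tree index, labelled with a one-symbol
class code (`=` identical intron chain, `j` shared junction, `u`
unrelated, …; fusions prefixed `f,`), and run-level recall/precision/F1
are reported at six levels — base, exon, intron, intron chain, transcript
and gene. A cumulative z-score ranks methods across levels.

## Worked example

Everything below runs offline from a bundled synthetic-data generator that
emulates the assembler error spectrum (fusion, fragmentation, duplication):

```sh
txweave fixtures make --seed 8 --out fx/
printf 'fx/asm%d.gtf\tasm%d\ttrue\n' 1 1 2 2 3 3 > inputs.tsv
txweave prepare --genome fx/genome.fasta --list inputs.tsv \
    --out prepared.gtf --out-fasta prepared.fasta
txweave evidence build --junctions fx/junctions.bed --orfs fx/orfs.bed12 \
    --homology fx/homology.tsv --cdna prepared.fasta --out store.db
txweave pick --gtf prepared.gtf --store store.db --out final.gff3
txweave compare -r fx/truth.gff3 -p final.gff3 -o cmp
```

On a corrupted dataset (seed 1; fusion rate 0.1, fragment rate 0.2,
duplicate rate 0.3 across three synthetic assemblers of a 20-gene toy
genome) the reproduction script prints:

```
pipeline_transcript_f1_percent: 90.9091 (n=20)
best_single_input_transcript_f1_percent: 76.1194 (n=20)
transcript_f1_gain_over_best_input_percent: 14.7897 (n=20)
fusions_split_to_correct_genes: 3.0 (n=3)
clean_input_transcript_f1_percent: 100.0 (n=20)
```

The integrated annotation recovers every truth transcript (100% recall)
and its transcript-level F1 exceeds the best single input by ~15 points;
every injected read-through fusion that survived preparation is split into
parts matching its two source genes; on pristine inputs the pipeline
returns the truth set exactly.

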