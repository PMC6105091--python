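"""Seeded synthetic fixtures: toy genomes, truth annotations and
assembler-like corrupted transcript sets.

The generator builds genes with canonical GT–AG introns, ATG…stop ORFs and
UTRs on both strands of small random chromosomes, then derives per-
"assembler" input sets by injecting the error classes real assemblers
produce: read-through fusions chaining neighbouring genes, fragmented
models, retained introns, strand labelling errors, exact duplicates and
ragged terminal extensions.  A bundle emitter produces the matching
evidence inputs (trusted junction BED, transcript-space ORF BED12, a
homology TSV and a coverage bedgraph) so the whole pipeline can run
without any external data or tools.

Everything is driven by a single pseudo-random stream keyed by the seed:
the same spec yields byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .models import AnnotationSet, TranscriptModel, extract_cdna
from .prepare import classify_introns, resolve_strand

BASES = np.array(list("ACGT"))
STOPS = ("TAA", "TAG", "TGA")
_CODONS = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in STOPS
]


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic dataset."""

    seed: int = 0
    chrom_count: int = 2
    gene_count: int = 20
    chrom_length: int | None = None  # None: sized to fit the genes
    n_assemblers: int = 3
    mono_prob: float = 0.2      # fraction of single-exon genes
    isoform_prob: float = 0.0   # chance of a second (exon-skipping) isoform
    # corruption rates, independent per transcript and assembler
    fusion_rate: float = 0.0
    fragment_rate: float = 0.0
    retained_intron_rate: float = 0.0
    strand_error_rate: float = 0.0
    duplicate_rate: float = 0.0
    terminal_extension_rate: float = 0.0

    def __post_init__(self):
        for name in (
            "fusion_rate", "fragment_rate", "retained_intron_rate",
            "strand_error_rate", "duplicate_rate", "terminal_extension_rate",
            "mono_prob", "isoform_prob",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass
class CorruptionRecord:
    assembler: str
    transcript_id: str
    corruption: str
    genes: tuple[str, ...]


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=n)])


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    idx = rng.integers(0, len(_CODONS), size=n_codons)
    stop = STOPS[rng.integers(0, 3)]
    return "ATG" + "".join(_CODONS[i] for i in idx) + stop


def _build_gene(rng: np.random.Generator, mono_prob: float = 0.2):
    """One gene's genomic segment in transcript orientation.

    Returns (segment sequence, exon intervals, cds intervals) with
    coordinates local to the segment and oriented 5'→3'.
    """
    u5 = rng.integers(60, 150)
    u3 = rng.integers(60, 150)
    cds = _random_cds(rng, int(rng.integers(80, 180)))
    cdna = _random_seq(rng, u5) + cds + _random_seq(rng, u3)
    cds_span = (u5, u5 + len(cds))
    if rng.random() < mono_prob:
        n_exons = 1
    else:
        n_exons = int(rng.integers(2, 6))
    # breakpoints on the cDNA, at least 30 bp per exon
    if n_exons > 1:
        while True:
            cuts = np.sort(rng.integers(30, len(cdna) - 30, size=n_exons - 1))
            if len(set(cuts)) == n_exons - 1 and np.all(np.diff(cuts) >= 30):
                break
        cuts = [0, *map(int, cuts), len(cdna)]
    else:
        cuts = [0, len(cdna)]
    seq_parts, exons, offset = [], [], 0
    intron_shift = []  # genomic offset added before each exon
    for i in range(n_exons):
        lo, hi = cuts[i], cuts[i + 1]
        if i > 0:
            ilen = int(rng.integers(80, 400))
            seq_parts.append("GT" + _random_seq(rng, ilen - 4) + "AG")
            offset += ilen
        seq_parts.append(cdna[lo:hi])
        exons.append((lo + offset, hi + offset))
        intron_shift.append(offset)
    segment = "".join(seq_parts)
    cds_g = []
    for i in range(n_exons):
        lo = max(cds_span[0], cuts[i])
        hi = min(cds_span[1], cuts[i + 1])
        if lo < hi:
            cds_g.append((lo + intron_shift[i], hi + intron_shift[i]))
    return segment, exons, cds_g


def _flip_segment(segment: str, intervals: list[tuple[int, int]]):
    """Mirror local intervals for a reverse-complemented segment."""
    from .models import reverse_complement

    n = len(segment)
    return (
        reverse_complement(segment),
        sorted((n - e, n - s) for s, e in intervals),
    )


def generate_truth(spec: FixtureSpec):
    """Build the genome and truth annotation for a spec.

    Returns ``(genome, truth)`` where ``genome`` maps chromosome name to
    sequence and ``truth`` is an :class:`AnnotationSet`; deterministic
    under the spec's seed.
    """
    rng = np.random.default_rng(spec.seed)
    genome: dict[str, str] = {}
    truth = AnnotationSet()
    genes_per_chrom = [
        spec.gene_count // spec.chrom_count
        + (1 if i < spec.gene_count % spec.chrom_count else 0)
        for i in range(spec.chrom_count)
    ]
    gene_n = 0
    for ci in range(spec.chrom_count):
        chrom = f"chr{ci + 1}"
        parts = [_random_seq(rng, int(rng.integers(500, 1500)))]
        pos = len(parts[0])
        for _ in range(genes_per_chrom[ci]):
            gene_n += 1
            gid = f"G{gene_n:03d}"
            strand = "+" if rng.random() < 0.5 else "-"
            segment, exons, cds = _build_gene(rng, spec.mono_prob)
            if strand == "-":
                seg_rc, exons = _flip_segment(segment, exons)
                _, cds = _flip_segment(segment, cds)
                segment = seg_rc
            t = TranscriptModel(
                id=f"{gid}.1",
                chrom=chrom,
                strand=strand,
                exons=[(s + pos, e + pos) for s, e in exons],
                cds_segments=[(s + pos, e + pos) for s, e in cds],
                gene_id=gid,
            )
            truth.add(t)
            if spec.isoform_prob and len(t.exons) >= 3 and rng.random() < spec.isoform_prob:
                # exon-skipping isoform: drop one internal exon
                k = int(rng.integers(1, len(t.exons) - 1))
                iso_exons = [e for i, e in enumerate(t.exons) if i != k]
                iso_cds = [
                    c for c in t.cds_segments
                    if any(s <= c[0] and c[1] <= e for s, e in iso_exons)
                ]
                truth.add(
                    TranscriptModel(
                        id=f"{gid}.2", chrom=chrom, strand=strand,
                        exons=iso_exons, cds_segments=iso_cds, gene_id=gid,
                    )
                )
            parts.append(segment)
            pos += len(segment)
            spacer = _random_seq(rng, int(rng.integers(500, 1500)))
            parts.append(spacer)
            pos += len(spacer)
        seq = "".join(parts)
        if spec.chrom_length is not None:
            if len(seq) > spec.chrom_length:
                raise ValueError(
                    f"{chrom}: {genes_per_chrom[ci]} genes need {len(seq)} bp "
                    f"but chrom_length is {spec.chrom_length}"
                )
            seq += _random_seq(rng, spec.chrom_length - len(seq))
        genome[chrom] = seq
    return genome, truth


# ---------------------------------------------------------------------------
# Corruption


def _fragment(t: TranscriptModel, rng) -> TranscriptModel:
    if t.is_monoexonic:
        s, e = t.exons[0]
        half = (e - s) // 2
        return replace_structure(t, [(s, s + half)])
    n = len(t.exons)
    keep = int(rng.integers(1, n))
    start = int(rng.integers(0, n - keep + 1))
    return replace_structure(t, t.exons[start:start + keep])


def replace_structure(t: TranscriptModel, exons) -> TranscriptModel:
    new = t.copy()
    new.exons = sorted(tuple(e) for e in exons)
    new.cds_segments = []
    return new


def _retain_intron(t: TranscriptModel, rng) -> TranscriptModel | None:
    if t.is_monoexonic:
        return None
    i = int(rng.integers(0, len(t.exons) - 1))
    exons = list(t.exons)
    exons[i] = (exons[i][0], exons[i + 1][1])
    del exons[i + 1]
    return replace_structure(t, exons)


def _extend_terminal(t: TranscriptModel, rng, chrom_len: int) -> TranscriptModel:
    exons = list(t.exons)
    ext5 = int(rng.integers(20, 100))
    ext3 = int(rng.integers(20, 100))
    s, e = exons[0]
    exons[0] = (max(0, s - ext5), e)
    s, e = exons[-1]
    exons[-1] = (s, min(chrom_len, e + ext3))
    return replace_structure(t, exons)


def _canonical_gap(seq: str, a_end: int, b_start: int, strand: str):
    """Splice boundaries for the artifactual intron joining two fused genes.

    Spliced aligners place junctions at canonical motifs on the transcript
    strand, so the read-through intron of a fused model starts at the first
    donor dinucleotide after the upstream gene and ends at the last
    acceptor before the downstream one.  Falls back to the plain gene
    boundaries when the gap lacks the motifs.
    """
    donor, acceptor = ("GT", "AG") if strand == "+" else ("CT", "AC")
    i = seq.find(donor, a_end, b_start - 22)
    j = seq.rfind(acceptor, a_end + 2, b_start)
    if i == -1 or j == -1 or (j + 2) - i < 20:
        return a_end, b_start
    return i, j + 2


def corrupt(
    truth: AnnotationSet, spec: FixtureSpec, genome: dict[str, str]
) -> tuple[dict[str, AnnotationSet], list[CorruptionRecord]]:
    """Derive per-assembler input sets from the truth annotation.

    Each assembler emits one model per truth transcript unless a fusion
    consumes a neighbouring gene pair, in which case the chained model
    replaces both.  Corruptions are drawn independently per transcript and
    assembler from the single seeded stream; every applied corruption is
    logged.
    """
    rng = np.random.default_rng(spec.seed + 1)
    sets: dict[str, AnnotationSet] = {}
    log: list[CorruptionRecord] = []
    ordered = list(truth)
    pending_duplicates: dict[str, list[TranscriptModel]] = {}
    assemblers = [f"asm{i + 1}" for i in range(spec.n_assemblers)]
    for ai, asm in enumerate(assemblers):
        out = AnnotationSet()
        fused_away: set[str] = set()
        for idx, t in enumerate(ordered):
            if t.id in fused_away:
                continue
            tid = f"{asm}.{t.id}"
            # fusion: chain with the next same-strand transcript on the chrom
            nxt = ordered[idx + 1] if idx + 1 < len(ordered) else None
            can_fuse = (
                nxt is not None
                and nxt.chrom == t.chrom
                and nxt.strand == t.strand
                and nxt.gene_id != t.gene_id
            )
            roll = rng.random(6)
            if spec.fusion_rate and can_fuse and roll[0] < spec.fusion_rate:
                a_exons, b_exons = list(t.exons), list(nxt.exons)
                gap_s, gap_e = _canonical_gap(
                    genome[t.chrom], a_exons[-1][1], b_exons[0][0], t.strand
                )
                a_exons[-1] = (a_exons[-1][0], gap_s)
                b_exons[0] = (gap_e, b_exons[0][1])
                fused = replace_structure(t, a_exons + b_exons)
                fused.id = f"{asm}.{t.gene_id}-{nxt.gene_id}.fused"
                fused.gene_id = ""
                fused.source_label = asm
                out.add(fused)
                fused_away.add(nxt.id)
                log.append(
                    CorruptionRecord(asm, fused.id, "fusion",
                                     (t.gene_id, nxt.gene_id))
                )
                continue
            model = t.copy()
            model.id = tid
            model.gene_id = ""
            model.source_label = asm
            corruption = None
            if spec.fragment_rate and roll[1] < spec.fragment_rate:
                model = _fragment(model, rng)
                corruption = "fragment"
            elif spec.retained_intron_rate and roll[2] < spec.retained_intron_rate:
                retained = _retain_intron(model, rng)
                if retained is not None:
                    model = retained
                    corruption = "retained_intron"
            elif spec.strand_error_rate and roll[3] < spec.strand_error_rate:
                model = model.copy()
                model.strand = "-" if model.strand == "+" else "+"
                corruption = "strand_error"
            elif spec.terminal_extension_rate and roll[4] < spec.terminal_extension_rate:
                model = _extend_terminal(model, rng, len(genome[model.chrom]))
                corruption = "terminal_extension"
            model.cds_segments = []  # assemblers report exon structure only
            out.add(model)
            if corruption:
                log.append(CorruptionRecord(asm, model.id, corruption, (t.gene_id,)))
            if spec.duplicate_rate and roll[5] < spec.duplicate_rate:
                target = assemblers[(ai + 1) % len(assemblers)]
                dup = model.copy()
                dup.id = f"{target}.dup.{t.id}"
                dup.source_label = target
                pending_duplicates.setdefault(target, []).append(dup)
                log.append(CorruptionRecord(target, dup.id, "duplicate", (t.gene_id,)))
        sets[asm] = out
    for asm, dups in pending_duplicates.items():
        for dup in dups:
            sets[asm].add(dup)
    return sets, log


# ---------------------------------------------------------------------------
# Evidence bundle


def scan_orfs(cdna: str, min_len: int = 200, max_orfs: int = 5):
    """Find ORFs on the forward strand of a cDNA, longest first.

    Emulates an ORF caller: complete ATG…stop ORFs in all three frames,
    plus 5'-partial (stop without upstream ATG, from the cDNA start) and
    3'-partial (ATG without downstream stop, to the cDNA end) cases.
    Returns (start, end, has_start, has_stop) tuples, 0-based half-open.
    """
    seq = cdna.upper()
    n = len(seq)
    found: list[tuple[int, int, bool, bool]] = []
    for frame in range(3):
        start = None
        partial_start = frame  # candidate 5'-partial ORF begins at frame
        for i in range(frame, n - 2, 3):
            codon = seq[i:i + 3]
            if codon in STOPS:
                if start is not None:
                    found.append((start, i + 3, True, True))
                    start = None
                elif partial_start is not None and i + 3 - partial_start >= min_len:
                    found.append((partial_start, i + 3, False, True))
                partial_start = None
            elif codon == "ATG" and start is None:
                start = i
        if start is not None and n - start >= min_len:
            end = start + (n - start) // 3 * 3
            if end - start >= 3:
                found.append((start, end, True, False))
    found = [f for f in found if f[1] - f[0] >= min_len]
    found.sort(key=lambda f: (-(f[1] - f[0]), f[0]))
    # drop ORFs nested in a longer one already taken
    out: list[tuple[int, int, bool, bool]] = []
    for f in found:
        if not any(o[0] <= f[0] and f[1] <= o[1] for o in out):
            out.append(f)
        if len(out) >= max_orfs:
            break
    return sorted(out)


def _post_prepare_model(t: TranscriptModel, genome) -> TranscriptModel | None:
    """The orientation a model will have after the preparation stage."""
    if t.is_monoexonic:
        return t  # strand-specific sources keep their strand
    verdicts = classify_introns(t, genome)
    d = resolve_strand(t, verdicts, strand_specific_source=True)
    if d.action == "discard":
        return None
    model = t.copy()
    if d.action == "flip_strand":
        if model.strand == "+":
            model.strand = "-"
        elif model.strand == "-":
            model.strand = "+"
        else:
            on = {v.canonical_on for v in verdicts} - {"none"}
            model.strand = on.pop() if on else "+"
    return model


def emit_bundle(
    truth: AnnotationSet,
    corrupted: dict[str, AnnotationSet],
    genome: dict[str, str],
):
    """Evidence inputs matching a corrupted dataset.

    Returns a dict with: ``junctions`` (truth introns as (chrom, s, e,
    strand) tuples), ``orf_rows`` (transcript-space BED12 rows), ``homology
    rows`` (TSV rows linking each ORF to a synthetic protein id, one per
    truth gene whose CDS the ORF's genomic footprint overlaps — fused
    models therefore hit two proteins), and ``coverage`` (per-chromosome
    depth-1 arrays over truth exons).
    """
    from .models import project_to_genome

    junctions = sorted(
        {(t.chrom, s, e, t.strand) for t in truth for s, e in t.introns}
    )
    # genomic CDS footprint per truth gene
    gene_cds: dict[str, list[tuple[str, int, int]]] = {}
    for t in truth:
        gene_cds.setdefault(t.gene_id, []).extend(
            (t.chrom, s, e) for s, e in t.cds_segments
        )
    orf_rows: list[str] = []
    homology_rows: list[str] = []
    for asm in sorted(corrupted):
        for t in corrupted[asm]:
            oriented = _post_prepare_model(t, genome)
            if oriented is None:
                continue
            cdna = extract_cdna(oriented, genome)
            for k, (s, e, has_start, has_stop) in enumerate(
                scan_orfs(cdna), start=1
            ):
                tag = (
                    "complete" if has_start and has_stop
                    else "5prime_partial" if has_stop
                    else "3prime_partial"
                )
                name = f"{t.id}.orf{k};type:{tag}"
                orf_rows.append(
                    "\t".join(
                        map(str, [
                            t.id, 0, len(cdna), name, 0, "+", s, e, 0, 1,
                            len(cdna), 0,
                        ])
                    )
                )
                footprint = project_to_genome(oriented, (s, e))
                orf_genes = sorted(
                    gid
                    for gid, segs in gene_cds.items()
                    if any(
                        g.chrom == c and g.start < ce and cs < g.end
                        for g in footprint
                        for c, cs, ce in segs
                    )
                )
                for gid in orf_genes:
                    bitscore = 100.0 + (e - s) / 3.0
                    homology_rows.append(
                        f"{t.id}\tPROT_{gid}\t1e-50\t{bitscore:.1f}\t"
                        f"{s + 1}\t{e}\t1\t{(e - s) // 3}"
                    )
    coverage = {
        chrom: np.zeros(len(seq), dtype=np.int32)
        for chrom, seq in genome.items()
    }
    for t in truth:
        for s, e in t.exons:
            coverage[t.chrom][s:e] = 1
    return {
        "junctions": junctions,
        "orf_rows": orf_rows,
        "homology_rows": homology_rows,
        "coverage": coverage,
    }


# ---------------------------------------------------------------------------
# File emission


def write_bundle(spec: FixtureSpec, outdir: str) -> dict[str, str]:
    """Generate a complete fixture on disk; returns the path map."""
    import os

    from . import io as tio

    os.makedirs(outdir, exist_ok=True)
    genome, truth = generate_truth(spec)
    corrupted, log = corrupt(truth, spec, genome)
    bundle = emit_bundle(truth, corrupted, genome)
    paths = {
        "genome": os.path.join(outdir, "genome.fasta"),
        "truth": os.path.join(outdir, "truth.gff3"),
        "junctions": os.path.join(outdir, "junctions.bed"),
        "orfs": os.path.join(outdir, "orfs.bed12"),
        "homology": os.path.join(outdir, "homology.tsv"),
        "coverage": os.path.join(outdir, "coverage.bedgraph"),
        "corruptions": os.path.join(outdir, "corruptions.tsv"),
    }
    tio.write_fasta(genome, paths["genome"])
    tio.write_gff3(truth, paths["truth"])
    for asm, annset in sorted(corrupted.items()):
        paths[asm] = os.path.join(outdir, f"{asm}.gtf")
        tio.write_gtf(annset, paths[asm], source=asm)
    with open(paths["junctions"], "w") as fh:
        for chrom, s, e, strand in bundle["junctions"]:
            fh.write(f"{chrom}\t{s}\t{e}\tjunc\t0\t{strand}\n")
    with open(paths["orfs"], "w") as fh:
        fh.write("\n".join(bundle["orf_rows"]) + ("\n" if bundle["orf_rows"] else ""))
    with open(paths["homology"], "w") as fh:
        fh.write("\n".join(bundle["homology_rows"])
                 + ("\n" if bundle["homology_rows"] else ""))
    with open(paths["coverage"], "w") as fh:
        for chrom in sorted(bundle["coverage"]):
            depth = bundle["coverage"][chrom]
            # run-length encode
            edges = np.flatnonzero(np.diff(depth)) + 1
            starts = [0, *edges.tolist()]
            ends = [*edges.tolist(), len(depth)]
            for s, e in zip(starts, ends):
                if depth[s]:
                    fh.write(f"{chrom}\t{s}\t{e}\t{int(depth[s])}\n")
    with open(paths["corruptions"], "w") as fh:
        fh.write("assembler\ttranscript_id\tcorruption\tgenes\n")
        for rec in log:
            fh.write(
                f"{rec.assembler}\t{rec.transcript_id}\t{rec.corruption}\t"
                f"{','.join(rec.genes)}\n"
            )
    return paths
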