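"""Core data model for transcript structures.

All coordinates are 0-based, half-open internally; the GTF/GFF3 readers and
writers convert at the boundary.  A :class:`TranscriptModel` is an exon chain
with an optional CDS; introns, cDNA length and the intron chain are derived.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

STRANDS = ("+", "-", ".")

_COMPLEMENT = str.maketrans("ACGTacgtNnRYKMrykm", "TGCAtgcaNnYRMKyrmk")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class TranscriptModel:
    """One assembled transcript: exon chain, optional CDS, provenance.

    ``exons`` and ``cds_segments`` are lists of (start, end) tuples on the
    genome, sorted by start and pairwise non-overlapping.  ``strand`` is one
    of ``+``, ``-``, ``.``; a ``.`` strand means unknown orientation.
    """

    id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    gene_id: str = ""
    source_label: str = ""
    cds_segments: list[tuple[int, int]] = field(default_factory=list)
    input_score: float | None = None
    attributes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.exons = sorted(tuple(e) for e in self.exons)
        self.cds_segments = sorted(tuple(c) for c in self.cds_segments)
        self.validate()

    def validate(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(f"{self.id}: invalid strand {self.strand!r}")
        if not self.exons:
            raise ValueError(f"{self.id}: transcript has no exons")
        prev_end = -1
        for s, e in self.exons:
            if not (0 <= s < e):
                raise ValueError(f"{self.id}: invalid exon ({s},{e})")
            if s < prev_end:
                raise ValueError(f"{self.id}: overlapping/unsorted exons")
            prev_end = e
        for s, e in self.cds_segments:
            if not any(xs <= s and e <= xe for xs, xe in self.exons):
                raise ValueError(
                    f"{self.id}: CDS segment ({s},{e}) not contained in an exon"
                )

    # -- derived structure ------------------------------------------------

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        ]

    @property
    def intron_chain(self) -> tuple[tuple[int, int], ...]:
        return tuple(self.introns)

    @property
    def cdna_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds_segments)

    @property
    def is_monoexonic(self) -> bool:
        return len(self.exons) == 1

    @property
    def exon_count(self) -> int:
        return len(self.exons)

    def copy(self) -> "TranscriptModel":
        return TranscriptModel(
            id=self.id,
            chrom=self.chrom,
            strand=self.strand,
            exons=list(self.exons),
            gene_id=self.gene_id,
            source_label=self.source_label,
            cds_segments=list(self.cds_segments),
            input_score=self.input_score,
            attributes=dict(self.attributes),
        )

    # -- coordinate mapping -----------------------------------------------

    def genome_to_cdna(self, pos: int) -> int:
        """Map a genomic base (within an exon) to its cDNA offset."""
        off = 0
        for s, e in self.exons:
            if s <= pos < e:
                plus = off + (pos - s)
                if self.strand == "-":
                    return self.cdna_length - 1 - plus
                return plus
            off += e - s
        raise ValueError(f"{self.id}: position {pos} not exonic")

    def sort_key(self) -> tuple:
        return (self.chrom, self.start, self.end, self.id)


def project_to_genome(
    t: TranscriptModel, cdna_interval: tuple[int, int]
) -> list[GenomicInterval]:
    """Project a cDNA interval onto the genome as exon-clipped segments.

    For a ``-`` strand transcript cDNA position 0 maps to the genomically
    last exon base.  The returned segments are sorted by genomic start and
    their total length equals the cDNA interval length.
    """
    cs, ce = cdna_interval
    L = t.cdna_length
    if not (0 <= cs < ce <= L):
        raise ValueError(
            f"{t.id}: cDNA interval ({cs},{ce}) outside cDNA of length {L}"
        )
    if t.strand == "-":
        # translate to plus-orientation cDNA coordinates
        cs, ce = L - ce, L - cs
    out: list[GenomicInterval] = []
    off = 0  # cDNA offset (plus orientation) at exon start
    for s, e in t.exons:
        elen = e - s
        lo = max(cs, off)
        hi = min(ce, off + elen)
        if lo < hi:
            out.append(
                GenomicInterval(t.chrom, s + (lo - off), s + (hi - off), t.strand)
            )
        off += elen
    return out


def extract_cdna(t: TranscriptModel, genome) -> str:
    """Spliced cDNA sequence; reverse-complemented on the ``-`` strand.

    ``genome`` is any mapping of chromosome name to a sliceable sequence
    (a :class:`pyfaidx.Fasta` works, as does a plain dict of strings).
    """
    if t.chrom not in genome:
        raise KeyError(f"{t.id}: chromosome {t.chrom!r} not in genome")
    chrom = genome[t.chrom]
    chrom_len = len(chrom)
    if t.end > chrom_len:
        raise ValueError(
            f"{t.id}: exon end {t.end} beyond chromosome length {chrom_len}"
        )
    seq = "".join(str(chrom[s:e]) for s, e in t.exons)
    if t.strand == "-":
        seq = reverse_complement(seq)
    return seq


class AnnotationSet:
    """Transcripts keyed by id with gene grouping and chromosome order."""

    def __init__(self, transcripts: Iterator[TranscriptModel] = ()):
        self.transcripts: dict[str, TranscriptModel] = {}
        self.genes: dict[str, list[str]] = {}
        for t in transcripts:
            self.add(t)

    def add(self, t: TranscriptModel) -> None:
        if t.id in self.transcripts:
            raise ValueError(f"duplicate transcript id {t.id!r}")
        if not t.gene_id:
            t.gene_id = t.id + ".gene"
        self.transcripts[t.id] = t
        self.genes.setdefault(t.gene_id, []).append(t.id)

    def remove(self, tid: str) -> TranscriptModel:
        t = self.transcripts.pop(tid)
        self.genes[t.gene_id].remove(tid)
        if not self.genes[t.gene_id]:
            del self.genes[t.gene_id]
        return t

    def __len__(self) -> int:
        return len(self.transcripts)

    def __iter__(self) -> Iterator[TranscriptModel]:
        return iter(sorted(self.transcripts.values(), key=TranscriptModel.sort_key))

    def __contains__(self, tid: str) -> bool:
        return tid in self.transcripts

    def __getitem__(self, tid: str) -> TranscriptModel:
        return self.transcripts[tid]

    @property
    def chromosomes(self) -> list[str]:
        return sorted({t.chrom for t in self.transcripts.values()})

    def gene_transcripts(self, gene_id: str) -> list[TranscriptModel]:
        return [self.transcripts[tid] for tid in self.genes.get(gene_id, [])]

    def structurally_equal(self, other: "AnnotationSet") -> bool:
        """Equality at the id/strand/exon/CDS level (attributes ignored)."""
        if set(self.transcripts) != set(other.transcripts):
            return False
        for tid, t in self.transcripts.items():
            o = other.transcripts[tid]
            if (
                t.chrom != o.chrom
                or t.strand != o.strand
                or t.exons != o.exons
                or t.cds_segments != o.cds_segments
            ):
                return False
        return True
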