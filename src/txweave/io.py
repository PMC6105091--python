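"""Readers and writers for GTF, GFF3, BED12 and FASTA.

File coordinates (1-based inclusive for GTF/GFF3, 0-based half-open for BED)
are converted to the internal 0-based half-open convention at this boundary.
Attributes are preserved verbatim as strings; unknown keys are never dropped.
Writers emit deterministically sorted, spec-conformant files.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .models import AnnotationSet, TranscriptModel


class ParseError(ValueError):
    """A malformed row; message carries the file and line number."""


@dataclass
class OrfRecord:
    """An open reading frame located on a transcript's cDNA.

    ``cdna_start``/``cdna_end`` are 0-based half-open on the cDNA in its
    5'→3' orientation; ``strand`` is relative to the cDNA.
    """

    transcript_id: str
    cdna_start: int
    cdna_end: int
    strand: str = "+"
    has_start: bool = False
    has_stop: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.cdna_start < self.cdna_end):
            raise ValueError(
                f"{self.transcript_id}: invalid ORF interval "
                f"({self.cdna_start},{self.cdna_end})"
            )
        if self.cdna_end - self.cdna_start < 3:
            raise ValueError(f"{self.transcript_id}: ORF shorter than 3 nt")

    @property
    def length(self) -> int:
        return self.cdna_end - self.cdna_start

    @property
    def is_complete(self) -> bool:
        return self.has_start and self.has_stop


# ---------------------------------------------------------------------------
# GTF


_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_gtf_attributes(field: str) -> dict[str, str]:
    return dict(_GTF_ATTR.findall(field))


def read_gtf(path) -> AnnotationSet:
    """Read a GTF file into an :class:`AnnotationSet`.

    Transcripts are reconstructed from ``exon`` (and optionally ``CDS``)
    rows; ``transcript`` feature rows are optional and used only for
    attributes.  Raises :class:`ParseError` with the offending line number
    on malformed rows.
    """
    exons: dict[str, list[tuple[int, int]]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 tab-separated fields")
            chrom, source, ftype, start, end, score, strand, _, attr = fields
            if ftype not in ("exon", "CDS", "transcript", "mRNA"):
                continue
            attrs = _parse_gtf_attributes(attr)
            tid = attrs.get("transcript_id")
            if tid is None:
                raise ParseError(f"{path}:{lineno}: missing transcript_id")
            try:
                s, e = int(start) - 1, int(end)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            if e <= s:
                raise ParseError(
                    f"{path}:{lineno}: end < start for transcript {tid}"
                )
            m = meta.setdefault(
                tid, {"chrom": chrom, "strand": strand, "gene_id": "",
                      "source": source, "score": None, "attributes": {}}
            )
            if attrs.get("gene_id"):
                m["gene_id"] = attrs["gene_id"]
            for k, v in attrs.items():
                if k not in ("transcript_id", "gene_id"):
                    m["attributes"].setdefault(k, v)
            if score not in (".", "") and m["score"] is None:
                try:
                    m["score"] = float(score)
                except ValueError:
                    pass
            if ftype == "exon":
                exons.setdefault(tid, []).append((s, e))
            elif ftype == "CDS":
                cds.setdefault(tid, []).append((s, e))
    out = AnnotationSet()
    for tid in sorted(exons, key=lambda i: (meta[i]["chrom"], min(s for s, _ in exons[i]), i)):
        m = meta[tid]
        out.add(
            TranscriptModel(
                id=tid,
                chrom=m["chrom"],
                strand=m["strand"] if m["strand"] in "+-" else ".",
                exons=exons[tid],
                cds_segments=_merge_adjacent(cds.get(tid, [])),
                gene_id=m["gene_id"],
                source_label=m["source"],
                input_score=m["score"],
                attributes=m["attributes"],
            )
        )
    return out


def _merge_adjacent(segs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge book-ended segments (GTF CDS split at stop codons, etc.)."""
    segs = sorted(segs)
    out: list[tuple[int, int]] = []
    for s, e in segs:
        if out and out[-1][1] == s:
            out[-1] = (out[-1][0], e)
        else:
            out.append((s, e))
    return [tuple(x) for x in out]


# ---------------------------------------------------------------------------
# GFF3


def _parse_gff3_attributes(field: str) -> dict[str, str]:
    out = {}
    for item in field.split(";"):
        item = item.strip()
        if not item:
            continue
        if "=" in item:
            k, v = item.split("=", 1)
            out[k] = v
    return out


_TRANSCRIPT_TYPES = {
    "mRNA", "transcript", "ncRNA", "lnc_RNA", "tRNA", "rRNA", "miRNA",
    "snoRNA", "snRNA", "pseudogenic_transcript",
}


def read_gff3(path) -> AnnotationSet:
    """Read a GFF3 gene/mRNA/exon/CDS hierarchy linked by ID/Parent.

    Exon or CDS rows with several parents are duplicated into every parent
    transcript.  CDS phase columns are ignored for structure but preserved
    in the transcript attributes.  A Parent that never resolves to a
    transcript row raises :class:`ParseError` naming the orphan.
    """
    tx_meta: dict[str, dict] = {}
    gene_of: dict[str, str] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    pending: list[tuple[int, str, str, int, int, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 tab-separated fields")
            chrom, source, ftype, start, end, score, strand, phase, attr = fields
            attrs = _parse_gff3_attributes(attr)
            try:
                s, e = int(start) - 1, int(end)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            if e <= s:
                raise ParseError(f"{path}:{lineno}: end < start")
            if ftype == "gene":
                continue
            if ftype in _TRANSCRIPT_TYPES:
                tid = attrs.get("ID")
                if tid is None:
                    raise ParseError(f"{path}:{lineno}: transcript row without ID")
                extra = {
                    k: v for k, v in attrs.items()
                    if k not in ("ID", "Parent")
                }
                tx_meta[tid] = {
                    "chrom": chrom,
                    "strand": strand if strand in "+-" else ".",
                    "source": source,
                    "score": float(score) if score not in (".", "") else None,
                    "attributes": extra,
                }
                gene_of[tid] = attrs.get("Parent", "")
            elif ftype in ("exon", "CDS"):
                for parent in attrs.get("Parent", "").split(","):
                    if not parent:
                        raise ParseError(
                            f"{path}:{lineno}: {ftype} row without Parent"
                        )
                    pending.append((lineno, ftype, parent, s, e, phase))
    for lineno, ftype, parent, s, e, phase in pending:
        if parent not in tx_meta:
            raise ParseError(
                f"{path}:{lineno}: dangling Parent {parent!r} for {ftype} feature"
            )
        if ftype == "exon":
            exons.setdefault(parent, []).append((s, e))
        else:
            cds.setdefault(parent, []).append((s, e))
            if phase not in (".", ""):
                tx_meta[parent]["attributes"].setdefault("cds_phases", "")
                tx_meta[parent]["attributes"]["cds_phases"] += f"{s}:{phase};"
    out = AnnotationSet()
    for tid in sorted(
        exons, key=lambda i: (tx_meta[i]["chrom"], min(s for s, _ in exons[i]), i)
    ):
        m = tx_meta[tid]
        out.add(
            TranscriptModel(
                id=tid,
                chrom=m["chrom"],
                strand=m["strand"],
                exons=exons[tid],
                cds_segments=_merge_adjacent(cds.get(tid, [])),
                gene_id=gene_of.get(tid, ""),
                source_label=m["source"],
                input_score=m["score"],
                attributes=m["attributes"],
            )
        )
    return out


# ---------------------------------------------------------------------------
# BED12


def _parse_bed12_line(path, lineno: int, line: str):
    fields = line.split("\t")
    if len(fields) < 12:
        raise ParseError(f"{path}:{lineno}: expected 12 BED columns")
    chrom = fields[0]
    start, end = int(fields[1]), int(fields[2])
    name = fields[3]
    score = fields[4]
    strand = fields[5] if fields[5] in "+-" else "."
    thick_start, thick_end = int(fields[6]), int(fields[7])
    n_blocks = int(fields[9])
    sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
    starts = [int(x) for x in fields[11].rstrip(",").split(",")]
    if len(sizes) != n_blocks or len(starts) != n_blocks:
        raise ParseError(f"{path}:{lineno}: blockCount mismatch")
    blocks = [(start + bs, start + bs + sz) for bs, sz in zip(starts, sizes)]
    if blocks[0][0] != start or blocks[-1][1] != end:
        raise ParseError(
            f"{path}:{lineno}: block arithmetic inconsistent with chromStart/chromEnd"
        )
    return chrom, start, end, name, score, strand, thick_start, thick_end, blocks


def _orf_type_flags(name: str) -> tuple[bool, bool]:
    """Completeness from an ORF-caller name tag; False/False when untagged.

    Understands the common ``type:complete`` / ``type:5prime_partial`` /
    ``type:3prime_partial`` / ``type:internal`` annotations.  Untagged ORFs
    are refined against the cDNA sequence by the evidence loader.
    """
    if "complete" in name:
        return True, True
    if "5prime_partial" in name:
        return False, True
    if "3prime_partial" in name:
        return True, False
    return False, False


def read_bed12(path, transcript_space: bool = False):
    """Read BED12: genomic transcript models, or transcript-space ORFs.

    In genomic mode each row becomes a :class:`TranscriptModel` whose thick
    range is intersected with the blocks to form CDS segments.  In
    transcript-space mode each row is an :class:`OrfRecord` on cDNA
    coordinates; ``has_start``/``has_stop`` are taken from the name field
    when it carries TransDecoder-style tags, otherwise left False and
    refined by the evidence loader.
    """
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            (chrom, start, end, name, score, strand,
             ts, te, blocks) = _parse_bed12_line(path, lineno, line)
            if transcript_space:
                if te <= ts:
                    continue  # no ORF on this transcript
                has_start, has_stop = _orf_type_flags(name)
                records.append(
                    OrfRecord(
                        transcript_id=chrom,
                        cdna_start=ts,
                        cdna_end=te,
                        strand=strand if strand in "+-" else "+",
                        has_start=has_start,
                        has_stop=has_stop,
                    )
                )
            else:
                cds_segments = []
                if te > ts:
                    for bs, be in blocks:
                        lo, hi = max(bs, ts), min(be, te)
                        if lo < hi:
                            cds_segments.append((lo, hi))
                records.append(
                    TranscriptModel(
                        id=name,
                        chrom=chrom,
                        strand=strand,
                        exons=blocks,
                        cds_segments=cds_segments,
                        input_score=float(score) if score not in (".", "") else None,
                    )
                )
    if transcript_space:
        return records
    out = AnnotationSet()
    for t in sorted(records, key=TranscriptModel.sort_key):
        out.add(t)
    return out


# ---------------------------------------------------------------------------
# Writers


def _cds_phases(t: TranscriptModel) -> dict[tuple[int, int], int]:
    """GFF3 phase per CDS segment, consistent with 5'→3' reading."""
    segs = t.cds_segments if t.strand != "-" else list(reversed(t.cds_segments))
    phases = {}
    cum = 0
    for seg in segs:
        phases[seg] = (3 - cum % 3) % 3
        cum += seg[1] - seg[0]
    return phases


def write_gff3(annset: AnnotationSet, path, source: str = "txweave") -> None:
    """Write a gene/mRNA/exon/CDS GFF3 hierarchy, 1-based inclusive.

    Round-trip guarantee: ``read_gff3(write_gff3(x))`` is structurally
    equal to ``x``.
    """
    genes: dict[str, list[TranscriptModel]] = {}
    for t in annset:
        genes.setdefault(t.gene_id, []).append(t)

    def gene_key(item):
        gid, txs = item
        return (txs[0].chrom, min(t.start for t in txs),
                max(t.end for t in txs), gid)

    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gid, txs in sorted(genes.items(), key=gene_key):
            chrom = txs[0].chrom
            gstart = min(t.start for t in txs)
            gend = max(t.end for t in txs)
            strands = {t.strand for t in txs}
            gstrand = strands.pop() if len(strands) == 1 else "."
            fh.write(
                f"{chrom}\t{source}\tgene\t{gstart + 1}\t{gend}\t.\t{gstrand}\t.\t"
                f"ID={gid}\n"
            )
            for t in sorted(txs, key=TranscriptModel.sort_key):
                score = "." if t.input_score is None else f"{t.input_score:g}"
                extra = "".join(
                    f";{k}={v}" for k, v in sorted(t.attributes.items())
                    if k != "cds_phases"
                )
                fh.write(
                    f"{chrom}\t{source}\tmRNA\t{t.start + 1}\t{t.end}\t{score}\t"
                    f"{t.strand}\t.\tID={t.id};Parent={gid}{extra}\n"
                )
                for i, (s, e) in enumerate(t.exons, 1):
                    fh.write(
                        f"{chrom}\t{source}\texon\t{s + 1}\t{e}\t.\t{t.strand}\t.\t"
                        f"ID={t.id}.exon{i};Parent={t.id}\n"
                    )
                phases = _cds_phases(t)
                for s, e in t.cds_segments:
                    fh.write(
                        f"{chrom}\t{source}\tCDS\t{s + 1}\t{e}\t.\t{t.strand}\t"
                        f"{phases[(s, e)]}\tID={t.id}.cds;Parent={t.id}\n"
                    )


def write_gtf(annset: AnnotationSet, path, source: str = "txweave") -> None:
    """Write transcripts as GTF (transcript + exon + CDS rows), sorted."""
    with open(path, "w") as fh:
        for t in annset:
            score = "." if t.input_score is None else f"{t.input_score:g}"
            base = f'gene_id "{t.gene_id}"; transcript_id "{t.id}";'
            extra = "".join(
                f' {k} "{v}";' for k, v in sorted(t.attributes.items())
            )
            fh.write(
                f"{t.chrom}\t{source}\ttranscript\t{t.start + 1}\t{t.end}\t"
                f"{score}\t{t.strand}\t.\t{base}{extra}\n"
            )
            for s, e in t.exons:
                fh.write(
                    f"{t.chrom}\t{source}\texon\t{s + 1}\t{e}\t.\t{t.strand}\t.\t"
                    f"{base}\n"
                )
            for s, e in t.cds_segments:
                fh.write(
                    f"{t.chrom}\t{source}\tCDS\t{s + 1}\t{e}\t.\t{t.strand}\t.\t"
                    f"{base}\n"
                )


def write_fasta(records: dict[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fasta(path) -> dict[str, str]:
    """Plain in-memory FASTA reader for small files; use pyfaidx for genomes."""
    out: dict[str, str] = {}
    name = None
    parts: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    out[name] = "".join(parts)
                name = line[1:].split()[0]
                parts = []
            elif name is not None:
                parts.append(line)
    if name is not None:
        out[name] = "".join(parts)
    return out
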