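"""Stage 1: validate, strand-correct, deduplicate and sort input transcripts.

Consolidates transcript models from many assemblies into one
coordinate-ordered GTF plus a matching cDNA FASTA.  Multiexonic models have
their introns checked for canonical splice dinucleotides; models whose
canonical introns sit on the wrong strand are flipped, models with canonical
introns on both strands are discarded (by default), and monoexonic models
from non-strand-specific assemblies lose their strand label.
"""

from __future__ import annotations

import heapq
import json
import logging
import os
import tempfile
from dataclasses import dataclass, field

from . import io as tio
from .models import AnnotationSet, TranscriptModel, extract_cdna, reverse_complement

logger = logging.getLogger(__name__)

#: U2/U12 canonical splice-site dinucleotide pairs (donor, acceptor),
#: given for the plus strand; the minus-strand test uses their reverse
#: complements read in transcript orientation.
CANONICAL_PAIRS = frozenset({("GT", "AG"), ("GC", "AG"), ("AT", "AC")})

DEFAULT_MIN_LENGTH = 200


@dataclass(frozen=True)
class IntronVerdict:
    """Canonicity of one intron's splice dinucleotides."""

    chrom: str
    start: int
    end: int
    donor2: str
    acceptor2: str
    canonical_on: str  # "+", "-", or "none"


@dataclass
class PrepareDecision:
    transcript_id: str
    action: str  # keep | flip_strand | strip_strand | discard
    reason: str


def classify_introns(
    t: TranscriptModel, genome, canonical_pairs=CANONICAL_PAIRS
) -> list[IntronVerdict]:
    """One verdict per intron of a multiexonic transcript.

    The donor/acceptor dinucleotides are read from the plus strand of the
    genome; an intron is canonical on "+" when (donor, acceptor) is in the
    canonical set and canonical on "-" when the pair read in minus-strand
    orientation (reverse complements, swapped) is.
    """
    chrom = genome[t.chrom]
    verdicts = []
    for s, e in t.introns:
        if e - s < 4:
            logger.warning("%s: intron %d-%d shorter than 4 nt", t.id, s, e)
            verdicts.append(IntronVerdict(t.chrom, s, e, "", "", "none"))
            continue
        donor2 = str(chrom[s:s + 2]).upper()
        acceptor2 = str(chrom[e - 2:e]).upper()
        plus = (donor2, acceptor2) in canonical_pairs
        minus = (
            reverse_complement(acceptor2),
            reverse_complement(donor2),
        ) in canonical_pairs
        if plus:
            canonical_on = "+"
        elif minus:
            canonical_on = "-"
        else:
            canonical_on = "none"
        verdicts.append(
            IntronVerdict(t.chrom, s, e, donor2, acceptor2, canonical_on)
        )
    return verdicts


def resolve_strand(
    t: TranscriptModel,
    verdicts: list[IntronVerdict],
    strand_specific_source: bool = False,
    keep_mixed: bool = False,
) -> PrepareDecision:
    """Decide keep / flip_strand / strip_strand / discard for one model.

    A multiexonic model is flipped only when at least one intron is
    canonical on the opposite strand and none is canonical on the annotated
    strand; canonical introns on both strands mean the model mixes genes
    from the two strands and it is discarded unless ``keep_mixed``.
    Monoexonic models from non-strand-specific sources are stripped of
    their strand label.
    """
    if t.is_monoexonic:
        if not strand_specific_source and t.strand != ".":
            return PrepareDecision(t.id, "strip_strand", "monoexonic_unstranded_source")
        return PrepareDecision(t.id, "keep", "ok")
    n_plus = sum(1 for v in verdicts if v.canonical_on == "+")
    n_minus = sum(1 for v in verdicts if v.canonical_on == "-")
    if n_plus and n_minus:
        if keep_mixed:
            return PrepareDecision(t.id, "keep", "mixed_strand_kept")
        return PrepareDecision(t.id, "discard", "mixed_strand_introns")
    if t.strand == ".":
        if n_plus or n_minus:
            return PrepareDecision(t.id, "flip_strand", "strand_assigned")
        return PrepareDecision(t.id, "keep", "ok")
    opposite = "-" if t.strand == "+" else "+"
    n_same = n_plus if t.strand == "+" else n_minus
    n_opp = n_minus if t.strand == "+" else n_plus
    del opposite
    if n_opp >= 1 and n_same == 0:
        return PrepareDecision(t.id, "flip_strand", "introns_canonical_on_opposite")
    return PrepareDecision(t.id, "keep", "ok")


def deduplicate(
    annset: AnnotationSet, source_order: list[str] | None = None
) -> tuple[AnnotationSet, list[PrepareDecision]]:
    """Collapse transcripts identical in (chrom, strand, exon chain).

    The survivor is the model from the earliest source in ``source_order``
    (input-file order), ties broken lexicographically by id.
    """
    rank = {label: i for i, label in enumerate(source_order or [])}

    def precedence(t: TranscriptModel):
        return (rank.get(t.source_label, len(rank)), t.id)

    groups: dict[tuple, list[TranscriptModel]] = {}
    for t in annset:
        groups.setdefault((t.chrom, t.strand, tuple(t.exons)), []).append(t)
    out = AnnotationSet()
    removals: list[PrepareDecision] = []
    for members in groups.values():
        members.sort(key=precedence)
        out.add(members[0].copy())
        for dup in members[1:]:
            removals.append(
                PrepareDecision(dup.id, "discard", f"duplicate_of:{members[0].id}")
            )
    return out, removals


# ---------------------------------------------------------------------------
# External-merge sort: memory bounded by a record cap.


_SORT_KEY = ("chrom", "start", "end", "id")


def _t_to_json(t: TranscriptModel) -> str:
    return json.dumps(
        {
            "id": t.id,
            "chrom": t.chrom,
            "strand": t.strand,
            "exons": t.exons,
            "cds": t.cds_segments,
            "gene_id": t.gene_id,
            "source": t.source_label,
            "score": t.input_score,
            "attrs": t.attributes,
        }
    )


def _t_from_json(line: str) -> TranscriptModel:
    d = json.loads(line)
    return TranscriptModel(
        id=d["id"],
        chrom=d["chrom"],
        strand=d["strand"],
        exons=[tuple(e) for e in d["exons"]],
        cds_segments=[tuple(c) for c in d["cds"]],
        gene_id=d["gene_id"],
        source_label=d["source"],
        input_score=d["score"],
        attributes=d["attrs"],
    )


def external_sorted(transcripts, record_cap: int = 50000):
    """Yield transcripts in (chrom, start, end, id) order.

    Holds at most ``record_cap`` records in memory: larger inputs are
    spilled to sorted temporary runs and merged back with a k-way heap.
    """
    chunk: list[TranscriptModel] = []
    run_paths: list[str] = []
    tmpdir = tempfile.mkdtemp(prefix="txweave_sort_")

    def spill():
        chunk.sort(key=TranscriptModel.sort_key)
        path = os.path.join(tmpdir, f"run{len(run_paths)}.jsonl")
        with open(path, "w") as fh:
            for t in chunk:
                fh.write(_t_to_json(t) + "\n")
        run_paths.append(path)
        chunk.clear()

    for t in transcripts:
        chunk.append(t)
        if len(chunk) >= record_cap:
            spill()
    try:
        if not run_paths:
            chunk.sort(key=TranscriptModel.sort_key)
            yield from chunk
            return
        if chunk:
            spill()

        def reader(path):
            with open(path) as fh:
                for line in fh:
                    yield _t_from_json(line)

        streams = [reader(p) for p in run_paths]
        yield from heapq.merge(*streams, key=TranscriptModel.sort_key)
    finally:
        for p in run_paths:
            try:
                os.unlink(p)
            except OSError:
                pass
        try:
            os.rmdir(tmpdir)
        except OSError:
            pass


# ---------------------------------------------------------------------------
# Driver


@dataclass
class PrepareResult:
    kept: int
    decisions: list[PrepareDecision] = field(default_factory=list)


def _read_any(path: str) -> AnnotationSet:
    lower = str(path).lower()
    if lower.endswith((".gff3", ".gff")):
        return tio.read_gff3(path)
    if lower.endswith(".bed12") or lower.endswith(".bed"):
        return tio.read_bed12(path)
    return tio.read_gtf(path)


def prepare_run(
    inputs: list[tuple[str, str, bool]],
    genome,
    out_gtf: str,
    out_fasta: str,
    min_length: int = DEFAULT_MIN_LENGTH,
    keep_mixed: bool = False,
    record_cap: int = 50000,
    canonical_pairs=CANONICAL_PAIRS,
) -> PrepareResult:
    """Run the full preparation stage.

    ``inputs`` is a list of (path, source_label, strand_specific) triples.
    Emits a coordinate-sorted GTF and the matching cDNA FASTA (ids equal),
    and returns one decision per input transcript.  Ids colliding across
    input files are disambiguated with a source-label suffix.
    """
    decisions: list[PrepareDecision] = []
    staged = AnnotationSet()
    source_order: list[str] = []
    seen_ids: set[str] = set()
    for path, label, strand_specific in inputs:
        source_order.append(label)
        for t in _read_any(path):
            t = t.copy()
            t.source_label = label
            if t.id in seen_ids:
                t.attributes["original_id"] = t.id
                t.id = f"{label}.{t.id}"
            seen_ids.add(t.id)
            if t.cdna_length < min_length:
                decisions.append(PrepareDecision(t.id, "discard", "below_min_length"))
                continue
            if t.is_monoexonic:
                d = resolve_strand(t, [], strand_specific, keep_mixed)
            else:
                verdicts = classify_introns(t, genome, canonical_pairs)
                d = resolve_strand(t, verdicts, strand_specific, keep_mixed)
                if d.action == "discard" and not keep_mixed:
                    decisions.append(d)
                    continue
            decisions.append(d)
            if d.action == "flip_strand":
                t = t.copy()
                if t.strand == "+":
                    t.strand = "-"
                elif t.strand == "-":
                    t.strand = "+"
                else:
                    verdicts = classify_introns(t, genome, canonical_pairs)
                    on = {v.canonical_on for v in verdicts} - {"none"}
                    t.strand = on.pop()
                t.cds_segments = []  # CDS orientation no longer trustworthy
            elif d.action == "strip_strand":
                t = t.copy()
                t.strand = "."
            if not t.is_monoexonic:
                verdicts = classify_introns(t, genome, canonical_pairs)
                n_can = sum(
                    1 for v in verdicts
                    if v.canonical_on == (t.strand if t.strand in "+-" else "+")
                )
                t.attributes["canonical_proportion"] = (
                    f"{n_can / len(verdicts):.4f}"
                )
            staged.add(t)

    deduped, removals = deduplicate(staged, source_order)
    decisions.extend(removals)

    kept = 0
    fasta_records: dict[str, str] = {}
    sink = AnnotationSet()
    for t in external_sorted(iter(deduped), record_cap):
        sink.add(t)
        fasta_records[t.id] = extract_cdna(t, genome)
        kept += 1
    tio.write_gtf(sink, out_gtf)
    tio.write_fasta(fasta_records, out_fasta)
    if kept == 0:
        logger.warning("no transcripts survived preparation; outputs are empty")
    return PrepareResult(kept=kept, decisions=decisions)


def write_decision_log(decisions: list[PrepareDecision], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("transcript_id\taction\treason\n")
        for d in decisions:
            fh.write(f"{d.transcript_id}\t{d.action}\t{d.reason}\n")
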