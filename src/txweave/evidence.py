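"""Stage 2: collect external evidence into a unified store.

Three kinds of evidence inform transcript selection: trusted splice
junctions (genomic BED), open reading frames called on the prepared cDNAs
(transcript-space BED12 or GFF3), and protein-homology hits (a tabular
digest of BLASTX/DIAMOND output).  The store persists to a single-file
SQLite database; lookups for unknown transcript ids return empty results.
"""

from __future__ import annotations

import logging
import sqlite3
from dataclasses import dataclass, field

from .io import OrfRecord, ParseError, _parse_bed12_line, _parse_gff3_attributes
from .models import TranscriptModel, project_to_genome

logger = logging.getLogger(__name__)

STOP_CODONS = {"TAA", "TAG", "TGA"}


class TrustedJunctionSet:
    """A deduplicated set of genomic introns; strandless rows match either strand."""

    def __init__(self, junctions=()):
        self._set: set[tuple[str, int, int, str]] = set()
        for j in junctions:
            self.add(*j)

    def add(self, chrom: str, start: int, end: int, strand: str = ".") -> None:
        if not 0 <= start < end:
            raise ValueError(f"invalid junction {chrom}:{start}-{end}")
        self._set.add((chrom, start, end, strand if strand in "+-" else "."))

    def __len__(self) -> int:
        return len(self._set)

    def __iter__(self):
        return iter(sorted(self._set))

    def __contains__(self, item) -> bool:
        chrom, start, end, strand = item
        if (chrom, start, end, ".") in self._set:
            return True
        if strand == ".":
            return (
                (chrom, start, end, "+") in self._set
                or (chrom, start, end, "-") in self._set
            )
        return (chrom, start, end, strand) in self._set


@dataclass
class HomologyHit:
    """One query-target protein similarity hit with its HSPs.

    HSP query intervals are 0-based half-open on the cDNA; target intervals
    likewise on the protein.
    """

    query_id: str
    target_id: str
    evalue: float
    bitscore: float
    hsps: list[tuple[tuple[int, int], tuple[int, int]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError(f"{self.query_id}: negative e-value")

    def query_coverage_of(self, interval: tuple[int, int]) -> float:
        """Fraction of ``interval`` on the cDNA covered by this hit's HSPs."""
        lo, hi = interval
        covered = _merged_length(
            [(max(qs, lo), min(qe, hi)) for (qs, qe), _ in self.hsps if qs < hi and lo < qe]
        )
        return covered / (hi - lo) if hi > lo else 0.0


def _merged_length(intervals: list[tuple[int, int]]) -> int:
    total = 0
    last_end = None
    for s, e in sorted(intervals):
        if last_end is None or s > last_end:
            total += e - s
            last_end = e
        elif e > last_end:
            total += e - last_end
            last_end = e
    return total


class EvidenceStore:
    """Junctions, per-transcript ORFs, and homology hits in one container."""

    def __init__(self):
        self.junctions = TrustedJunctionSet()
        self.orfs: dict[str, list[OrfRecord]] = {}
        self.hits: dict[str, list[HomologyHit]] = {}

    def orfs_for(self, tid: str) -> list[OrfRecord]:
        return self.orfs.get(tid, [])

    def hits_for(self, tid: str) -> list[HomologyHit]:
        return self.hits.get(tid, [])

    # -- persistence ------------------------------------------------------

    _SCHEMA = """
    CREATE TABLE junction (chrom TEXT, start INT, end INT, strand TEXT);
    CREATE TABLE orf (tid TEXT, cdna_start INT, cdna_end INT, strand TEXT,
                      has_start INT, has_stop INT);
    CREATE TABLE hit (hit_id INTEGER PRIMARY KEY, qid TEXT, tid TEXT,
                      evalue REAL, bitscore REAL);
    CREATE TABLE hsp (hit_id INT, qstart INT, qend INT, tstart INT, tend INT);
    CREATE INDEX idx_orf ON orf(tid);
    CREATE INDEX idx_hit ON hit(qid);
    """

    def save(self, path: str) -> None:
        import os

        if os.path.exists(path):
            os.unlink(path)
        con = sqlite3.connect(path)
        try:
            con.executescript(self._SCHEMA)
            con.executemany(
                "INSERT INTO junction VALUES (?,?,?,?)", list(self.junctions)
            )
            for tid, orfs in sorted(self.orfs.items()):
                con.executemany(
                    "INSERT INTO orf VALUES (?,?,?,?,?,?)",
                    [
                        (tid, o.cdna_start, o.cdna_end, o.strand,
                         int(o.has_start), int(o.has_stop))
                        for o in orfs
                    ],
                )
            hit_id = 0
            for qid, hits in sorted(self.hits.items()):
                for h in hits:
                    con.execute(
                        "INSERT INTO hit VALUES (?,?,?,?,?)",
                        (hit_id, qid, h.target_id, h.evalue, h.bitscore),
                    )
                    con.executemany(
                        "INSERT INTO hsp VALUES (?,?,?,?,?)",
                        [
                            (hit_id, qs, qe, ts, te)
                            for (qs, qe), (ts, te) in h.hsps
                        ],
                    )
                    hit_id += 1
            con.commit()
        finally:
            con.close()

    @classmethod
    def load(cls, path: str) -> "EvidenceStore":
        store = cls()
        con = sqlite3.connect(path)
        try:
            for row in con.execute("SELECT chrom, start, end, strand FROM junction"):
                store.junctions.add(*row)
            for tid, cs, ce, strand, hs, hp in con.execute(
                "SELECT tid, cdna_start, cdna_end, strand, has_start, has_stop "
                "FROM orf ORDER BY tid, cdna_start"
            ):
                store.orfs.setdefault(tid, []).append(
                    OrfRecord(tid, cs, ce, strand, bool(hs), bool(hp))
                )
            hsps: dict[int, list] = {}
            for hid, qs, qe, ts, te in con.execute(
                "SELECT hit_id, qstart, qend, tstart, tend FROM hsp"
            ):
                hsps.setdefault(hid, []).append(((qs, qe), (ts, te)))
            for hid, qid, tid, ev, bs in con.execute(
                "SELECT hit_id, qid, tid, evalue, bitscore FROM hit "
                "ORDER BY qid, evalue ASC, bitscore DESC"
            ):
                store.hits.setdefault(qid, []).append(
                    HomologyHit(qid, tid, ev, bs, hsps.get(hid, []))
                )
        finally:
            con.close()
        return store


# ---------------------------------------------------------------------------
# Loaders


def load_junctions(path: str) -> TrustedJunctionSet:
    """Load trusted introns from a genomic BED6 or BED12 file.

    BED6 rows give the intron interval directly; in BED12 rows each gap
    between consecutive blocks is an intron (the TopHat/Portcullis
    junctions.bed convention).
    """
    out = TrustedJunctionSet()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) >= 12 and fields[9].strip().isdigit() and int(fields[9]) > 1:
                (chrom, _s, _e, _n, _sc, strand,
                 _ts, _te, blocks) = _parse_bed12_line(path, lineno, line)
                for i in range(len(blocks) - 1):
                    out.add(chrom, blocks[i][1], blocks[i + 1][0], strand)
            else:
                chrom = fields[0]
                start, end = int(fields[1]), int(fields[2])
                strand = fields[5] if len(fields) > 5 and fields[5] in "+-" else "."
                out.add(chrom, start, end, strand)
    return out


def _refine_completeness(orf: OrfRecord, cdna: str | None) -> OrfRecord:
    """Fill has_start/has_stop from the cDNA sequence when not tagged."""
    if cdna is None:
        return orf
    seq = cdna.upper()
    if not orf.has_start:
        orf.has_start = seq[orf.cdna_start:orf.cdna_start + 3] == "ATG"
    if not orf.has_stop:
        orf.has_stop = seq[orf.cdna_end - 3:orf.cdna_end] in STOP_CODONS
    return orf


def load_orfs(
    path: str,
    cdnas: dict[str, str] | None = None,
    drop_reverse: bool = True,
) -> dict[str, list[OrfRecord]]:
    """Load transcript-space ORFs from BED12 or GFF3.

    All ORFs per transcript are kept, sorted by cDNA start.  ORFs on the
    reverse strand of the cDNA are dropped (preparation has already
    oriented the transcripts) unless ``drop_reverse`` is False, in which
    case they are kept as-is for the caller to handle.  ORFs extending
    beyond the cDNA length are rejected and logged.
    """
    lower = str(path).lower()
    records: list[OrfRecord] = []
    if lower.endswith((".gff3", ".gff")):
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) != 9:
                    raise ParseError(f"{path}:{lineno}: expected 9 fields")
                chrom, _src, ftype, start, end, _sc, strand, _ph, attr = fields
                if ftype != "CDS":
                    continue
                attrs = _parse_gff3_attributes(attr)
                records.append(
                    OrfRecord(
                        transcript_id=chrom,
                        cdna_start=int(start) - 1,
                        cdna_end=int(end),
                        strand=strand if strand in "+-" else "+",
                        has_start="complete" in attrs.get("ID", ""),
                        has_stop="complete" in attrs.get("ID", ""),
                    )
                )
    else:
        from .io import read_bed12

        records = read_bed12(path, transcript_space=True)
    out: dict[str, list[OrfRecord]] = {}
    for orf in records:
        tid = orf.transcript_id
        cdna = cdnas.get(tid) if cdnas else None
        if cdna is not None and orf.cdna_end > len(cdna):
            logger.warning(
                "%s: ORF (%d,%d) exceeds cDNA length %d; rejected",
                tid, orf.cdna_start, orf.cdna_end, len(cdna),
            )
            continue
        if orf.strand == "-" and drop_reverse:
            logger.info("%s: reverse-strand ORF dropped", tid)
            continue
        out.setdefault(tid, []).append(_refine_completeness(orf, cdna))
    for tid in out:
        out[tid].sort(key=lambda o: (o.cdna_start, o.cdna_end))
    return out


def load_homology(path: str) -> dict[str, list[HomologyHit]]:
    """Load a tabular homology digest.

    Expected columns (tab-separated, 1-based inclusive coordinates as in
    BLAST tabular output): qid, tid, evalue, bitscore, qstart, qend,
    tstart, tend.  Rows sharing (qid, tid) are aggregated into one hit
    whose e-value/bitscore are the best over its HSPs; hits are sorted by
    ascending e-value then descending bit score.
    """
    grouped: dict[tuple[str, str], HomologyHit] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 8:
                raise ParseError(f"{path}:{lineno}: expected 8 columns")
            qid, tid = fields[0], fields[1]
            try:
                evalue = float(fields[2])
                bitscore = float(fields[3])
            except ValueError:
                raise ParseError(
                    f"{path}:{lineno}: non-numeric e-value or bit score"
                ) from None
            qs, qe = int(fields[4]) - 1, int(fields[5])
            ts, te = int(fields[6]) - 1, int(fields[7])
            key = (qid, tid)
            if key not in grouped:
                grouped[key] = HomologyHit(qid, tid, evalue, bitscore, [])
            hit = grouped[key]
            hit.evalue = min(hit.evalue, evalue)
            hit.bitscore = max(hit.bitscore, bitscore)
            hit.hsps.append(((qs, qe), (ts, te)))
    out: dict[str, list[HomologyHit]] = {}
    for (qid, _tid), hit in grouped.items():
        out.setdefault(qid, []).append(hit)
    for qid in out:
        out[qid].sort(key=lambda h: (h.evalue, -h.bitscore, h.target_id))
    return out


def build_store(
    junctions_path: str | None = None,
    orfs_path: str | None = None,
    homology_path: str | None = None,
    cdnas: dict[str, str] | None = None,
) -> EvidenceStore:
    store = EvidenceStore()
    if junctions_path:
        store.junctions = load_junctions(junctions_path)
    if orfs_path:
        store.orfs = load_orfs(orfs_path, cdnas)
    if homology_path:
        store.hits = load_homology(homology_path)
    return store


# ---------------------------------------------------------------------------
# Attachment to transcripts


def verify_introns(
    t: TranscriptModel, junctions: TrustedJunctionSet
) -> tuple[int, int]:
    """(verified, total) introns of ``t`` found in the trusted set."""
    introns = t.introns
    verified = sum(
        1 for s, e in introns if (t.chrom, s, e, t.strand) in junctions
    )
    return verified, len(introns)


def assign_orfs(
    t: TranscriptModel, orfs: list[OrfRecord]
) -> tuple[TranscriptModel, int]:
    """Attach the primary ORF to a transcript as its CDS.

    The primary ORF is the longest on the cDNA (ties broken 5'-most); its
    genomic projection becomes the CDS segments.  The returned count is the
    number of ORFs that do not overlap the primary on the cDNA, plus the
    primary itself — i.e. the number of independent coding regions, >1 of
    which marks a candidate false fusion.
    """
    t = t.copy()
    if not orfs:
        t.cds_segments = []
        return t, 0
    primary = max(orfs, key=lambda o: (o.length, -o.cdna_start))
    segments = project_to_genome(t, (primary.cdna_start, primary.cdna_end))
    t.cds_segments = [(g.start, g.end) for g in segments]
    disjoint = sum(
        1
        for o in orfs
        if o is not primary
        and (o.cdna_end <= primary.cdna_start or o.cdna_start >= primary.cdna_end)
    )
    n_internal = disjoint + 1
    t.attributes["has_start_codon"] = str(primary.has_start)
    t.attributes["has_stop_codon"] = str(primary.has_stop)
    t.attributes["number_internal_orfs"] = str(n_internal)
    return t, n_internal
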