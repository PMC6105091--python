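"""Reference-vs-prediction comparison.

Each prediction transcript is matched against the reference transcripts in
its genomic vicinity (found through an interval tree), scored for
nucleotide, junction and exon recall/precision, and labelled with a
one-symbol class code describing the structural relation; predictions that
bridge two or more reference genes get an ``f,`` prefix.  Run-level
statistics report recall, precision and F1 at six feature levels: base,
exon, intron, intron chain, transcript and gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from intervaltree import IntervalTree

from .models import AnnotationSet, TranscriptModel

MONO_RECIPROCAL_OVERLAP = 0.8  # mono-vs-mono full-match threshold
FUSION_MIN_OVERLAP = 0.1       # of the shorter transcript's cDNA
NEIGHBOUR_FLANK = 1000         # bp for the p/P codes

LEVELS = ("base", "exon", "intron", "intron_chain", "transcript", "gene")


# ---------------------------------------------------------------------------
# Pairwise feature statistics


def _exonic_overlap(a: TranscriptModel, b: TranscriptModel) -> int:
    total = 0
    for s1, e1 in a.exons:
        for s2, e2 in b.exons:
            total += max(0, min(e1, e2) - max(s1, s2))
    return total


@dataclass
class PairStats:
    n_recall: float
    n_precision: float
    j_recall: float
    j_precision: float
    e_recall: float
    e_precision: float

    @staticmethod
    def _f1(r: float, p: float) -> float:
        return 2 * r * p / (r + p) if (r + p) else 0.0

    @property
    def n_f1(self) -> float:
        return self._f1(self.n_recall, self.n_precision)

    @property
    def j_f1(self) -> float:
        return self._f1(self.j_recall, self.j_precision)

    @property
    def e_f1(self) -> float:
        return self._f1(self.e_recall, self.e_precision)


def pair_stats(p: TranscriptModel, r: TranscriptModel) -> PairStats:
    """Nucleotide/junction/exon recall & precision of prediction ``p`` vs ``r``.

    Junctions are the introns of the two models; exons match on exact
    coordinates.
    """
    nt = _exonic_overlap(p, r)
    p_introns, r_introns = set(p.introns), set(r.introns)
    shared_j = len(p_introns & r_introns)
    p_exons, r_exons = set(p.exons), set(r.exons)
    shared_e = len(p_exons & r_exons)
    return PairStats(
        n_recall=nt / r.cdna_length if r.cdna_length else 0.0,
        n_precision=nt / p.cdna_length if p.cdna_length else 0.0,
        j_recall=shared_j / len(r_introns) if r_introns else 0.0,
        j_precision=shared_j / len(p_introns) if p_introns else 0.0,
        e_recall=shared_e / len(r_exons) if r_exons else 0.0,
        e_precision=shared_e / len(p_exons) if p_exons else 0.0,
    )


# ---------------------------------------------------------------------------
# Class codes


def _strands_opposite(a: str, b: str) -> bool:
    return a in "+-" and b in "+-" and a != b


def _is_contiguous_subchain(sub, chain) -> bool:
    if not sub:
        return False
    n, m = len(sub), len(chain)
    return any(tuple(chain[i:i + n]) == tuple(sub) for i in range(m - n + 1))


def _cds_introns(t: TranscriptModel) -> set[tuple[int, int]]:
    if not t.cds_segments:
        return set()
    lo = t.cds_segments[0][0]
    hi = t.cds_segments[-1][1]
    return {(s, e) for s, e in t.introns if lo <= s and e <= hi}


def _reciprocal_overlap(p: TranscriptModel, r: TranscriptModel) -> float:
    nt = _exonic_overlap(p, r)
    return min(
        nt / p.cdna_length if p.cdna_length else 0.0,
        nt / r.cdna_length if r.cdna_length else 0.0,
    )


def classify_pair(
    p: TranscriptModel, r: TranscriptModel, flank: int = NEIGHBOUR_FLANK
) -> str:
    """The class code of prediction ``p`` against reference ``r``.

    Decision table (a re-derivation of the cuffcompare-family codes, every
    predicate explicit): "=" identical intron chain; "_" mono-vs-mono with
    ≥80% reciprocal overlap; "n"/"J" extension/truncation of the reference
    chain with all shared junctions agreeing; "h" chains differ but all CDS
    junctions shared; "j" ≥1 shared junction otherwise; "c"/"C"
    contained/containing without shared junctions; "e"/"o" other exonic
    overlap (mono-vs-multi / multi-vs-multi); "x"/"X" overlap on the
    opposite strand; "i"/"I" prediction within reference introns; "p"/"P"
    nearby downstream/upstream; "u" unrelated.
    """
    if p.chrom != r.chrom:
        return "u"
    span_overlap = p.start < r.end and r.start < p.end
    exonic = _exonic_overlap(p, r)
    if not span_overlap:
        if r.start - flank < p.end <= r.start or r.end <= p.start < r.end + flank:
            # upstream/downstream relative to reference orientation
            pred_after = p.start >= r.end
            downstream = pred_after if r.strand != "-" else not pred_after
            return "p" if downstream else "P"
        return "u"
    if _strands_opposite(p.strand, r.strand):
        return "x" if p.is_monoexonic else "X"
    p_chain, r_chain = p.intron_chain, r.intron_chain
    if p_chain and r_chain and p_chain == r_chain:
        return "="
    shared = set(p_chain) & set(r_chain)
    if shared:
        extras_outside = all(
            e <= r.start or s >= r.end
            for s, e in set(p_chain) - set(r_chain)
        )
        if len(shared) == len(r_chain) and len(p_chain) > len(r_chain) and \
                _is_contiguous_subchain(r_chain, p_chain) and extras_outside:
            return "n"
        if len(shared) == len(p_chain) and len(p_chain) < len(r_chain) and \
                _is_contiguous_subchain(p_chain, r_chain):
            return "J"
        p_cds_j, r_cds_j = _cds_introns(p), _cds_introns(r)
        if p_cds_j and p_cds_j == r_cds_j:
            return "h"
        return "j"
    if exonic > 0:
        if p.is_monoexonic and r.is_monoexonic:
            if _reciprocal_overlap(p, r) >= MONO_RECIPROCAL_OVERLAP:
                return "_"
        contained = all(
            any(rs <= s and e <= re for rs, re in r.exons) for s, e in p.exons
        )
        containing = all(
            any(ps <= s and e <= pe for ps, pe in p.exons) for s, e in r.exons
        )
        if contained:
            return "c"
        if containing:
            return "C"
        if p.is_monoexonic or r.is_monoexonic:
            return "e"
        return "o"
    # span overlap without exonic overlap: prediction within reference introns
    return "i" if p.is_monoexonic else "I"


# ---------------------------------------------------------------------------
# Reference index


class ReferenceIndex:
    """Interval-tree index of a reference annotation for vicinity queries."""

    def __init__(self, reference: AnnotationSet):
        self.reference = reference
        self._trees: dict[str, IntervalTree] = {}
        for t in reference:
            self._trees.setdefault(t.chrom, IntervalTree()).addi(
                t.start, t.end, t.id
            )

    def query(self, chrom: str, start: int, end: int) -> list[TranscriptModel]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = {iv.data for iv in tree.overlap(start, end)}
        return sorted(
            (self.reference[tid] for tid in hits),
            key=TranscriptModel.sort_key,
        )


def build_reference_index(reference: AnnotationSet) -> ReferenceIndex:
    return ReferenceIndex(reference)


# ---------------------------------------------------------------------------
# TMAP / REFMAP


@dataclass
class TmapRow:
    prediction_id: str
    ref_gene: str
    ref_transcript: str
    class_code: str
    stats: PairStats | None = None


@dataclass
class RefmapRow:
    ref_transcript: str
    ref_gene: str
    best_prediction: str
    class_code: str
    n_f1: float = 0.0
    j_f1: float = 0.0


def classify_prediction(
    p: TranscriptModel,
    reference: AnnotationSet,
    index: ReferenceIndex,
    fusion_min_overlap: float = FUSION_MIN_OVERLAP,
) -> TmapRow:
    """Best reference match, class code and fusion flag for one prediction.

    The best match maximises junction F1, ties broken by nucleotide F1.
    The fusion rule: the prediction intersects at least one transcript per
    gene from two or more genes, each with either a shared junction or an
    exonic overlap above ``fusion_min_overlap`` of the shorter model's
    cDNA; such codes get the ``f,`` prefix.
    """
    candidates = index.query(p.chrom, p.start - NEIGHBOUR_FLANK, p.end + NEIGHBOUR_FLANK)
    if not candidates:
        return TmapRow(p.id, "-", "-", "u")
    best: TranscriptModel | None = None
    best_stats: PairStats | None = None
    fusion_genes: set[str] = set()
    p_introns = set(p.introns)
    for r in candidates:
        st = pair_stats(p, r)
        if best_stats is None or (st.j_f1, st.n_f1) > (best_stats.j_f1, best_stats.n_f1):
            best, best_stats = r, st
        if not _strands_opposite(p.strand, r.strand):
            shared = bool(p_introns & set(r.introns))
            shorter = min(p.cdna_length, r.cdna_length)
            strong_overlap = (
                shorter > 0 and _exonic_overlap(p, r) > fusion_min_overlap * shorter
            )
            if shared or strong_overlap:
                fusion_genes.add(r.gene_id)
    assert best is not None
    code = classify_pair(p, best)
    if len(fusion_genes) >= 2 and code not in ("u",):
        code = "f," + code
    return TmapRow(p.id, best.gene_id, best.id, code, best_stats)


# ---------------------------------------------------------------------------
# Run-level statistics


@dataclass
class CompareStats:
    """Recall/precision/F1 (percent) per feature level."""

    levels: dict[str, tuple[float, float, float]] = field(default_factory=dict)

    def recall(self, level: str) -> float:
        return self.levels[level][0]

    def precision(self, level: str) -> float:
        return self.levels[level][1]

    def f1(self, level: str) -> float:
        return self.levels[level][2]


def _rpf(tp_ref: float, n_ref: float, tp_pred: float, n_pred: float):
    r = 100.0 * tp_ref / n_ref if n_ref else 0.0
    p = 100.0 * tp_pred / n_pred if n_pred else 0.0
    f = 2 * r * p / (r + p) if (r + p) else 0.0
    return (r, p, f)


def _base_sets(annset: AnnotationSet) -> dict[tuple[str, str], set[int]]:
    out: dict[tuple[str, str], set[int]] = {}
    for t in annset:
        bucket = out.setdefault((t.chrom, t.strand), set())
        for s, e in t.exons:
            bucket.update(range(s, e))
    return out


def _transcript_matches(p: TranscriptModel, r: TranscriptModel) -> bool:
    """Full transcript-level match: identical intron chain, or for two
    monoexonic models ≥80% reciprocal overlap."""
    if p.chrom != r.chrom or _strands_opposite(p.strand, r.strand):
        return False
    if p.is_monoexonic != r.is_monoexonic:
        return False
    if p.is_monoexonic:
        return _reciprocal_overlap(p, r) >= MONO_RECIPROCAL_OVERLAP
    return p.intron_chain == r.intron_chain


def compare_run(
    reference: AnnotationSet, prediction: AnnotationSet
) -> tuple[list[TmapRow], list[RefmapRow], CompareStats]:
    """Full comparison: one TMAP row per prediction, one REFMAP row per
    reference transcript, and six-level accuracy statistics."""
    index = build_reference_index(reference)
    tmap = [classify_prediction(p, reference, index) for p in prediction]

    # refmap: best prediction per reference transcript
    pred_index = build_reference_index(prediction)
    refmap = []
    for r in reference:
        cands = pred_index.query(r.chrom, r.start, r.end)
        best_p, best_st = None, None
        for p in cands:
            st = pair_stats(p, r)
            if best_st is None or (st.j_f1, st.n_f1) > (best_st.j_f1, best_st.n_f1):
                best_p, best_st = p, st
        if best_p is None:
            refmap.append(RefmapRow(r.id, r.gene_id, "-", "u"))
        else:
            refmap.append(
                RefmapRow(
                    r.id, r.gene_id, best_p.id,
                    classify_pair(best_p, r), best_st.n_f1, best_st.j_f1,
                )
            )

    stats = CompareStats()
    # base level
    rb, pb = _base_sets(reference), _base_sets(prediction)
    tp = sum(len(rb.get(k, set()) & pb.get(k, set())) for k in set(rb) | set(pb))
    stats.levels["base"] = _rpf(
        tp, sum(len(v) for v in rb.values()), tp, sum(len(v) for v in pb.values())
    )
    # exon / intron levels (exact-coordinate feature sets)
    for level, feats in (
        ("exon", lambda t: [(t.chrom, t.strand, s, e) for s, e in t.exons]),
        ("intron", lambda t: [(t.chrom, t.strand, s, e) for s, e in t.introns]),
    ):
        rset = {f for t in reference for f in feats(t)}
        pset = {f for t in prediction for f in feats(t)}
        shared = len(rset & pset)
        stats.levels[level] = _rpf(shared, len(rset), shared, len(pset))
    # intron chain level (multiexonic only)
    rchains = {
        (t.chrom, t.strand, t.intron_chain) for t in reference if not t.is_monoexonic
    }
    pchains = {
        (t.chrom, t.strand, t.intron_chain) for t in prediction if not t.is_monoexonic
    }
    shared = len(rchains & pchains)
    stats.levels["intron_chain"] = _rpf(shared, len(rchains), shared, len(pchains))
    # transcript level
    ref_list = list(reference)
    pred_list = list(prediction)
    ref_matched = {
        r.id for r in ref_list if any(_transcript_matches(p, r) for p in pred_list)
    }
    pred_matched = {
        p.id for p in pred_list if any(_transcript_matches(p, r) for r in ref_list)
    }
    stats.levels["transcript"] = _rpf(
        len(ref_matched), len(ref_list), len(pred_matched), len(pred_list)
    )
    # gene level
    ref_genes_matched = {
        r.gene_id for r in ref_list if r.id in ref_matched
    }
    pred_genes_matched = {
        p.gene_id for p in pred_list if p.id in pred_matched
    }
    stats.levels["gene"] = _rpf(
        len(ref_genes_matched), len(reference.genes),
        len(pred_genes_matched), len(prediction.genes),
    )
    return tmap, refmap, stats


# ---------------------------------------------------------------------------
# z-score ranking across methods


def zscore_rank(methods: dict[str, dict[str, float]]) -> list[tuple[str, float]]:
    """Cumulative z-score per method over the six level F1s, ranked.

    ``methods`` maps method name to a {level: F1} dict.  Per level the
    z-score uses the population standard deviation over methods (a zero
    deviation yields z = 0); the cumulative score sums the levels.
    Requires at least two methods.
    """
    if len(methods) < 2:
        raise ValueError("z-scores need at least two methods")
    names = sorted(methods)
    levels = sorted({lvl for m in methods.values() for lvl in m})
    total = {name: 0.0 for name in names}
    for lvl in levels:
        vals = np.array([methods[n].get(lvl, 0.0) for n in names], dtype=float)
        sd = vals.std()  # population sd
        if sd > 0:
            z = (vals - vals.mean()) / sd
        else:
            z = np.zeros_like(vals)
        for n, zi in zip(names, z):
            total[n] += float(zi)
    return sorted(total.items(), key=lambda kv: (-kv[1], kv[0]))


# ---------------------------------------------------------------------------
# Methods utilities: UTR trim and the reconstructable filter


def trim_terminal_utr(t: TranscriptModel, max_utr: int = 50) -> TranscriptModel:
    """Shorten terminal UTR exons to at most ``max_utr`` bases.

    Trimming proceeds from the outer end of each terminal exon and never
    crosses the CDS boundary; internal exons are untouched.  Transcripts
    without a CDS are returned unchanged.
    """
    if not t.cds_segments:
        return t.copy()
    t = t.copy()
    cds_lo = t.cds_segments[0][0]
    cds_hi = t.cds_segments[-1][1]
    exons = list(t.exons)
    s, e = exons[0]
    if e <= cds_lo:  # UTR-only leading exon
        if e - s > max_utr:
            exons[0] = (e - max_utr, e)
    elif s < cds_lo:
        if cds_lo - s > max_utr:
            exons[0] = (cds_lo - max_utr, e)
    s, e = exons[-1]
    if s >= cds_hi:  # UTR-only trailing exon
        if e - s > max_utr:
            exons[-1] = (s, s + max_utr)
    elif e > cds_hi:
        if e - cds_hi > max_utr:
            exons[-1] = (s, cds_hi + max_utr)
    t.exons = sorted(exons)
    return t


def reconstructable_filter(
    reference: AnnotationSet,
    coverage: dict[str, np.ndarray],
    detected_junctions: set[tuple[str, int, int]],
    max_utr: int = 50,
) -> AnnotationSet:
    """Keep reference transcripts fully supported by read evidence.

    A transcript is reconstructable when every splice junction (if any) is
    in the detected set and every internal base — every exonic base after
    terminal UTR trimming to ``max_utr`` — has depth ≥ 1.
    """
    out = AnnotationSet()
    for t in reference:
        trimmed = trim_terminal_utr(t, max_utr)
        if any((t.chrom, s, e) not in detected_junctions for s, e in trimmed.introns):
            continue
        depth = coverage.get(t.chrom)
        if depth is None:
            continue
        covered = all(
            bool(np.all(depth[s:e] >= 1)) and e <= len(depth)
            for s, e in trimmed.exons
        )
        if covered:
            out.add(trimmed)
    return out


# ---------------------------------------------------------------------------
# File writers


def write_tmap(rows: list[TmapRow], path: str) -> None:
    with open(path, "w") as fh:
        fh.write(
            "prediction_id\tref_gene\tref_transcript\tclass_code\t"
            "n_recall\tn_precision\tj_recall\tj_precision\te_recall\te_precision\n"
        )
        for row in rows:
            if row.stats is None:
                fh.write(f"{row.prediction_id}\t-\t-\t{row.class_code}\t"
                         "0\t0\t0\t0\t0\t0\n")
            else:
                s = row.stats
                fh.write(
                    f"{row.prediction_id}\t{row.ref_gene}\t{row.ref_transcript}\t"
                    f"{row.class_code}\t{s.n_recall:.4f}\t{s.n_precision:.4f}\t"
                    f"{s.j_recall:.4f}\t{s.j_precision:.4f}\t"
                    f"{s.e_recall:.4f}\t{s.e_precision:.4f}\n"
                )


def write_refmap(rows: list[RefmapRow], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("ref_transcript\tref_gene\tbest_prediction\tclass_code\tn_f1\tj_f1\n")
        for row in rows:
            fh.write(
                f"{row.ref_transcript}\t{row.ref_gene}\t{row.best_prediction}\t"
                f"{row.class_code}\t{row.n_f1:.4f}\t{row.j_f1:.4f}\n"
            )


def write_stats(stats: CompareStats, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("level\trecall\tprecision\tf1\n")
        for level in LEVELS:
            r, p, f = stats.levels[level]
            fh.write(f"{level}\t{r:.2f}\t{p:.2f}\t{f:.2f}\n")
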