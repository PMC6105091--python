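"""Stage 3: cluster transcripts into loci and select the final gene models.

Transcripts are grouped through sequential phases — superloci by flanked
span overlap, subloci by shared introns (multiexonic) or exonic overlap
(monoexonic) — then scored in group context.  Candidate chimeras (models
with several disjoint ORFs whose homology does not tie them to one
protein) are split before grouping.  Locus primaries are chosen by greedy
iterative selection over the conflict graph; valid alternative-splicing
isoforms are added afterwards, and loci that look like fragments of a
higher-scoring neighbour are flagged and purged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .compare import classify_pair
from .evidence import EvidenceStore, assign_orfs
from .io import OrfRecord
from .models import AnnotationSet, TranscriptModel, project_to_genome
from .scoring import ScoringConfig, compute_metrics, score_group

logger = logging.getLogger(__name__)

DEFAULT_FLANK = 200


@dataclass
class LocusGroup:
    """A staged cluster of transcripts; final loci carry a primary."""

    stage: str  # superlocus | sublocus | monosublocus | locus
    chrom: str
    strand: str
    transcript_ids: list[str]
    primary_id: str | None = None
    scores: dict[str, float] = field(default_factory=dict)
    fragment: bool = False


@dataclass
class SplitOutcome:
    original_id: str
    split: bool
    parts: list[TranscriptModel]


def _strands_compatible(a: str, b: str) -> bool:
    return a == "." or b == "." or a == b


def _exonic_overlap_bp(a: TranscriptModel, b: TranscriptModel) -> int:
    if a.chrom != b.chrom:
        return 0
    total = 0
    for s1, e1 in a.exons:
        for s2, e2 in b.exons:
            total += max(0, min(e1, e2) - max(s1, s2))
    return total


def _intersects(a: TranscriptModel, b: TranscriptModel) -> bool:
    """Direct conflict: exonic overlap on a compatible strand."""
    return (
        _strands_compatible(a.strand, b.strand)
        and _exonic_overlap_bp(a, b) > 0
    )


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


# ---------------------------------------------------------------------------
# Clustering phases


def build_superloci(
    models: list[TranscriptModel], flank: int = DEFAULT_FLANK
) -> list[LocusGroup]:
    """Phase-1 clusters: transitive flanked span overlap on compatible strands.

    ``+`` groups with ``+``/``.``, ``-`` with ``-``/``.``; an unknown
    strand joins either side (and can therefore bridge the two).
    """
    models = sorted(models, key=TranscriptModel.sort_key)
    uf = _UnionFind(len(models))
    by_chrom: dict[str, list[int]] = {}
    for i, t in enumerate(models):
        by_chrom.setdefault(t.chrom, []).append(i)
    for idxs in by_chrom.values():
        for a_pos, i in enumerate(idxs):
            ti = models[i]
            for j in idxs[a_pos + 1:]:
                tj = models[j]
                if tj.start - flank >= ti.end + flank:
                    break
                if _strands_compatible(ti.strand, tj.strand):
                    uf.union(i, j)
    groups: dict[int, list[TranscriptModel]] = {}
    for i, t in enumerate(models):
        groups.setdefault(uf.find(i), []).append(t)
    out = []
    for members in groups.values():
        strands = {t.strand for t in members} - {"."}
        out.append(
            LocusGroup(
                stage="superlocus",
                chrom=members[0].chrom,
                strand=strands.pop() if len(strands) == 1 else ".",
                transcript_ids=[t.id for t in members],
            )
        )
    out.sort(key=lambda g: (g.chrom, g.transcript_ids[0]))
    return out


def build_subloci(members: list[TranscriptModel]) -> list[list[TranscriptModel]]:
    """Phase-2 clusters within one superlocus.

    Multiexonic transcripts group transitively when they share at least one
    identical intron; monoexonic transcripts group by exonic overlap.  The
    two kinds never co-group.
    """
    multi = sorted((t for t in members if not t.is_monoexonic), key=TranscriptModel.sort_key)
    mono = sorted((t for t in members if t.is_monoexonic), key=TranscriptModel.sort_key)
    out: list[list[TranscriptModel]] = []
    if multi:
        uf = _UnionFind(len(multi))
        intron_owner: dict[tuple[int, int], int] = {}
        for i, t in enumerate(multi):
            for intron in t.introns:
                if intron in intron_owner:
                    uf.union(intron_owner[intron], i)
                else:
                    intron_owner[intron] = i
        groups: dict[int, list[TranscriptModel]] = {}
        for i, t in enumerate(multi):
            groups.setdefault(uf.find(i), []).append(t)
        out.extend(groups.values())
    if mono:
        uf = _UnionFind(len(mono))
        for i, a in enumerate(mono):
            for j in range(i + 1, len(mono)):
                b = mono[j]
                if b.start >= a.end:
                    break
                if _exonic_overlap_bp(a, b) > 0:
                    uf.union(i, j)
        groups = {}
        for i, t in enumerate(mono):
            groups.setdefault(uf.find(i), []).append(t)
        out.extend(groups.values())
    out.sort(key=lambda g: (g[0].chrom, g[0].start, g[0].id))
    return out


# ---------------------------------------------------------------------------
# Chimera resolution


def _orf_clusters(orfs: list[OrfRecord]) -> list[list[OrfRecord]]:
    """Group ORFs that overlap on the cDNA into clusters, 5'→3'."""
    clusters: list[list[OrfRecord]] = []
    cluster_end = -1
    for orf in sorted(orfs, key=lambda o: (o.cdna_start, o.cdna_end)):
        if clusters and orf.cdna_start < cluster_end:
            clusters[-1].append(orf)
            cluster_end = max(cluster_end, orf.cdna_end)
        else:
            clusters.append([orf])
            cluster_end = orf.cdna_end
    return clusters


def detect_and_split_fusions(
    t: TranscriptModel,
    orfs: list[OrfRecord],
    hits,
    min_overlap: float = 0.2,
) -> SplitOutcome:
    """Split a candidate chimera into one transcript per coding region.

    A transcript with two or more cDNA-disjoint ORF clusters is a fusion
    candidate.  If any single target protein's HSPs cover at least
    ``min_overlap`` of two clusters, those clusters are treated as parts of
    the same gene and merged.  Remaining clusters each yield one part:
    exons are cut at the cDNA midpoint between consecutive clusters and the
    cluster's longest ORF becomes the part's CDS.
    """
    clusters = _orf_clusters(orfs)
    if len(clusters) < 2:
        return SplitOutcome(t.id, False, [t])
    spans = [(c[0].cdna_start, max(o.cdna_end for o in c)) for c in clusters]
    uf = _UnionFind(len(clusters))
    for hit in hits or []:
        covered = [
            i for i, span in enumerate(spans)
            if hit.query_coverage_of(span) >= min_overlap
        ]
        for i in covered[1:]:
            uf.union(covered[0], i)
    merged: dict[int, list[int]] = {}
    for i in range(len(clusters)):
        merged.setdefault(uf.find(i), []).append(i)
    if len(merged) < 2:
        return SplitOutcome(t.id, False, [t])
    # merged groups ordered along the cDNA
    group_list = sorted(merged.values(), key=lambda idxs: spans[idxs[0]][0])
    group_spans = [
        (min(spans[i][0] for i in idxs), max(spans[i][1] for i in idxs))
        for idxs in group_list
    ]
    boundaries = [0]
    for k in range(len(group_spans) - 1):
        boundaries.append((group_spans[k][1] + group_spans[k + 1][0]) // 2)
    boundaries.append(t.cdna_length)
    parts: list[TranscriptModel] = []
    for k, idxs in enumerate(group_list):
        lo, hi = boundaries[k], boundaries[k + 1]
        exon_ivs = project_to_genome(t, (lo, hi))
        rep = max(
            (orf for i in idxs for orf in clusters[i]),
            key=lambda o: (o.length, -o.cdna_start),
        )
        cds_ivs = project_to_genome(t, (rep.cdna_start, rep.cdna_end))
        part = TranscriptModel(
            id=f"{t.id}.split{k + 1}",
            chrom=t.chrom,
            strand=t.strand,
            exons=[(g.start, g.end) for g in exon_ivs],
            cds_segments=[(g.start, g.end) for g in cds_ivs],
            gene_id="",
            source_label=t.source_label,
            input_score=t.input_score,
            attributes=dict(t.attributes),
        )
        part.attributes["split_from"] = t.id
        part.attributes["has_start_codon"] = str(rep.has_start)
        part.attributes["has_stop_codon"] = str(rep.has_stop)
        part.attributes["number_internal_orfs"] = "1"
        parts.append(part)
    return SplitOutcome(t.id, True, parts)


# ---------------------------------------------------------------------------
# Primary selection


def _rank_key(scores: dict[str, float]):
    def key(t: TranscriptModel):
        return (-scores.get(t.id, 0.0), -t.cdna_length, t.id)

    return key


def select_primary(
    group: list[TranscriptModel], scores: dict[str, float]
) -> list[LocusGroup]:
    """Greedy iterative locus definition over the conflict graph.

    Repeatedly pick the highest-scoring remaining transcript (ties: longer
    cDNA, then id), seed a locus with it, and drop every transcript that
    directly intersects it (exonic overlap on a compatible strand).  This
    keeps read-through events from suppressing their neighbour loci.
    """
    remaining = sorted(group, key=_rank_key(scores))
    loci: list[LocusGroup] = []
    while remaining:
        primary = remaining.pop(0)
        loci.append(
            LocusGroup(
                stage="locus",
                chrom=primary.chrom,
                strand=primary.strand,
                transcript_ids=[primary.id],
                primary_id=primary.id,
                scores={primary.id: scores.get(primary.id, 0.0)},
            )
        )
        remaining = [t for t in remaining if not _intersects(t, primary)]
    loci.sort(key=lambda g: (g.chrom, g.transcript_ids[0]))
    return loci


def add_alternative_splicing(
    locus: LocusGroup,
    candidates: list[TranscriptModel],
    scores: dict[str, float],
    transcripts: dict[str, TranscriptModel],
    config: ScoringConfig,
) -> LocusGroup:
    """Admit valid splice variants to a finalized locus.

    Candidates are considered in decreasing score order and accepted only
    when their class code against the primary is a valid alternative
    splicing event, their intron chain differs from every member already in
    the locus, and their score reaches the configured fraction of the
    primary's (default one half), up to the isoform cap.
    """
    primary = transcripts[locus.primary_id]
    primary_score = locus.scores[locus.primary_id]
    accepted_chains = {
        (transcripts[tid].chrom, transcripts[tid].strand,
         transcripts[tid].intron_chain, transcripts[tid].is_monoexonic
         and tuple(transcripts[tid].exons))
        for tid in locus.transcript_ids
    }
    n_added = 0
    for cand in sorted(candidates, key=_rank_key(scores)):
        if n_added >= config.as_rules.max_isoforms:
            break
        if cand.id in locus.transcript_ids:
            continue
        score = scores.get(cand.id, 0.0)
        if score < config.as_rules.min_score_ratio * primary_score:
            continue
        chain_key = (
            cand.chrom, cand.strand, cand.intron_chain,
            cand.is_monoexonic and tuple(cand.exons),
        )
        if chain_key in accepted_chains:
            continue
        code = classify_pair(cand, primary)
        if code not in config.as_rules.valid_class_codes:
            continue
        locus.transcript_ids.append(cand.id)
        locus.scores[cand.id] = score
        accepted_chains.add(chain_key)
        n_added += 1
    locus.transcript_ids.sort(
        key=lambda tid: (tid != locus.primary_id, tid)
    )
    return locus


def flag_fragments(
    loci: list[LocusGroup],
    transcripts: dict[str, TranscriptModel],
    config: ScoringConfig,
    mvs: dict[str, dict] | None = None,
) -> list[LocusGroup]:
    """Flag loci whose primary looks like a fragment of a better neighbour.

    A locus is flagged when its primary's class code against the primary of
    a higher-scoring locus within ``fragment_max_distance`` falls in the
    fragment code set (intronic, proximal, antisense).  Loci whose primary
    passes the configured ``not_fragmentary`` expression are exempt.
    """
    for locus in loci:
        primary = transcripts[locus.primary_id]
        score = locus.scores[locus.primary_id]
        if mvs and config.not_fragmentary.atoms:
            ok, _ = config.not_fragmentary.evaluate(mvs[primary.id])
            if ok:
                continue
        for other in loci:
            if other is locus or other.chrom != locus.chrom:
                continue
            o_primary = transcripts[other.primary_id]
            o_score = other.scores[other.primary_id]
            if (o_score, o_primary.cdna_length, o_primary.id) <= (
                score, primary.cdna_length, primary.id
            ):
                continue
            gap = max(
                o_primary.start - primary.end, primary.start - o_primary.end
            )
            if gap > config.fragment_max_distance:
                continue
            code = classify_pair(
                primary, o_primary, flank=config.fragment_max_distance
            )
            if code.removeprefix("f,") in config.fragment_codes:
                locus.fragment = True
                break
    return loci


# ---------------------------------------------------------------------------
# Driver


@dataclass
class PickResult:
    annotation: AnnotationSet
    loci: list[LocusGroup]
    metrics: dict[str, dict]
    scores: dict[str, float]
    log: list[str] = field(default_factory=list)


def _pick_winner(group: list[TranscriptModel], scores: dict[str, float]) -> TranscriptModel:
    return sorted(group, key=_rank_key(scores))[0]


def pick_run(
    prepared: AnnotationSet,
    store: EvidenceStore,
    config: ScoringConfig | None = None,
) -> PickResult:
    """Run the full selection stage over a prepared annotation set.

    Per superlocus: requirements filter → chimera split → subloci →
    group scoring → monosublocus winners → greedy primary selection →
    alternative-splicing admission; then genome-wide fragment flagging.
    """
    from .scoring import default_config

    config = config or default_config()
    log: list[str] = []
    all_metrics: dict[str, dict] = {}
    all_scores: dict[str, float] = {}

    # attach ORFs, split chimeras
    staged: list[TranscriptModel] = []
    for t in prepared:
        orfs = store.orfs_for(t.id)
        if t.id not in store.orfs and (store.orfs or store.hits):
            logger.warning("%s: no evidence records for this id", t.id)
        t2, n_orfs = assign_orfs(t, orfs)
        outcome = detect_and_split_fusions(
            t2, orfs, store.hits_for(t.id), config.fusion_min_overlap
        )
        if outcome.split:
            log.append(
                f"{t.id}: split into {len(outcome.parts)} parts "
                f"({n_orfs} disjoint ORFs)"
            )
        staged.extend(outcome.parts)

    # requirements filter (intrinsic context)
    surviving: list[TranscriptModel] = []
    for t in staged:
        mv = compute_metrics(t, [t], store)
        ok, failing = config.requirements.evaluate(mv)
        if ok:
            surviving.append(t)
        else:
            log.append(f"{t.id}: failed requirements ({', '.join(failing)})")

    transcripts = {t.id: t for t in surviving}
    final_loci: list[LocusGroup] = []
    for superlocus in build_superloci(surviving, config.flank):
        members = [transcripts[tid] for tid in superlocus.transcript_ids]
        # subloci: score in context, keep each sublocus winner
        winners: list[TranscriptModel] = []
        for sub in build_subloci(members):
            mvs = {t.id: compute_metrics(t, sub, store) for t in sub}
            sub_scores = score_group(sub, mvs, config)
            winners.append(_pick_winner(sub, sub_scores))
        # monosublocus winners compete at the superlocus level
        pool_mvs = {t.id: compute_metrics(t, winners, store) for t in winners}
        pool_scores = score_group(winners, pool_mvs, config)
        loci = select_primary(winners, pool_scores)
        # alternative splicing per locus
        for locus in loci:
            primary = transcripts[locus.primary_id]
            candidates = [
                t for t in members
                if t.id != locus.primary_id and _unambiguous(t, locus, loci, transcripts)
            ]
            group = [primary] + candidates
            mvs = {t.id: compute_metrics(t, group, store) for t in group}
            grp_scores = score_group(group, mvs, config)
            locus.scores[locus.primary_id] = grp_scores[primary.id]
            locus = add_alternative_splicing(
                locus, candidates, grp_scores, transcripts, config
            )
            for tid in locus.transcript_ids:
                all_metrics[tid] = mvs[tid]
                all_scores[tid] = grp_scores[tid]
            final_loci.append(locus)

    final_loci.sort(
        key=lambda g: (g.chrom, transcripts[g.primary_id].start, g.primary_id)
    )
    flag_fragments(final_loci, transcripts, config, all_metrics)

    out = AnnotationSet()
    locus_n = 0
    for locus in final_loci:
        if locus.fragment:
            if config.purge_fragments:
                log.append(f"locus of {locus.primary_id}: purged as fragment")
                continue
        locus_n += 1
        gene_id = f"txw_gene_{locus_n}"
        for tid in locus.transcript_ids:
            t = transcripts[tid].copy()
            t.gene_id = gene_id
            t.attributes["locus_score"] = f"{locus.scores.get(tid, 0.0):.4f}"
            t.attributes["primary"] = str(tid == locus.primary_id)
            if locus.fragment:
                t.attributes["fragment"] = "True"
            out.add(t)
    return PickResult(out, final_loci, all_metrics, all_scores, log)


def _unambiguous(
    t: TranscriptModel,
    locus: LocusGroup,
    loci: list[LocusGroup],
    transcripts: dict[str, TranscriptModel],
) -> bool:
    """True when ``t`` intersects exactly one locus primary: this one."""
    owners = [
        g for g in loci if _intersects(t, transcripts[g.primary_id])
    ]
    return len(owners) == 1 and owners[0] is locus


# ---------------------------------------------------------------------------
# Small utilities exposed on the CLI


def grep(annset: AnnotationSet, ids: set[str]) -> AnnotationSet:
    """Extract the transcripts (or whole genes) named in ``ids``."""
    out = AnnotationSet()
    for t in annset:
        if t.id in ids or t.gene_id in ids:
            out.add(t.copy())
    return out


def write_metrics_tsv(metrics: dict[str, dict], path: str) -> None:
    from .scoring import METRIC_NAMES

    with open(path, "w") as fh:
        fh.write("transcript_id\t" + "\t".join(METRIC_NAMES) + "\n")
        for tid in sorted(metrics):
            mv = metrics[tid]
            fh.write(
                tid + "\t" + "\t".join(
                    f"{float(mv[name]):g}" for name in METRIC_NAMES
                ) + "\n"
            )


def write_scores_tsv(scores: dict[str, float], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("transcript_id\tscore\n")
        for tid in sorted(scores):
            fh.write(f"{tid}\t{scores[tid]:.4f}\n")
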