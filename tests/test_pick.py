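"""Locus clustering, chimera splitting, primary selection, AS, fragments."""

import itertools

from txweave.evidence import EvidenceStore, HomologyHit
from txweave.io import OrfRecord
from txweave.models import AnnotationSet
from txweave.pick import (
    LocusGroup,
    add_alternative_splicing,
    build_subloci,
    build_superloci,
    detect_and_split_fusions,
    flag_fragments,
    grep,
    pick_run,
    select_primary,
)
from txweave.scoring import default_config

from conftest import make_transcript


class TestBuildSuperloci:
    def test_flank_bridges_gap(self):
        a = make_transcript(tid="A", exons=[(0, 300)])
        b = make_transcript(tid="B", exons=[(450, 800)])  # gap 150
        assert len(build_superloci([a, b], flank=200)) == 1
        assert len(build_superloci([a, b], flank=50)) == 2

    def test_opposite_strands_split(self):
        a = make_transcript(tid="A", exons=[(0, 300), (400, 600)], strand="+")
        b = make_transcript(tid="B", exons=[(100, 350), (420, 700)], strand="-")
        assert len(build_superloci([a, b])) == 2

    def test_unknown_strand_joins_either(self):
        a = make_transcript(tid="A", exons=[(0, 300)], strand="+")
        b = make_transcript(tid="B", exons=[(100, 400)], strand=".")
        groups = build_superloci([a, b])
        assert len(groups) == 1

    def test_singleton(self):
        a = make_transcript(tid="A", exons=[(0, 300)])
        [g] = build_superloci([a])
        assert g.transcript_ids == ["A"]

    def test_transitive_chaining(self):
        a = make_transcript(tid="A", exons=[(0, 300)])
        b = make_transcript(tid="B", exons=[(250, 600)])
        c = make_transcript(tid="C", exons=[(550, 900)])
        assert len(build_superloci([a, b, c], flank=0)) == 1


class TestBuildSubloci:
    def test_shared_intron_groups(self):
        a = make_transcript(tid="A", exons=[(0, 200), (300, 500)])
        b = make_transcript(tid="B", exons=[(50, 200), (300, 450)])
        groups = build_subloci([a, b])
        assert len(groups) == 1

    def test_disjoint_intron_sets_split(self):
        a = make_transcript(tid="A", exons=[(0, 200), (300, 500)])
        b = make_transcript(tid="B", exons=[(0, 210), (320, 500)])
        assert len(build_subloci([a, b])) == 2

    def test_mono_inside_intron_not_grouped(self):
        multi = make_transcript(tid="M", exons=[(0, 100), (500, 600)])
        mono = make_transcript(tid="m", exons=[(200, 450)])
        assert len(build_subloci([multi, mono])) == 2

    def test_mono_and_multi_never_cogroup(self):
        multi = make_transcript(tid="M", exons=[(0, 300), (400, 600)])
        mono = make_transcript(tid="m", exons=[(0, 300)])  # overlaps exon
        assert len(build_subloci([multi, mono])) == 2

    def test_overlapping_monos_group(self):
        a = make_transcript(tid="a", exons=[(0, 300)])
        b = make_transcript(tid="b", exons=[(200, 500)])
        assert len(build_subloci([a, b])) == 1


class TestDetectAndSplitFusions:
    def _fused(self):
        # two gene contents on one model: exons (0,600) and (1000,1600)
        return make_transcript(
            tid="F", exons=[(0, 600), (1000, 1600)]
        )  # cDNA 1200: gene1 at 0..600, gene2 at 600..1200

    def _orfs(self):
        return [OrfRecord("F", 50, 500), OrfRecord("F", 700, 1100)]

    def test_distinct_proteins_split(self):
        hits = [
            HomologyHit("F", "P1", 1e-50, 100, [((50, 500), (0, 150))]),
            HomologyHit("F", "P2", 1e-50, 100, [((700, 1100), (0, 133))]),
        ]
        out = detect_and_split_fusions(self._fused(), self._orfs(), hits)
        assert out.split and len(out.parts) == 2
        assert [p.id for p in out.parts] == ["F.split1", "F.split2"]

    def test_single_spanning_hit_prevents_split(self):
        hits = [HomologyHit("F", "P1", 1e-60, 300, [((50, 1100), (0, 350))])]
        out = detect_and_split_fusions(self._fused(), self._orfs(), hits)
        assert not out.split
        assert out.parts == [self._fused()] or out.parts[0].id == "F"

    def test_single_orf_unchanged(self):
        out = detect_and_split_fusions(
            self._fused(), [OrfRecord("F", 50, 500)], []
        )
        assert not out.split and out.parts[0].id == "F"

    def test_no_hits_still_splits_candidates(self):
        out = detect_and_split_fusions(self._fused(), self._orfs(), [])
        assert out.split

    def test_parts_partition_the_cdna(self):
        out = detect_and_split_fusions(self._fused(), self._orfs(), [])
        p1, p2 = out.parts
        # parts' exons are within the original's and pairwise disjoint
        original = self._fused()
        for part in (p1, p2):
            for s, e in part.exons:
                assert any(xs <= s and e <= xe for xs, xe in original.exons)
        assert p1.end <= p2.start or p2.end <= p1.start
        # each part carries its own ORF as CDS
        assert p1.cds_segments and p2.cds_segments
        assert p1.cds_length == 450 and p2.cds_length == 400

    def test_overlapping_orfs_are_one_cluster(self):
        t = make_transcript(tid="F", exons=[(0, 1200)])
        orfs = [OrfRecord("F", 0, 600), OrfRecord("F", 500, 900)]
        assert not detect_and_split_fusions(t, orfs, []).split

    def test_minus_strand_split_parts_cover_both_genes(self):
        t = make_transcript(tid="F", strand="-", exons=[(0, 600), (1000, 1600)])
        # cDNA 0 maps to genomic 1600; ORF1 (cDNA 5') is the right-hand gene
        orfs = [OrfRecord("F", 50, 500), OrfRecord("F", 700, 1100)]
        out = detect_and_split_fusions(t, orfs, [])
        assert out.split
        spans = sorted((p.start, p.end) for p in out.parts)
        assert spans[0][1] <= 600 and spans[1][0] >= 1000


def _overlap_graph_transcripts(n, edges):
    """Transcripts realizing an arbitrary overlap graph via shared exon slots."""
    slot = {}
    pos = 0
    for i, j in itertools.combinations(range(n), 2):
        slot[(i, j)] = pos
        pos += 20
    private = {i: pos + i * 20 for i in range(n)}
    out = []
    for i in range(n):
        exons = [(private[i], private[i] + 10)]
        for (a, b), p in slot.items():
            if (a, b) in edges and i in (a, b):
                exons.append((p, p + 10))
        out.append(make_transcript(tid=f"T{i}", exons=sorted(exons)))
    return out


def _greedy_oracle(n, edges, scores, lengths):
    """Independent greedy max-score selection over an adjacency-set graph."""
    adj = {i: set() for i in range(n)}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    remaining = set(range(n))
    picked = []
    while remaining:
        best = min(remaining, key=lambda i: (-scores[i], -lengths[i], f"T{i}"))
        picked.append(best)
        remaining -= adj[best] | {best}
    return sorted(picked)


class TestSelectPrimary:
    def test_chain_graph_keeps_ends(self):
        ts = _overlap_graph_transcripts(3, {(0, 1), (1, 2)})
        scores = {"T0": 10.0, "T1": 8.0, "T2": 6.0}
        loci = select_primary(ts, scores)
        assert sorted(g.primary_id for g in loci) == ["T0", "T2"]

    def test_clique_keeps_top_scorer(self):
        ts = _overlap_graph_transcripts(3, {(0, 1), (0, 2), (1, 2)})
        loci = select_primary(ts, {"T0": 1.0, "T1": 5.0, "T2": 3.0})
        assert [g.primary_id for g in loci] == ["T1"]

    def test_independent_set_all_kept(self):
        ts = _overlap_graph_transcripts(4, set())
        loci = select_primary(ts, {f"T{i}": float(i) for i in range(4)})
        assert len(loci) == 4

    def test_matches_oracle_on_random_graphs(self, rng):
        for _ in range(150):
            n = int(rng.integers(1, 7))
            pairs = list(itertools.combinations(range(n), 2))
            edges = {p for p in pairs if rng.random() < 0.5}
            ts = _overlap_graph_transcripts(n, edges)
            scores = {f"T{i}": float(rng.integers(0, 5)) for i in range(n)}
            lengths = {i: ts[i].cdna_length for i in range(n)}
            expected = _greedy_oracle(
                n, edges, {i: scores[f"T{i}"] for i in range(n)}, lengths
            )
            got = sorted(int(g.primary_id[1:]) for g in select_primary(ts, scores))
            assert got == expected

    def test_primaries_pairwise_nonintersecting(self, rng):
        from txweave.pick import _intersects

        for _ in range(30):
            n = int(rng.integers(2, 7))
            pairs = list(itertools.combinations(range(n), 2))
            edges = {p for p in pairs if rng.random() < 0.6}
            ts = _overlap_graph_transcripts(n, edges)
            scores = {f"T{i}": float(rng.integers(0, 10)) for i in range(n)}
            loci = select_primary(ts, scores)
            prim = {g.primary_id: t for g in loci for t in ts if t.id == g.primary_id}
            for a, b in itertools.combinations(prim.values(), 2):
                assert not _intersects(a, b)


def _locus(primary, score):
    return LocusGroup(
        stage="locus", chrom=primary.chrom, strand=primary.strand,
        transcript_ids=[primary.id], primary_id=primary.id,
        scores={primary.id: score},
    )


class TestAlternativeSplicing:
    def _primary(self):
        return make_transcript(
            tid="P", exons=[(0, 200), (300, 500), (600, 800)]
        )

    def test_low_score_rejected(self):
        primary = self._primary()
        cand = make_transcript(tid="C", exons=[(0, 200), (300, 500), (610, 800)])
        locus = _locus(primary, 10.0)
        out = add_alternative_splicing(
            locus, [cand], {"C": 4.0}, {"P": primary, "C": cand}, default_config()
        )
        assert out.transcript_ids == ["P"]

    def test_half_score_boundary_accepted(self):
        primary = self._primary()
        cand = make_transcript(tid="C", exons=[(0, 200), (300, 500), (610, 800)])
        locus = _locus(primary, 10.0)
        out = add_alternative_splicing(
            locus, [cand], {"C": 5.0}, {"P": primary, "C": cand}, default_config()
        )
        assert out.transcript_ids == ["P", "C"]

    def test_identical_chain_rejected_as_redundant(self):
        primary = self._primary()
        cand = make_transcript(tid="C", exons=[(10, 200), (300, 500), (600, 790)])
        locus = _locus(primary, 10.0)
        out = add_alternative_splicing(
            locus, [cand], {"C": 9.0}, {"P": primary, "C": cand}, default_config()
        )
        assert out.transcript_ids == ["P"]

    def test_shared_junction_variant_accepted(self):
        primary = self._primary()
        cand = make_transcript(tid="C", exons=[(0, 200), (300, 450), (620, 800)])
        locus = _locus(primary, 10.0)
        out = add_alternative_splicing(
            locus, [cand], {"C": 8.0}, {"P": primary, "C": cand}, default_config()
        )
        assert "C" in out.transcript_ids

    def test_isoform_cap(self):
        primary = self._primary()
        cands, scores, lookup = [], {}, {"P": primary}
        for k in range(8):
            c = make_transcript(
                tid=f"C{k}",
                exons=[(0, 200), (300, 500), (610 + k, 800)],
            )
            cands.append(c)
            scores[c.id] = 9.0 - k * 0.1
            lookup[c.id] = c
        config = default_config()
        config.as_rules.max_isoforms = 2
        out = add_alternative_splicing(_locus(primary, 10.0), cands, scores, lookup, config)
        assert len(out.transcript_ids) == 3

    def test_raising_ratio_never_adds_isoforms(self):
        primary = self._primary()
        cands, scores, lookup = [], {}, {"P": primary}
        for k in range(5):
            c = make_transcript(
                tid=f"C{k}", exons=[(0, 200), (300, 500), (605 + 3 * k, 800)]
            )
            cands.append(c)
            scores[c.id] = 10.0 - k
            lookup[c.id] = c
        counts = []
        for ratio in (0.1, 0.3, 0.5, 0.7, 0.9):
            config = default_config()
            config.as_rules.min_score_ratio = ratio
            out = add_alternative_splicing(
                _locus(primary, 10.0), list(cands), scores, lookup, config
            )
            counts.append(len(out.transcript_ids))
        assert counts == sorted(counts, reverse=True)


class TestFlagFragments:
    def test_intronic_mono_flagged(self):
        coding = make_transcript(
            tid="big", exons=[(0, 200), (1000, 1400)], cds=[(50, 200), (1000, 1200)]
        )
        stray = make_transcript(tid="stray", exons=[(400, 700)])
        loci = [_locus(coding, 20.0), _locus(stray, 2.0)]
        out = flag_fragments(loci, {"big": coding, "stray": stray}, default_config())
        flags = {g.primary_id: g.fragment for g in out}
        assert flags == {"big": False, "stray": True}

    def test_distant_locus_not_flagged(self):
        a = make_transcript(tid="A", exons=[(0, 400)])
        b = make_transcript(tid="b", exons=[(5000, 5300)])
        loci = [_locus(a, 20.0), _locus(b, 2.0)]
        out = flag_fragments(loci, {"A": a, "b": b}, default_config())
        assert not any(g.fragment for g in out)

    def test_antisense_overlap_flagged(self):
        sense = make_transcript(tid="S", exons=[(0, 300), (400, 800)], strand="+")
        anti = make_transcript(tid="a", exons=[(100, 350)], strand="-")
        loci = [_locus(sense, 20.0), _locus(anti, 3.0)]
        out = flag_fragments(loci, {"S": sense, "a": anti}, default_config())
        assert {g.primary_id: g.fragment for g in out} == {"S": False, "a": True}

    def test_not_fragmentary_exemption(self):
        coding = make_transcript(
            tid="big", exons=[(0, 200), (1000, 1400)], cds=[(50, 200), (1000, 1200)]
        )
        near = make_transcript(tid="near", exons=[(1500, 1600), (1700, 1900)])
        loci = [_locus(coding, 20.0), _locus(near, 2.0)]
        mvs = {"big": {"is_monoexonic": False, "is_complete": True},
               "near": {"is_monoexonic": False, "is_complete": False}}
        out = flag_fragments(loci, {"big": coding, "near": near},
                             default_config(), mvs)
        assert not any(g.fragment for g in out)  # multiexonic → exempt


class TestPickRun:
    def test_single_transcript_identity(self):
        t = make_transcript(tid="T1", exons=[(0, 300), (400, 700)])
        result = pick_run(AnnotationSet([t.copy()]), EvidenceStore())
        assert len(result.annotation) == 1
        out = next(iter(result.annotation))
        assert out.exons == t.exons
        assert out.attributes["primary"] == "True"

    def test_every_output_traces_to_an_input(self, rng):
        from conftest import random_transcript

        inputs = AnnotationSet()
        for k in range(30):
            inputs.add(random_transcript(rng, tid=f"T{k}"))
        result = pick_run(inputs, EvidenceStore())
        for t in result.annotation:
            base = t.id.split(".split")[0]
            assert base in inputs

    def test_tandem_duplication_fixture(self):
        """A tandem trio plus a separate monoexonic gene, each correctly
        assembled by a different source: four loci, each matching truth."""
        truth = {
            "g1": [(0, 200), (300, 500)],
            "g2": [(800, 1000), (1100, 1300)],
            "g3": [(1600, 1800), (1900, 2100)],
            "mono": [(2600, 2900)],
        }
        inputs = AnnotationSet()
        # source A: g1/g2/g3 correct, misses mono
        for name in ("g1", "g2", "g3"):
            inputs.add(make_transcript(tid=f"A.{name}", exons=truth[name]))
        # source B: fuses g1-g2, has mono correct
        inputs.add(
            make_transcript(tid="B.fused", exons=truth["g1"] + truth["g2"])
        )
        inputs.add(make_transcript(tid="B.mono", exons=truth["mono"]))
        # source C: fragments of g3
        inputs.add(make_transcript(tid="C.g3frag", exons=[truth["g3"][0]]))
        store = EvidenceStore()
        # each clean model carries one complete ORF at cDNA 50..350
        for tid in ("A.g1", "A.g2", "A.g3"):
            store.orfs[tid] = [OrfRecord(tid, 50, 350, has_start=True, has_stop=True)]
            store.hits[tid] = [
                HomologyHit(tid, f"P_{tid[-2:]}", 1e-50, 100, [((50, 350), (0, 100))])
            ]
        # the fused model shows two disjoint ORFs hitting distinct proteins
        store.orfs["B.fused"] = [
            OrfRecord("B.fused", 50, 350, has_start=True, has_stop=True),
            OrfRecord("B.fused", 450, 750, has_start=True, has_stop=True),
        ]
        store.hits["B.fused"] = [
            HomologyHit("B.fused", "P_g1", 1e-50, 100, [((50, 350), (0, 100))]),
            HomologyHit("B.fused", "P_g2", 1e-50, 100, [((450, 750), (0, 100))]),
        ]
        config = default_config()
        config.fragment_max_distance = 100  # tandem genes are close by design
        result = pick_run(inputs, store, config)
        primaries = {
            t.id for t in result.annotation if t.attributes["primary"] == "True"
        }
        assert primaries == {"A.g1", "A.g2", "A.g3", "B.mono"}
        chains = {tuple(t.exons) for t in result.annotation}
        assert chains == {tuple(v) for v in truth.values()}

    def test_fusion_model_resolved_against_truth(self):
        """A model chaining two genes is split and both loci recovered."""
        g1 = [(0, 300), (400, 700)]
        g2 = [(1200, 1500), (1600, 1900)]
        inputs = AnnotationSet()
        inputs.add(make_transcript(tid="fused", exons=g1 + g2))
        store = EvidenceStore()
        # cDNA: g1 content 0..600, g2 content 600..1200
        store.orfs["fused"] = [
            OrfRecord("fused", 30, 570, has_start=True, has_stop=True),
            OrfRecord("fused", 630, 1170, has_start=True, has_stop=True),
        ]
        store.hits["fused"] = [
            HomologyHit("fused", "P1", 1e-50, 100, [((30, 570), (0, 180))]),
            HomologyHit("fused", "P2", 1e-50, 100, [((630, 1170), (0, 180))]),
        ]
        result = pick_run(inputs, store)
        assert len(result.annotation.genes) == 2
        spans = sorted((t.start, t.end) for t in result.annotation)
        assert spans[0][1] <= 1200 and spans[1][0] >= 700

    def test_determinism(self, rng):
        from conftest import random_transcript

        inputs1 = AnnotationSet()
        inputs2 = AnnotationSet()
        for k in range(20):
            t = random_transcript(rng, tid=f"T{k}")
            inputs1.add(t.copy())
            inputs2.add(t.copy())
        r1 = pick_run(inputs1, EvidenceStore())
        r2 = pick_run(inputs2, EvidenceStore())
        assert [t.id for t in r1.annotation] == [t.id for t in r2.annotation]
        assert r1.scores == r2.scores


class TestGrep:
    def test_extract_by_transcript_and_gene(self):
        a = make_transcript(tid="A", exons=[(0, 300)], gene_id="G1")
        b = make_transcript(tid="B", exons=[(400, 700)], gene_id="G2")
        c = make_transcript(tid="C", exons=[(800, 1000)], gene_id="G2")
        s = AnnotationSet([a, b, c])
        assert {t.id for t in grep(s, {"A"})} == {"A"}
        assert {t.id for t in grep(s, {"G2"})} == {"B", "C"}
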