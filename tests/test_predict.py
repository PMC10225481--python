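import warnings

import numpy as np
import pytest

from oriseek.errors import UnsupportedOperationError
from oriseek.genome_io import GeneFeature, GenomeRecord, IGS, extract_igs
from oriseek.motifs import MotifConfig, MotifPattern
from oriseek.predict import (
    IndicatorHit,
    IndicatorTable,
    find_indicator_genes,
    predict_oric,
    predict_oric_draft,
    predict_terminus,
    rank_candidates,
    score_igs,
)
from oriseek.simulate import SimParams, simulate_genome, split_genome
from oriseek.zcurve import circular_distance

from conftest import random_dna


def gene(start, end, strand="+", name="", product="", tag=None, kind="CDS"):
    return GeneFeature(
        locus_tag=tag or f"g{start}", start=start, end=end, strand=strand,
        kind=kind, gene_name=name, product=product,
    )


def make_igs(seq, start, L, left=None, right=None, rid="r"):
    end = (start + len(seq)) % L if start + len(seq) > L else start + len(seq)
    return IGS(rid, start, end, len(seq), seq, left, right)


class TestIndicatorGenes:
    def test_gene_name_match_is_primary(self):
        rec = GenomeRecord(id="r", sequence="A" * 100,
                           features=[gene(0, 30, name="dnaA")])
        hits = find_indicator_genes(rec)
        assert len(hits) == 1 and hits[0].tier == "primary"

    def test_product_word_fallback(self):
        rec = GenomeRecord(
            id="r", sequence="A" * 100,
            features=[gene(0, 30, product="chromosomal replication initiator protein DnaA")],
        )
        assert len(find_indicator_genes(rec)) == 1

    def test_secondary_chromosome_type(self):
        rec = GenomeRecord(id="r", sequence="A" * 100,
                           features=[gene(0, 30, name="rctB")])
        table = IndicatorTable(chromosome_type="secondary")
        hits = find_indicator_genes(rec, table)
        # on a secondary replicon the rctB/repA tier is principal
        assert len(hits) == 1 and hits[0].tier == "primary"

    def test_fallback_orfs_never_match(self):
        rec = GenomeRecord(id="r", sequence="A" * 100,
                           features=[gene(0, 30, kind="ORF_fallback")])
        assert find_indicator_genes(rec) == []


class TestScoreIgs:
    L = 10_000

    def test_maximal_worked_example(self):
        seq = "CC".join(["TTATCCACA"] * 3)  # 3 exact boxes
        dnaa = gene(0, 300, name="dnaA")
        igs = make_igs(seq, 300, self.L, left=dnaa)
        indicators = [IndicatorHit(dnaa, "primary")]
        c = score_igs(igs, igs.midpoint(self.L), self.L, "circular", indicators)
        assert (c.s_dist, c.s_gene, c.s_box) == (1.0, 1.0, 1.0)
        assert c.total == 3.0

    def test_mid_worked_example(self):
        # d = L/4, no indicator, one box with 1 mismatch, k_max = 1
        seq = "TTATGCACA" + "C" * 20  # 29 bp, midpoint = start + 14
        start = 2500 - 14
        igs = make_igs(seq, start, self.L)
        c = score_igs(igs, 0, self.L, "circular", [])
        assert c.s_dist == pytest.approx(0.5)
        assert c.s_gene == 0.0
        assert c.s_box == pytest.approx(1 / 6)
        assert c.total == pytest.approx(2 / 3)

    def test_zero_worked_example(self):
        igs = make_igs("C" * 30, 5000 - 15, self.L)  # antipode of gc_min = 0
        c = score_igs(igs, 0, self.L, "circular", [])
        assert c.total == 0.0

    def test_secondary_flank_and_proximity_tiers(self):
        seq = "C" * 30
        dnan = gene(100, 300, name="dnaN")
        igs = make_igs(seq, 300, self.L, left=dnan)
        c = score_igs(igs, 315, self.L, "circular", [IndicatorHit(dnan, "secondary")])
        assert c.s_gene == 0.75
        far = gene(2000, 2300, name="dnaA")
        igs2 = make_igs(seq, 300, self.L)
        c2 = score_igs(igs2, 315, self.L, "circular", [IndicatorHit(far, "primary")])
        assert c2.s_gene == 0.5  # within 5 kb but not flanking

    def test_box_score_saturates_at_three_equivalents(self):
        seq = "CC".join(["TTATCCACA"] * 6)
        igs = make_igs(seq, 0, self.L)
        c = score_igs(igs, igs.midpoint(self.L), self.L, "circular", [])
        assert c.s_box == 1.0

    def test_adding_exact_box_never_lowers_total(self):
        totals = []
        for k in range(5):
            seq = ("TTATCCACA" + "CC") * k + "C" * (60 - 11 * k)
            igs = make_igs(seq, 100, self.L)
            totals.append(score_igs(igs, 130, self.L, "circular", []).total)
        assert all(b >= a for a, b in zip(totals, totals[1:]))

    def test_s_dist_monotone_in_distance(self):
        seq = "C" * 30
        dists = []
        for start in (0, 500, 1500, 3000, 4985):
            igs = make_igs(seq, start, self.L)
            dists.append(score_igs(igs, 0, self.L, "circular", []).s_dist)
        assert all(a >= b for a, b in zip(dists, dists[1:]))

    def test_score_bounds_on_random_inputs(self):
        rng = np.random.default_rng(21)
        for _ in range(50):
            seq = random_dna(rng, int(rng.integers(30, 200)))
            start = int(rng.integers(0, self.L))
            igs = make_igs(seq, start, self.L)
            inds = []
            if rng.random() < 0.5:
                g = gene(start % 500, start % 500 + 100, name="dnaA")
                inds = [IndicatorHit(g, "primary")]
            c = score_igs(igs, int(rng.integers(0, self.L)), self.L, "circular", inds)
            for comp in (c.s_dist, c.s_gene, c.s_box):
                assert 0.0 <= comp <= 1.0
            assert 0.0 <= c.total <= 3.0


class TestRanking:
    def _cand(self, total, n_trios=0, gatc=0, seq="CCCC", start=0):
        from oriseek.motifs import TrioArray
        from oriseek.predict import CandidateScore

        igs = make_igs(seq, start, 1000)
        return CandidateScore(
            igs=igs, s_dist=total, s_gene=0, s_box=0, total=total,
            trios=[TrioArray(0, "+", 3)] * n_trios, gatc_count=gatc,
        )

    def test_higher_total_first(self):
        a, b = self._cand(1.4), self._cand(2.1, start=100)
        assert rank_candidates([a, b])[0] is b

    def test_tie_broken_by_trios(self):
        a, b = self._cand(1.0, n_trios=1), self._cand(1.0, n_trios=0, start=100)
        assert rank_candidates([b, a])[0] is a

    def test_tie_broken_by_gatc_then_at_then_start(self):
        a = self._cand(1.0, gatc=2, start=500)
        b = self._cand(1.0, gatc=1, start=100)
        assert rank_candidates([b, a])[0] is a
        c = self._cand(1.0, seq="AAAA", start=500)
        d = self._cand(1.0, seq="CCCC", start=100)
        assert rank_candidates([d, c])[0] is c
        e, f = self._cand(1.0, start=300), self._cand(1.0, start=100)
        assert rank_candidates([e, f])[0] is f

    def test_empty_list_warns(self):
        with pytest.warns(UserWarning):
            assert rank_candidates([]) == []


class TestPredictOric:
    def test_recovers_planted_origin(self):
        sim = simulate_genome(SimParams(seed=7))
        preds = predict_oric(sim.record)
        assert preds and preds[0].rank == 1
        s, e = sim.truth_oric
        p = preds[0]
        assert p.start < e and p.end > s  # overlap with truth interval

    def test_two_identical_candidates_both_reported(self):
        L = 2000
        bg = "AT" * (L // 2)
        planted = "TTAATTAA"
        seq = list(bg)
        for pos in (480, 1480):  # midpoints 500 and 1500, both at d = L/4 from 0
            seq[pos : pos + len(planted)] = planted
        seq = "".join(seq)
        feats = [gene(0, 300, tag="a"), gene(700, 1300, tag="b"), gene(1700, 2000, tag="c")]
        rec = GenomeRecord(id="twin", sequence=seq, topology="circular", features=feats)
        cfg = MotifConfig(dnaa_box=MotifPattern("DnaA_box", "TTAATTAA"), dnaa_box_max_mm=0)
        preds = predict_oric(rec, config=cfg, min_igs_len=80)
        assert len(preds) == 2
        assert preds[0].total == preds[1].total
        assert {p.start for p in preds} == {300, 1300}

    def test_all_coding_genome_empty_with_warning(self):
        rec = GenomeRecord(id="r", sequence="A" * 500, topology="circular",
                           features=[gene(0, 500)])
        with pytest.warns(UserWarning, match="no IGS"):
            assert predict_oric(rec) == []

    def test_unannotated_input_uses_orf_fallback(self):
        sim = simulate_genome(SimParams(L=30_000, seed=19))
        bare = GenomeRecord(id="bare", sequence=sim.record.sequence, topology="circular")
        preds = predict_oric(bare)
        # fallback ORFs delimit IGSs; no indicator genes can match by name
        assert all(p.candidate.s_gene == 0.0 for p in preds)


class TestPredictDraft:
    def test_split_consistency_with_unsplit_run(self):
        sim = simulate_genome(SimParams(seed=11))
        L = len(sim.record)
        unsplit = predict_oric(sim.record)[0]
        contigs = split_genome(sim.record, 3, avoid=sim.truth_oric)
        offsets = {c.id: off for c, off in contigs}
        preds = predict_oric_draft([c for c, _ in contigs])
        top = preds[0]
        gstart = (offsets[top.record_id] + top.start) % L
        gend = gstart + top.candidate.igs.length
        assert gstart < unsplit.end + L and gend > unsplit.start  # same interval
        assert (gstart, top.candidate.igs.length) == (unsplit.start, unsplit.candidate.igs.length)

    def test_contig_scored_against_own_gc_minimum(self):
        # one gene-free AT-only contig: flat GC curve, gc_min at 0; the IGS
        # midpoint distance uses the contig's own coordinates and length
        rec = GenomeRecord(id="c1", sequence="AT" * 500, topology="linear")
        preds = predict_oric_draft([rec], min_total=-1.0)
        assert len(preds) == 1
        c = preds[0].candidate
        expected = 1 - circular_distance(500, 0, 1000, "linear") / 500
        assert c.s_dist == pytest.approx(max(0.0, expected))

    def test_winner_comes_from_evidence_contig(self):
        planted = "CC".join(["TTATCCACA"] * 3) + "C" * 50
        dnaa = gene(0, 300, name="dnaA", tag="dnaA")
        other = gene(300 + len(planted), 900 + len(planted), tag="x")
        seq1 = random_dna(np.random.default_rng(1), 300) + planted + \
            random_dna(np.random.default_rng(2), 600)
        rec1 = GenomeRecord(id="has_oric", sequence=seq1, topology="linear",
                            features=[dnaa, other])
        rec2 = GenomeRecord(id="boring", sequence="AC" * 600, topology="linear",
                            features=[gene(0, 400, tag="y"), gene(800, 1200, tag="z")])
        preds = predict_oric_draft([rec2, rec1])
        assert preds[0].record_id == "has_oric"
        assert preds[0].candidate.s_box == 1.0 and preds[0].candidate.s_gene == 1.0


class TestPredictTerminus:
    def test_dif_hit_wins_over_gc_max(self):
        sim = simulate_genome(SimParams(L=30_000, seed=23, plant_dif=True))
        cfg = MotifConfig(dif=MotifPattern("dif", sim.params.dif_seq))
        t = predict_terminus(sim.record, cfg)
        assert t.method == "dif"
        mid = sim.truth_ter + len(sim.params.dif_seq) // 2
        assert abs(t.position - mid) <= len(sim.params.dif_seq)

    def test_gc_max_fallback(self, standard_sim):
        t = predict_terminus(standard_sim.record)
        assert t.method == "gc_max" and t.dif_hit is None
        L = len(standard_sim.record)
        assert circular_distance(t.position, standard_sim.truth_ter, L) <= 0.02 * L

    def test_draft_rejected(self):
        recs = [GenomeRecord(id=f"c{i}", sequence="ACGT" * 30) for i in range(2)]
        with pytest.raises(UnsupportedOperationError):
            predict_terminus(recs)
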