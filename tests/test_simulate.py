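"""Simulator unit and property tests: cleavage, fragmentation, translation."""

import re

import numpy as np
import pytest

import ribofrag as rf
from ribofrag.simulate import ConfigurationError, FragmentEntry, first_downstream_orf


class TestBuildTranscriptome:
    def test_seed_determinism(self):
        a = rf.build_transcriptome(3, seed=7)
        b = rf.build_transcriptome(3, seed=7)
        assert [(t.id, t.sequence, t.cds_start, t.cds_end, t.uorfs) for t in a] \
            == [(t.id, t.sequence, t.cds_start, t.cds_end, t.uorfs) for t in b]

    def test_invariants_hold(self, small_transcriptome):
        for t in small_transcriptome:
            assert 0 <= t.cds_start < t.cds_end <= t.length
            assert (t.cds_end - t.cds_start) % 3 == 0
            assert t.sequence[t.cds_start:t.cds_start + 3] == "AUG"
            for s, e in t.uorfs:
                assert 0 <= s < e <= t.cds_end

    def test_uorf_fraction_zero(self):
        ts = rf.build_transcriptome(50, uorf_fraction=0.0, seed=3)
        assert all(t.uorfs == () for t in ts)

    def test_uorf_fraction_matches_binomial_expectation(self):
        # binomial(500, 0.3): observed fraction within +-0.05 of target
        ts = rf.build_transcriptome(500, uorf_fraction=0.3, seed=1)
        frac = sum(1 for t in ts if t.uorfs) / len(ts)
        assert abs(frac - 0.3) < 0.05

    @pytest.mark.parametrize("kwargs", [
        dict(n_genes=0),
        dict(n_genes=5, cds_codons_range=(1, 1)),
        dict(n_genes=5, utr5_range=(0, 5)),
        dict(n_genes=5, utr5_range=(3, 5), uorf_fraction=0.5),
    ])
    def test_infeasible_configs_raise(self, kwargs):
        with pytest.raises(ConfigurationError):
            rf.build_transcriptome(**kwargs)


class TestCleavageSites:
    def test_rnasel_uu_ua_positions(self):
        # cut 3' of each motif: UU at 2-3 -> 4, UA at 3-4 -> 5
        t = rf.TranscriptModel("x", "AAUUAAA", 0, 3)
        assert [p for p, _ in rf.cleavage_sites(t, rf.RNASE_L)] == [4, 5]

    def test_no_motif_no_sites(self):
        t = rf.TranscriptModel("x", "GGGGGG", 0, 3)
        assert rf.cleavage_sites(t, rf.RNASE_L) == []

    def test_ire1_ugc(self):
        t = rf.TranscriptModel("x", "UGCUGC", 0, 3)
        assert [p for p, _ in rf.cleavage_sites(t, rf.IRE1)] == [3, 6]

    def test_matches_exhaustive_scan_oracle(self, small_transcriptome):
        # independent oracle: regex scan over every motif occurrence
        for t in small_transcriptome[:10]:
            for spec in (rf.RNASE_L, rf.RNASE_A, rf.IRE1):
                expect = {}
                for motif, w in spec.motif_weights.items():
                    for m in re.finditer(f"(?={motif})", t.sequence):
                        p = m.start() + len(motif)
                        expect[p] = expect.get(p, 0.0) + w
                assert rf.cleavage_sites(t, spec) == sorted(expect.items())

    def test_motif_specificity(self, small_transcriptome):
        # every RNase L cut position is immediately 3' of UU or UA
        for t in small_transcriptome[:10]:
            for p, _ in rf.cleavage_sites(t, rf.RNASE_L):
                assert t.sequence[p - 2:p] in ("UU", "UA")


class TestFragmentPool:
    def test_zero_intensity_zero_loss_is_intact(self, small_transcriptome):
        expr = rf.ExpressionState.uniform(small_transcriptome, 10)
        pool = rf.fragment_pool(small_transcriptome, expr, rf.RNASE_L,
                                rf.FragmentationParams(0.0, 0.0, 5))
        assert all(e.provenance == "intact" for e in pool.entries)
        assert {e.transcript_id: e.abundance for e in pool.entries} \
            == {t.id: 10 for t in small_transcriptome}

    def test_mean_cuts_matches_poisson_rate(self):
        # one transcript, many copies: mean cuts/copy -> intensity * n_sites
        t = rf.build_transcriptome(1, seed=2)[0]
        m = len(rf.cleavage_sites(t, rf.RNASE_L))
        lam = 0.01
        expr = rf.ExpressionState({t.id: 4000})
        pool = rf.fragment_pool([t], expr, rf.RNASE_L,
                                rf.FragmentationParams(lam, 0.0, 9))
        # cuts per copy = fragments per copy - 1 (capped draws are rare at
        # this rate); count total fragments from cut copies
        cut_frags = sum(e.abundance for e in pool.entries
                        if e.provenance != "intact")
        intact = sum(e.abundance for e in pool.entries
                     if e.provenance == "intact")
        ncut_copies = 4000 - intact
        # total cuts = total boundaries among cut copies
        total_cuts = cut_frags - ncut_copies
        rate = lam * m
        expect = 4000 * rate  # mean of Poisson total (conditioning on >0 cut
        # copies only removes zero-count copies, which contribute no cuts)
        se = np.sqrt(4000 * rate)
        assert abs(total_cuts - expect) < 3 * se

    def test_baseline_loss_thins_pool(self, small_transcriptome):
        expr = rf.ExpressionState.uniform(small_transcriptome, 100)
        pool = rf.fragment_pool(small_transcriptome, expr, rf.RNASE_L,
                                rf.FragmentationParams(0.0, 0.9, 11))
        total = sum(e.abundance for e in pool.entries)
        n = 100 * len(small_transcriptome)
        se = np.sqrt(n * 0.9 * 0.1)
        assert abs(total - 0.1 * n) < 3 * se

    def test_nucleotide_conservation(self, small_transcriptome):
        expr = rf.ExpressionState.uniform(small_transcriptome, 20)
        input_nt = sum(20 * t.length for t in small_transcriptome)
        intact_pool = rf.fragment_pool(small_transcriptome, expr, rf.RNASE_L,
                                       rf.FragmentationParams(0.05, 0.0, 3))
        assert intact_pool.total_nt() == pytest.approx(input_nt)
        lossy = rf.fragment_pool(small_transcriptome, expr, rf.RNASE_L,
                                 rf.FragmentationParams(0.05, 0.5, 3))
        assert lossy.total_nt() <= input_nt

    def test_mean_cuts_monotone_in_intensity(self, small_transcriptome):
        # averaged over >= 20 seeds, cut count is nondecreasing in intensity
        def mean_cuts(intensity):
            tot = 0.0
            for s in range(20):
                expr = rf.ExpressionState.uniform(small_transcriptome[:10], 20)
                pool = rf.fragment_pool(small_transcriptome[:10], expr,
                                        rf.RNASE_L,
                                        rf.FragmentationParams(intensity, 0.0, s))
                tot += sum(e.abundance for e in pool.entries
                           if e.provenance != "intact")
            return tot / 20

        cuts = [mean_cuts(i) for i in (0.0, 0.01, 0.05, 0.1)]
        assert cuts == sorted(cuts)

    def test_resistance_raises_survival(self, small_transcriptome):
        ids = [t.id for t in small_transcriptome]
        expr = rf.ExpressionState.uniform(small_transcriptome, 200)
        expr.resistance = {ids[0]: 4.0}
        pool = rf.fragment_pool(small_transcriptome, expr, rf.RNASE_L,
                                rf.FragmentationParams(0.0, 0.9, 21))
        ab = {}
        for e in pool.entries:
            ab[e.transcript_id] = ab.get(e.transcript_id, 0) + e.abundance
        others = np.mean([ab.get(i, 0) for i in ids[1:]])
        assert ab[ids[0]] > 2.5 * others  # 4x survival advantage


class TestSimulateFootprints:
    def test_intact_only_psites_inside_orf(self, small_transcriptome):
        expr = rf.ExpressionState.uniform(small_transcriptome, 20)
        pool = rf.fragment_pool(small_transcriptome, expr, rf.RNASE_L,
                                rf.FragmentationParams(0.0, 0.0, 1))
        tp = rf.TranslationParams(density=0.1, reinit_prob=0.0,
                                  stall_weight=0.0, seed=1)
        reads = rf.simulate_footprints(pool, small_transcriptome, tp)
        by_id = {t.id: t for t in small_transcriptome}
        assert reads
        for r in reads:
            t = by_id[r.transcript_id]
            assert t.cds_start <= rf.assign_psite(r) < t.cds_end

    def test_reinit_translates_past_stop_into_utr3(self):
        # hand-built 3' fragment starting inside the CDS whose first AUG
        # opens an out-of-frame ORF running past the annotated stop
        utr5 = "GGGGG"
        cds = "AUG" + "GGC" * 3 + "G" + "AUG" + "CCG" * 8 + "AA"  # len 39
        cds = cds[:36]  # truncate to 36 nt (12 codons)
        seq = utr5 + cds + "CCGCCGCCGCCGCCGCCGUAGGGGG"  # stop far into 3'UTR
        t = rf.TranscriptModel("h", seq, 5, 41)
        frag = FragmentEntry("h", 18, t.length, 50, "3p")
        orf = first_downstream_orf(t.sequence, 18, t.length, min_codons=5)
        assert orf is not None and orf[1] > t.cds_end  # sanity: runs past stop
        tp = rf.TranslationParams(density=0.5, reinit_prob=1.0, seed=4)
        reads = rf.simulate_footprints(rf.FragmentPool([frag]), [t], tp)
        psites = [rf.assign_psite(r) for r in reads]
        assert any(p >= t.cds_end for p in psites)

    def test_stall_mass_at_fragment_end(self, toy_transcript):
        t = toy_transcript
        frag = FragmentEntry(t.id, 0, 40, 100, "5p")  # cut inside the CDS
        tp = rf.TranslationParams(density=0.05, reinit_prob=0.0,
                                  stall_weight=50.0, seed=8)
        reads = rf.simulate_footprints(rf.FragmentPool([frag]), [t], tp)
        psites = [rf.assign_psite(r) for r in reads]
        vals, counts = np.unique(psites, return_counts=True)
        assert vals[np.argmax(counts)] == 39  # fragment_end - 1

    def test_no_stall_when_stop_codon_retained(self, toy_transcript):
        t = toy_transcript
        # fragment ends in the 3'UTR: main ORF complete, ribosomes terminate
        frag = FragmentEntry(t.id, 0, 60, 100, "5p")
        tp = rf.TranslationParams(density=0.05, reinit_prob=0.0,
                                  stall_weight=50.0, seed=8)
        reads = rf.simulate_footprints(rf.FragmentPool([frag]), [t], tp)
        assert all(rf.assign_psite(r) < t.cds_end for r in reads)

    def test_seed_determinism(self, small_transcriptome):
        expr = rf.ExpressionState.uniform(small_transcriptome, 10)
        pool = rf.fragment_pool(small_transcriptome, expr, rf.RNASE_L,
                                rf.FragmentationParams(0.05, 0.5, 2))
        tp = rf.TranslationParams(density=0.1, reinit_prob=0.5, seed=3)
        r1 = rf.simulate_footprints(pool, small_transcriptome, tp)
        r2 = rf.simulate_footprints(pool, small_transcriptome, tp)
        assert r1 == r2

    def test_footprint_lengths_in_range(self, small_transcriptome):
        expr = rf.ExpressionState.uniform(small_transcriptome, 10)
        pool = rf.fragment_pool(small_transcriptome, expr, rf.RNASE_L,
                                rf.FragmentationParams(0.0, 0.0, 2))
        tp = rf.TranslationParams(density=0.1, seed=3)
        for r in rf.simulate_footprints(pool, small_transcriptome, tp):
            assert 25 <= r.length <= 34
            assert len(r.umi) == 7


class TestSimulateRnaseq:
    def test_equal_abundance_count_ratio_near_one(self):
        ts = rf.build_transcriptome(2, seed=6)
        pool = rf.FragmentPool([
            FragmentEntry(ts[0].id, 0, ts[0].length, 100, "intact"),
            FragmentEntry(ts[1].id, 0, ts[1].length,
                          100 * (ts[0].cds_end - ts[0].cds_start)
                          / (ts[1].cds_end - ts[1].cds_start), "intact"),
        ])
        counts = rf.simulate_rnaseq(pool, ts, depth=2e5, dispersion=0.0, seed=3)
        a, b = counts.iloc[0, 0], counts.iloc[1, 0]
        se = np.sqrt(a + b)
        assert abs(a - b) < 3 * se

    def test_zero_abundance_gene_zero_counts(self, small_transcriptome):
        entries = [FragmentEntry(t.id, 0, t.length, 10, "intact")
                   for t in small_transcriptome[1:]]
        counts = rf.simulate_rnaseq(rf.FragmentPool(entries),
                                    small_transcriptome, depth=1e5, seed=4)
        assert counts.loc[small_transcriptome[0].id].sum() == 0

    def test_same_seed_identical_table(self, small_transcriptome):
        expr = rf.ExpressionState.uniform(small_transcriptome, 10)
        pool = rf.fragment_pool(small_transcriptome, expr, rf.RNASE_L,
                                rf.FragmentationParams(0.02, 0.5, 2))
        a = rf.simulate_rnaseq(pool, small_transcriptome, 1e5, 0.05, seed=9,
                               n_replicates=3)
        b = rf.simulate_rnaseq(pool, small_transcriptome, 1e5, 0.05, seed=9,
                               n_replicates=3)
        assert a.equals(b)
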