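import math

import numpy as np
import pytest

import genefamkit as gk
from genefamkit.kaks import SENSE_CODONS, codon_syn_fraction, pathway_differences
from oracles import oracle_ng86


def _codon_aln(a, b):
    return gk.CodonAlignment(
        [gk.SequenceRecord("a", "", a, aligned=True), gk.SequenceRecord("b", "", b, aligned=True)]
    )


class TestBacktranslate:
    def test_gap_expansion(self):
        prot = gk.Alignment(
            [
                gk.SequenceRecord("a", "", "M-A", aligned=True),
                gk.SequenceRecord("b", "", "MKA", aligned=True),
            ]
        )
        ca = gk.backtranslate(
            prot,
            gk.SequenceRecord("a", "", "ATGGCT"),
            gk.SequenceRecord("b", "", "ATGAAAGCT"),
        )
        assert ca.rows[0].residues == "ATG---GCT"
        assert ca.rows[1].residues == "ATGAAAGCT"

    def test_trailing_stop_trimmed(self):
        prot = gk.Alignment(
            [
                gk.SequenceRecord("a", "", "MA", aligned=True),
                gk.SequenceRecord("b", "", "MA", aligned=True),
            ]
        )
        ca = gk.backtranslate(
            prot,
            gk.SequenceRecord("a", "", "ATGGCTTAA"),
            gk.SequenceRecord("b", "", "ATGGCA"),
        )
        assert ca.length_bp == 6

    def test_internal_stop_rejected(self):
        prot = gk.Alignment(
            [
                gk.SequenceRecord("a", "", "MAA", aligned=True),
                gk.SequenceRecord("b", "", "MAA", aligned=True),
            ]
        )
        with pytest.raises(ValueError, match="stop codon at codon 2"):
            gk.backtranslate(
                prot,
                gk.SequenceRecord("a", "", "ATGTAAGCT"),
                gk.SequenceRecord("b", "", "ATGGCTGCT"),
            )

    def test_length_not_codon_multiple_rejected(self):
        prot = gk.Alignment(
            [
                gk.SequenceRecord("a", "", "M", aligned=True),
                gk.SequenceRecord("b", "", "M", aligned=True),
            ]
        )
        with pytest.raises(ValueError, match="divisible by 3"):
            gk.backtranslate(
                prot, gk.SequenceRecord("a", "", "ATGA"), gk.SequenceRecord("b", "", "ATG")
            )

    def test_translation_mismatch_cites_codon(self):
        prot = gk.Alignment(
            [
                gk.SequenceRecord("a", "", "MK", aligned=True),
                gk.SequenceRecord("b", "", "MK", aligned=True),
            ]
        )
        with pytest.raises(ValueError, match="codon 2"):
            gk.backtranslate(
                prot, gk.SequenceRecord("a", "", "ATGGTT"), gk.SequenceRecord("b", "", "ATGAAA")
            )

    def test_round_trip_on_simulated_pairs(self):
        from genefamkit.kaks import translate_cds

        for seed in range(20):
            sim = gk.simulate_codon_pair(
                gk.CodonSimSpec(n_codons=40, target_ks=0.2, target_ka=0.1, rng_seed=seed)
            )
            prot_aln = gk.Alignment([sim.protein_a, sim.protein_b])
            ca = gk.backtranslate(prot_aln, sim.cds_a, sim.cds_b)
            for row, prot in zip(ca.rows, (sim.protein_a, sim.protein_b)):
                assert translate_cds(row.ungapped()) == prot.residues


class TestNG86:
    def test_identical_sequences(self):
        est = gk.ng86(_codon_aln("ATGGCTAAA", "ATGGCTAAA"))
        assert est.ka == est.ks == 0.0
        assert math.isnan(est.ratio)

    def test_phe_leu_hand_example(self):
        # TTT vs TTA: S = (1/3 + 2/3)/2, one nonsynonymous 1-step path
        est = gk.ng86(_codon_aln("TTT", "TTA"))
        assert est.s_sites == pytest.approx(0.5)
        assert est.n_sites == pytest.approx(2.5)
        assert (est.sd, est.nd) == (0.0, 1.0)
        assert est.ks == 0.0
        assert est.ka == pytest.approx(-0.75 * math.log(1 - (4 / 3) * 0.4), abs=1e-12)

    def test_site_counts_partition_codons(self):
        rng = np.random.default_rng(2)
        codons = [SENSE_CODONS[i] for i in rng.integers(0, len(SENSE_CODONS), 50)]
        est = gk.ng86(_codon_aln("".join(codons), "".join(codons)))
        assert est.n_sites + est.s_sites == pytest.approx(3 * 50)

    def test_symmetric_in_rows(self):
        a, b = "ATGGCTAAATTTCCC", "ATGGCAAAATTACCC"
        e1, e2 = gk.ng86(_codon_aln(a, b)), gk.ng86(_codon_aln(b, a))
        assert (e1.ka, e1.ks, e1.s_sites, e1.sd) == (e2.ka, e2.ks, e2.s_sites, e2.sd)

    def test_agrees_with_brute_force_oracle(self):
        rng = np.random.default_rng(99)
        for _ in range(200):
            codons_a = [SENSE_CODONS[i] for i in rng.integers(0, len(SENSE_CODONS), 100)]
            codons_b = []
            for c in codons_a:
                if rng.random() < 0.2:
                    codons_b.append(SENSE_CODONS[int(rng.integers(0, len(SENSE_CODONS)))])
                else:
                    codons_b.append(c)
            est = gk.ng86(_codon_aln("".join(codons_a), "".join(codons_b)))
            oka, oks, oS, oN, osd, ond = oracle_ng86(codons_a, codons_b)
            assert est.s_sites == pytest.approx(oS, abs=1e-12)
            assert est.n_sites == pytest.approx(oN, abs=1e-12)
            assert est.sd == pytest.approx(osd, abs=1e-12)
            assert est.nd == pytest.approx(ond, abs=1e-12)
            for mine, theirs in ((est.ka, oka), (est.ks, oks)):
                if math.isnan(theirs):
                    assert math.isnan(mine)
                else:
                    assert mine == pytest.approx(theirs, abs=1e-12)

    def test_agrees_with_biopython_on_hand_pair(self):
        from Bio import Align
        from Bio.Align import analysis

        dn, ds = analysis.calculate_dn_ds(Align.Alignment(["TTT", "TTA"]), method="NG86")
        est = gk.ng86(_codon_aln("TTT", "TTA"))
        assert est.ka == pytest.approx(dn, abs=1e-9)
        assert est.ks == pytest.approx(ds, abs=1e-9)

    def test_gap_codons_excluded(self):
        est = gk.ng86(_codon_aln("ATG---AAA", "ATGGCTAAA"))
        assert est.n_sites + est.s_sites == pytest.approx(6)

    def test_no_comparable_codons_rejected(self):
        with pytest.raises(ValueError, match="no comparable"):
            gk.ng86(_codon_aln("---", "ATG"))

    def test_all_pathways_through_stops_skips_codon(self):
        # site fractions cached independently of pathway blocking
        assert pathway_differences("TTT", "TTT") == (0.0, 0.0)
        assert codon_syn_fraction("TGG") == 0.0  # Trp: every change nonsyn or stop


class TestSlidingWindow:
    def test_single_window_when_alignment_fits(self):
        rng = np.random.default_rng(0)
        codons = "".join(SENSE_CODONS[i] for i in rng.integers(0, 61, 50))
        prof = gk.sliding_window_kaks(_codon_aln(codons, codons))
        assert len(prof) == 1
        assert (prof.start_bp[0], prof.end_bp[0]) == (1, 150)

    def test_window_longer_than_alignment_degenerates(self):
        prof = gk.sliding_window_kaks(_codon_aln("ATGAAA", "ATGAAG"))
        assert len(prof) == 1
        assert prof.end_bp[0] == 6

    def test_identical_window_reports_missing_ratio(self):
        prof = gk.sliding_window_kaks(_codon_aln("ATGGCT", "ATGGCT"))
        assert prof.ka[0] == prof.ks[0] == 0.0
        assert math.isnan(prof.ratio[0])

    def test_nonoverlapping_windows_recombine_to_whole_gene(self):
        rng = np.random.default_rng(12)
        a = [SENSE_CODONS[i] for i in rng.integers(0, 61, 120)]
        b = [
            SENSE_CODONS[int(rng.integers(0, 61))] if rng.random() < 0.3 else c for c in a
        ]
        aln = _codon_aln("".join(a), "".join(b))
        whole = gk.ng86(aln)
        S = N = sd = nd = 0.0
        for start in range(0, 120, 50):
            est = gk.ng86(aln.slice_codons(start, min(start + 50, 120)))
            S += est.s_sites
            N += est.n_sites
            sd += est.sd
            nd += est.nd
        assert S == pytest.approx(whole.s_sites, abs=1e-12)
        assert N == pytest.approx(whole.n_sites, abs=1e-12)
        assert sd == pytest.approx(whole.sd, abs=1e-12)
        assert nd == pytest.approx(whole.nd, abs=1e-12)

    def test_homogeneous_pair_windows_track_global_ratio(self):
        sim = gk.simulate_codon_pair(
            gk.CodonSimSpec(n_codons=300, target_ks=0.4, target_ka=0.2, rng_seed=77)
        )
        aln = _codon_aln(sim.cds_a.residues, sim.cds_b.residues)
        whole = gk.ng86(aln)
        prof = gk.sliding_window_kaks(aln)  # 900 bp, window 150, step 9
        mean_ratio = prof.ratio.dropna().mean()
        assert mean_ratio == pytest.approx(whole.ratio, rel=0.2)


class TestDating:
    def test_unit_conversion(self):
        assert gk.date_from_ks(0.0182) == pytest.approx(1.0)
        assert gk.date_from_ks(0.0) == 0.0

    def test_reference_pair_date(self):
        # mean flanking Ks 0.2857 dates the duplication to ~15.70 Mya
        assert gk.date_from_ks(0.2857) == pytest.approx(15.6974, rel=5e-4)

    def test_saturated_ks_rejected(self):
        with pytest.raises(ValueError, match="saturated"):
            gk.date_from_ks(2.5)

    def test_linear_in_ks_inverse_in_rate(self):
        assert gk.date_from_ks(0.4) == pytest.approx(2 * gk.date_from_ks(0.2))
        assert gk.date_from_ks(0.2, clock_rate=1.82e-8) == pytest.approx(
            gk.date_from_ks(0.2) / 2
        )

    def _est(self, ks, ka=0.05):
        return gk.KaKsEstimate(
            ka=ka, ks=ks, n_sites=100, s_sites=50, nd=1, sd=1, saturated=ks > 2.0
        )

    def test_block_mean_and_date(self):
        block = gk.date_block([self._est(k) for k in (0.29, 0.30, 0.31)], label="pair")
        assert block.mean_ks == pytest.approx(0.30)
        assert block.date_mya == pytest.approx(16.48, abs=0.005)
        assert block.n_flanking == 3
        assert block.sd_defined

    def test_saturated_estimates_excluded(self):
        block = gk.date_block([self._est(k) for k in (0.29, 0.31, 2.5)])
        assert block.n_flanking == 2
        assert block.mean_ks == pytest.approx(0.30)

    def test_single_estimate_flags_sd(self):
        block = gk.date_block([self._est(0.3)])
        assert block.sd_ks == 0.0
        assert not block.sd_defined

    def test_all_saturated_rejected(self):
        with pytest.raises(ValueError, match="saturated"):
            gk.date_block([self._est(2.5), self._est(3.0)])


class TestSelection:
    @pytest.mark.parametrize(
        "ratio,expected",
        [(0.2956, "purifying"), (1.0, "neutral"), (1.3, "positive"), (1.0 + 1e-12, "neutral")],
    )
    def test_classification(self, ratio, expected):
        assert gk.classify_selection(ratio) == expected

    def test_undefined_ratio_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            gk.classify_selection(float("nan"))
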