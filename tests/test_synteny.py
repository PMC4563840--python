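import numpy as np
import pandas as pd
import pytest

import genefamkit as gk
from genefamkit.synteny import _effective_window_size


def _toy_genomes(n_genes=40, homologs=(), transposons=()):
    """Two single-chromosome genomes; homologs is a list of (rank_a, rank_b)
    pairs that get strong homology entries."""
    def build(label):
        models = []
        pos = 1000
        for i in range(n_genes):
            start, end = pos + 500, pos + 1500
            models.append(
                gk.GeneModel(
                    f"{label}_g{i:02d}", "chr1", "+", start, end, [(start, end)],
                    is_transposon=(label, i) in transposons,
                )
            )
            pos = end
        return gk.Genome.from_models(label, models)

    ga, gb = build("A"), build("B")
    records = [
        (f"A_g{i:02d}", f"B_g{j:02d}", 200.0, 1e-40) for i, j in homologs
    ]
    return ga, gb, gk.HomologyTable.from_records(records)


class TestDetectBlock:
    def test_planted_block_found_with_expected_pair_count(self, genome_sim):
        hom = genome_sim.homology()
        cfg = gk.RunConfig()
        for blk in genome_sim.truth["blocks"]:
            a, b = blk["anchor"]
            found = gk.detect_block(
                gk.AnchorPair(a, b, "ga", "gb"), genome_sim.genome_a, genome_sim.genome_b,
                hom, cfg,
            )
            assert found is not None
            assert found.n_conserved == len(blk["pairs"])
            assert set(map(tuple, blk["pairs"])) == set(found.conserved_pairs)

    def test_too_few_conserved_pairs_returns_none(self):
        # anchor pair + one more homolog = 2 < 3
        ga, gb, hom = _toy_genomes(homologs=[(20, 20), (22, 22)])
        block = gk.detect_block(gk.AnchorPair("A_g20", "B_g20", "A", "B"), ga, gb, hom)
        assert block is None

    def test_threshold_boundary_inclusive(self):
        ga, gb, hom = _toy_genomes(homologs=[(20, 20), (22, 22), (18, 19)])
        block = gk.detect_block(gk.AnchorPair("A_g20", "B_g20", "A", "B"), ga, gb, hom)
        assert block is not None and block.n_conserved == 3

    def test_window_truncated_at_chromosome_end(self):
        ga, gb, hom = _toy_genomes(homologs=[(4, 4), (2, 2), (6, 6)])
        block = gk.detect_block(gk.AnchorPair("A_g04", "B_g04", "A", "B"), ga, gb, hom)
        assert block is not None
        assert block.window_a[0] == "A_g00"  # truncated left edge
        assert len(block.window_a) == 20  # 4 left + anchor + 15 right

    def test_homolog_outside_window_ignored(self):
        ga, gb, hom = _toy_genomes(homologs=[(20, 20), (22, 22), (39, 0)])
        block = gk.detect_block(gk.AnchorPair("A_g20", "B_g20", "A", "B"), ga, gb, hom)
        assert block is None

    def test_missing_anchor_raises_key_error(self):
        ga, gb, hom = _toy_genomes()
        with pytest.raises(KeyError):
            gk.detect_block(gk.AnchorPair("A_zz", "B_g00", "A", "B"), ga, gb, hom)


class TestSyntenyQuality:
    def test_perfect_conservation_is_100(self):
        pairs = [(i, i) for i in range(5, 36)]  # every window gene pairs up
        ga, gb, hom = _toy_genomes(homologs=pairs)
        block = gk.detect_block(gk.AnchorPair("A_g20", "B_g20", "A", "B"), ga, gb, hom)
        assert block.n_conserved == 31
        assert gk.synteny_quality(block, ga, gb, hom) == pytest.approx(100.0)

    def test_formula_arithmetic(self):
        pairs = [(i, i) for i in range(16, 26)]  # 10 conserved pairs
        ga, gb, hom = _toy_genomes(homologs=pairs)
        block = gk.detect_block(gk.AnchorPair("A_g20", "B_g20", "A", "B"), ga, gb, hom)
        assert block.n_conserved == 10
        q = gk.synteny_quality(block, ga, gb, hom)
        assert q == pytest.approx(100 * 2 * 10 / 62, abs=1e-9)

    def test_transposons_excluded_from_denominator(self):
        pairs = [(i, i) for i in range(16, 26)]
        te = tuple(("A", i) for i in range(28, 32))  # 4 flagged genes in window A
        ga, gb, hom = _toy_genomes(homologs=pairs, transposons=te)
        ga_plain, gb_plain, hom_plain = _toy_genomes(homologs=pairs)
        block = gk.detect_block(gk.AnchorPair("A_g20", "B_g20", "A", "B"), ga, gb, hom)
        plain = gk.detect_block(
            gk.AnchorPair("A_g20", "B_g20", "A", "B"), ga_plain, gb_plain, hom_plain
        )
        q_te = gk.synteny_quality(block, ga, gb, hom)
        q_plain = gk.synteny_quality(plain, ga_plain, gb_plain, hom_plain)
        assert q_te == pytest.approx(100 * 2 * 10 / 58)
        assert q_te > q_plain

    def test_tandem_runs_collapse_once(self):
        # consecutive homologous genes in one window count once
        pairs = [(i, i) for i in range(18, 24)]
        ga, gb, hom0 = _toy_genomes(homologs=pairs)
        records = list(hom0.entries.itertuples(index=False, name=None))
        records.append(("A_g26", "A_g27", 300.0, 1e-45))  # tandem pair inside window A
        hom = gk.HomologyTable.from_records(records)
        block = gk.detect_block(gk.AnchorPair("A_g20", "B_g20", "A", "B"), ga, gb, hom)
        na = _effective_window_size(block.window_a, ga, hom, gk.RunConfig())
        assert na == 30  # 31 genes, one tandem run of two collapsed

    def test_quality_monotone_in_conserved_pairs(self):
        qualities = []
        for n_pairs in (3, 5, 8, 12):
            pairs = [(i, i) for i in range(20 - n_pairs // 2, 20 - n_pairs // 2 + n_pairs)]
            ga, gb, hom = _toy_genomes(homologs=pairs)
            block = gk.detect_block(gk.AnchorPair("A_g20", "B_g20", "A", "B"), ga, gb, hom)
            qualities.append(gk.synteny_quality(block, ga, gb, hom))
        assert qualities == sorted(qualities)


class TestSummarizeQuality:
    def test_reference_aggregation(self):
        summary = gk.summarize_quality(gk.load_synteny_quality())
        rounded = {k: gk.round_half_up(v) for k, v in summary.pair_means.items()}
        assert rounded["At-Ptr"] == 25.83
        assert rounded["At-Vv"] == 30.43
        assert rounded["Ptr-Vv"] == 42.19
        assert gk.round_half_up(summary.overall) == 25.85

    def test_single_block_all_means_equal(self):
        df = pd.DataFrame(
            [{"species_pair": "A-B", "clade": 1, "quality_pct": 33.3}]
        )
        s = gk.summarize_quality(df)
        assert s.pair_means["A-B"] == s.overall == 33.3

    def test_order_invariance(self):
        df = gk.load_synteny_quality()
        shuffled = df.sample(frac=1.0, random_state=1)
        assert gk.summarize_quality(shuffled).overall == pytest.approx(
            gk.summarize_quality(df).overall
        )

    def test_empty_groups_omitted(self):
        df = pd.DataFrame(
            [
                {"species_pair": "A-B", "clade": 1, "quality_pct": 10.0},
                {"species_pair": "A-B", "clade": 3, "quality_pct": 30.0},
            ]
        )
        s = gk.summarize_quality(df)
        # missing clade 2 must not drag the mean toward zero
        assert s.pair_means["A-B"] == pytest.approx(20.0)

    def test_no_records_rejected(self):
        with pytest.raises(ValueError):
            gk.summarize_quality(pd.DataFrame(columns=["species_pair", "clade", "quality_pct"]))


class TestDetectionPerformance:
    def test_recall_and_false_positive_rate_over_replicates(self):
        """Planted blocks are always recovered; anchors in background
        (non-syntenic) regions are almost never called blocks (100 seeded
        replicates). Background anchors are sampled with their window clear
        of planted members — a window overlapping a planted block sits in a
        genuinely syntenic region, so a call there is signal, not error."""
        rng = np.random.default_rng(2024)
        cfg = gk.RunConfig()
        n_blocks = n_found = 0
        fp = fp_total = 0
        for rep in range(100):
            sim = gk.simulate_genome_pair(
                gk.GenomeSimSpec(rng_seed=int(rng.integers(0, 2**31)))
            )
            hom = sim.homology()
            for blk in sim.truth["blocks"]:
                a, b = blk["anchor"]
                n_blocks += 1
                block = gk.detect_block(
                    gk.AnchorPair(a, b, "ga", "gb"), sim.genome_a, sim.genome_b, hom, cfg
                )
                if block is not None:
                    n_found += 1
            planted_a = {p[0] for blk in sim.truth["blocks"] for p in blk["pairs"]}
            background = []
            for cmap in sim.genome_a.maps.values():
                order = cmap.ordered_gene_ids
                planted_ranks = [i for i, g in enumerate(order) if g in planted_a]
                for i, g in enumerate(order):
                    if all(abs(i - r) > cfg.window_genes for r in planted_ranks):
                        background.append(g)
            ids_b = sorted(sim.genome_b.models)
            for _ in range(5):
                a = background[int(rng.integers(0, len(background)))]
                b = ids_b[int(rng.integers(0, len(ids_b)))]
                fp_total += 1
                if gk.detect_block(
                    gk.AnchorPair(a, b, "ga", "gb"), sim.genome_a, sim.genome_b, hom, cfg
                ) is not None:
                    fp += 1
        assert n_found == n_blocks  # recall 1.0
        assert fp / fp_total <= 0.05
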