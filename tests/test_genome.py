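"""Duplication calling, spliced alignment, structure cross-checks."""
import numpy as np
import pytest

from hsfkit import genome, simulate, tables
from hsfkit.genome import (DuplicationPair, GeneModel, StructureNotFoundError,
                           check_length_consistency, detect_duplications,
                           find_tandem_clusters, pair_alignment_stats,
                           spliced_align, summarize_intron_counts)
from hsfkit.io import GeneLocus, SequenceRecord

import oracles


class TestDuplicationPair:
    def test_canonical_storage_and_validation(self):
        p = DuplicationPair("z", "a", 0.9, 0.9, "segmental")
        assert (p.gene_a, p.gene_b) == ("a", "z")
        with pytest.raises(ValueError):
            DuplicationPair("a", "a", 0.9, 0.9, "segmental")
        with pytest.raises(ValueError):
            DuplicationPair("a", "b", 1.5, 0.9, "segmental")


class TestDetectDuplications:
    def test_planted_pairs(self, family_sim):
        _, loci, cds, truth = family_sim
        pairs = detect_duplications(cds, loci)
        found = {(p.gene_a, p.gene_b) for p in pairs}
        # the 0.95/0.95 planted pair passes, the 0.75-identity pair does not
        good = tuple(sorted((truth.duplication_pairs[0]["gene_a"],
                             truth.duplication_pairs[0]["gene_b"])))
        bad = tuple(sorted((truth.duplication_pairs[1]["gene_a"],
                            truth.duplication_pairs[1]["gene_b"])))
        assert good in found and bad not in found

    def test_tandem_vs_segmental_typing(self, family_sim):
        _, loci, cds, truth = family_sim
        pairs = detect_duplications(cds, loci)
        by_pair = {(p.gene_a, p.gene_b): p.type for p in pairs}
        cluster = set(truth.tandem_cluster)
        for (a, b), kind in by_pair.items():
            if a in cluster and b in cluster:
                assert kind == "tandem"
            else:
                assert kind == "segmental"

    def test_symmetric_deduplicated(self, family_sim):
        _, loci, cds, truth = family_sim
        pairs = detect_duplications(cds, loci)
        keys = [(p.gene_a, p.gene_b) for p in pairs]
        assert len(keys) == len(set(keys))
        assert all(a < b for a, b in keys)

    def test_alignment_stats_match_score_oracle(self):
        """The aligner used for the 80/80 rule is score-equivalent to an
        exhaustive Gotoh DP with free end gaps."""
        from Bio.Align import PairwiseAligner
        rng = np.random.default_rng(21)
        for _ in range(8):
            a = simulate.random_dna(rng, int(rng.integers(60, 120)))
            b = simulate.random_dna(rng, int(rng.integers(60, 120)))
            aligner = genome._nt_aligner()
            assert aligner.score(a, b) == pytest.approx(
                oracles.semiglobal_score(a, b))


class TestSplicedAlign:
    def test_planted_exons_recovered_exactly(self, family_sim):
        chroms, _, cds, truth = family_sim
        seq_of = {c.id: c.sequence for c in chroms}
        for rec in cds:
            t = truth.genes[rec.id]
            s0, e0 = t.gene_span
            region = SequenceRecord("r", seq_of[t.chromosome][s0 - 1 : e0])
            model = spliced_align(rec, region)
            got = [(s + s0 - 1, e + s0 - 1) for s, e in model.exons]
            assert got == [tuple(x) for x in t.exons_genomic]
            assert model.strand == t.strand
            assert model.gtag_consistent

    def test_intronless_cds_single_exon(self):
        rng = np.random.default_rng(31)
        cds = simulate.random_dna(rng, 300)
        genomic = simulate.random_dna(rng, 150) + cds + simulate.random_dna(rng, 150)
        model = spliced_align(SequenceRecord("c", cds), SequenceRecord("g", genomic))
        assert model.exons == [(151, 450)] and model.n_introns == 0

    def test_three_exon_gene(self):
        rng = np.random.default_rng(32)
        cds = simulate.random_dna(rng, 450)
        gene, exons_local = simulate._split_exons(cds, 2, rng, 0.35)
        genomic = simulate.random_dna(rng, 100) + gene + simulate.random_dna(rng, 100)
        model = spliced_align(SequenceRecord("c", cds), SequenceRecord("g", genomic))
        assert model.n_introns == 2
        assert model.exons == [(s + 100, e + 100) for s, e in exons_local]

    def test_unalignable_cds_raises(self):
        rng = np.random.default_rng(33)
        cds = simulate.random_dna(rng, 300)
        other = simulate.random_dna(rng, 900)
        with pytest.raises(StructureNotFoundError):
            spliced_align(SequenceRecord("c", cds), SequenceRecord("g", other))


class TestGeneModel:
    def test_invariants(self):
        with pytest.raises(ValueError):
            GeneModel("g", [(1, 100), (50, 200)])
        model = GeneModel("g", [(1, 100), (201, 300)])
        assert model.introns == [(101, 200)]
        assert model.intron_lengths == [100]

    def test_intron_count_histograms(self):
        models = [GeneModel("a", [(1, 90)]), GeneModel("b", [(1, 30), (61, 90)]),
                  GeneModel("c", [(1, 30), (61, 90)])]
        assert summarize_intron_counts(models) == {0: 1, 1: 2}
        assert summarize_intron_counts([]) == {}


class TestLengthConsistency:
    @pytest.mark.parametrize("gene,expected", [
        ("GhHsf7", 515), ("GhHsf39", 380), ("GhHsf2", 332)])
    def test_census_rows(self, gene, expected):
        model = next(m for m in tables.gene_models_from_structure_table()
                     if m.gene_id == gene)
        ok, implied = check_length_consistency(model, expected)
        assert ok and implied == expected

    def test_failure_reports_implied_length(self):
        model = GeneModel("g", [(1, 99)])
        ok, implied = check_length_consistency(model, 40)
        assert not ok and implied == 32


class TestTandemClusters:
    def test_planted_adjacent_cluster(self):
        loci = [GeneLocus(f"g{i}", "chr4", 1000 * i, 1000 * i + 500) for i in range(4)]
        clusters = find_tandem_clusters(loci)
        assert clusters == [[f"g{i}" for i in range(4)]]

    def test_different_chromosomes_no_cluster(self):
        loci = [GeneLocus("a", "chr1", 100, 200), GeneLocus("b", "chr2", 100, 200)]
        assert find_tandem_clusters(loci) == []

    def test_two_separate_clusters(self):
        loci = ([GeneLocus(f"a{i}", "chr1", 1000 * i, 1000 * i + 100) for i in range(2)]
                + [GeneLocus(f"b{i}", "chr1", 10_000_000 + 1000 * i,
                             10_000_000 + 1000 * i + 100) for i in range(2)])
        clusters = find_tandem_clusters(loci)
        assert sorted(len(c) for c in clusters) == [2, 2]

    def test_census_window_counting(self):
        family = [GeneLocus("f1", "chr1", 100, 200), GeneLocus("f2", "chr1", 100_000, 100_100)]
        census = family + [GeneLocus(f"o{i}", "chr1", 10_000 * (i + 1), 10_000 * (i + 1) + 10)
                           for i in range(9)]
        # nine intervening genes: beyond the default window of 5
        assert find_tandem_clusters(family, census=census) == []
        assert find_tandem_clusters(family, window=10, census=census) == [["f1", "f2"]]


class TestConsistencyReport:
    def test_known_internal_inconsistencies_flagged(self):
        report = tables.build_consistency_report()
        linker_genes = {d["gene"] for d in report.linker_mismatches}
        dbd_genes = {d["gene"] for d in report.dbd_length_mismatches}
        assert "GhHsf4" in linker_genes
        assert {"GhHsf24", "GhHsf29", "GhHsf30", "GhHsf33"} <= dbd_genes
        assert "GhHsf40" not in dbd_genes  # its stated 83 matches 1-83
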