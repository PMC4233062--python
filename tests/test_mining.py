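"""Homology search, assembly, and full-length validation."""
import numpy as np
import pytest
from Bio.Align import substitution_matrices

from hsfkit import mining, simulate
from hsfkit.io import SequenceRecord
from hsfkit.mining import (assemble_contigs, best_orf, local_align,
                           search_homologs, translate_six_frames,
                           validate_full_length)

import oracles

BLOSUM62 = substitution_matrices.load("BLOSUM62")


def _planted_cds(seed: int, klass: str = "A"):
    rec, truth = simulate.generate_hsf_protein(klass, f"{klass}1", seed=seed,
                                               gene_id=f"ref{seed}")
    rng = np.random.default_rng(seed + 1000)
    cds = simulate.reverse_translate(truth.protein, rng)
    return rec, truth, cds


class TestTranslation:
    def test_forward_frame(self):
        assert translate_six_frames(SequenceRecord("x", "ATGAAA"))[1] == "MK"

    def test_reverse_frame(self):
        # reverse complement of TTTCAT is ATGAAA
        assert translate_six_frames(SequenceRecord("x", "TTTCAT"))[-1] == "MK"

    def test_partial_codon_dropped(self):
        assert translate_six_frames(SequenceRecord("x", "ATGA"))[1] == "M"


class TestLocalAlign:
    def test_identical_similarity_one(self):
        seq = "MKTAYIAKQRQISFVKSHFS"
        score, _, sim = local_align(seq, seq)
        assert sim == 1.0 and score > 0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            local_align("", "MK")

    def test_disjoint_sequences_score_zero(self):
        # negative-scoring residue pairs only: empty local alignment
        score, _, sim = local_align("WWWWWWWW", "PPPPPPPP")
        assert score == 0.0 and sim == 0.0

    def test_score_symmetric_and_nonnegative(self):
        rng = np.random.default_rng(0)
        letters = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        for _ in range(10):
            a = "".join(rng.choice(letters, 30))
            b = "".join(rng.choice(letters, 30))
            sab, _, _ = local_align(a, b)
            sba, _, _ = local_align(b, a)
            assert sab == sba >= 0

    def test_matches_brute_force_dp(self):
        """Score equals an exhaustive affine-gap DP oracle on short peptides."""
        rng = np.random.default_rng(1)
        letters = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        for _ in range(15):
            a = "".join(rng.choice(letters, int(rng.integers(4, 11))))
            b = "".join(rng.choice(letters, int(rng.integers(4, 11))))
            expected = oracles.sw_score_affine(a, b, BLOSUM62, 11.0, 1.0)
            score, _, _ = local_align(a, b)
            assert score == pytest.approx(expected)


class TestSearch:
    def test_reverse_complement_copy_found(self):
        rec, truth, cds = _planted_cds(0)
        pool = [SequenceRecord("rc", simulate.reverse_complement(cds))]
        hits = search_homologs([rec], pool)
        assert len(hits) == 1
        assert hits[0].similarity == 1.0 and hits[0].frame < 0

    def test_strand_completeness(self):
        """Recovery is invariant under reverse-complementing the pool entry."""
        rec, truth, cds = _planted_cds(1)
        fwd = search_homologs([rec], [SequenceRecord("s", cds)])
        rev = search_homologs([rec], [SequenceRecord("s", simulate.reverse_complement(cds))])
        assert len(fwd) == len(rev) == 1
        assert fwd[0].similarity == rev[0].similarity
        # the rev hit's coordinates live on the reverse-complemented entry;
        # mirroring them back must recover the forward hit's interval
        L = len(cds)
        mirrored = (L - rev[0].subject_end + 1, L - rev[0].subject_start + 1)
        assert mirrored == (fwd[0].subject_start, fwd[0].subject_end)

    def test_mutated_homolog_recovered(self):
        """A homolog at ~70% amino-acid identity is still found."""
        rec, truth, _ = _planted_cds(2)
        rng = np.random.default_rng(7)
        letters = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        protein = list(truth.protein)
        for i in range(len(protein)):
            if rng.random() < 0.30:
                protein[i] = str(rng.choice(letters))
        mutated_cds = simulate.reverse_translate("".join(protein), rng)
        hits = search_homologs([rec], [SequenceRecord("mut", mutated_cds)])
        assert len(hits) == 1

    def test_random_pool_no_hits(self):
        rec, _, _ = _planted_cds(3)
        for s in range(20):
            rng = np.random.default_rng(500 + s)
            pool = [SequenceRecord(f"r{i}", simulate.random_dna(rng, 600))
                    for i in range(3)]
            assert search_homologs([rec], pool) == []

    def test_empty_pool_rejected(self):
        rec, _, _ = _planted_cds(4)
        with pytest.raises(ValueError):
            search_homologs([rec], [])


class TestAssembly:
    def test_two_overlapping_reads(self):
        rng = np.random.default_rng(3)
        source = simulate.random_dna(rng, 300)
        reads = [SequenceRecord("r1", source[:180]), SequenceRecord("r2", source[130:])]
        contigs = assemble_contigs(reads)
        assert len(contigs) == 1
        assert contigs[0].consensus == source

    def test_disjoint_reads_stay_separate(self):
        rng = np.random.default_rng(4)
        reads = [SequenceRecord("r1", simulate.random_dna(rng, 100)),
                 SequenceRecord("r2", simulate.random_dna(rng, 100))]
        assert len(assemble_contigs(reads)) == 2

    def test_error_free_coverage_reassembles_source(self):
        """Error-free reads at coverage >= 5 rebuild the source exactly
        (up to orientation), across seeds."""
        for seed in range(6):
            rng = np.random.default_rng(900 + seed)
            source = simulate.random_dna(rng, 700)
            reads = simulate.generate_ests(SequenceRecord("src", source),
                                           coverage=6, read_len=150, seed=seed)
            contigs = assemble_contigs(reads)
            assert len(contigs) == 1
            consensus = contigs[0].consensus
            assert consensus == source or \
                simulate.reverse_complement(consensus) == source

    def test_members_map_to_consensus(self):
        rng = np.random.default_rng(5)
        source = simulate.random_dna(rng, 400)
        reads = simulate.generate_ests(SequenceRecord("src", source),
                                       coverage=5, read_len=120, seed=1)
        contig = assemble_contigs(reads)[0]
        assert len(contig.consensus) >= max(len(r.sequence) for r in reads)
        depth = contig.depth_profile
        assert depth.min() >= 1


class TestValidation:
    def test_synthetic_hsf_accepted(self):
        rec, truth, cds = _planted_cds(5)
        contig = mining.Contig("c1", cds, {"c1": 0})
        accepted, reason = validate_full_length(contig, [rec])
        assert accepted, reason

    def test_hrab_deleted_rejected(self):
        rec, truth, _ = _planted_cds(6)
        # delete everything C-terminal of the DBD: no heptad blocks remain
        protein = truth.protein[: truth.dbd[1] + 3]
        rng = np.random.default_rng(11)
        cds = simulate.reverse_translate(protein, rng)
        contig = mining.Contig("c1", cds, {"c1": 0})
        accepted, reason = validate_full_length(contig, [rec])
        assert not accepted and "HR-A/B" in reason

    def test_forty_of_fortythree_accepted(self):
        """Planted family: contigs lacking the two core structures drop out."""
        refs = []
        contigs = []
        for i in range(8):
            rec, truth, cds = _planted_cds(20 + i, klass="ABC"[i % 3])
            refs.append(rec)
            contigs.append(mining.Contig(f"good{i}", cds, {}))
        # three decoys: DBD-free low-complexity coding sequence
        rng = np.random.default_rng(99)
        for j in range(3):
            protein = "".join(rng.choice(np.array(list("AGSTNQPHED")), 250))
            contigs.append(mining.Contig(f"bad{j}",
                                         simulate.reverse_translate(protein, rng), {}))
        accepted = [c for c in contigs
                    if validate_full_length(c, refs)[0]]
        assert len(accepted) == 8
        assert all(c.id.startswith("good") for c in accepted)

    def test_best_orf_finds_planted_frame(self):
        rec, truth, cds = _planted_cds(7)
        orf = best_orf(simulate.reverse_complement(cds))
        assert truth.protein in orf or orf in truth.protein
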