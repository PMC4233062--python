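"""Distances, NJ reconstruction, bootstrap, substitution counting."""
import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hsfkit import evolution, simulate
from hsfkit.evolution import (DistanceMatrix, bipartitions, bootstrap_support,
                              build_nj, count_substitutions_ng, distance_matrix,
                              mutation_frequency, p_distance_pairwise_deletion,
                              poisson_correct)
from hsfkit.io import SequenceRecord

import oracles


class TestDistances:
    def test_p_distance_basics(self):
        assert p_distance_pairwise_deletion("AAAA", "AAAA") == 0.0
        assert p_distance_pairwise_deletion("AAAA", "AAAT") == 0.25

    def test_pairwise_deletion_denominator(self):
        # the gap column drops, leaving 3 compared columns, 0 mismatches
        assert p_distance_pairwise_deletion("AA-A", "AATA") == 0.0
        assert p_distance_pairwise_deletion("AC-A", "AGTA") == pytest.approx(1 / 3)

    def test_poisson_known_values(self):
        assert poisson_correct(0.0) == 0.0
        assert poisson_correct(0.1) == pytest.approx(0.105361, abs=1e-6)
        assert poisson_correct(1.0) is None

    @given(st.floats(min_value=1e-6, max_value=0.999))
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_poisson_monotone_and_dominating(self, p):
        d = poisson_correct(p)
        assert d >= p
        assert poisson_correct(min(p * 1.01, 0.9999)) > d

    def test_matrix_invariants_enforced(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [2.0, 0.0]]))
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[0.5, 1.0], [1.0, 0.0]]))

    def test_complete_vs_pairwise_deletion(self):
        aln = {"a": "ACGTAC", "b": "ACG-AC", "c": "ACGTAT"}
        pw = distance_matrix(aln, deletion="pairwise", correction=None)
        cd = distance_matrix(aln, deletion="complete", correction=None)
        ia, ic = pw.labels.index("a"), pw.labels.index("c")
        assert pw.matrix[ia, ic] == pytest.approx(1 / 6)  # gap column kept for a-c
        assert cd.matrix[ia, ic] == pytest.approx(1 / 5)  # dropped for everyone


class TestNeighborJoining:
    def test_four_taxa_additive_topology(self):
        # additive distances on ((a,b),(c,d)) with known branch lengths
        D = np.array([[0, 3, 8, 9],
                      [3, 0, 9, 10],
                      [8, 9, 0, 5],
                      [9, 10, 5, 0]], float)
        result = build_nj(DistanceMatrix(["a", "b", "c", "d"], D))
        expected = {frozenset((frozenset("ab"), frozenset("cd")))}
        assert bipartitions(result.tree) == expected
        assert not result.clamped_negative

    def test_three_taxa_closed_form(self):
        D = np.array([[0, 5, 9], [5, 0, 8], [9, 8, 0]], float)
        result = build_nj(DistanceMatrix(["a", "b", "c"], D))
        # la = (5+9-8)/2 = 3, lb = (5+8-9)/2 = 2, lc = (9+8-5)/2 = 6
        assert result.newick == "(a:3,b:2,c:6);"

    def test_recovers_generating_topology_up_to_eight_taxa(self):
        rng = np.random.default_rng(17)
        for n in (4, 5, 6, 7, 8):
            for rep in range(5):
                labels = [f"t{i}" for i in range(n)]
                dist, true_parts = oracles.random_additive_tree(labels, rng)
                result = build_nj(DistanceMatrix(labels, dist))
                assert bipartitions(result.tree) == true_parts

    def test_agrees_with_exhaustive_search_five_taxa(self):
        """NJ topology equals the least-squares best over all 15 topologies."""
        rng = np.random.default_rng(18)
        labels = [f"t{i}" for i in range(5)]
        for rep in range(5):
            dist, _ = oracles.random_additive_tree(labels, rng)
            nj_parts = bipartitions(build_nj(DistanceMatrix(labels, dist)).tree)
            assert nj_parts == oracles.best_topology_least_squares(labels, dist)

    def test_ultrametric_ties_deterministic(self):
        D = np.ones((4, 4)) - np.eye(4)
        dm = DistanceMatrix(["a", "b", "c", "d"], D)
        assert build_nj(dm).newick == build_nj(dm).newick

    def test_agrees_with_skbio(self):
        """Independent NJ implementation recovers the same topology."""
        import skbio
        rng = np.random.default_rng(19)
        labels = [f"t{i}" for i in range(6)]
        dist, _ = oracles.random_additive_tree(labels, rng)
        ours = bipartitions(build_nj(DistanceMatrix(labels, dist)).tree)
        sk_tree = skbio.tree.nj(skbio.DistanceMatrix(dist, labels))
        theirs = set()
        for node in sk_tree.non_tips():
            side = frozenset(t.name for t in node.tips())
            other = frozenset(labels) - side
            if len(side) >= 2 and len(other) >= 2:
                theirs.add(frozenset((side, other)))
        assert ours == theirs


class TestBootstrap:
    @staticmethod
    def _two_clade_alignment(n_cols=500, seed=23):
        rng = np.random.default_rng(seed)
        letters = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        anc1 = rng.choice(letters, n_cols)
        anc2 = anc1.copy()
        flip = rng.random(n_cols) < 0.3  # divergence between clades
        anc2[flip] = rng.choice(letters, int(flip.sum()))
        aln = {}
        for name, anc in [("a1", anc1), ("a2", anc1), ("b1", anc2), ("b2", anc2)]:
            seq = anc.copy()
            noise = rng.random(n_cols) < 0.01  # divergence within clades
            seq[noise] = rng.choice(letters, int(noise.sum()))
            aln[name] = "".join(seq)
        return aln

    def test_separating_edge_strongly_supported(self):
        aln = self._two_clade_alignment()
        result, support = bootstrap_support(aln, n_reps=200, seed=1)
        part = frozenset((frozenset(("a1", "a2")), frozenset(("b1", "b2"))))
        assert support[part] >= 0.95

    def test_zero_replicates_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_support({"a": "AC", "b": "AG", "c": "AT"}, n_reps=0)

    def test_same_seed_same_support(self):
        aln = self._two_clade_alignment()
        _, s1 = bootstrap_support(aln, n_reps=50, seed=9)
        _, s2 = bootstrap_support(aln, n_reps=50, seed=9)
        assert s1 == s2

    def test_relabeling_invariance(self):
        """Support is invariant under a permutation of taxon labels."""
        aln = self._two_clade_alignment()
        mapping = {"a1": "x1", "a2": "x2", "b1": "y1", "b2": "y2"}
        renamed = {mapping[k]: v for k, v in aln.items()}
        _, s1 = bootstrap_support(aln, n_reps=100, seed=3)
        _, s2 = bootstrap_support(renamed, n_reps=100, seed=3)

        def translate(part):
            return frozenset(frozenset(mapping[t] for t in side) for side in part)

        assert {translate(p): v for p, v in s1.items()} == s2


class TestNeiGojobori:
    def test_identical_cds(self):
        assert count_substitutions_ng("TTTAAA", "TTTAAA")[:2] == (0.0, 0.0)

    def test_hand_enumerated_codon(self):
        sd, nd, s, n = count_substitutions_ng("TTT", "TTC")
        assert (sd, nd) == (1.0, 0.0)
        assert s == pytest.approx(1 / 3)
        assert n == pytest.approx(3 - 1 / 3)

    def test_two_position_pathway_average(self):
        # TTT -> TTA (Phe->Leu, nonsyn) -> CTA (Leu->Leu, syn)
        # TTT -> CTT (Phe->Leu, nonsyn) -> CTA (Leu->Leu, syn)
        sd, nd, _, _ = count_substitutions_ng("TTT", "CTA")
        assert (sd, nd) == (1.0, 1.0)

    def test_planted_counts_recovered(self):
        rng = np.random.default_rng(41)
        _, truth = simulate.generate_hsf_protein("B", "B2", seed=8)
        cds = SequenceRecord("c", simulate.reverse_translate(truth.protein, rng))
        for n_syn, n_nonsyn in [(0, 0), (4, 0), (0, 6), (3, 7)]:
            a, b = simulate.generate_ortholog_pair(cds, n_syn, n_nonsyn,
                                                   seed=n_syn * 10 + n_nonsyn)
            sd, nd, _, _ = count_substitutions_ng(a.sequence, b.sequence)
            assert (sd, nd) == (float(n_syn), float(n_nonsyn))

    def test_length_contracts(self):
        with pytest.raises(ValueError):
            count_substitutions_ng("TTT", "TTTAAA")
        with pytest.raises(ValueError):
            count_substitutions_ng("TTTA", "TTTA")


class TestMutationFrequency:
    def test_arithmetic_example(self):
        # one pair, 999 sites, 4 synonymous + 6 non-synonymous changes
        rng = np.random.default_rng(43)
        _, truth = simulate.generate_hsf_protein("A", "A2", seed=9)
        cds = SequenceRecord("c", simulate.reverse_translate(truth.protein, rng))
        a, b = simulate.generate_ortholog_pair(cds, 4, 6, seed=5)
        stats = mutation_frequency([(a.sequence, b.sequence)])
        sites = stats.sites_compared
        assert stats.total_freq == pytest.approx(10 / sites)
        assert stats.syn_freq == pytest.approx(4 / sites)
        assert stats.nonsyn_freq == pytest.approx(6 / sites)

    def test_zero_divergence(self):
        stats = mutation_frequency([("TTTAAAGGG", "TTTAAAGGG")])
        assert (stats.total_freq, stats.syn_freq, stats.nonsyn_freq) == (0, 0, 0)

    def test_shared_denominator_identity(self):
        """syn + nonsyn frequencies sum exactly to the total frequency."""
        rng = np.random.default_rng(44)
        pairs = []
        for seed in range(6):
            _, truth = simulate.generate_hsf_protein("B", "B1", seed=seed + 50)
            cds = SequenceRecord("c", simulate.reverse_translate(truth.protein, rng))
            a, b = simulate.generate_ortholog_pair(
                cds, int(rng.integers(0, 6)), int(rng.integers(0, 8)), seed=seed)
            pairs.append((a.sequence, b.sequence))
        stats = mutation_frequency(pairs)
        assert stats.syn_freq + stats.nonsyn_freq == pytest.approx(
            stats.total_freq, abs=1e-12)
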