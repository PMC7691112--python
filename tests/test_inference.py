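"""Distance matrices, BIONJ, bootstrap supports and the ML adapter."""

import itertools

import numpy as np
import pytest

from corephylo import (
    Alignment,
    DistanceMatrix,
    MLBackendUnavailableError,
    bionj_from_alignment,
    bionj_tree,
    bipartitions,
    bootstrap_supports,
    distance_matrix,
    external_ml_adapter,
    to_phylip,
    tts,
)


def _aln(*seqs, labels=None):
    labels = labels or [f"s{i}" for i in range(len(seqs))]
    return Alignment.from_strings(zip(labels, seqs))


class TestDistanceMatrix:
    def test_identical_sequences_zero(self):
        dm = distance_matrix(_aln("ACGT", "ACGT", "ACGT"))
        assert np.allclose(dm.values, 0.0)

    def test_jc69_closed_form(self):
        # 10% raw difference between s0 and s1
        a = "A" * 1000
        b = "G" * 100 + "A" * 900
        dm = distance_matrix(_aln(a, b, a))
        assert dm.values[0, 1] == pytest.approx(-0.75 * np.log(1 - 0.4 / 3))
        assert dm.values[0, 1] == pytest.approx(0.10732, abs=1e-5)

    def test_raw_is_p_distance(self):
        a = "A" * 10
        b = "G" * 3 + "A" * 7
        dm = distance_matrix(_aln(a, b, a), correction="raw")
        assert dm.values[0, 1] == pytest.approx(0.3)

    def test_saturated_pair_capped_with_warning(self, caplog):
        a = "A" * 100
        b = "G" * 75 + "C" * 25  # p = 1.0
        with caplog.at_level("WARNING"):
            dm = distance_matrix(_aln(a, b, a))
        cap = -0.75 * np.log(1 - 4 * 0.74 / 3)
        assert dm.values[0, 1] == pytest.approx(cap)
        assert "saturated" in caplog.text

    def test_no_comparable_sites_names_the_pair(self):
        with pytest.raises(ValueError, match="s0.*s1"):
            distance_matrix(_aln("AANN", "NNAA", "AAAA"))


def _additive_matrix(newick_tree):
    """Path-length matrix of a tree (independent route: dendropy's own
    phylogenetic distance matrix)."""
    pdm = newick_tree.phylogenetic_distance_matrix()
    labels = sorted(t.label for t in newick_tree.taxon_namespace)
    taxa = {t.label: t for t in newick_tree.taxon_namespace}
    n = len(labels)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d[i, j] = d[j, i] = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
    return DistanceMatrix(tuple(labels), d)


class TestBIONJ:
    def test_additive_four_taxon_recovers_tree_exactly(self):
        from corephylo import read_newick

        true = read_newick("((A:1,B:2):1,(C:3,D:4));")
        dm = _additive_matrix(true)
        # hand-solved: d(A,B)=3, d(A,C)=5, d(A,D)=6, d(B,C)=6, d(B,D)=7, d(C,D)=7
        assert dm.values[0, 1] == pytest.approx(3)
        assert dm.values[2, 3] == pytest.approx(7)
        est = bionj_tree(dm)
        assert bipartitions(est) == bipartitions(true)
        est_dm = _additive_matrix(est)
        assert np.allclose(est_dm.values, dm.values, atol=1e-9)

    def test_all_15_five_taxon_topologies_recovered(self):
        """NJ consistency on additive matrices, exhaustively over every
        unrooted 5-taxon topology with random positive branch lengths."""
        from corephylo import read_newick

        rng = np.random.default_rng(17)
        # enumerate: insert D on one of the 3 edges of the (A,B,C) star,
        # then E on one of the resulting 5 edges -> all 15 topologies
        count = 0
        for d_pos in "ABC":
            for e_pos in ["A", "B", "C", "D", "X"]:  # X = internal edge made by D
                count += 1
                bl = {k: rng.uniform(0.5, 3.0) for k in "ABCDEXY"}
                parts = {k: f"{k}:{bl[k]:.6f}" for k in "ABC"}
                ld, le = f"D:{bl['D']:.6f}", f"E:{bl['E']:.6f}"
                x, y = f"{bl['X']:.6f}", f"{bl['Y']:.6f}"
                if e_pos == d_pos:
                    sub = f"(({parts[d_pos]},{le}):{y},{ld}):{x}"
                elif e_pos == "D":
                    sub = f"({parts[d_pos]},({ld},{le}):{y}):{x}"
                elif e_pos == "X":
                    sub = f"(({parts[d_pos]},{ld}):{x},{le}):{y}"
                else:
                    sub = f"({parts[d_pos]},{ld}):{x}"
                    parts[e_pos] = f"({parts[e_pos]},{le}):{y}"
                parts[d_pos] = sub
                true = read_newick(f"({parts['A']},{parts['B']},{parts['C']});")
                est = bionj_tree(_additive_matrix(true))
                assert bipartitions(est) == bipartitions(true), (d_pos, e_pos)
        assert count == 15

    def test_matches_independent_nj_oracle_on_additive_input(self):
        """scikit-bio's neighbor joining as the independent implementation
        on the same additive matrix."""
        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj

        from corephylo import read_newick

        true = read_newick("(((A:1,B:1.5):0.7,C:2):0.5,(D:1,E:2):0.8,F:1.2);")
        dm = _additive_matrix(true)
        sk_tree = read_newick(str(nj(SkbioDM(dm.values, ids=list(dm.labels)))))
        est = bionj_tree(dm)
        assert bipartitions(est) == bipartitions(sk_tree) == bipartitions(true)

    def test_degenerate_equal_distances_runs(self):
        labels = tuple("ABCDE")
        d = np.ones((5, 5)) - np.eye(5)
        tree = bionj_tree(DistanceMatrix(labels, d))
        assert sorted(l for l in (leaf.taxon.label for leaf in tree.leaf_node_iter())) \
            == list(labels)

    def test_clonal_simulation_recovers_generating_topology(
        self, species20, clonal_result
    ):
        est = bionj_from_alignment(clonal_result.alignment)
        assert tts(species20.tree, est).score == 100.0

    def test_asymmetric_matrix_rejected(self):
        d = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0.0]])
        with pytest.raises(ValueError):
            DistanceMatrix(("A", "B", "C"), d)


def _synapomorphy_alignment(reps=200):
    """Columns are perfect clade indicators of ((A,B),(C,D),(E,F))-style
    groups on 8 taxa; every bipartition has overwhelming support."""
    labels = list("ABCDEFGH")
    clades = [
        "AB", "CD", "EF", "GH", "ABCD", "EFGH",
    ]
    cols = []
    for clade in clades:
        cols.append(["T" if lab in clade else "A" for lab in labels])
    block = np.array(cols).T  # (taxa, sites)
    seqs = ["".join(row) * reps for row in block]
    return Alignment.from_strings(zip(labels, seqs))


class TestBootstrap:
    def test_perfect_signal_gives_full_support(self):
        aln = _synapomorphy_alignment()
        st = bootstrap_supports(aln, replicates=20, rng_seed=11)
        assert st.supports and all(v == 100.0 for v in st.supports.values())
        assert st.mean_support == 100.0

    def test_single_replicate_supports_are_binary(self, clonal_result):
        sub = clonal_result.alignment.take_sites(np.arange(2_000))
        st = bootstrap_supports(sub, replicates=1, rng_seed=0)
        assert set(st.supports.values()) <= {0.0, 100.0}

    def test_deterministic_given_seed(self, clonal_result):
        sub = clonal_result.alignment.take_sites(np.arange(2_000))
        a = bootstrap_supports(sub, replicates=10, rng_seed=5)
        b = bootstrap_supports(sub, replicates=10, rng_seed=5)
        assert a.supports == b.supports

    def test_invariant_to_taxon_order(self, clonal_result):
        sub = clonal_result.alignment.take_sites(np.arange(2_000))
        perm = np.random.default_rng(3).permutation(sub.n_sequences)
        shuffled = Alignment(
            tuple(sub.labels[i] for i in perm), sub.data[perm]
        )
        a = bootstrap_supports(sub, replicates=10, rng_seed=5)
        b = bootstrap_supports(shuffled, replicates=10, rng_seed=5)
        assert a.supports == b.supports

    def test_newick_export_carries_supports(self):
        st = bootstrap_supports(_synapomorphy_alignment(), replicates=5, rng_seed=2)
        assert "100" in st.newick_with_supports()


class TestMLAdapter:
    def test_missing_program_reports_unavailability(self, clonal_result):
        with pytest.raises(MLBackendUnavailableError, match="unavailable"):
            external_ml_adapter(
                clonal_result.alignment, program="no-such-ml-program"
            )

    def test_ml_recovers_clonal_topology(self):
        from corephylo import SimConfig, evolve, random_species

        sp = random_species(seed=77, n=13, length=20_000, divergence=0.015,
                            min_internal_branch=0.005)
        res = evolve(SimConfig(tree=sp.tree, params=sp.params, rho=0.0, rng_seed=4))
        ml = external_ml_adapter(res.alignment)
        assert tts(sp.tree, ml).score == 100.0

    def test_ml_and_distance_agree_at_low_recombination(self, species20):
        from corephylo import SimConfig, evolve

        res = evolve(SimConfig(tree=species20.tree, params=species20.params,
                               rho=0.2, rng_seed=8))
        ml_score = tts(species20.tree, external_ml_adapter(res.alignment)).score
        nj_score = tts(species20.tree, bionj_from_alignment(res.alignment)).score
        assert ml_score >= 80.0 and nj_score >= 80.0


def test_phylip_export_shape():
    dm = DistanceMatrix(("A", "B", "C"), np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0.0]]))
    text = to_phylip(dm)
    lines = text.strip().split("\n")
    assert lines[0] == "3" and lines[1].startswith("A")
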