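from __future__ import annotations

import math

import numpy as np
import pytest

import barcodeval as bv
from barcodeval.trees import SupportTree

from .oracles import (
    best_topology_by_least_squares,
    enumerate_unrooted_topologies,
    topology_bipartitions,
    tree_path_distances,
    _edges,
)


def aln(members, rows, locus="x"):
    return bv.LocusAlignment(locus, members, rows)


class TestPDistance:
    @pytest.mark.parametrize(
        "a, b, expected, comparable",
        [
            ("ACGT", "ACGT", 0.0, 4),
            ("ACGT", "AGGT", 0.25, 4),
            ("AC-T", "ACGT", 0.0, 3),
            ("ACNT", "ACGT", 0.0, 3),
        ],
    )
    def test_pairwise_values(self, a, b, expected, comparable):
        D = bv.p_distance(aln(["q", "s"], [a, b]))
        assert D.values[0, 1] == pytest.approx(expected)
        assert D.comparable_sites[0, 1] == comparable

    def test_symmetry_zero_diagonal(self):
        D = bv.p_distance(aln(["a", "b", "c"], ["ACGT", "AGGT", "TTTT"]))
        assert np.allclose(D.values, D.values.T)
        assert np.all(np.diag(D.values) == 0)


class TestK2P:
    def test_identical_zero(self):
        D = bv.k2p_distance(aln(["a", "b"], ["ACGT", "ACGT"]))
        assert D.values[0, 1] == 0.0

    def test_one_transition_in_four_sites(self):
        # P=0.25, Q=0 -> d = -1/2 ln(0.5) = 0.3466
        D = bv.k2p_distance(aln(["a", "b"], ["ACGT", "GCGT"]))
        assert D.values[0, 1] == pytest.approx(-0.5 * math.log(0.5), abs=1e-4)

    def test_transversion_saturation_marked(self):
        # Q = 0.5 makes 1-2Q = 0: saturated
        D = bv.k2p_distance(aln(["a", "b"], ["AAGG", "CCGG"]))
        assert np.isnan(D.values[0, 1])

    def test_agrees_with_p_distance_at_small_divergence(self):
        rng = np.random.default_rng(5)
        base = rng.choice(list("ACGT"), 2000)
        for _ in range(10):
            other = base.copy()
            k = int(rng.integers(0, 30))
            idx = rng.choice(2000, k, replace=False)
            for i in idx:
                other[i] = rng.choice([c for c in "ACGT" if c != other[i]])
            A = aln(["a", "b"], ["".join(base), "".join(other)])
            p = bv.p_distance(A).values[0, 1]
            k2 = bv.k2p_distance(A).values[0, 1]
            if p < 0.02:
                assert abs(p - k2) < 0.01


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        D = bv.DistanceMatrix(
            ["a", "b", "c"],
            np.array([[0.0, 3.0, 4.0], [3.0, 0.0, 5.0], [4.0, 5.0, 0.0]]),
            np.full((3, 3), 100),
        )
        tree = bv.neighbor_joining(D)
        # star tree with branch lengths (ab+ac-bc)/2 = 1, 2, 3
        lengths = {
            lf.taxon.label: lf.edge.length for lf in tree.tree.leaf_node_iter()
        }
        assert lengths == pytest.approx({"a": 1.0, "b": 2.0, "c": 3.0})

    def test_four_taxa_additive_topology(self):
        # distances from ((A:1,B:2):1,(C:3,D:1)); AB|CD must be recovered
        leaves = ["A", "B", "C", "D"]
        vals = np.array(
            [
                [0, 3, 5, 3],
                [3, 0, 6, 4],
                [5, 6, 0, 4],
                [3, 4, 4, 0],
            ],
            dtype=float,
        )
        D = bv.DistanceMatrix(leaves, vals, np.full((4, 4), 100))
        tree = bv.neighbor_joining(D)
        assert tree.has_bipartition({"A", "B"})
        # exhaustive least-squares over the 3 unrooted quartet topologies
        assert tree.bipartitions() == best_topology_by_least_squares(vals, leaves)

    @pytest.mark.parametrize("n", [5, 6])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_additive_matrices_recover_generating_topology(self, n, seed):
        rng = np.random.default_rng(seed)
        leaves = [f"t{i}" for i in range(n)]
        topos = enumerate_unrooted_topologies(leaves)
        tree = topos[int(rng.integers(len(topos)))]
        lengths = {frozenset(e): float(rng.uniform(0.5, 2.0)) for e in _edges(tree)}
        D = tree_path_distances(tree, lengths, leaves)
        nj = bv.neighbor_joining(
            bv.DistanceMatrix(leaves, D, np.full((n, n), 100))
        )
        assert nj.bipartitions() == topology_bipartitions(tree, leaves)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        leaves = [f"t{i}" for i in range(6)]
        topos = enumerate_unrooted_topologies(leaves)
        tree = topos[10]
        lengths = {frozenset(e): float(rng.uniform(0.5, 2.0)) for e in _edges(tree)}
        D = tree_path_distances(tree, lengths, leaves)
        perm = rng.permutation(6)
        D2 = D[np.ix_(perm, perm)]
        leaves2 = [leaves[i] for i in perm]
        t1 = bv.neighbor_joining(bv.DistanceMatrix(leaves, D, np.full((6, 6), 10)))
        t2 = bv.neighbor_joining(bv.DistanceMatrix(leaves2, D2, np.full((6, 6), 10)))
        assert t1.bipartitions() == t2.bipartitions()

    def test_matches_independent_nj_implementation(self):
        skbio = pytest.importorskip("skbio")
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(11)
        leaves = [f"t{i}" for i in range(8)]
        # noisy but tree-like distances: random additive + jitter
        base = rng.uniform(0.5, 2.0, (8, 8))
        D = (base + base.T) / 2
        np.fill_diagonal(D, 0.0)
        sk_tree = skbio_nj(skbio.DistanceMatrix(D, ids=leaves))
        ours = bv.neighbor_joining(
            bv.DistanceMatrix(leaves, D, np.full((8, 8), 10))
        )
        sk_bips = set()
        for node in sk_tree.non_tips():
            side = frozenset(t.name for t in node.tips())
            if 2 <= len(side) <= 6:
                sk_bips.add(ours.canonical(side))
        assert sk_bips == ours.bipartitions()

    def test_undefined_pairs_rejected(self):
        vals = np.array([[0, np.nan, 1], [np.nan, 0, 1], [1, 1, 0.0]])
        comp = np.array([[4, 0, 4], [0, 4, 4], [4, 4, 4]])
        with pytest.raises(bv.ValidationError, match="undefined"):
            bv.neighbor_joining(bv.DistanceMatrix(["a", "b", "c"], vals, comp))


class TestBootstrap:
    def make_clean_alignment(self):
        # two clearly separated pairs: AB|CD signal in every column
        rows = {
            "a1": "A" * 600,
            "a2": "A" * 590 + "G" * 10,
            "b1": "C" * 600,
            "b2": "C" * 590 + "T" * 10,
        }
        return aln(list(rows), list(rows.values()))

    def test_saturated_signal_gives_full_support(self):
        A = self.make_clean_alignment()
        tree = bv.nj_with_support(A, replicates=100, seed=0, model="p")
        assert tree.support_for({"a1", "a2"}) == 100.0

    def test_supports_in_range_and_deterministic(self):
        rng = np.random.default_rng(2)
        base = rng.choice(list("ACGT"), 200)
        rows = []
        for _ in range(6):
            row = base.copy()
            idx = rng.choice(200, 20, replace=False)
            row[idx] = rng.choice(list("ACGT"), 20)
            rows.append("".join(row))
        A = aln([f"t{i}" for i in range(6)], rows)
        t1 = bv.nj_with_support(A, replicates=50, seed=7)
        t2 = bv.nj_with_support(A, replicates=50, seed=7)
        assert t1.support == t2.support
        assert all(0 <= v <= 100 for v in t1.support.values())

    def test_replicates_must_be_positive(self):
        A = self.make_clean_alignment()
        base = bv.neighbor_joining(bv.p_distance(A))
        with pytest.raises(bv.ValidationError):
            bv.bootstrap_support(A, base, replicates=0)

    def test_partitioned_resampling_stays_within_blocks(self):
        # one invariant partition + one variable partition: with partitioned
        # resampling every replicate keeps exactly 100 variable columns
        A = aln(["a", "b", "c", "d"],
                ["A" * 100 + "A" * 100,
                 "A" * 100 + "C" * 100,
                 "A" * 100 + "G" * 100,
                 "A" * 100 + "T" * 100])
        base = bv.neighbor_joining(bv.p_distance(A))
        res = bv.bootstrap_support(
            A, base, replicates=20, seed=1, partitions=[(0, 100), (100, 200)],
            model="p",
        )
        assert res.redrawn == 0
        assert all(0 <= v <= 100 for v in res.tree.support.values())


class TestSupportTreeNewick:
    def test_newick_round_trip_supports(self):
        st = bv.nj_with_support(
            aln(["a1", "a2", "b1", "b2"],
                ["AAAA" * 50, "AAAA" * 50, "CCCC" * 50, "CCCC" * 50]),
            replicates=10, seed=0, model="p",
        )
        back = SupportTree.from_newick(st.newick())
        assert back.support_for({"a1", "a2"}) == st.support_for({"a1", "a2"})


class TestIntraspecificVariation:
    def make_dataset(self, rows_by_id, plots):
        recs = [
            bv.SpecimenRecord(sid, "Alpha one", "Alpha", "Fam1", plots[sid])
            for sid in rows_by_id
        ]
        A = aln(list(rows_by_id), list(rows_by_id.values()), locus="rbcL")
        return bv.Dataset(recs, {"rbcL": A})

    def test_identical_conspecifics_no_variable_sites(self):
        ds = self.make_dataset(
            {"x": "ACGT" * 25, "y": "ACGT" * 25}, {"x": "BB", "y": "BB"}
        )
        (v,) = bv.intraspecific_variation(ds, "rbcL")
        assert v.n_variable_sites == 0

    def test_single_between_plot_difference(self):
        seq = "A" * 100
        ds = self.make_dataset(
            {"x": seq, "y": "C" + seq[1:]}, {"x": "BB", "y": "JJYL"}
        )
        (v,) = bv.intraspecific_variation(ds, "rbcL")
        assert v.n_variable_sites == 1
        assert v.n_between_plot_only == 1
        assert v.n_within_plot == 0

    def test_within_plot_variation_classified(self):
        seq = "A" * 100
        ds = self.make_dataset(
            {"x": seq, "y": "C" + seq[1:], "z": seq},
            {"x": "BB", "y": "BB", "z": "JJYL"},
        )
        (v,) = bv.intraspecific_variation(ds, "rbcL")
        assert v.n_within_plot == 1 and v.n_between_plot_only == 0

    def test_plot_structured_divergence_shows_between_plot_excess(self):
        # generator with extra between-plot divergence: between-plot-only
        # variable sites dominate within-plot ones
        cfg = bv.SimConfig(
            n_families=2, genera_per_family=2, species_per_genus=2,
            samples_per_species=4,
            loci=(bv.LocusConfig("rbcL", 1500, intra_species_height=0.0005),),
            plots=(("BB", 1.0), ("JJYL", 1.0)),
            misid_rate=0.0, between_plot_extra=0.004, seed=2,
        )
        between = within = 0
        for seed in range(5):
            ds, _ = bv.generate_dataset(
                bv.SimConfig(**{**cfg.__dict__, "seed": seed})
            )
            for v in bv.intraspecific_variation(ds, "rbcL"):
                between += v.n_between_plot_only
                within += v.n_within_plot
        assert between > within
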