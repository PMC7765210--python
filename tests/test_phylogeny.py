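"""Distances, neighbor joining, bootstrap and progressive alignment."""

import networkx as nx
import numpy as np
import pytest

import loxminer as lm
from loxminer.io_formats import SequenceRecord as SR
from loxminer.phylogeny import DistanceMatrix


def random_tree_matrix(rng, n):
    """A random unrooted binary tree and its (additive) leaf distance matrix.

    Built edge by edge with networkx — an oracle independent of the NJ code.
    """
    G = nx.Graph()
    center = "i0"
    for leaf in ("t0", "t1", "t2"):
        G.add_edge(center, leaf, w=float(rng.uniform(0.1, 1.0)))
    next_internal = 1
    for k in range(3, n):
        u, v = list(G.edges())[int(rng.integers(0, G.number_of_edges()))]
        w = G[u][v]["w"]
        G.remove_edge(u, v)
        mid = f"i{next_internal}"
        next_internal += 1
        split = float(rng.uniform(0.2, 0.8))
        G.add_edge(u, mid, w=w * split)
        G.add_edge(mid, v, w=w * (1 - split))
        G.add_edge(mid, f"t{k}", w=float(rng.uniform(0.1, 1.0)))
    leaves = sorted(x for x in G.nodes if x.startswith("t"))
    lengths = dict(nx.all_pairs_dijkstra_path_length(G, weight="w"))
    mat = np.zeros((len(leaves), len(leaves)))
    for i, a in enumerate(leaves):
        for j, b in enumerate(leaves):
            if i != j:
                mat[i, j] = lengths[a][b]
    bipartitions = set()
    full = set(leaves)
    ref = min(full)
    for u, v in G.edges():
        H = G.copy()
        H.remove_edge(u, v)
        side = {x for x in nx.node_connected_component(H, u)
                if x.startswith("t")}
        if 1 < len(side) < len(full) - 1:
            bipartitions.add(frozenset(side if ref not in side
                                       else full - side))
    return DistanceMatrix(ids=leaves, values=mat, model="additive"), bipartitions


class TestDistances:
    def test_identical_sequences_zero(self):
        msa = [SR("a", "MKLV", "protein"), SR("b", "MKLV", "protein")]
        dm = lm.distances_from_alignment(msa)
        assert dm.values[0, 1] == 0.0

    def test_poisson_correction_at_half(self):
        msa = [SR("a", "AAAA", "protein"), SR("b", "AAGG", "protein")]
        dm = lm.distances_from_alignment(msa, model="poisson")
        assert dm.values[0, 1] == pytest.approx(-np.log(0.5), abs=1e-12)

    def test_pairwise_gap_deletion_matches_column_oracle(self, rng):
        aas = "ACDE-"
        for _ in range(20):
            seqs = ["".join(aas[i] for i in rng.integers(0, 5, size=40))
                    for _ in range(4)]
            msa = [SR(f"s{k}", s, "protein") for k, s in enumerate(seqs)]
            try:
                dm = lm.distances_from_alignment(msa, model="p-distance")
            except ValueError:
                continue  # no comparable columns for some pair
            for i in range(4):
                for j in range(i + 1, 4):
                    cols = [(x, y) for x, y in zip(seqs[i], seqs[j])
                            if x != "-" and y != "-"]
                    p = sum(x != y for x, y in cols) / len(cols)
                    assert dm.values[i, j] == pytest.approx(p)

    def test_saturated_pair_is_error_naming_pair(self):
        msa = [SR("aa", "AAAA", "protein"), SR("bb", "GGGG", "protein")]
        with pytest.raises(ValueError, match="aa.*bb"):
            lm.distances_from_alignment(msa, model="poisson")


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        d = np.array([[0.0, 0.3, 0.5],
                      [0.3, 0.0, 0.6],
                      [0.5, 0.6, 0.0]])
        tree = lm.neighbor_joining(DistanceMatrix(["a", "b", "c"], d))
        lengths = {child.name: blen for child, blen in tree.root.children}
        assert lengths["a"] == pytest.approx((0.3 + 0.5 - 0.6) / 2)
        assert lengths["b"] == pytest.approx((0.3 + 0.6 - 0.5) / 2)
        assert lengths["c"] == pytest.approx((0.5 + 0.6 - 0.3) / 2)

    def test_fewer_than_three_taxa_error(self):
        d = np.array([[0.0, 0.1], [0.1, 0.0]])
        with pytest.raises(ValueError):
            lm.neighbor_joining(DistanceMatrix(["a", "b"], d))

    def test_recovers_constructed_four_taxon_tree(self, rng):
        dm, bps = random_tree_matrix(rng, 4)
        tree = lm.neighbor_joining(dm)
        assert tree.bipartitions() == bps
        got = tree.leaf_distances()
        assert np.allclose(got.values, dm.values, atol=1e-9)

    def test_recovers_random_additive_matrices_exactly(self, rng):
        for n in (5, 8, 12):
            for _ in range(5):
                dm, bps = random_tree_matrix(rng, n)
                tree = lm.neighbor_joining(dm)
                assert tree.bipartitions() == bps
                assert np.allclose(tree.leaf_distances().values, dm.values,
                                   atol=1e-8)
                assert tree.n_edges() == 2 * n - 3

    def test_negative_estimates_clamped_and_flagged(self):
        # a decidedly non-additive matrix forces a negative branch estimate
        d = np.array([[0.0, 0.1, 1.0, 1.0],
                      [0.1, 0.0, 1.0, 1.0],
                      [1.0, 1.0, 0.0, 0.05],
                      [1.0, 1.0, 0.05, 0.0]])
        tree = lm.neighbor_joining(DistanceMatrix(list("abcd"), d))
        def lengths(node):
            out = []
            for child, blen in node.children:
                out.append(blen)
                out.extend(lengths(child))
            return out
        assert all(b >= 0 for b in lengths(tree.root))


class TestBootstrap:
    def _two_clade_msa(self, rng, per_clade=4, length=300):
        aas = "ACDEFGHIKLMNPQRSTVWY"
        base_a = "".join(aas[i] for i in rng.integers(0, 20, size=length))
        base_b = "".join(
            aas[(aas.index(c) + 1 + int(rng.integers(0, 19))) % 20]
            if rng.random() < 0.5 else c
            for c in base_a)
        msa = []
        for k in range(per_clade):
            for name, base in (("A", base_a), ("B", base_b)):
                seq = list(base)
                for _ in range(3):
                    pos = int(rng.integers(0, length))
                    seq[pos] = aas[int(rng.integers(0, 20))]
                msa.append(SR(f"{name}{k}", "".join(seq), "protein"))
        return msa

    def test_deep_clades_get_high_support(self, rng):
        msa = self._two_clade_msa(rng)
        tree = lm.bootstrap_support(msa, replicates=100, seed=42)
        clade_a = frozenset(r.id for r in msa if r.id.startswith("A"))
        full = {r.id for r in msa}
        key = clade_a if min(full) not in clade_a else frozenset(full - clade_a)
        assert tree.supports[key] >= 95.0

    def test_same_seed_identical_supports(self, rng):
        msa = self._two_clade_msa(rng)
        t1 = lm.bootstrap_support(msa, replicates=25, seed=7)
        t2 = lm.bootstrap_support(msa, replicates=25, seed=7)
        assert t1.supports == t2.supports

    def test_supports_invariant_to_taxon_order(self, rng):
        msa = self._two_clade_msa(rng)
        t1 = lm.bootstrap_support(msa, replicates=25, seed=7)
        t2 = lm.bootstrap_support(list(reversed(msa)), replicates=25, seed=7)
        shared = set(t1.supports) & set(t2.supports)
        assert shared  # the deep split is found either way
        clade_a = frozenset(r.id for r in msa if r.id.startswith("A"))
        full = {r.id for r in msa}
        key = clade_a if min(full) not in clade_a else frozenset(full - clade_a)
        assert key in shared

    def test_identical_sequences_degenerate(self):
        msa = [SR(f"s{i}", "MKLVMKLV", "protein") for i in range(4)]
        tree = lm.bootstrap_support(msa, replicates=10, seed=1)
        assert tree.degenerate

    def test_subfamily_clades_match_manifest(self, default_bundle,
                                             bundle_proteins):
        fam = default_bundle.manifest[default_bundle.manifest["role"] == "true"]
        msa = lm.align_progressive(
            [bundle_proteins[g] for g in fam["gene_id"]])
        tree = lm.neighbor_joining(lm.distances_from_alignment(msa))
        nine = frozenset(fam[fam["subfamily"] == "9-LOX"]["gene_id"])
        full = set(fam["gene_id"])
        key = nine if min(full) not in nine else frozenset(full - nine)
        assert key in tree.bipartitions()


class TestProgressiveAlignment:
    def test_identical_pair_gap_free(self):
        recs = [SR("a", "MKLVWY", "protein"), SR("b", "MKLVWY", "protein")]
        msa = lm.align_progressive(recs)
        assert [r.sequence for r in msa] == ["MKLVWY", "MKLVWY"]

    def test_single_indel_gets_one_gap(self):
        recs = [SR("a", "MKLVAAAWPQRSTNEF", "protein"),
                SR("b", "MKLVAAAPQRSTNEF", "protein")]
        msa = lm.align_progressive(recs)
        assert msa[0].sequence == "MKLVAAAWPQRSTNEF"
        assert msa[1].sequence.count("-") == 1
        assert msa[1].sequence.replace("-", "") == recs[1].sequence

    def test_degapping_restores_inputs(self, rng):
        aas = "ACDEFGHIKLMNPQRSTVWY"
        recs = [
            SR(f"s{i}",
               "".join(aas[j] for j in rng.integers(0, 20,
                                                    size=rng.integers(30, 60))),
               "protein")
            for i in range(6)
        ]
        msa = lm.align_progressive(recs)
        lengths = {len(r.sequence) for r in msa}
        assert len(lengths) == 1
        by_id = {r.id: r.sequence for r in msa}
        for rec in recs:
            assert by_id[rec.id].replace("-", "") == rec.sequence
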