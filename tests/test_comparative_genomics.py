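"""Global alignment, identity matrices, intron phases, duplication calls."""

from functools import lru_cache

import numpy as np
import pytest

import loxminer as lm
from loxminer.comparative_genomics import alignment_score
from loxminer.io_formats import GeneModel, SequenceRecord as SR


def brute_force_score(a, b, score_fn, gap_open, gap_extend):
    """Exhaustive affine-gap global alignment by memoized recursion over all
    (match / gap-in-a / gap-in-b) move sequences. Independent of the DP
    engine under test."""
    NEG = float("-inf")

    @lru_cache(maxsize=None)
    def rec(i, j, prev):
        if i == len(a) and j == len(b):
            return 0.0
        best = NEG
        if i < len(a) and j < len(b):
            best = max(best, score_fn(a[i], b[j]) + rec(i + 1, j + 1, 0))
        if i < len(a):
            cost = gap_extend if prev == 1 else gap_open
            best = max(best, -cost + rec(i + 1, j, 1))
        if j < len(b):
            cost = gap_extend if prev == 2 else gap_open
            best = max(best, -cost + rec(i, j + 1, 2))
        return best

    return rec(0, 0, 0)


class TestGlobalAlign:
    def test_identical_sequences(self):
        ident, simil, length = lm.global_align(
            SR("a", "MKLV", "protein"), SR("b", "MKLV", "protein"))
        assert ident == simil == 100.0 and length == 4

    def test_single_mismatch_no_gaps(self):
        ident, _, length = lm.global_align(
            SR("a", "ACGT", "nucleotide"), SR("b", "ACGA", "nucleotide"))
        assert ident == pytest.approx(75.0) and length == 4

    def test_mixed_alphabets_error(self):
        with pytest.raises(ValueError):
            lm.global_align(SR("a", "ACGT", "nucleotide"),
                            SR("b", "ACGT", "protein"))

    def test_ambiguity_codes_do_not_count_as_identity(self):
        ident, _, _ = lm.global_align(
            SR("a", "ACGN", "nucleotide"), SR("b", "ACGN", "nucleotide"))
        assert ident == pytest.approx(75.0)

    def test_score_equals_bruteforce_all_short_binary_pairs(self):
        params = lm.AlignmentParams("NUC+5/-4", 16.0, 4.0, "nucleotide")
        def score(x, y):
            return 5.0 if x == y else -4.0
        strings = []
        for length in range(1, 5):
            for bits in range(2 ** length):
                strings.append("".join("AC"[(bits >> k) & 1]
                                       for k in range(length)))
        for a in strings:
            for b in strings:
                assert alignment_score(a, b, params) == pytest.approx(
                    brute_force_score(a, b, score, 16.0, 4.0))

    def test_score_equals_bruteforce_random_protein_pairs(self, rng):
        from Bio.Align import substitution_matrices
        params = lm.AlignmentParams.protein_default()
        blosum = substitution_matrices.load("BLOSUM62")
        def score(x, y):
            return float(blosum[x, y])
        aas = "ACDEFGHIKLMNPQRSTVWY"
        for _ in range(15):
            a = "".join(aas[i] for i in rng.integers(0, 20,
                                                     size=rng.integers(1, 6)))
            b = "".join(aas[i] for i in rng.integers(0, 20,
                                                     size=rng.integers(1, 6)))
            assert alignment_score(a, b, params) == pytest.approx(
                brute_force_score(a, b, score, 12.0, 2.0))


class TestIdentityMatrix:
    def test_two_identical_one_distinct(self):
        recs = [SR("a", "MKLVWYPQ", "protein"), SR("b", "MKLVWYPQ", "protein"),
                SR("c", "GGGGGGGG", "protein")]
        mat = lm.identity_matrix(recs)
        assert mat.identity.loc["a", "b"] == 100.0
        assert np.allclose(np.diag(mat.identity), 100.0)
        assert mat.identity.loc["a", "c"] < 50.0

    def test_symmetry_random_records(self, rng):
        aas = "ACDEFGHIKLMNPQRSTVWY"
        recs = [SR(f"r{i}", "".join(aas[j] for j in rng.integers(0, 20, 30)),
                   "protein") for i in range(10)]
        mat = lm.identity_matrix(recs)
        assert np.allclose(mat.identity.to_numpy(), mat.identity.to_numpy().T)
        assert np.allclose(mat.similarity.to_numpy(),
                           mat.similarity.to_numpy().T)


class TestIntronPhases:
    def test_single_exon_gene(self):
        model = GeneModel("g", "s", 1, 300, "+", exons=[(1, 300)])
        s = lm.intron_phases(model)
        assert s.intron_phases == () and s.intron_lengths == ()

    def test_two_exon_phase_arithmetic(self):
        # coding lengths 100 and 50: the intron falls 100 % 3 = 1 into a codon
        model = GeneModel("g", "s", 1, 250, "+",
                          exons=[(1, 100), (201, 250)])
        s = lm.intron_phases(model)
        assert s.exon_lengths == (100, 50)
        assert s.intron_phases == (1,)
        assert s.intron_lengths == (100,)

    def test_minus_strand_phases_follow_coding_order(self):
        # coding order is right to left on the minus strand
        model = GeneModel("g", "s", 1, 250, "-",
                          exons=[(1, 50), (201, 250), (101, 150)])
        s = lm.intron_phases(model)
        assert s.exon_lengths == (50, 50, 50)
        assert s.intron_phases == (50 % 3, 100 % 3)

    def test_cds_sum_not_codon_multiple_is_error(self):
        model = GeneModel("g", "s", 1, 100, "+", exons=[(1, 100)])
        with pytest.raises(ValueError):
            lm.intron_phases(model)

    def test_round_trip_against_written_gff3(self, default_bundle, tmp_path):
        paths = lm.write_bundle(default_bundle, tmp_path)
        reread = {m.gene_id: m for m in lm.read_gff3(paths["gff3"])}
        for model in default_bundle.genes:
            original = lm.intron_phases(model)
            recovered = lm.intron_phases(reread[model.gene_id])
            assert recovered == original
            # independent recomputation: cumulative coding length mod 3
            cum = np.cumsum(original.exon_lengths)[:-1]
            assert tuple(int(c) % 3 for c in cum) == original.intron_phases


class TestDuplications:
    def test_published_coordinates_and_identities(self):
        models = lm.datasets.splox_gene_models()
        pairs = lm.datasets.load_splox_pair_identities()
        ids = [m.gene_id for m in models]
        mat = lm.IdentityMatrix.from_pairs(
            ids,
            {(r.gene_a, r.gene_b): r.protein_identity
             for r in pairs.itertuples()},
            fill=50.0)
        calls = lm.detect_duplications(models, mat)
        tandem = sorted((c.members for c in calls if c.kind == "tandem"),
                        key=len)
        assert tandem == [("SpLOX1", "SpLOX2"), ("SpLOX6", "SpLOX7", "SpLOX8")]
        assert [c for c in calls if c.kind == "segmental"] == []

    def test_distant_genes_never_cluster(self):
        models = [GeneModel("a", "s1", 1, 1000, "+", exons=[(1, 1000)]),
                  GeneModel("b", "s1", 201_000, 202_000, "+",
                            exons=[(201_000, 202_000)])]
        mat = lm.IdentityMatrix.from_pairs(["a", "b"], {("a", "b"): 80.0})
        assert lm.detect_duplications(models, mat) == []

    def test_tandem_precedence_over_segmental(self):
        models = [GeneModel("a", "s1", 1, 1000, "+", exons=[(1, 1000)]),
                  GeneModel("b", "s1", 2000, 3000, "+", exons=[(2000, 3000)])]
        mat = lm.IdentityMatrix.from_pairs(["a", "b"], {("a", "b"): 95.0})
        calls = lm.detect_duplications(models, mat)
        assert [c.kind for c in calls] == ["tandem"]

    def test_missing_gene_in_matrix_is_error(self):
        models = [GeneModel("a", "s1", 1, 10, "+", exons=[(1, 10)]),
                  GeneModel("z", "s1", 20, 30, "+", exons=[(20, 30)])]
        mat = lm.IdentityMatrix.from_pairs(["a", "b"], {("a", "b"): 80.0})
        with pytest.raises(ValueError, match="z"):
            lm.detect_duplications(models, mat)

    def test_synthetic_clusters_recovered(self):
        for seed in range(5):
            bundle = lm.generate_genome_bundle(lm.SimulationConfig(seed=seed))
            proteins = {r.id: r for r in bundle.proteins}
            fam = bundle.manifest[bundle.manifest["role"] == "true"]
            mat = lm.identity_matrix([proteins[g] for g in fam["gene_id"]])
            models = [g for g in bundle.genes
                      if g.gene_id in set(fam["gene_id"])]
            calls = lm.detect_duplications(models, mat)
            expected = {
                tuple(sorted(sub["gene_id"]))
                for cid, sub in fam.groupby("cluster_id") if cid != "n/a"
            }
            got = {tuple(sorted(c.members)) for c in calls
                   if c.kind == "tandem"}
            assert got == expected
            assert not any(c.kind == "segmental" for c in calls)
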