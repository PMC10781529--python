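"""Jaccard and alternative binary similarity coefficients."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from lagenaria.bandmatrix import pool
from lagenaria.similarity import (
    SimilarityMatrix,
    alt_coefficients,
    jaccard,
    read_similarity,
    round_half_up,
    similarity_report,
    write_similarity,
)
from lagenaria import datasets

from .conftest import make_matrix


class TestJaccard:
    def test_study_protein_spot_cells(self, protein):
        s = jaccard(protein)
        # S1 carries all 17 bands, S2 lacks two: a=15, b=2, c=0
        assert round_half_up(s.value("S1", "S2")) == 0.882
        assert s.value("S2", "S8") == pytest.approx(13 / 17)
        # shared absences are ignored: S2 and S9 both lack the 12 kDa band
        assert s.value("S2", "S9") == pytest.approx(15 / 16)

    def test_study_protein_full_matrix_matches_published(self, protein):
        s = jaccard(protein)
        pub = datasets.protein_similarity_published()
        for i, x in enumerate(pub.genotypes):
            for y in pub.genotypes[i + 1 :]:
                assert round_half_up(s.value(x, y)) == pub.value(x, y), (x, y)

    def test_identical_and_disjoint_columns(self):
        m = make_matrix([[1, 1, 0], [1, 1, 0], [0, 0, 1]])
        s = jaccard(m)
        assert s.value("g1", "g2") == 1.0
        assert s.value("g1", "g3") == 0.0

    def test_matches_scipy_on_random_matrices(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            grid = rng.integers(0, 2, size=(12, 6))
            grid[0] = 1  # guarantees every genotype pair has a presence
            grid = grid[grid.sum(axis=1) > 0]  # a locus must be observed
            m = make_matrix(grid)
            ours = jaccard(m).values
            ref = 1.0 - squareform(pdist(grid.T, metric="jaccard"))
            np.fill_diagonal(ref, 1.0)
            np.testing.assert_allclose(ours, ref, atol=1e-12)

    def test_zero_union_pair_warns_and_scores_zero(self):
        # g2 and g3 carry no bands at all: their union is empty
        m = make_matrix([[1, 0, 0], [1, 0, 0]])
        with pytest.warns(UserWarning, match="share no observed bands"):
            s = jaccard(m)
        assert s.value("g2", "g3") == 0.0

    def test_requires_two_genotypes(self):
        with pytest.raises(ValueError, match="at least 2"):
            jaccard(make_matrix([[1]]))

    def test_label_stable_under_genotype_permutation(self, protein):
        rng = np.random.default_rng(3)
        order = list(rng.permutation(protein.genotypes))
        s1 = jaccard(protein)
        s2 = jaccard(protein.reorder_genotypes(order))
        for x in protein.genotypes[:4]:
            for y in protein.genotypes[4:]:
                assert s1.value(x, y) == s2.value(x, y)


class TestPooledJaccard:
    def test_pool_equals_count_pooling(self, protein, pod_binary, ppo_binary):
        """Jaccard of pooled loci equals (sum a)/(sum union) per assay."""
        mats = [protein, pod_binary, ppo_binary]
        s = jaccard(pool(mats))
        gen = protein.genotypes
        for i, x in enumerate(gen):
            for y in gen[i + 1 :]:
                a = u = 0
                for m in mats:
                    xi = m.presence[:, m.genotypes.index(x)]
                    yi = m.presence[:, m.genotypes.index(y)]
                    a += int(((xi == 1) & (yi == 1)).sum())
                    u += int(((xi == 1) | (yi == 1)).sum())
                assert s.value(x, y) == pytest.approx(a / u)

    def test_study_pooled_matches_published_except_transposed_cell(
        self, protein, pod_binary, ppo_binary
    ):
        """All published pooled cells reproduce except (S2,S7), whose
        published digit contradicts the published band data: S7's
        profile is identical to S3's, so the cell must equal (S2,S3)."""
        s = jaccard(pool([protein, pod_binary, ppo_binary]))
        pub = datasets.pooled_similarity_published()
        for i, x in enumerate(pub.genotypes):
            for y in pub.genotypes[i + 1 :]:
                if (x, y) == ("S2", "S7"):
                    continue
                assert round_half_up(s.value(x, y)) == pub.value(x, y), (x, y)
        assert s.value("S2", "S7") == s.value("S2", "S3")
        assert round_half_up(s.value("S2", "S7")) == 0.852

    def test_study_pooled_extremes(self, protein, pod_binary, ppo_binary):
        rep = similarity_report(jaccard(pool([protein, pod_binary, ppo_binary])))
        assert round_half_up(rep.min_value) == 0.778
        assert rep.min_pairs == [("S2", "S8")]


class TestAltCoefficients:
    def test_identical_columns_are_one_under_both(self):
        m = make_matrix([[1, 1, 0], [1, 1, 1], [0, 0, 1]])
        for method in ("dice", "simple_matching"):
            assert alt_coefficients(m, method).value("g1", "g2") == 1.0

    def test_derived_abc_example(self):
        # a=1, b=1, c=1, d=0
        m = make_matrix([[1, 1], [1, 0], [0, 1]])
        assert jaccard(m).value("g1", "g2") == pytest.approx(1 / 3)
        assert alt_coefficients(m, "dice").value("g1", "g2") == pytest.approx(1 / 2)

    def test_all_absent_pair_definitional_edge(self):
        # g2, g3 share only absences: simple matching 1, Jaccard 0
        m = make_matrix([[1, 0, 0]])
        sm = alt_coefficients(m, "simple_matching")
        assert sm.value("g2", "g3") == 1.0
        with pytest.warns(UserWarning):
            assert jaccard(m).value("g2", "g3") == 0.0

    def test_dice_dominates_jaccard(self, protein, pod_binary):
        m = pool([protein, pod_binary])
        j = jaccard(m).values
        d = alt_coefficients(m, "dice").values
        off = ~np.eye(len(j), dtype=bool)
        assert (d[off] >= j[off] - 1e-12).all()

    def test_unknown_method_rejected(self, tiny_matrix):
        with pytest.raises(ValueError, match="unknown"):
            alt_coefficients(tiny_matrix, "phi")


class TestReport:
    def test_study_scot_extremes(self, scot_sim):
        rep = similarity_report(scot_sim)
        assert (round_half_up(rep.min_value), rep.min_pairs) == (0.675, [("S5", "S9")])
        assert (round_half_up(rep.max_value), rep.max_pairs) == (0.889, [("S5", "S7")])

    def test_two_genotype_matrix(self):
        rep = similarity_report(jaccard(make_matrix([[1, 1], [1, 0]])))
        assert rep.min_value == rep.max_value == 0.5

    def test_ties_reported_exhaustively(self):
        s = SimilarityMatrix(["a", "b", "c"], np.array(
            [[1.0, 0.5, 0.5], [0.5, 1.0, 0.5], [0.5, 0.5, 1.0]]
        ))
        rep = similarity_report(s)
        assert len(rep.min_pairs) == len(rep.max_pairs) == 3


class TestIO:
    def test_lower_triangular_round_trip(self, protein, tmp_path):
        s = jaccard(protein)
        p = write_similarity(s, tmp_path / "s.csv", lower=True, ndigits=None)
        back = read_similarity(p)
        np.testing.assert_allclose(back.values, s.values, atol=1e-9)
        assert back.genotypes == s.genotypes

    def test_full_square_round_trip(self, scot_sim, tmp_path):
        p = write_similarity(scot_sim, tmp_path / "s.csv", lower=False, ndigits=3)
        back = read_similarity(p)
        np.testing.assert_allclose(back.values, scot_sim.values, atol=5e-4)
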