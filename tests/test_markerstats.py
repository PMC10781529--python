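"""Locus classification, polymorphism percentages, unique markers, and
primer informativeness indices."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lagenaria.bandmatrix import pool
from lagenaria.markerstats import (
    emr_group,
    genotype_specific_markers,
    locus_stats,
    pic_group,
    polymorphism_percent,
    primer_summary,
    rp_group,
    summary_frame,
)

from .conftest import make_matrix


class TestLocusStats:
    def test_study_126kda_band_is_unique_negative(self, protein):
        st126 = next(
            s
            for s, loc in zip(locus_stats(protein), protein.loci)
            if loc.size_label == 126.0
        )
        assert st126.p == Fraction(9, 10)
        assert st126.klass == "unique_negative"

    def test_monomorphic_and_unique_positive(self):
        m = make_matrix([[1] * 10, [1] + [0] * 9])
        s_all, s_one = locus_stats(m)
        assert (s_all.p, s_all.klass) == (1, "monomorphic")
        assert (s_one.p, s_one.klass) == (Fraction(1, 10), "unique_positive")

    def test_mid_frequency_band_is_plain_polymorphic(self, protein):
        # absent from two cultivars: polymorphic but not genotype-specific
        st12 = next(
            s
            for s, loc in zip(locus_stats(protein), protein.loci)
            if loc.size_label == 12.0
        )
        assert st12.klass == "polymorphic"
        assert st12.p == Fraction(8, 10)

    def test_agrees_with_exhaustive_counting_on_small_matrices(self):
        """Oracle: per-column counting on all random matrices <= 8x8."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            n_loci = rng.integers(1, 9)
            n_gen = rng.integers(2, 9)
            grid = rng.integers(0, 2, size=(n_loci, n_gen))
            grid = grid[grid.sum(axis=1) > 0]
            if not len(grid):
                continue
            m = make_matrix(grid)
            for s, row in zip(locus_stats(m), grid):
                count = sum(1 for v in row if v == 1)
                assert s.count == count
                expected = (
                    "monomorphic"
                    if count == n_gen
                    else "unique_positive"
                    if count == 1
                    else "unique_negative"
                    if count == n_gen - 1
                    else "polymorphic"
                )
                assert s.klass == expected


class TestPolymorphismPercent:
    def test_study_protein_percentage(self, protein):
        assert polymorphism_percent(protein) == pytest.approx(29.4117647, abs=1e-6)

    def test_isozyme_twenty_percent_per_enzyme(self, pod_binary, ppo_binary):
        both = pool([pod_binary, ppo_binary])
        assert polymorphism_percent(both, by_group=True) == {
            "POD": pytest.approx(20.0),
            "PPO": pytest.approx(20.0),
        }

    def test_all_monomorphic_is_zero(self):
        assert polymorphism_percent(make_matrix([[1, 1], [1, 1]])) == 0.0

    def test_invariant_under_reordering(self, protein):
        rng = np.random.default_rng(0)
        order = list(rng.permutation(protein.genotypes))
        assert polymorphism_percent(protein.reorder_genotypes(order)) == (
            polymorphism_percent(protein)
        )
        shuffled = make_matrix(
            protein.presence[list(rng.permutation(protein.n_loci))],
            genotypes=protein.genotypes,
        )
        assert polymorphism_percent(shuffled) == polymorphism_percent(protein)


class TestGenotypeSpecificMarkers:
    def test_study_protein_negative_markers(self, protein):
        df = genotype_specific_markers(protein)
        assert (df["polarity"] == "negative").all()
        got = sorted(zip(df["genotype"], df["size_label"]))
        assert got == [("S2", 11.0), ("S6", 23.0), ("S8", 100.0), ("S8", 126.0)]

    def test_identity_matrix_gives_one_positive_per_band(self):
        m = make_matrix(np.eye(4, dtype=np.int8))
        df = genotype_specific_markers(m)
        assert list(df["polarity"]) == ["positive"] * 4
        assert sorted(df["genotype"]) == ["g1", "g2", "g3", "g4"]

    def test_all_monomorphic_gives_empty_table(self):
        assert genotype_specific_markers(make_matrix([[1, 1, 1]])).empty


class TestIndices:
    def test_pic_examples(self):
        assert pic_group([1, 1, 1]) == 0.0
        assert pic_group([0.5]) == 0.5
        assert pic_group([0.9, 0.1]) == pytest.approx(0.18)

    def test_pic_rejects_empty_and_out_of_range(self):
        with pytest.raises(ValueError):
            pic_group([])
        with pytest.raises(ValueError):
            pic_group([1.2])

    def test_emr_examples(self):
        assert emr_group(5, 5) == 5.0
        assert emr_group(3, 0) == 0.0
        assert emr_group(11, 7) == pytest.approx(7 * 7 / 11)
        with pytest.raises(ValueError):
            emr_group(0, 0)

    def test_rp_examples(self):
        assert rp_group([1, 1, 1]) == 0.0
        assert rp_group([0.5]) == 1.0
        assert rp_group([0.8, 0.5]) == pytest.approx(1.4)

    @settings(max_examples=60, derandomize=True)
    @given(
        freqs=st.lists(
            st.floats(0, 1, allow_nan=False), min_size=1, max_size=12
        ),
        seed=st.integers(0, 10_000),
    )
    def test_pic_permutation_invariant_and_bounded(self, freqs, seed):
        rng = np.random.default_rng(seed)
        shuffled = list(rng.permutation(freqs))
        assert pic_group(shuffled) == pytest.approx(pic_group(freqs))
        assert 0.0 <= pic_group(freqs) <= 0.5
        # maximum attained exactly when every p = 0.5
        assert pic_group([0.5] * len(freqs)) == 0.5


class TestPrimerSummary:
    def test_fully_monomorphic_group(self):
        m = make_matrix([[1] * 10] * 3, group="SCoT-2")
        (s,) = primer_summary(m)
        assert (s.tbn, s.mbn, s.pbn) == (3, 3, 0)
        assert s.p_pct == 0.0
        assert s.pic == 0.0
        assert s.emr == 0.0
        assert s.rp == 0.0

    def test_mixed_group_pic_is_mean_of_band_pic(self):
        m = make_matrix([[1, 0], [1, 1]])
        (s,) = primer_summary(m)
        assert s.pic == pytest.approx((0.5 + 0.0) / 2)

    def test_mi_identity_on_study_matrices(self, protein, pod_binary, ppo_binary):
        pooled = pool([protein, pod_binary, ppo_binary])
        for s in primer_summary(pooled):
            assert s.mi == s.pic * s.emr
            assert s.tbn == s.mbn + s.pbn
            assert 0.0 <= s.p_pct <= 100.0

    def test_bsr_spans_group_band_sizes(self, protein):
        (s,) = primer_summary(protein)
        assert s.bsr == (9.0, 126.0)

    def test_summary_frame_totals_and_averages(self, protein, pod_binary):
        df = summary_frame(primer_summary(pool([protein, pod_binary])))
        body = df[~df["group"].isin(["Total", "Average"])]
        total = df[df["group"] == "Total"].iloc[0]
        avg = df[df["group"] == "Average"].iloc[0]
        assert total["tbn"] == body["tbn"].sum() == 22
        assert avg["p_pct"] == pytest.approx(body["p_pct"].mean())

    def test_empty_group_input_errors(self):
        with pytest.raises(ValueError):
            summary_frame([])
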