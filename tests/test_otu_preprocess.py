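"""Count-table model, IO, filtering, rarefaction, diversity, composition."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oralmark import otu_preprocess as op
from oralmark.otu_preprocess import OtuTable, OtuTableError


def random_table(rng, n_taxa=12, n_samples=6, depth=300) -> OtuTable:
    counts = rng.multinomial(depth, rng.dirichlet(np.ones(n_taxa)),
                             size=n_samples).T
    return OtuTable(
        [f"t{i}" for i in range(n_taxa)], [""] * n_taxa,
        [f"s{j}" for j in range(n_samples)], counts,
    )


class TestIO:
    def test_tsv_round_trip(self, toy_table, tmp_path):
        path = tmp_path / "table.tsv"
        op.write_otu_table(toy_table, path)
        assert op.read_otu_table(path) == toy_table

    def test_biom_round_trip(self, toy_table, tmp_path):
        path = tmp_path / "table.biom"
        op.write_otu_table(toy_table, path, format="biom")
        got = op.read_otu_table(path, format="biom")
        assert np.array_equal(got.counts, toy_table.counts)
        assert got.sample_ids == toy_table.sample_ids

    def test_negative_count_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("#OTU ID\ts1\ts2\ttaxonomy\nt1\t5\t-3\tk__B\n")
        with pytest.raises(OtuTableError, match="negative"):
            op.read_otu_table(path)

    def test_non_integer_count_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("#OTU ID\ts1\ttaxonomy\nt1\t2.5\tk__B\n")
        with pytest.raises(OtuTableError, match="non-integer"):
            op.read_otu_table(path)

    def test_taxonomy_preserved_verbatim(self, toy_table, tmp_path):
        path = tmp_path / "table.tsv"
        op.write_otu_table(toy_table, path)
        assert op.read_otu_table(path).lineages == toy_table.lineages

    def test_duplicate_ids_rejected(self):
        with pytest.raises(OtuTableError, match="unique"):
            OtuTable(["a", "a"], ["", ""], ["s1"], np.array([[1], [2]]))


class TestFilterLowAbundance:
    def test_single_sample_taxon_removed(self):
        counts = np.zeros((2, 6), dtype=int)
        counts[0] = [0, 0, 7, 0, 0, 0]     # present in exactly one sample
        counts[1] = [500, 500, 500, 500, 500, 500]
        t = OtuTable(["rare", "common"], ["", ""],
                     [f"s{i}" for i in range(6)], counts)
        out = op.filter_low_abundance(t)
        assert out.taxon_ids == ["common"]

    def test_dominant_taxon_retained(self):
        counts = np.array([[50, 50], [40, 40], [5, 15]])
        t = OtuTable(["half", "b", "c"], [""] * 3, ["s1", "s2"], counts)
        assert "half" in op.filter_low_abundance(t).taxon_ids

    def test_boundary_at_0_05_percent(self):
        # grand total 10,000; totals 4 (0.04%, removed), 5 (exactly 0.05%,
        # retained) and 6 (retained), all present in >=2 of 4 samples
        counts = np.array([
            [2, 2, 0, 0],
            [2, 3, 0, 0],
            [3, 3, 0, 0],
            [4985, 2000, 1500, 1500],
        ])
        assert counts.sum() == 10_000
        t = OtuTable(["x4", "x5", "x6", "fill"], [""] * 4,
                     ["s1", "s2", "s3", "s4"], counts)
        out = op.filter_low_abundance(t)
        assert out.taxon_ids == ["x5", "x6", "fill"]

    def test_idempotent(self, rng):
        t = random_table(rng, n_taxa=30, n_samples=8)
        once = op.filter_low_abundance(t)
        twice = op.filter_low_abundance(once)
        assert once == twice

    def test_subject_mode_counts_subjects_not_samples(self):
        # taxon present in two samples of the SAME subject -> prevalence 1
        counts = np.array([[300, 400, 0], [100, 100, 100000]])
        t = OtuTable(["dup", "fill"], ["", ""], ["a1", "a2", "b1"], counts)
        subj = {"a1": "A", "a2": "A", "b1": "B"}
        out = op.filter_low_abundance(t, subject_of_sample=subj)
        assert out.taxon_ids == ["fill"]
        assert op.filter_low_abundance(t).taxon_ids == ["dup", "fill"]

    def test_all_removed_warns(self):
        t = OtuTable(["only"], [""], ["s1", "s2"], np.array([[1, 0]]))
        with pytest.warns(UserWarning, match="every taxon"):
            out = op.filter_low_abundance(t)
        assert out.n_taxa == 0


class TestRarefy:
    def test_exact_depth_unchanged(self, toy_table):
        res = op.rarefy(toy_table, 10, seed=0)
        # s1 has exactly 10 reads: exhaustive draw
        j = res.table.sample_ids.index("s1")
        assert np.array_equal(res.table.counts[:, j], [5, 3, 2])

    def test_shallow_sample_dropped_and_reported(self, toy_table):
        res = op.rarefy(toy_table, 15, seed=0)
        assert res.dropped == ["s1"]
        assert res.table.sample_ids == ["s2"]
        assert res.table.sample_sums()[0] == 15

    def test_column_sums_equal_depth(self, rng):
        t = random_table(rng, depth=500)
        res = op.rarefy(t, 200, seed=3)
        assert np.all(res.table.sample_sums() == 200)

    def test_deterministic_given_seed(self, rng):
        t = random_table(rng, depth=500)
        a = op.rarefy(t, 100, seed=11).table
        b = op.rarefy(t, 100, seed=11).table
        assert a == b

    def test_invalid_depth(self, toy_table):
        with pytest.raises(ValueError, match="depth"):
            op.rarefy(toy_table, 0, seed=0)

    def test_hypergeometric_expectation(self):
        # (90, 10) sample at depth 10: E[taxon 1] = 10*90/100 = 9.0
        t = OtuTable(["a", "b"], ["", ""], ["s"], np.array([[90], [10]]))
        draws = np.array(
            [op.rarefy(t, 10, seed=s).table.counts[0, 0] for s in range(2000)]
        )
        var = 10 * 0.9 * 0.1 * 90 / 99      # hypergeometric variance
        se = np.sqrt(var / len(draws))
        assert abs(draws.mean() - 9.0) < 3 * se

    def test_rarefy_mean_returns_float_matrix(self, rng):
        t = random_table(rng, depth=500)
        mat = op.rarefy_mean(t, 200, seed=5, n_draws=4)
        assert mat.shape == t.counts.shape
        assert np.allclose(mat.sum(axis=0), 200)


class TestAggregateTaxonomy:
    def test_two_species_one_genus_sum(self):
        lin = [
            "k__B; p__F; c__B; o__L; f__Streptococcaceae; g__Streptococcus; s__salivarius",
            "k__B; p__F; c__B; o__L; f__Streptococcaceae; g__Streptococcus; s__parasanguinis",
        ]
        t = OtuTable(["a", "b"], lin, ["s1"], np.array([[3], [4]]))
        out = op.aggregate_taxonomy(t, "genus")
        assert out.taxon_ids == ["Streptococcus"]
        assert out.counts[0, 0] == 7

    def test_species_level_identity_shape(self, toy_table):
        out = op.aggregate_taxonomy(toy_table, "species")
        assert out.n_taxa == toy_table.n_taxa
        assert np.array_equal(out.counts, toy_table.counts)

    def test_family_hand_grouping(self):
        lineages = [
            "k__B; p__F; c__C; o__O; f__Lachnospiraceae; g__Blautia; s__x",
            "k__B; p__F; c__C; o__O; f__Lachnospiraceae; g__Roseburia; s__y",
            "k__B; p__F; c__C; o__O; f__Ruminococcaceae; g__Faecalibacterium; s__z",
            "k__B; p__F; c__C; o__O; f__Ruminococcaceae; g__Subdoligranulum; s__v",
            "k__B; p__B; c__C; o__O; f__Bacteroidaceae; g__Bacteroides; s__w",
            "k__B; p__B; c__C; o__O",                      # unclassified at family
        ]
        counts = np.array([[1], [2], [4], [8], [16], [32]])
        t = OtuTable([f"t{i}" for i in range(6)], lineages, ["s"], counts)
        out = op.aggregate_taxonomy(t, "family")
        got = dict(zip(out.taxon_ids, out.counts[:, 0]))
        assert got == {"Lachnospiraceae": 3, "Ruminococcaceae": 12,
                       "Bacteroidaceae": 16, "unclassified_family": 32}

    def test_grand_total_conserved(self, rng):
        t = random_table(rng, n_taxa=10)
        t.lineages[:] = [
            f"k__B; p__P; c__C; o__O; f__F{i % 3}; g__G{i % 4}; s__s{i}"
            for i in range(10)
        ]
        for rank in ("family", "genus", "species"):
            assert op.aggregate_taxonomy(t, rank).counts.sum() == t.counts.sum()

    def test_unknown_rank(self, toy_table):
        with pytest.raises(ValueError, match="rank"):
            op.aggregate_taxonomy(toy_table, "phylum")


class TestRelativeAbundanceAndDiversity:
    def test_half_half(self):
        t = OtuTable(["a", "b"], ["", ""], ["s"], np.array([[2], [2]]))
        assert np.allclose(op.relative_abundance(t)[:, 0], [0.5, 0.5])

    def test_columns_sum_to_one(self, rng):
        t = random_table(rng)
        assert np.allclose(op.relative_abundance(t).sum(axis=0), 1, atol=1e-12)

    def test_zero_sum_sample_named(self):
        t = OtuTable(["a"], [""], ["good", "empty"], np.array([[3, 0]]))
        with pytest.raises(OtuTableError, match="empty"):
            op.relative_abundance(t)

    def test_shannon_single_taxon_zero(self):
        assert op.shannon_diversity([17]) == 0.0

    def test_shannon_uniform_ln_k(self):
        assert op.shannon_diversity([5, 5, 5, 5]) == pytest.approx(np.log(4))

    def test_shannon_1_2_3_hand_value(self):
        # p = (1/6, 1/3, 1/2): H = ln6/6 + ln3/3 + ln2/2
        expected = np.log(6) / 6 + np.log(3) / 3 + np.log(2) / 2
        assert op.shannon_diversity([1, 2, 3]) == pytest.approx(expected, abs=1e-12)

    def test_shannon_empty_sample(self):
        with pytest.raises(ValueError):
            op.shannon_diversity([0, 0])


class TestBrayCurtis:
    def test_identical_samples_zero(self):
        t = OtuTable(["a", "b"], ["", ""], ["s1", "s2"],
                     np.array([[4, 4], [6, 6]]))
        assert op.bray_curtis(t)["s1", "s2"] == 0

    def test_disjoint_supports_one(self):
        t = OtuTable(["a", "b"], ["", ""], ["s1", "s2"],
                     np.array([[9, 0], [0, 9]]))
        assert op.bray_curtis(t)["s1", "s2"] == 1

    def test_hand_value_one_third(self):
        t = OtuTable(["a", "b"], ["", ""], ["u", "v"],
                     np.array([[6, 2], [2, 2]]))
        assert op.bray_curtis(t)["u", "v"] == pytest.approx(1 / 3)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_symmetric_and_bounded(self, seed):
        t = random_table(np.random.default_rng(seed), n_taxa=8, n_samples=5)
        d = np.asarray(op.bray_curtis(t).data)
        assert np.allclose(d, d.T)
        assert np.all((d >= 0) & (d <= 1))
        assert np.all(np.diag(d) == 0)


class TestPermanova:
    def test_degenerate_identical_samples_flagged(self):
        t = OtuTable(["a", "b"], ["", ""], [f"s{i}" for i in range(6)],
                     np.tile([[3], [7]], (1, 6)))
        res = op.permanova(op.bray_curtis(t), [0, 0, 0, 1, 1, 1], n_perm=99)
        assert res.degenerate

    def test_single_group_rejected(self, rng):
        t = random_table(rng, n_samples=6)
        with pytest.raises(ValueError, match="two groups"):
            op.permanova(op.bray_curtis(t), [1] * 6)

    def test_deterministic_given_seed(self, rng):
        t = random_table(rng, n_samples=10)
        dm = op.bray_curtis(t)
        labels = [0] * 5 + [1] * 5
        a = op.permanova(dm, labels, n_perm=199, seed=7)
        b = op.permanova(dm, labels, n_perm=199, seed=7)
        assert (a.pseudo_f, a.p_value) == (b.pseudo_f, b.p_value)

    def test_pseudo_f_matches_skbio(self, rng):
        from skbio.stats.distance import permanova as skbio_permanova

        t = random_table(rng, n_taxa=15, n_samples=12, depth=400)
        dm = op.bray_curtis(t)
        labels = ["x"] * 6 + ["y"] * 6
        mine = op.permanova(dm, labels, n_perm=99, seed=0)
        ref = skbio_permanova(dm, grouping=list(labels), permutations=99)
        assert mine.pseudo_f == pytest.approx(ref["test statistic"], rel=1e-9)
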