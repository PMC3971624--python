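import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from necbiome.cluster import (
    aggregate_relative_abundance,
    assign_subtypes,
    choose_k,
    classify_dysbiosis,
    cluster_diagnostics,
    ward_cluster,
)
from necbiome.io import OtuTable, SampleRecord

from _oracles import ward_greedy_partitions


def _two_pairs():
    # two tight pairs far apart
    pts = np.array([[0.0, 0], [0.1, 0], [10, 0], [10.1, 0]])
    return squareform(pdist(pts))


class TestWardCluster:
    def test_two_separated_pairs(self):
        tree = ward_cluster(_two_pairs())
        labels = tree.labels(2)
        assert labels["0"] == labels["1"]
        assert labels["2"] == labels["3"]
        assert labels["0"] != labels["2"]
        # the first two merges each join a pair
        first_two = {tuple(sorted(map(int, row[:2]))) for row in tree.merges[:2]}
        assert first_two == {(0, 1), (2, 3)}

    def test_duplicate_points_merge_first_at_zero(self):
        d = squareform(pdist(np.array([[0.0], [0.0], [5.0]])))
        tree = ward_cluster(d)
        assert tree.merges[0, 2] == 0.0
        assert tree.ss_increase[0] == 0.0

    def test_merge_ss_increase_monotone(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            d = squareform(pdist(rng.standard_normal((9, 3))))
            tree = ward_cluster(d)
            assert np.all(np.diff(tree.ss_increase) >= -1e-9)

    def test_matches_greedy_ss_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            n = int(rng.integers(4, 9))
            d = squareform(pdist(rng.standard_normal((n, 3))))
            tree = ward_cluster(d)
            oracle = ward_greedy_partitions(d)
            for k in range(2, n):
                labels = tree.labels(k)
                got = {frozenset(i for i, s in enumerate(tree.sample_ids) if labels[s] == c)
                       for c in set(labels.values())}
                assert got == set(oracle[k])

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            ward_cluster(np.array([[0, 1.0], [2.0, 0]]))


class TestDiagnostics:
    def test_two_pairs_pseudo_f_peaks_at_two(self):
        tree = ward_cluster(_two_pairs())
        diag = cluster_diagnostics(tree, k_max=3).set_index("k")
        assert diag.loc[2, "pseudo_F"] > diag.loc[3, "pseudo_F"]
        # W_2 uses only within-pair distances: each pair SS = d^2/2 = 0.01/2
        d2 = _two_pairs() ** 2
        w2_expected = 2 * (d2[0, 1] / 2)
        n, k = 4, 2
        total = ward_cluster(_two_pairs())._d2.sum() / (2 * 4)
        expected_f = ((total - w2_expected) / (k - 1)) / (w2_expected / (n - k))
        assert diag.loc[2, "pseudo_F"] == pytest.approx(expected_f)

    def test_identical_points_zero_within_ss(self):
        d = np.zeros((5, 5))
        tree = ward_cluster(d)
        diag = cluster_diagnostics(tree, k_max=4)
        # T = W_k = 0 for all k
        assert np.all(diag["pseudo_F"].to_numpy() == 0.0)

    def test_singleton_merge_t2_is_ss_increase(self):
        d = squareform(pdist(np.array([[0.0], [1.0], [10.0]])))
        tree = ward_cluster(d)
        diag = cluster_diagnostics(tree, k_max=2).set_index("k")
        # merge forming the 2-cluster solution joins the two singletons 0,1
        assert diag.loc[2, "pseudo_T2"] == pytest.approx(tree.ss_increase[0])


class TestChooseK:
    def test_sharp_peak_wins(self):
        diag = pd.DataFrame({"k": [2, 3, 4, 5], "pseudo_F": [5, 6, 20, 4],
                             "pseudo_T2": [1, 1, 1, 1]})
        assert choose_k(diag) == 4

    def test_override_wins(self):
        diag = pd.DataFrame({"k": [2, 3], "pseudo_F": [5, 50], "pseudo_T2": [1, 1]})
        assert choose_k(diag, k_override=4) == 4

    def test_monotone_decreasing_falls_back_to_two(self):
        diag = pd.DataFrame({"k": [2, 3, 4], "pseudo_F": [9, 7, 3],
                             "pseudo_T2": [1, 1, 1]})
        assert choose_k(diag) == 2


class TestAggregateRelativeAbundance:
    def test_single_taxon_sample(self, tiny_taxonomy):
        t = OtuTable(["s"], ["A"], [[7]])
        assert aggregate_relative_abundance(t, tiny_taxonomy, "phylum", "Proteobacteria", "s") == 1.0

    def test_absent_taxon_zero(self, tiny_table, tiny_taxonomy):
        assert aggregate_relative_abundance(
            tiny_table, tiny_taxonomy, "genus", "Propionibacterium", "s1"
        ) == pytest.approx(1 / 6)
        t = OtuTable(["s"], ["A", "B"], [[3, 4]])
        assert aggregate_relative_abundance(t, tiny_taxonomy, "genus", "Propionibacterium", "s") == 0.0

    def test_phylum_shares_conserve_assigned_fraction(self, default_cohort):
        c = default_cohort
        sid = c.table.sample_ids[0]
        total = sum(
            aggregate_relative_abundance(c.table, c.taxonomy, "phylum", p, sid)
            for p in ("Proteobacteria", "Firmicutes", "Actinobacteria")
        )
        assert total == pytest.approx(1.0)

    def test_unknown_rank_rejected(self, tiny_table, tiny_taxonomy):
        with pytest.raises(KeyError):
            aggregate_relative_abundance(tiny_table, tiny_taxonomy, "species", "X", "s1")


def _mini_cohort():
    """3 infants: one Firmicutes-dysbiotic, one Proteobacteria-dysbiotic (w2),
    one control with Propionibacterium; OTUs F (Firmicutes), P (Proteo), Pr."""
    from necbiome.io import Lineage, TaxonomyMap

    tax = TaxonomyMap({
        "F": Lineage("Bacteria", "Firmicutes", "Bacilli", "Bacillales",
                     "Staphylococcaceae", "Staphylococcus"),
        "P": Lineage("Bacteria", "Proteobacteria", "Gammaproteobacteria",
                     "Enterobacteriales", "Enterobacteriaceae", "Enterobacter"),
        "Pr": Lineage("Bacteria", "Actinobacteria", "Actinobacteria",
                      "Actinomycetales", "Propionibacteriaceae", "Propionibacterium"),
    })
    table = OtuTable(
        ["i1_w1", "i2_w1", "i2_w2", "i3_w1", "i3_w2"],
        ["F", "P", "Pr"],
        [
            [993, 7, 0],     # i1 w1: 99.3% Firmicutes, no Propionibacterium
            [150, 850, 0],   # i2 w1: control-like, no Propionibacterium
            [50, 950, 0],    # i2 w2: 95% Proteobacteria
            [170, 810, 20],  # i3 w1: control-like with Propionibacterium
            [300, 700, 0],   # i3 w2: 70% Proteobacteria
        ],
    )
    records = [
        SampleRecord("i1_w1", "i1", 5, "NEC", onset_day=9),
        SampleRecord("i2_w1", "i2", 6, "NEC", onset_day=25),
        SampleRecord("i2_w2", "i2", 12, "NEC", onset_day=25),
        SampleRecord("i3_w1", "i3", 5, "control"),
        SampleRecord("i3_w2", "i3", 11, "control"),
    ]
    return table, tax, records


class TestClassifyDysbiosis:
    def test_flags_and_null_handling(self):
        table, tax, records = _mini_cohort()
        calls = {c.infant_id: c for c in classify_dysbiosis(table, tax, records)}
        i1, i2, i3 = calls["i1"], calls["i2"], calls["i3"]
        assert i1.firmicutes_dysbiosis_w1 is True
        assert i1.propionibacterium_absent_w1 is True
        # i1 has no window-2 sample: window-2 flag and combined flags are null
        assert i1.proteobacteria_dysbiosis_w2 is None
        assert i1.either_dysbiosis is None
        assert i1.combined_criterion is None
        assert i2.firmicutes_dysbiosis_w1 is False
        assert i2.proteobacteria_dysbiosis_w2 is True
        assert i2.either_dysbiosis is True
        assert i2.combined_criterion is True
        assert i3.propionibacterium_absent_w1 is False
        assert i3.proteobacteria_dysbiosis_w2 is False  # 0.70 < 0.90
        assert i3.combined_criterion is False

    def test_threshold_boundary_strict(self):
        table, tax, records = _mini_cohort()
        # 0.895 < 0.90 stays negative; at threshold 0.95 exactly, >= passes
        calls = {c.infant_id: c for c in classify_dysbiosis(
            table, tax, records, proteobacteria_threshold=0.951)}
        assert calls["i2"].proteobacteria_dysbiosis_w2 is False
        calls = {c.infant_id: c for c in classify_dysbiosis(
            table, tax, records, proteobacteria_threshold=0.95)}
        assert calls["i2"].proteobacteria_dysbiosis_w2 is True

    def test_monotone_in_thresholds(self):
        table, tax, records = _mini_cohort()
        strict = classify_dysbiosis(table, tax, records, 0.99, 0.99)
        loose = classify_dysbiosis(table, tax, records, 0.5, 0.5)
        for s, l in zip(strict, loose):
            for flag in ("firmicutes_dysbiosis_w1", "proteobacteria_dysbiosis_w2"):
                if getattr(s, flag) is True:
                    assert getattr(l, flag) is True

    def test_subtype_assignment(self):
        table, tax, records = _mini_cohort()
        calls = classify_dysbiosis(table, tax, records)
        w1_labels = {"i1_w1": 1, "i2_w1": 2, "i3_w1": 2}
        w2_labels = {"i2_w2": 1, "i3_w2": 2}
        assign_subtypes(calls, w1_labels, w2_labels)
        by = {c.infant_id: c.subtype for c in calls}
        assert by["i1"] == "NEC-I-like"
        assert by["i2"] == "NEC-II-like"
        assert by["i3"] == "unclassified"
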