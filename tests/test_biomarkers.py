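import numpy as np
import pytest

from necbiome.biomarkers import (
    TwoByTwo,
    alanine_histidine_ratio,
    evaluate_binary,
    fisher_exact,
    roc_cutpoint,
    table3_report,
)
from necbiome.cluster import classify_dysbiosis
from necbiome.io import MetaboliteRecord

from _oracles import roc_scan_best_c


def _flags_outcomes(n_case_pos, n_case, n_ctrl_pos, n_ctrl):
    flags, outcomes = {}, {}
    for i in range(n_case):
        flags[f"case{i}"] = i < n_case_pos
        outcomes[f"case{i}"] = "NEC"
    for i in range(n_ctrl):
        flags[f"ctrl{i}"] = i < n_ctrl_pos
        outcomes[f"ctrl{i}"] = "control"
    return flags, outcomes


class TestEvaluateBinary:
    def test_firmicutes_dysbiosis_row(self):
        r = evaluate_binary(*_flags_outcomes(4, 9, 0, 18))
        assert r.sensitivity == pytest.approx(4 / 9)
        assert r.specificity == pytest.approx(1.0)
        assert r.c_statistic == pytest.approx(0.722, abs=5e-4)

    def test_combined_criterion_row(self):
        r = evaluate_binary(*_flags_outcomes(7, 7, 4, 16))
        assert r.c_statistic == pytest.approx(0.875)

    def test_uninformative_predictor(self):
        flags, outcomes = _flags_outcomes(5, 5, 8, 8)
        r = evaluate_binary(flags, outcomes)
        assert (r.sensitivity, r.specificity, r.c_statistic) == (1.0, 0.0, 0.5)

    def test_null_flags_excluded_and_counted(self):
        flags, outcomes = _flags_outcomes(2, 4, 1, 4)
        flags["case3"] = None
        flags["ctrl3"] = None
        r = evaluate_binary(flags, outcomes)
        assert r.n_excluded == 2
        assert r.table.n_cases == 3
        assert r.table.n_controls == 3

    def test_no_evaluable_cases_is_error(self):
        with pytest.raises(ValueError):
            evaluate_binary({"c": True}, {"c": "control"})


class TestFisherExact:
    def test_printed_values(self):
        assert fisher_exact(TwoByTwo(4, 5, 0, 18)) == pytest.approx(0.007, abs=5e-4)
        assert fisher_exact(TwoByTwo(7, 0, 4, 12)) == pytest.approx(0.001, abs=5e-4)

    def test_balanced_table_is_one(self):
        assert fisher_exact(TwoByTwo(1, 1, 1, 1)) == 1.0


class TestRatio:
    def test_cluster_one_medians(self):
        m = MetaboliteRecord("i", 5, alanine=3.34, histidine=0.59, pyridoxine=1.0)
        assert alanine_histidine_ratio(m) == pytest.approx(5.66, abs=5e-3)

    def test_equal_values_unity(self):
        m = MetaboliteRecord("i", 5, alanine=2.0, histidine=2.0, pyridoxine=1.0)
        assert alanine_histidine_ratio(m) == 1.0

    def test_cutoff_flag(self):
        m = MetaboliteRecord("i", 5, alanine=4.1, histidine=1.0, pyridoxine=1.0)
        assert alanine_histidine_ratio(m) > 4


class TestRocCutpoint:
    def test_known_configuration(self):
        values = {"c1": 5.0, "c2": 6.0, "c3": 7.0, "c4": 9.0,
                  "k1": 1.0, "k2": 2.0, "k3": 3.0, "k4": 8.0}
        outcomes = {k: ("NEC" if k.startswith("c") else "control") for k in values}
        thr, res = roc_cutpoint(values, outcomes)
        assert 3 < thr < 5
        assert res.sensitivity == 1.0
        assert res.specificity == 0.75

    def test_perfect_separation(self):
        values = {"c1": 10.0, "c2": 11.0, "k1": 1.0, "k2": 2.0}
        outcomes = {"c1": "NEC", "c2": "NEC", "k1": "control", "k2": "control"}
        _, res = roc_cutpoint(values, outcomes)
        assert res.c_statistic == 1.0

    def test_identical_values_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            roc_cutpoint({"a": 1.0, "b": 1.0}, {"a": "NEC", "b": "control"})

    def test_table_row6_counts_reproduced(self):
        """Ratios built to put 9/11 cases and 5/20 controls above 4 give c=0.784,
        and the ROC scan cannot do better for this configuration."""
        rng = np.random.default_rng(0)
        case_vals = [1.0, 1.6] + list(np.linspace(4.2, 6.0, 9))
        ctrl_vals = list(np.linspace(0.9, 3.9, 15)) + list(np.linspace(8, 12, 5))
        values = {f"c{i}": v for i, v in enumerate(case_vals)}
        values |= {f"k{i}": v for i, v in enumerate(ctrl_vals)}
        outcomes = {k: ("NEC" if k.startswith("c") else "control") for k in values}
        thr, res = roc_cutpoint(values, outcomes)
        assert res.c_statistic == pytest.approx(0.784, abs=5e-4)
        assert res.c_statistic == pytest.approx(
            roc_scan_best_c(case_vals, ctrl_vals), rel=1e-12
        )
        assert res.table.a == 9 and res.table.n_cases == 11
        assert res.table.c == 5 and res.table.n_controls == 20


class TestTable3Report:
    def test_perfect_signal_cohort(self):
        """When no control is dysbiotic and every case lacks Propionibacterium,
        the combined criterion is a perfect predictor."""
        from necbiome.io import Lineage, OtuTable, SampleRecord, TaxonomyMap

        tax = TaxonomyMap({
            "F": Lineage("Bacteria", "Firmicutes", "Bacilli", "Bacillales",
                         "Staphylococcaceae", "Staphylococcus"),
            "P": Lineage("Bacteria", "Proteobacteria", "Gammaproteobacteria",
                         "Enterobacteriales", "Enterobacteriaceae", "Enterobacter"),
            "Pr": Lineage("Bacteria", "Actinobacteria", "Actinobacteria",
                          "Actinomycetales", "Propionibacteriaceae", "Propionibacterium"),
        })
        rows, ids, records = [], [], []
        for i in range(2):  # Firmicutes-dysbiotic cases, no Propionibacterium
            ids += [f"n{i}_w1", f"n{i}_w2"]
            rows += [[990, 10, 0], [400, 600, 0]]
            records += [SampleRecord(f"n{i}_w1", f"n{i}", 5, "NEC", onset_day=20),
                        SampleRecord(f"n{i}_w2", f"n{i}", 12, "NEC", onset_day=20)]
        for i in range(3):  # controls: mixed communities carrying Propionibacterium
            ids += [f"k{i}_w1", f"k{i}_w2"]
            rows += [[200, 780, 20], [250, 740, 10]]
            records += [SampleRecord(f"k{i}_w1", f"k{i}", 5, "control"),
                        SampleRecord(f"k{i}_w2", f"k{i}", 12, "control")]
        table = OtuTable(ids, ["F", "P", "Pr"], rows)
        calls = classify_dysbiosis(table, tax, records)
        results = table3_report(calls)
        combined = results[4]
        assert combined.sensitivity == 1.0
        assert combined.specificity == 1.0

    def test_report_shape_and_logic(self, default_cohort):
        calls = classify_dysbiosis(
            default_cohort.table, default_cohort.taxonomy, default_cohort.records
        )
        results = table3_report(calls, default_cohort.metabolites)
        assert len(results) == 6
        r1, r2, r3, r4, r5, r6 = results
        # combined criterion can only lose positives relative to either-dysbiosis
        assert r5.table.a <= r4.table.a
        assert r5.table.c <= r4.table.c
        # cases never carry Propionibacterium in the generated cohort
        assert r2.sensitivity == 1.0
        # both-window restriction shrinks (or keeps) the case denominator
        assert r4.table.n_cases <= r1.table.n_cases
        for r in results:
            assert 0 <= r.c_statistic <= 1
            assert r.c_statistic == pytest.approx((r.sensitivity + r.specificity) / 2)
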