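import numpy as np
import pytest
from scipy import integrate, stats as _st

from necbiome.cluster import assign_subtypes, classify_dysbiosis
from necbiome.pipeline import PipelineConfig, analyze_cohort
from necbiome.simulate import CohortDesign, generate_cohort
from necbiome.stats import bh_adjust, kruskal_wallis, spearman, table2_report, welch_t

from _oracles import (
    bh_stepup,
    kw_permutation_p,
    kw_statistic,
    spearman_permutation_p,
    spearman_rho_formula,
)


class TestKruskalWallis:
    def test_statistic_matches_rank_formula_and_permutation_p(self):
        groups = {"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0]}
        res = kruskal_wallis(groups)
        assert res.statistic == pytest.approx(kw_statistic(list(groups.values())), rel=1e-9)
        # exact p: 2 of the 20 distinct assignments are as extreme
        assert kw_permutation_p(list(groups.values())) == pytest.approx(0.1)

    def test_identical_groups_null(self):
        res = kruskal_wallis({"a": [2.0, 2.0], "b": [2.0, 2.0]})
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_two_group_reduction_to_ranksum(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=8), rng.normal(loc=1, size=9)
        h = kruskal_wallis({"a": a, "b": b}).statistic
        z = _st.ranksums(a, b).statistic
        assert h == pytest.approx(z**2, rel=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            kruskal_wallis({"a": [1.0], "b": []})


class TestSpearman:
    def test_perfect_monotone(self):
        assert spearman([1, 2, 5], [10, 20, 50]).rho == pytest.approx(1.0)
        assert spearman([1, 2, 5], [-1, -2, -5]).rho == pytest.approx(-1.0)

    def test_matches_rank_formula_and_permutation_p(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            n = int(rng.integers(4, 8))
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            res = spearman(x, y)
            assert res.rho == pytest.approx(spearman_rho_formula(x, y), rel=1e-9)
        # one exact permutation p at n=5
        x, y = [1.0, 2, 3, 4, 5], [2.0, 1, 4, 3, 5]
        p_exact = spearman_permutation_p(x, y)
        assert 0 < p_exact <= 1
        assert abs(spearman(x, y).rho) == pytest.approx(abs(spearman_rho_formula(x, y)))

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestBenjaminiHochberg:
    def test_single_p_identity(self):
        assert bh_adjust([0.03]) == pytest.approx([0.03])

    def test_stepup_hand_case(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04])

    def test_matches_stepup_oracle_and_inflates(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            p = rng.uniform(1e-6, 1, size=int(rng.integers(1, 12)))
            adj = bh_adjust(p)
            assert np.allclose(adj, bh_stepup(p), atol=1e-12)
            assert np.all(adj >= p - 1e-15)
            assert np.all(adj <= 1)

    def test_rejection_set_equals_classic_rule(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            p = rng.uniform(1e-6, 1, size=8)
            rejected = set(np.flatnonzero(bh_adjust(p) <= 0.05))
            # classic step-up: largest k with p_(k) <= 0.05 k/m
            order = np.argsort(p)
            k_star = 0
            for k in range(1, 9):
                if p[order[k - 1]] <= 0.05 * k / 8:
                    k_star = k
            classic = set(order[:k_star])
            assert rejected == classic

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 0.0])
        with pytest.raises(ValueError):
            bh_adjust([1.2])


class TestWelchT:
    def test_identical_groups_null(self):
        res = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_extreme_separation(self):
        assert welch_t([0, 0, 0, 1e-6], [10, 10, 10, 10 + 1e-6]).p_value < 1e-3

    def test_matches_quadrature_oracle(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(size=6), rng.normal(loc=0.8, size=9)
        res = welch_t(a, b)
        va, vb = np.var(a, ddof=1) / len(a), np.var(b, ddof=1) / len(b)
        t = (np.mean(a) - np.mean(b)) / np.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
        tail, _ = integrate.quad(lambda u: _st.t.pdf(u, df), abs(t), np.inf)
        assert res.p_value == pytest.approx(2 * tail, rel=1e-6)

    def test_zero_variance_both_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            welch_t([1.0, 1.0], [2.0, 2.0])


class TestTable2Report:
    def _result(self, seed, coupled=True):
        d = CohortDesign(seed=seed, couple_metabolites=coupled)
        c = generate_cohort(d)
        return analyze_cohort(c, PipelineConfig(seed=seed, design=d, run_nmds=False))

    def test_row_count_bookkeeping(self, default_cohort):
        calls = classify_dysbiosis(
            default_cohort.table, default_cohort.taxonomy, default_cohort.records
        )
        assign_subtypes(calls, None, None)
        df = table2_report(default_cohort.metabolites, calls, bh=True)
        assert len(df) == 3 * (3 + 5)
        assert "p_bh" in df.columns
        ok = df["p_bh"].notna()
        assert np.all(df.loc[ok, "p_bh"] >= df.loc[ok, "p_value"] - 1e-15)

    def test_planted_sign_pattern(self):
        """Coupled cohorts show the expected association directions."""
        t2 = self._result(3).table2
        def rho(met, feat):
            return float(t2[(t2.metabolite == met) & (t2.against == feat)].rho.iloc[0])
        assert rho("alanine", "firmicutes_w1") > 0
        assert rho("alanine", "proteobacteria_w1") < 0
        assert rho("alanine_histidine_ratio", "propionibacterium_w1") < 0

    def test_null_cohorts_show_no_strong_association(self):
        """With metabolites decoupled from the communities, individual
        correlations stay weak: per-pair |rho| < 0.4 in >= 90% of
        (seed, pair) draws and the across-seed median of each pair is near 0."""
        all_rhos = []
        for seed in range(12):
            t2 = self._result(seed, coupled=False).table2
            all_rhos.append(t2[t2.kind == "spearman"].rho.to_numpy())
        all_rhos = np.vstack(all_rhos)
        assert np.mean(np.abs(all_rhos) < 0.4) >= 0.9
        assert np.all(np.abs(np.median(all_rhos, axis=0)) < 0.2)
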