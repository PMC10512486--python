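"""Expression statistics against hand arithmetic, brute-force oracles and
statsmodels cross-checks."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multitest import multipletests

import oracles
from astroquant import (
    bh_adjust,
    filter_low_expression,
    marker_panel_score,
    qpcr_relative_expression,
    row_zscore,
    two_way_anova,
)


def toy_design(samples, protocols=None, lines=None):
    n = len(samples)
    return pd.DataFrame(
        {
            "line": lines or ["CTRL1"] * n,
            "protocol": protocols or ["LSF"] * (n // 2) + ["SSC"] * (n - n // 2),
            "replicate": list(range(1, n + 1)),
        },
        index=pd.Index(samples, name="sample"),
    )


class TestFilterLowExpression:
    def setup_method(self):
        self.samples = ["s1", "s2", "s3", "s4"]
        self.design = toy_design(self.samples)

    def test_all_zero_gene_removed_and_expressed_gene_kept(self):
        counts = pd.DataFrame(
            {"s1": [0, 100], "s2": [0, 100], "s3": [0, 100], "s4": [0, 100]},
            index=["dead", "alive"],
        )
        out = filter_low_expression(counts, self.design)
        assert list(out.index) == ["alive"]

    def test_toy_matrix_matches_exhaustive_rule_application(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(
            rng.integers(0, 50, size=(5, 4)),
            index=[f"g{i}" for i in range(5)], columns=self.samples,
        )
        cutoff, k = 1.0, 2
        out = filter_low_expression(counts, self.design, cpm_cutoff=cutoff,
                                    min_samples=k)
        lib = counts.sum(axis=0)
        expected = [
            g for g in counts.index
            if sum(counts.loc[g, s] / lib[s] * 1e6 >= cutoff
                   for s in self.samples) >= k
        ]
        assert list(out.index) == expected

    def test_auto_k_is_smallest_group_size(self):
        # groups: (CTRL1, LSF) n=1 and (CTRL1, SSC) n=3 -> k = 1
        design = toy_design(self.samples, protocols=["LSF", "SSC", "SSC", "SSC"])
        counts = pd.DataFrame(
            {"s1": [5000], "s2": [0], "s3": [0], "s4": [0]}, index=["g"]
        )
        counts.loc["filler"] = [1000, 1000, 1000, 1000]
        assert "g" in filter_low_expression(counts, design).index

    def test_gene_above_cutoff_everywhere_never_removed(self):
        rng = np.random.default_rng(1)
        counts = pd.DataFrame(
            rng.integers(0, 30, size=(20, 4)),
            index=[f"g{i}" for i in range(20)], columns=self.samples,
        )
        counts.loc["high"] = [1000, 2000, 1500, 1200]
        out = filter_low_expression(counts, self.design)
        cpm = counts / counts.sum(axis=0) * 1e6
        always_high = cpm.index[(cpm >= 1.0).all(axis=1)]
        assert set(always_high) <= set(out.index)

    def test_zero_library_size_names_sample(self):
        counts = pd.DataFrame(
            {"s1": [1], "s2": [0], "s3": [2], "s4": [3]}, index=["g"]
        )
        with pytest.raises(ValueError, match="s2"):
            filter_low_expression(counts, self.design)


class TestBhAdjust:
    def test_hand_worked_stepup_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged_and_all_ones_stay_one(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_bruteforce_and_statsmodels(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.random(rng.integers(1, 40))
        ours = bh_adjust(p)
        np.testing.assert_allclose(ours, oracles.bh_stepup(p), atol=1e-12)
        np.testing.assert_allclose(
            ours, multipletests(p, method="fdr_bh")[1], atol=1e-12
        )

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=30))
    def test_monotone_bounded_and_conservative(self, pvals):
        q = bh_adjust(pvals)
        order = np.argsort(pvals, kind="mergesort")
        assert np.all(np.diff(q[order]) >= -1e-12)  # order-preserving
        assert np.all(q >= np.asarray(pvals) - 1e-12)  # never anti-conservative
        assert np.all(q <= 1.0)

    def test_invalid_inputs_rejected(self):
        for bad in ([1.2], [-0.1], [np.nan]):
            with pytest.raises(ValueError):
                bh_adjust(bad)


class TestRowZscore:
    def test_simple_row_and_constant_row(self):
        m = pd.DataFrame([[1.0, 2.0, 3.0], [5.0, 5.0, 5.0]],
                         index=["a", "b"], columns=["s1", "s2", "s3"])
        z = row_zscore(m)
        np.testing.assert_allclose(z.loc["a"], [-1, 0, 1])
        np.testing.assert_allclose(z.loc["b"], [0, 0, 0])

    def test_rows_have_zero_mean_unit_sd_or_all_zero(self):
        rng = np.random.default_rng(2)
        m = pd.DataFrame(rng.random((30, 6)))
        m.iloc[7] = 3.14  # one constant row
        z = row_zscore(m)
        for i in range(30):
            row = z.iloc[i].to_numpy()
            if np.allclose(row, 0):
                continue
            assert row.mean() == pytest.approx(0, abs=1e-12)
            assert row.std(ddof=1) == pytest.approx(1, abs=1e-12)

    def test_fewer_than_two_samples_rejected(self):
        with pytest.raises(ValueError):
            row_zscore(pd.DataFrame({"only": [1.0, 2.0]}))


class TestMarkerPanelScore:
    def _matrix(self):
        return pd.DataFrame(
            [[1.0, 2.0, 3.0, 4.0], [2.0, 4.0, 6.0, 8.0], [9.0, 7.0, 5.0, 3.0]],
            index=["GFAP", "AQP4", "TUBB3"], columns=list("abcd"),
        )

    def test_single_up_gene_score_equals_its_zscore_row(self):
        m = self._matrix()
        panel = pd.DataFrame({"gene": ["GFAP"]})
        scores, matched = marker_panel_score(m, panel)
        np.testing.assert_allclose(scores, row_zscore(m).loc["GFAP"])
        assert matched == ["GFAP"]

    def test_identical_samples_score_zero(self):
        m = pd.DataFrame([[5.0, 5.0, 5.0]] * 2, index=["GFAP", "AQP4"],
                         columns=list("abc"))
        scores, _ = marker_panel_score(m, pd.DataFrame({"gene": ["GFAP",
                                                                 "AQP4"]}))
        np.testing.assert_allclose(scores, 0.0)

    def test_hand_computed_mean_of_zscores_with_down_gene(self):
        m = self._matrix()
        panel = pd.DataFrame({"gene": ["GFAP", "AQP4", "TUBB3"],
                              "direction": ["up", "up", "down"]})
        scores, matched = marker_panel_score(m, panel)
        z = row_zscore(m)
        expected = (z.loc["GFAP"] + z.loc["AQP4"] - z.loc["TUBB3"]) / 3
        np.testing.assert_allclose(scores, expected)
        assert matched == ["GFAP", "AQP4", "TUBB3"]

    def test_missing_genes_skipped_and_empty_panel_rejected(self):
        m = self._matrix()
        panel = pd.DataFrame({"gene": ["GFAP", "NOPE"]})
        scores, matched = marker_panel_score(m, panel)
        assert matched == ["GFAP"]
        with pytest.raises(ValueError, match="no panel gene"):
            marker_panel_score(m, pd.DataFrame({"gene": ["X", "Y"]}))


class TestTwoWayAnova:
    def _balanced(self, seed, I=2, J=2, n=3):
        rng = np.random.default_rng(seed)
        a = np.repeat([f"a{i}" for i in range(I)], J * n)
        b = np.tile(np.repeat([f"b{j}" for j in range(J)], n), I)
        y = rng.normal(size=I * J * n) + (a == "a1") * rng.normal()
        return y, a, b

    def test_symmetric_data_gives_zero_factor_a_ss(self):
        # swapping A-levels leaves the data unchanged
        y = [1.0, 2.0, 1.0, 2.0, 3.0, 4.0, 3.0, 4.0]
        a = ["a1", "a1", "a2", "a2", "a1", "a1", "a2", "a2"]
        b = ["b1", "b1", "b1", "b1", "b2", "b2", "b2", "b2"]
        res = two_way_anova(y, a, b)
        assert res.f_a == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_bruteforce_and_statsmodels(self, seed):
        rng = np.random.default_rng(seed)
        I, J, n = rng.choice([2, 3]), rng.choice([2, 3]), rng.choice([2, 4])
        y, a, b = self._balanced(seed, I, J, n)
        res = two_way_anova(y, a, b)
        fa, fb, fab = oracles.anova_ss(y, a, b)
        assert res.f_a == pytest.approx(fa, rel=1e-10, abs=1e-10)
        assert res.f_b == pytest.approx(fb, rel=1e-10, abs=1e-10)
        assert res.f_ab == pytest.approx(fab, rel=1e-10, abs=1e-10)

        frame = pd.DataFrame({"y": y, "a": a, "b": b})
        table = anova_lm(ols("y ~ C(a) * C(b)", frame).fit(), typ=2)
        assert res.f_a == pytest.approx(table.loc["C(a)", "F"], rel=1e-8)
        assert res.p_ab == pytest.approx(
            table.loc["C(a):C(b)", "PR(>F)"], rel=1e-8, abs=1e-12)

    def test_unbalanced_design_rejected_with_advice(self):
        y = [1.0, 2.0, 3.0, 4.0, 5.0]
        a = ["a1", "a1", "a1", "a2", "a2"]
        b = ["b1", "b2", "b1", "b1", "b2"]
        with pytest.raises(ValueError, match="rebalance"):
            two_way_anova(y, a, b)

    def test_single_observation_cells_rejected(self):
        with pytest.raises(ValueError, match="n >= 2"):
            two_way_anova([1.0, 2.0, 3.0, 4.0],
                          ["a1", "a1", "a2", "a2"], ["b1", "b2", "b1", "b2"])

    def test_zero_residual_variance_rejected(self):
        y = [1.0, 1.0, 2.0, 2.0, 3.0, 3.0, 4.0, 4.0]
        a = ["a1"] * 4 + ["a2"] * 4
        b = (["b1"] * 2 + ["b2"] * 2) * 2
        with pytest.raises(ValueError, match="residual"):
            two_way_anova(y, a, b)


class TestQpcrRelativeExpression:
    def _ct(self):
        rows = []
        # reference group LSF: r1, r2; test group SSC: t1
        for sample, tgt_ct in [("r1", 21.0), ("r2", 23.0), ("t1", 20.0)]:
            rows.append(dict(sample=sample, gene="GFAP", ct=tgt_ct))
            rows.append(dict(sample=sample, gene="ACTB", ct=18.0))
            rows.append(dict(sample=sample, gene="L27", ct=20.0))
        return pd.DataFrame(rows)

    def _design(self):
        return toy_design(["r1", "r2", "t1"], protocols=["LSF", "LSF", "SSC"])

    def test_delta_ct_uses_mean_of_housekeeping_cts(self):
        out = qpcr_relative_expression(self._ct(), ["GFAP"],
                                       design=self._design())
        t1 = out.query("sample == 't1'").iloc[0]
        assert t1.delta_ct == pytest.approx(20.0 - 19.0)  # mean(18, 20) = 19

    def test_rq_doubles_per_cycle_below_reference(self):
        out = qpcr_relative_expression(self._ct(), ["GFAP"],
                                       design=self._design())
        # reference dCts are 2 and 4 -> mean 3; t1 dCt 1 -> ddCt -2 -> RQ 4
        t1 = out.query("sample == 't1'").iloc[0]
        assert t1.delta_delta_ct == pytest.approx(1.0 - 3.0)
        assert t1.rq == pytest.approx(4.0)
        # a hypothetical sample with dCt exactly 1 above a reference mean of 2
        ddct = 1.0 - 2.0
        assert 2.0 ** (-ddct) == pytest.approx(2.0)

    def test_reference_sample_at_group_mean_has_rq_one(self):
        ct = self._ct()
        ct.loc[(ct["sample"] == "r2") & (ct.gene == "GFAP"), "ct"] = 21.0
        out = qpcr_relative_expression(ct, ["GFAP"], design=self._design())
        r1 = out.query("sample == 'r1'").iloc[0]
        assert r1.rq == pytest.approx(1.0)

    def test_missing_housekeeping_ct_names_sample_and_gene(self):
        ct = self._ct()
        ct = ct[~((ct["sample"] == "r2") & (ct.gene == "L27"))]
        with pytest.raises(ValueError, match="L27.*r2"):
            qpcr_relative_expression(ct, ["GFAP"], design=self._design())
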