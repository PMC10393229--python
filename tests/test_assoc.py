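"""Association engines: linear/logistic/partial-Spearman, CLR, group tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from npxtools import assoc
from npxtools.enrich import hypergeom_upper


def _idx(n):
    return pd.Index([f"S{i}" for i in range(n)])


class TestLinearAssoc:
    def test_perfect_fit(self):
        x = pd.Series(np.arange(10.0), index=_idx(10))
        row = assoc.linear_assoc(x, x)
        assert row["beta"] == pytest.approx(1.0, abs=1e-10)
        assert row["p"] < 1e-12

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(41)
        for _ in range(30):
            n = 40
            C = pd.DataFrame(rng.normal(0, 1, (n, 3)), index=_idx(n))
            x = pd.Series(rng.normal(0, 1, n), index=_idx(n))
            y = pd.Series(rng.normal(0, 1, n), index=_idx(n))
            row = assoc.linear_assoc(y, x, C)
            X = np.column_stack([np.ones(n), C.to_numpy(), x.to_numpy()])
            beta = np.linalg.solve(X.T @ X, X.T @ y.to_numpy())
            assert row["beta"] == pytest.approx(beta[-1], abs=1e-8)

    def test_null_calibration(self):
        rng = np.random.default_rng(42)
        hits = reps = 0
        for _ in range(500):
            x = pd.Series(rng.normal(0, 1, 30), index=_idx(30))
            y = pd.Series(rng.normal(0, 1, 30), index=_idx(30))
            hits += assoc.linear_assoc(y, x)["p"] < 0.05
            reps += 1
        half = 1.96 * np.sqrt(0.05 * 0.95 / reps)
        assert abs(hits / reps - 0.05) < half + 0.015


class TestBulkLinearAssoc:
    def test_matches_single_fits(self):
        rng = np.random.default_rng(43)
        n = 50
        covs = pd.DataFrame(rng.normal(0, 1, (n, 2)), index=_idx(n), columns=["a", "b"])
        preds = pd.DataFrame(rng.normal(0, 1, (n, 5)), index=_idx(n),
                             columns=[f"P{j}" for j in range(5)])
        resp = pd.DataFrame(rng.normal(0, 1, (n, 3)), index=_idx(n),
                            columns=[f"F{j}" for j in range(3)])
        tbl = assoc.bulk_linear_assoc(resp, preds, covs).set_index(["feature", "protein"])
        for f in resp.columns:
            for p in preds.columns:
                single = assoc.linear_assoc(resp[f], preds[p], covs)
                row = tbl.loc[(f, p)]
                assert row["beta"] == pytest.approx(single["beta"], abs=1e-9)
                assert row["p"] == pytest.approx(single["p"], rel=1e-6, abs=1e-12)

    def test_missing_response_rows_handled(self):
        rng = np.random.default_rng(44)
        n = 40
        preds = pd.DataFrame(rng.normal(0, 1, (n, 2)), index=_idx(n), columns=["P0", "P1"])
        resp = pd.DataFrame({"F0": rng.normal(0, 1, n)}, index=_idx(n))
        resp.iloc[:5, 0] = np.nan
        tbl = assoc.bulk_linear_assoc(resp, preds)
        assert (tbl["n_used"] == n - 5).all()


class TestLogisticAssoc:
    def test_two_by_two_cross_product_identity(self):
        # events 30/100 in exposed vs 10/100 in unexposed
        event = pd.Series([1] * 30 + [0] * 70 + [1] * 10 + [0] * 90, index=_idx(200))
        x = pd.Series([1.0] * 100 + [0.0] * 100, index=_idx(200))
        row = assoc.logistic_assoc(event, x, standardize=False)
        assert row["or_"] == pytest.approx((30 * 90) / (70 * 10), rel=1e-6)

    def test_random_tables_match_cross_product(self):
        rng = np.random.default_rng(45)
        for _ in range(100):
            a, b, c, d = rng.integers(5, 40, 4)
            event = pd.Series([1] * a + [0] * b + [1] * c + [0] * d)
            x = pd.Series([1.0] * (a + b) + [0.0] * (c + d))
            row = assoc.logistic_assoc(event, x, standardize=False)
            assert row["or_"] == pytest.approx(a * d / (b * c), rel=1e-5)

    def test_constant_x_flagged(self):
        event = pd.Series([1, 0] * 20)
        x = pd.Series([2.0] * 40)
        row = assoc.logistic_assoc(event, x)
        assert row["flag"] == "constant_x" and np.isnan(row["or_"])

    def test_separation_flagged_not_crashed(self):
        event = pd.Series([0] * 20 + [1] * 20)
        x = pd.Series(np.arange(40.0))
        row = assoc.logistic_assoc(event, x)
        assert row["flag"] == "separation"

    def test_one_outcome_class_rejected(self):
        with pytest.raises(ValueError):
            assoc.logistic_assoc(pd.Series([1] * 10), pd.Series(np.arange(10.0)))


class TestPartialSpearman:
    def test_monotone_transform_gives_one(self):
        x = pd.Series(np.linspace(0, 5, 25), index=_idx(25))
        y = np.exp(x)  # monotone transform, ranks identical
        row = assoc.partial_spearman(x, y)
        assert row["rho"] == pytest.approx(1.0, abs=1e-12)

    def test_y_equal_to_covariate_adjusted_away(self):
        rng = np.random.default_rng(46)
        z = pd.Series(rng.normal(0, 1, 40), index=_idx(40))
        x = pd.Series(rng.normal(0, 1, 40), index=_idx(40))
        y = z.copy()  # the clinical parameter IS the covariate
        row = assoc.partial_spearman(x, y, covariates=pd.DataFrame({"z": z}))
        assert abs(row["rho"]) < 0.35
        assert row["p"] > 0.05

    def test_matches_permutation_null(self):
        rng = np.random.default_rng(47)
        n = 30
        C = pd.DataFrame({"c": rng.normal(0, 1, n)}, index=_idx(n))
        x = pd.Series(rng.normal(0, 1, n), index=_idx(n)) + C["c"]
        y = pd.Series(rng.normal(0, 1, n), index=_idx(n)) + C["c"]
        row = assoc.partial_spearman(x, y, C)
        stat = abs(row["rho"])
        perm_ge = 0
        n_perm = 2000
        for _ in range(n_perm):
            yp = pd.Series(rng.permutation(y.to_numpy()), index=y.index)
            perm_ge += abs(assoc.partial_spearman(x, yp, C)["rho"]) >= stat
        p_perm = (perm_ge + 1) / (n_perm + 1)
        # t-approximation agrees with the permutation null within MC error
        assert abs(p_perm - row["p"]) < 3 * np.sqrt(p_perm * (1 - p_perm) / n_perm) + 0.02


class TestCLR:
    def test_uniform_composition_gives_zeros(self):
        tbl = pd.DataFrame([[0.25] * 4, [0.25] * 4])
        np.testing.assert_allclose(assoc.clr_transform(tbl), 0.0, atol=1e-12)

    def test_rows_sum_to_zero(self):
        rng = np.random.default_rng(48)
        raw = rng.dirichlet(np.ones(12), size=30)
        raw[raw < 0.02] = 0.0
        tbl = pd.DataFrame(raw / raw.sum(axis=1, keepdims=True))
        clr = assoc.clr_transform(tbl)
        np.testing.assert_allclose(clr.sum(axis=1), 0.0, atol=1e-9)

    def test_scale_invariance(self):
        rng = np.random.default_rng(49)
        raw = pd.DataFrame(rng.dirichlet(np.ones(8), size=10))
        doubled = raw * 2.0
        a = assoc.clr_transform(raw, pseudocount=1e-12)
        b = assoc.clr_transform(doubled, pseudocount=1e-12)
        np.testing.assert_allclose(a, b, atol=1e-7)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            assoc.clr_transform(pd.DataFrame([[-0.1, 1.1]]))


class TestPrevalenceFilter:
    @pytest.mark.parametrize("present,kept", [(20, True), (19, False), (0, False)])
    def test_boundaries(self, present, kept):
        vals = np.zeros((100, 1))
        vals[:present, 0] = 0.5
        tbl = pd.DataFrame(vals, columns=["sp"])
        out = assoc.prevalence_filter(tbl, 0.20)
        assert ("sp" in out.columns) is kept


class TestProportionComparison:
    def test_identical_groups_chi2_zero(self):
        tbl = pd.DataFrame(
            {"protein": ["a"] * 10 + ["b"] * 10,
             "p": [0.01] * 5 + [0.5] * 5 + [0.01] * 5 + [0.5] * 5}
        )
        groups = pd.Series({"a": "g1", "b": "g2"})
        props, pairwise = assoc.proportion_significant_comparison(tbl, groups)
        assert pairwise.loc[0, "chi2"] == 0.0
        assert pairwise.loc[0, "p"] == 1.0

    def test_hand_computed_chi2(self):
        # 2x2 counts 40/60 vs 10/90 -> chi2 = 24.0 without correction
        tbl = pd.DataFrame(
            {"protein": ["a"] * 100 + ["b"] * 100,
             "p": [0.01] * 40 + [0.5] * 60 + [0.01] * 10 + [0.5] * 90}
        )
        groups = pd.Series({"a": "g1", "b": "g2"})
        props, pairwise = assoc.proportion_significant_comparison(tbl, groups)
        assert pairwise.loc[0, "chi2"] == pytest.approx(24.0, abs=1e-9)

    def test_proportions_reported_per_group(self):
        tbl = pd.DataFrame(
            {"protein": ["a", "a", "b", "b", "c", "c"],
             "p": [0.01, 0.01, 0.5, 0.01, 0.5, 0.5]}
        )
        groups = pd.Series({"a": "g1", "b": "g2", "c": "g3"})
        props, pairwise = assoc.proportion_significant_comparison(tbl, groups)
        by = dict(zip(props["group"], props["proportion"]))
        assert by == {"g1": 1.0, "g2": 0.5, "g3": 0.0}
        assert len(pairwise) == 3


class TestSetEnrichmentFisher:
    def test_brute_force_tail(self):
        universe = [f"U{i}" for i in range(20)]
        A = universe[:10]
        B = universe[:8] + universe[10:12]  # overlap 8
        res = assoc.set_enrichment_fisher(A, B, universe)
        expect = hypergeom_upper(8, 10, 10, 20)
        assert res["p"] == pytest.approx(expect, abs=1e-12)
        assert res["overlap"] == 8

    def test_maximal_enrichment(self):
        universe = [f"U{i}" for i in range(20)]
        A = universe[:10]
        res = assoc.set_enrichment_fisher(A, A, universe)
        assert res["p"] == pytest.approx(hypergeom_upper(10, 10, 10, 20), abs=1e-12)

    def test_independent_sets_null_uniform(self):
        rng = np.random.default_rng(50)
        universe = [f"U{i}" for i in range(60)]
        ps = []
        for _ in range(300):
            A = rng.choice(universe, 20, replace=False)
            B = rng.choice(universe, 20, replace=False)
            ps.append(assoc.set_enrichment_fisher(A, B, universe)["p"])
        # discrete conservative test: not anti-conservative at the 5% level
        assert np.mean(np.asarray(ps) < 0.05) < 0.08

    def test_subset_violation_rejected(self):
        with pytest.raises(ValueError):
            assoc.set_enrichment_fisher(["X"], ["U0"], ["U0", "U1"])


class TestTwoStageScreen:
    def _tbl(self, beta, p, fdr, ids):
        return pd.DataFrame({"beta": beta, "p": p, "fdr": fdr}, index=ids)

    def test_stage_rules(self):
        s1 = self._tbl([1.0, 1.0, 1.0], [1e-4] * 3, [0.01, 0.01, 0.2], ["a", "b", "c"])
        s2 = self._tbl([1.0, -1.0, 1.0], [0.01, 0.01, 0.01], [0.1] * 3, ["a", "b", "c"])
        res = assoc.two_stage_cvd_screen(s1, s2)
        assert res["stage1_hits"] == ["a", "b"]
        assert res["replicated"] == ["a"]  # b flips sign, c fails stage 1

    def test_stage2_p_threshold(self):
        s1 = self._tbl([1.0], [1e-4], [0.01], ["a"])
        s2 = self._tbl([1.0], [0.06], [0.3], ["a"])
        assert assoc.two_stage_cvd_screen(s1, s2)["replicated"] == []


class TestOverlapVenn:
    def test_identical_sets(self):
        s = set("abcdef")
        v = assoc.overlap_venn(s, s, s)
        assert v["abc"] == 6
        assert v["a_only"] == v["ab_only"] == 0

    def test_pairwise_disjoint(self):
        v = assoc.overlap_venn({"a"}, {"b"}, {"c"})
        assert v["abc"] == 0 and v["union"] == 3

    def test_regions_partition_union(self):
        rng = np.random.default_rng(51)
        universe = [f"U{i}" for i in range(40)]
        for _ in range(20):
            A, B, C = (set(rng.choice(universe, rng.integers(0, 30))) for _ in range(3))
            v = assoc.overlap_venn(A, B, C)
            total = sum(v[k] for k in
                        ("a_only", "b_only", "c_only", "ab_only", "ac_only", "bc_only", "abc"))
            assert total == v["union"] == len(A | B | C)
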