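"""Differential expression: OLS, eBayes moderation, BH, sDEP calling, PCA test."""

import json
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from npxtools import diffexp, synth
from npxtools.diffexp import EBayesPrior
from tests.conftest import toy_matrix

DATA = Path(__file__).parent / "data"


def _random_fit(rng, n=30, k=4, p=20):
    X = pd.DataFrame(rng.normal(0, 1, (n, k)), columns=[f"c{i}" for i in range(k)])
    X.insert(0, "intercept", 1.0)
    X = X.rename(columns={"c0": "group"})
    Y = pd.DataFrame(rng.normal(0, 1, (n, p)), index=X.index,
                     columns=[f"G{j}" for j in range(p)])
    return X, Y


class TestFitLinearModels:
    def test_agrees_with_lstsq_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            X, Y = _random_fit(rng, n=30, k=3, p=5)
            fits = diffexp.fit_linear_models(Y, X, coef="group")
            Xm = X.to_numpy()
            j = list(X.columns).index("group")
            for g, col in enumerate(Y.columns):
                beta = np.linalg.lstsq(Xm, Y[col].to_numpy(), rcond=None)[0]
                assert fits.loc[col, "effect"] == pytest.approx(beta[j], abs=1e-8)
                resid = Y[col].to_numpy() - Xm @ beta
                s2 = resid @ resid / (30 - Xm.shape[1])
                assert fits.loc[col, "s2"] == pytest.approx(s2, rel=1e-8)

    def test_noiseless_planted_effect_is_exact(self, small_config):
        cfg = small_config
        cfg = synth.SynthConfig(**{**cfg.__dict__, "noise_sd": 0.0, "n_low_detect": 0,
                                   "n_outlier_plhiv_disc": 0, "n_outlier_hc_disc": 0})
        m, samples, truth = synth.generate_cohort(cfg, "discovery")
        X = diffexp.make_design(samples)
        fits = diffexp.fit_linear_models(m, X)
        prot = m.proteins()
        for pid, effect in list(truth.true_dep_effects.items())[:10]:
            aid = [a for a in m.assay_ids if prot[a] == pid][0]
            assert fits.loc[aid, "effect"] == pytest.approx(effect, abs=1e-9)
            assert fits.loc[aid, "s2"] == pytest.approx(0.0, abs=1e-16)

    def test_orthogonal_group_equals_mean_difference(self):
        rng = np.random.default_rng(12)
        n = 40
        group = np.repeat([0.0, 1.0], n // 2)
        X = pd.DataFrame({"intercept": 1.0, "group": group})
        Y = pd.DataFrame({"G0": rng.normal(0, 1, n)})
        fits = diffexp.fit_linear_models(Y, X)
        diff = Y["G0"][group == 1].mean() - Y["G0"][group == 0].mean()
        assert fits.loc["G0", "effect"] == pytest.approx(diff, abs=1e-12)

    def test_rank_deficient_design_is_error(self):
        X = pd.DataFrame({"intercept": 1.0, "group": [0, 1] * 5, "dup": [0, 1] * 5})
        Y = pd.DataFrame({"G0": np.arange(10.0)})
        with pytest.raises(ValueError, match="rank"):
            diffexp.fit_linear_models(Y, X)


class TestEBayes:
    def _fits(self, rng, p=40, n=16):
        group = np.repeat([0.0, 1.0], n // 2)
        X = pd.DataFrame({"intercept": 1.0, "group": group})
        Y = pd.DataFrame(rng.normal(0, 1, (n, p)), columns=[f"G{j}" for j in range(p)])
        return diffexp.fit_linear_models(Y, X)

    def test_d0_zero_reproduces_ordinary_t(self):
        fits = self._fits(np.random.default_rng(13))
        mod = diffexp.ebayes_moderate(fits, EBayesPrior(d0=0.0, s0_sq=1.0))
        t_ord = fits["effect"] / fits["se"]
        np.testing.assert_allclose(mod["t_mod"], t_ord, rtol=1e-12)

    def test_d0_inf_shrinks_fully(self):
        fits = self._fits(np.random.default_rng(14))
        mod = diffexp.ebayes_moderate(fits, EBayesPrior(d0=np.inf, s0_sq=2.5))
        np.testing.assert_allclose(mod["s2_post"], 2.5)

    def test_equal_variances_are_fixed_point(self):
        fits = self._fits(np.random.default_rng(15))
        fits["s2"] = 1.7
        for d0 in (0.5, 4.0, 100.0):
            mod = diffexp.ebayes_moderate(fits, EBayesPrior(d0=d0, s0_sq=1.7))
            np.testing.assert_allclose(mod["s2_post"], 1.7, rtol=1e-12)

    def test_posterior_between_sample_and_prior(self):
        fits = self._fits(np.random.default_rng(16))
        mod = diffexp.ebayes_moderate(fits)
        prior = mod.attrs["prior"]
        lo = np.minimum(fits["s2"], prior.s0_sq)
        hi = np.maximum(fits["s2"], prior.s0_sq)
        assert ((mod["s2_post"] >= lo - 1e-12) & (mod["s2_post"] <= hi + 1e-12)).all()

    def test_matches_limma_reference(self):
        """Frozen moderated statistics from the Bioconductor limma fit."""
        ref = json.loads((DATA / "limma_reference.json").read_text())
        rng = np.random.default_rng(20240917)
        n, p = 24, 50
        group = np.repeat([0.0, 1.0], n // 2)
        age = rng.uniform(25, 70, n)
        sigma = np.exp(rng.normal(0.0, 0.5, p))
        effect = rng.normal(0.0, 0.5, p)
        Y = (
            2.0
            + np.outer(group, effect)
            + 0.02 * np.outer(age - 45, np.ones(p))
            + rng.normal(0, 1, (n, p)) * sigma[None, :]
        )
        vals = pd.DataFrame(Y, columns=[f"G{i}" for i in range(p)])
        X = pd.DataFrame({"intercept": 1.0, "group": group, "age": age})
        mod = diffexp.ebayes_moderate(diffexp.fit_linear_models(vals, X))
        prior = mod.attrs["prior"]
        assert prior.d0 == pytest.approx(ref["d0"], rel=1e-9)
        assert prior.s0_sq == pytest.approx(ref["s0_sq"], rel=1e-9)
        np.testing.assert_allclose(mod["effect"], ref["coef"], atol=1e-10)
        np.testing.assert_allclose(mod["t_mod"], ref["t"], atol=1e-9)
        np.testing.assert_allclose(mod["p"], ref["p"], atol=1e-9)
        np.testing.assert_allclose(mod["s2_post"], ref["s2_post"], atol=1e-9)

    def test_null_calibration(self):
        """Moderated P values are uniform under the null (pooled over seeds)."""
        hits = total = 0
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            fits = self._fits(rng, p=400, n=60)
            mod = diffexp.ebayes_moderate(fits)
            hits += int((mod["p"] < 0.05).sum())
            total += len(mod)
        frac = hits / total
        # 95% binomial CI around 0.05 for n=2000
        half = 1.96 * np.sqrt(0.05 * 0.95 / total)
        assert abs(frac - 0.05) < half + 1e-12

    def test_sign_flip_symmetry(self):
        fits = self._fits(np.random.default_rng(17))
        flipped = fits.copy()
        flipped["effect"] = -flipped["effect"]
        a = diffexp.ebayes_moderate(fits)
        b = diffexp.ebayes_moderate(flipped)
        np.testing.assert_allclose(a["p"], b["p"], rtol=1e-12)
        np.testing.assert_allclose(a["t_mod"], -b["t_mod"], rtol=1e-12)


class TestBHAdjust:
    def test_hand_computed_step_up(self):
        adj = diffexp.bh_adjust([0.01, 0.02, 0.04, 0.05])
        np.testing.assert_allclose(adj, [0.04, 0.04, 0.05, 0.05])

    def test_single_p_unchanged(self):
        assert diffexp.bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_ties_all_equal(self):
        np.testing.assert_allclose(diffexp.bh_adjust([0.2] * 6), [0.2] * 6)

    def test_matches_direct_definition_and_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(18)
        for _ in range(200):
            m = int(rng.integers(1, 40))
            p = rng.random(m)
            mine = diffexp.bh_adjust(p)
            # direct definition: min over j >= rank of p_(j) * m / j
            order = np.argsort(p, kind="stable")
            direct = np.empty(m)
            for pos, idx in enumerate(order):
                js = np.arange(pos, m)
                direct[idx] = min(1.0, (p[order][pos:] * m / (js + 1)).min())
            np.testing.assert_allclose(mine, direct, rtol=1e-12)
            sm_adj = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(mine, sm_adj, rtol=1e-12)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50))
    @settings(deadline=None, max_examples=50)
    def test_monotone_and_bounded(self, p):
        adj = diffexp.bh_adjust(p)
        assert ((adj >= np.asarray(p) - 1e-15) & (adj <= 1.0)).all()
        order = np.argsort(p, kind="stable")
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            diffexp.bh_adjust([0.5, 1.5])


class TestCallSdeps:
    def _table(self, effect, p, fdr):
        return pd.DataFrame({"effect": effect, "p": p, "fdr": fdr},
                            index=[f"P{i}" for i in range(len(effect))])

    def test_rule_membership_and_direction(self):
        disc = self._table([1.0, 1.0, -1.0], [1e-4] * 3, [0.04, 0.04, 0.04])
        repl = self._table([0.5, -0.5, -0.2], [0.03, 0.03, 0.03], [0.2] * 3)
        sdeps = diffexp.call_sdeps(disc, repl)
        assert list(sdeps.index) == ["P0", "P2"]  # P1 flips sign
        assert sdeps.loc["P0", "up"] and not sdeps.loc["P2", "up"]

    def test_thresholds_are_strict(self):
        disc = self._table([1.0], [0.01], [0.05])
        repl = self._table([1.0], [0.05], [0.5])
        assert len(diffexp.call_sdeps(disc, repl)) == 0

    def test_missing_proteins_excluded(self):
        disc = self._table([1.0, 1.0], [1e-4] * 2, [0.01] * 2)
        repl = self._table([1.0], [0.001], [0.01])
        sdeps = diffexp.call_sdeps(disc, repl.iloc[:1])
        assert list(sdeps.index) == ["P0"]

    def test_group_relabel_flips_sign_keeps_p(self, small_config):
        m, samples, _ = synth.generate_cohort(small_config, "discovery")
        from npxtools import qc as qcmod

        m, _ = qcmod.dedup_control_assays(m, synth.CONTROL_PROTEINS, "inflammation")
        de_a = diffexp.run_de(m, samples)
        flipped = samples.copy()
        flipped["group"] = np.where(flipped["group"] == "PLHIV", "HC", "PLHIV")
        de_b = diffexp.run_de(m, flipped)
        np.testing.assert_allclose(de_a["effect"], -de_b["effect"], rtol=1e-9)
        np.testing.assert_allclose(de_a["p"], de_b["p"], rtol=1e-9)


class TestFoldChangeSubset:
    def _sdeps(self, eff_d, eff_r):
        return pd.DataFrame(
            {"effect_disc": eff_d, "effect_repl": eff_r,
             "fdr_disc": 0.01, "p_repl": 0.01, "up": np.asarray(eff_d) > 0},
            index=[f"P{i}" for i in range(len(eff_d))],
        )

    def test_both_cohort_requirement(self):
        sdeps = self._sdeps([1.6, 1.6], [1.7, 1.4])
        assert diffexp.fold_change_subset(sdeps, 1.5, "npx_diff") == ["P0"]

    def test_linear_scale(self):
        sdeps = self._sdeps([0.585], [0.60])
        assert diffexp.fold_change_subset(sdeps, 1.5, "linear_fc") == ["P0"]
        assert diffexp.fold_change_subset(sdeps, 1.5, "npx_diff") == []

    def test_unknown_scale_rejected(self):
        with pytest.raises(ValueError):
            diffexp.fold_change_subset(self._sdeps([1.0], [1.0]), 1.5, "bogus")


class TestPCAGroupTest:
    def test_u_statistic_matches_counting_oracle(self):
        rng = np.random.default_rng(19)
        vals = rng.normal(0, 1, (16, 6))
        m = toy_matrix(vals)
        groups = pd.Series(["A"] * 8 + ["B"] * 8, index=m.sample_ids)
        res = diffexp.pca_group_test(m, groups)
        scores = res["scores"]
        for pc in ("PC1", "PC2"):
            a = scores[pc][:8].to_numpy()
            b = scores[pc][8:].to_numpy()
            u_brute = sum((x > y) + 0.5 * (x == y) for x in a for y in b)
            assert res["tests"][pc]["U"] == pytest.approx(u_brute)

    def test_separated_groups_extreme_u(self):
        vals = np.zeros((12, 4))
        vals[:6] += 5.0
        vals += np.random.default_rng(20).normal(0, 0.01, vals.shape)
        m = toy_matrix(vals)
        groups = pd.Series(["A"] * 6 + ["B"] * 6, index=m.sample_ids)
        res = diffexp.pca_group_test(m, groups)
        assert res["tests"]["PC1"]["U"] in (0.0, 36.0)
        assert res["tests"]["PC1"]["p"] < 0.01
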