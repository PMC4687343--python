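"""Differential expression: linear fit, variance moderation, selection.

The moderated-t implementation is checked against reference statistics
computed once with R/Bioconductor limma (lmFit + eBayes) on the exact
matrix regenerated below; the frozen numbers are limma's output.
"""

import numpy as np
import pandas as pd
import pytest

from fxsmap import diffexpr as de


def _two_group(ko, wt):
    """Expression frame + metadata from per-group value lists (1 gene)."""
    ko, wt = list(map(float, ko)), list(map(float, wt))
    cols = [f"k{i}" for i in range(len(ko))] + [f"w{i}" for i in range(len(wt))]
    expr = pd.DataFrame([ko + wt], index=["g"], columns=cols)
    meta = pd.DataFrame({"genotype": ["KO"] * len(ko) + ["WT"] * len(wt)},
                        index=cols)
    return expr, meta


class TestGenewiseFit:
    def test_zero_variance_groups(self):
        expr, meta = _two_group([2, 2], [1, 1])
        fit = de.fit_genewise_model(expr, meta)
        assert fit.loc["g", "beta_hat"] == 1.0
        assert fit.loc["g", "s2"] == 0.0

    def test_pooled_variance_hand_computed(self):
        # KO {3,1}: mean 2, SS 2; WT {2,0}: mean 1, SS 2; s2 = 4/2 = 2
        expr, meta = _two_group([3, 1], [2, 0])
        fit = de.fit_genewise_model(expr, meta)
        assert fit.loc["g", "beta_hat"] == pytest.approx(1.0)
        assert fit.loc["g", "s2"] == pytest.approx(2.0)
        assert fit.loc["g", "df_residual"] == 2

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(0)
        cols = [f"s{i}" for i in range(10)]
        expr = pd.DataFrame(rng.normal(size=(20, 10)), columns=cols)
        meta = pd.DataFrame({"genotype": ["KO"] * 5 + ["WT"] * 5}, index=cols)
        perm = rng.permutation(cols)
        a = de.de_table(expr, meta)
        b = de.de_table(expr[perm], meta.loc[perm])
        pd.testing.assert_frame_equal(a, b)

    def test_small_group_raises_with_stratum_name(self):
        expr, meta = _two_group([1], [2, 3])
        with pytest.raises(ValueError, match="KO"):
            de.fit_genewise_model(expr, meta)


class TestModeration:
    def test_matches_limma_reference(self):
        # regenerate the oracle matrix (identical RNG stream)
        rng = np.random.default_rng(42)
        g = 80
        sd = np.exp(rng.normal(-0.7, 0.5, g))
        beta = np.where(rng.random(g) < 0.2, rng.normal(0, 1, g), 0.0)
        ko = rng.normal(0, 1, (g, 5)) * sd[:, None] + beta[:, None]
        wt = rng.normal(0, 1, (g, 5)) * sd[:, None]
        expr = pd.DataFrame(np.hstack([ko, wt]),
                            index=[f"g{i}" for i in range(g)],
                            columns=[f"K{i}" for i in range(5)]
                                    + [f"W{i}" for i in range(5)])
        meta = pd.DataFrame({"genotype": ["KO"] * 5 + ["WT"] * 5},
                            index=expr.columns)
        tab = de.de_table(expr, meta)
        # frozen limma (eBayes) output for this matrix
        assert tab["df_prior"].iloc[0] == pytest.approx(4.000336437, rel=1e-6)
        assert tab["s2_prior"].iloc[0] == pytest.approx(0.1866892628, rel=1e-6)
        expected = {  # gene index (1-based) -> (t, p, s2_post)
            1: (-2.253335069, 0.04373287477, 0.2938545675),
            2: (-2.203488307, 0.0478358253, 0.1952002087),
            3: (-2.151942595, 0.05246038345, 0.6045320897),
            10: (-0.7967839505, 0.4410560417, 0.1012866317),
            25: (-1.488974671, 0.162297658, 0.09814271286),
            50: (0.3366055247, 0.7422275769, 0.2639121001),
            80: (-0.8005539303, 0.4389520721, 0.1158219878),
        }
        for idx, (t, p, s2p) in expected.items():
            row = tab.iloc[idx - 1]
            assert row["t_moderated"] == pytest.approx(t, rel=1e-6)
            assert row["p_value"] == pytest.approx(p, rel=1e-6)
            assert row["s2_posterior"] == pytest.approx(s2p, rel=1e-6)

    def test_shrinkage_formula(self):
        # d0=2, s0^2=4, df=4, s2=1 -> posterior (2*4 + 4*1)/(2+4) = 2
        post = (2 * 4 + 4 * 1) / (2 + 4)
        assert post == 2.0
        stats = de.ModeratedStats(df_prior=2.0, s2_prior=4.0,
                                  s2_posterior=np.array([post]))
        assert stats.s2_posterior[0] == pytest.approx(
            (stats.df_prior * stats.s2_prior + 4 * 1)
            / (stats.df_prior + 4))

    def test_posterior_between_prior_and_observed(self):
        rng = np.random.default_rng(3)
        s2 = rng.chisquare(4, 500) / 4 * 0.3
        mod = de.moderate_variances(s2, 8.0)
        assert 0 < mod.df_prior < np.inf
        lo = np.minimum(s2, mod.s2_prior)
        hi = np.maximum(s2, mod.s2_prior)
        assert np.all(mod.s2_posterior >= lo - 1e-12)
        assert np.all(mod.s2_posterior <= hi + 1e-12)

    def test_all_equal_variances_full_shrinkage(self):
        mod = de.moderate_variances(np.full(50, 0.7), 8.0)
        assert np.isinf(mod.df_prior)
        assert mod.s2_prior == pytest.approx(0.7)
        assert np.allclose(mod.s2_posterior, 0.7)

    def test_few_genes_falls_back_to_ordinary_t(self):
        with pytest.warns(UserWarning, match="fewer than 10"):
            mod = de.moderate_variances(np.array([1.0, 2.0]), 4.0)
        assert mod.df_prior == 0.0
        assert np.allclose(mod.s2_posterior, [1.0, 2.0])

    def test_trigamma_inverse_round_trip(self):
        from scipy.special import polygamma
        x = np.array([0.01, 0.1, 1.0, 5.0, 50.0])
        y = de.trigamma_inverse(x)
        assert np.allclose(polygamma(1, y), x, rtol=1e-6)


class TestDeTable:
    def test_sign_antisymmetry_under_label_swap(self):
        rng = np.random.default_rng(1)
        cols = [f"s{i}" for i in range(12)]
        expr = pd.DataFrame(rng.normal(size=(50, 12)), columns=cols)
        meta = pd.DataFrame({"genotype": ["KO"] * 6 + ["WT"] * 6}, index=cols)
        a = de.de_table(expr, meta, levels=("KO", "WT"))
        b = de.de_table(expr, meta, levels=("WT", "KO"))
        assert np.allclose(a["beta_hat"], -b["beta_hat"])
        assert np.allclose(a["t_moderated"], -b["t_moderated"])
        assert np.allclose(a["p_value"], b["p_value"])

    def test_scale_equivariance(self):
        rng = np.random.default_rng(2)
        cols = [f"s{i}" for i in range(10)]
        expr = pd.DataFrame(rng.normal(size=(60, 10)), columns=cols)
        meta = pd.DataFrame({"genotype": ["KO"] * 5 + ["WT"] * 5}, index=cols)
        a = de.de_table(expr, meta)
        b = de.de_table(expr * 3.0, meta)
        assert np.allclose(b["beta_hat"], 3.0 * a["beta_hat"])
        assert np.allclose(b["t_moderated"], a["t_moderated"])
        assert np.allclose(b["p_value"], a["p_value"])

    def test_zero_variance_zero_effect_gene(self):
        cols = [f"s{i}" for i in range(8)]
        expr = pd.DataFrame(np.ones((12, 8)), columns=cols)
        meta = pd.DataFrame({"genotype": ["KO"] * 4 + ["WT"] * 4}, index=cols)
        tab = de.de_table(expr, meta)
        assert (tab["t_moderated"] == 0).all()
        assert (tab["p_value"] == 1.0).all()

    def test_fmr1_most_significant_down_gene_in_every_stratum(self):
        from fxsmap import synthetic
        cfg = synthetic.MouseSimConfig(n_genes=300, sigma_noise=0.05, seed=6)
        expr, meta, truth = synthetic.simulate_mouse_dataset(cfg)
        fmr1 = truth.params["fmr1_gene_id"]
        for region in ("cortex", "hippocampus"):
            for system in ("culture", "tissue"):
                tab = de.de_table(expr, meta,
                                  stratum={"region": region, "system": system})
                down = tab[tab["direction"] == "down"]
                assert down["p_value"].idxmin() == fmr1


class TestSelection:
    @staticmethod
    def _fake(ps, dirs):
        return pd.DataFrame({"p_value": ps, "direction": dirs},
                            index=[f"g{i}" for i in range(len(ps))])

    def test_nothing_significant(self):
        up, down, comb = de.select_de(self._fake([0.5, 0.5], ["up", "down"]))
        assert up == [] and down == [] and comb == []

    def test_threshold_and_direction(self):
        up, down, comb = de.select_de(
            self._fake([0.01, 0.04, 0.06], ["up", "down", "up"]), alpha=0.05)
        assert up == ["g0"] and down == ["g1"] and set(comb) == {"g0", "g1"}

    def test_counts_equal_bruteforce_refilter(self):
        rng = np.random.default_rng(4)
        tab = self._fake(rng.uniform(size=200),
                         rng.choice(["up", "down"], 200))
        up, down, comb = de.select_de(tab, alpha=0.07)
        brute = tab[tab["p_value"] < 0.07]
        assert len(up) == (brute["direction"] == "up").sum()
        assert len(down) == (brute["direction"] == "down").sum()
        assert len(comb) == len(brute)

    def test_bh_adjustment_monotone(self):
        tab = self._fake([0.001, 0.01, 0.02, 0.8], ["up"] * 4)
        _, _, raw = de.select_de(tab, alpha=0.05)
        _, _, adj = de.select_de(tab, alpha=0.05, adjust="bh")
        assert set(adj) <= set(raw)


class TestDuplicateCollapse:
    def test_duplicates_averaged_into_source(self):
        cols = ["a", "a_d", "b"]
        expr = pd.DataFrame([[1.0, 3.0, 5.0]], columns=cols)
        meta = pd.DataFrame({"genotype": ["KO"] * 3,
                             "source_id": ["", "a", ""]}, index=cols)
        out, meta2 = de.collapse_duplicates(expr, meta)
        assert list(out.columns) == ["a", "b"]
        assert out.loc[0, "a"] == 2.0
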