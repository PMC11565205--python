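"""Two-way ANOVA, variance components, heritability, GCV/PCV, fold change."""

import numpy as np
import pandas as pd
import pytest

import sorghum_iwue as si
from sorghum_iwue.quantgen import variance_components
from sorghum_iwue.schema import DataQualityWarning


def _long(values):
    """values[g][t] is a list of replicate observations."""
    rows = []
    for g, by_trt in enumerate(values):
        for t, obs in zip(("WW", "WS"), by_trt):
            for r, y in enumerate(obs):
                rows.append((f"G{g + 1}", t, r + 1, y))
    return pd.DataFrame(rows, columns=["genotype_id", "treatment", "replicate", "y"])


def _brute_force_ss(df):
    """Direct double-loop deviation sums for the balanced two-way layout."""
    gs = sorted(df["genotype_id"].unique())
    ts = sorted(df["treatment"].unique())
    grand = df["y"].mean()
    cell = {
        (g, t): df.loc[(df.genotype_id == g) & (df.treatment == t), "y"]
        for g in gs
        for t in ts
    }
    r = len(next(iter(cell.values())))
    g_mean = {g: df.loc[df.genotype_id == g, "y"].mean() for g in gs}
    t_mean = {t: df.loc[df.treatment == t, "y"].mean() for t in ts}
    ss_g = len(ts) * r * sum((g_mean[g] - grand) ** 2 for g in gs)
    ss_t = len(gs) * r * sum((t_mean[t] - grand) ** 2 for t in ts)
    ss_gt = r * sum(
        (cell[(g, t)].mean() - g_mean[g] - t_mean[t] + grand) ** 2
        for g in gs
        for t in ts
    )
    ss_e = sum(
        ((cell[(g, t)] - cell[(g, t)].mean()) ** 2).sum() for g in gs for t in ts
    )
    return ss_g, ss_t, ss_gt, ss_e


class TestTwoWayAnova:
    def test_matches_brute_force_enumeration(self, rng):
        for n_g, n_r in [(2, 2), (3, 3), (5, 4)]:
            values = [
                [rng.normal(10, 3, size=n_r), rng.normal(8, 3, size=n_r)]
                for _ in range(n_g)
            ]
            df = _long(values)
            res = si.TwoWayAnova(df, "y").fit()
            ss = _brute_force_ss(df)
            for name, expected in zip(
                ["genotype_id", "treatment", "genotype_id:treatment", "residual"], ss
            ):
                assert res.table.loc[name, "sum_sq"] == pytest.approx(
                    expected, rel=1e-10
                )

    def test_matches_statsmodels(self, rng):
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        values = [
            [rng.normal(10, 2, size=3), rng.normal(7, 2, size=3)] for _ in range(6)
        ]
        df = _long(values)
        res = si.TwoWayAnova(df, "y").fit()
        lm = ols("y ~ C(genotype_id) * C(treatment)", data=df).fit()
        ref = sm.stats.anova_lm(lm, typ=1)
        assert res.table.loc["genotype_id", "sum_sq"] == pytest.approx(
            ref.loc["C(genotype_id)", "sum_sq"], rel=1e-9
        )
        assert res.table.loc["genotype_id:treatment", "F"] == pytest.approx(
            ref.loc["C(genotype_id):C(treatment)", "F"], rel=1e-9
        )
        assert res.table.loc["treatment", "p"] == pytest.approx(
            ref.loc["C(treatment)", "PR(>F)"], rel=1e-6, abs=1e-12
        )

    def test_constant_data_gives_zero_ss_and_missing_f(self):
        df = _long([[[5.0, 5.0], [5.0, 5.0]], [[5.0, 5.0], [5.0, 5.0]]])
        res = si.TwoWayAnova(df, "y").fit()
        assert (res.table["sum_sq"] == 0).all()
        assert np.isnan(res.table.loc["genotype_id", "F"])

    def test_genotype_shift_only_moves_genotype_ss(self, rng):
        values = [
            [rng.normal(10, 1, size=3), rng.normal(10, 1, size=3)] for _ in range(4)
        ]
        df = _long(values)
        base = si.TwoWayAnova(df, "y").fit().table
        shifted = df.copy()
        shift = shifted["genotype_id"].map({"G1": 0.0, "G2": 3.0, "G3": 6.0, "G4": 9.0})
        shifted["y"] = shifted["y"] + shift
        after = si.TwoWayAnova(shifted, "y").fit().table
        assert after.loc["genotype_id", "sum_sq"] > base.loc["genotype_id", "sum_sq"]
        for src in ("treatment", "genotype_id:treatment", "residual"):
            assert after.loc[src, "sum_sq"] == pytest.approx(
                base.loc[src, "sum_sq"], rel=1e-9
            )

    def test_unbalanced_falls_back_to_unweighted_means(self, rng):
        values = [
            [rng.normal(10, 2, size=3), rng.normal(8, 2, size=3)] for _ in range(3)
        ]
        df = _long(values).drop(index=[0])  # remove one replicate
        with pytest.warns(DataQualityWarning, match="unbalanced"):
            res = si.TwoWayAnova(df, "y").fit()
        assert not res.balanced
        assert np.isfinite(res.table.loc["genotype_id", "F"])

    def test_empty_cell_is_design_error(self):
        df = _long([[[1.0, 2.0], [3.0, 4.0]], [[5.0, 6.0], [7.0, 8.0]]])
        df = df.loc[~((df.genotype_id == "G2") & (df.treatment == "WS"))]
        with pytest.raises(ValueError, match="empty cells"):
            si.TwoWayAnova(df, "y").fit()

    def test_p_invariant_to_constant_offset(self, rng):
        values = [
            [rng.normal(10, 2, size=3), rng.normal(8, 2, size=3)] for _ in range(4)
        ]
        df = _long(values)
        p1 = si.TwoWayAnova(df, "y").fit().table["p"]
        df2 = df.assign(y=df["y"] + 1000.0)
        p2 = si.TwoWayAnova(df2, "y").fit().table["p"]
        np.testing.assert_allclose(p1.dropna(), p2.dropna(), rtol=1e-8)


class TestVarianceComponents:
    def test_paper_literal_arithmetic(self):
        vc = variance_components(
            127.2, 61.6, 61.49, n_treatments=2, n_replicates_std=5,
            convention="paper_literal",
        )
        assert vc.sigma2_g == pytest.approx(127.2)
        assert vc.sigma2_p == pytest.approx(127.2 + 61.6 / 2 + 61.49 / 5, rel=1e-12)
        assert vc.sigma2_p == pytest.approx(170.298, abs=1e-3)

    def test_interaction_divisor_override(self):
        vc = variance_components(100.0, 40.0, 20.0, interaction_divisor=4.0)
        assert vc.sigma2_p == pytest.approx(100.0 + 10.0 + 4.0)

    def test_all_zero_mean_squares(self):
        vc = variance_components(0.0, 0.0, 0.0)
        assert vc.sigma2_p == 0.0
        with pytest.warns(DataQualityWarning):
            assert vc.heritability == 0.0

    def test_ems_truncation_flagged(self):
        vc = variance_components(
            10.0, 20.0, 5.0, n_treatments=2, n_replicates=3, convention="ems"
        )
        assert vc.sigma2_g == 0.0
        assert "sigma2_g" in vc.truncated

    def test_ems_estimators(self):
        vc = variance_components(
            50.0, 14.0, 8.0, n_treatments=2, n_replicates=3, convention="ems"
        )
        assert vc.sigma2_e == pytest.approx(8.0)
        assert vc.sigma2_gxt == pytest.approx((14.0 - 8.0) / 3)
        assert vc.sigma2_g == pytest.approx((50.0 - 14.0) / 6)

    def test_paper_literal_heritability_bounded(self, rng):
        for _ in range(20):
            ms = rng.uniform(0.1, 100.0, size=3)
            vc = variance_components(*ms)
            assert 0.0 <= vc.heritability <= 1.0


class TestHeritabilityAndCv:
    @pytest.mark.parametrize(
        "s2g, s2p, expected",
        [(127.2, 160.03, 0.79), (963.0, 1281.63, 0.75), (0.0, 5.0, 0.0)],
    )
    def test_heritability(self, s2g, s2p, expected):
        assert si.heritability(s2g, s2p) == pytest.approx(expected, abs=0.005)

    @pytest.mark.parametrize(
        "s2g, s2p, mean, gcv, pcv",
        [
            (127.2, 160.03, 23.2, 48.61, 54.53),
            (963.0, 1281.63, 148.35, 20.92, 24.13),
        ],
    )
    def test_gcv_pcv(self, s2g, s2p, mean, gcv, pcv):
        got = si.gcv_pcv(s2g, s2p, mean)
        assert got[0] == pytest.approx(gcv, abs=0.005)
        assert got[1] == pytest.approx(pcv, abs=0.005)

    def test_zero_genotypic_variance(self):
        gcv, pcv = si.gcv_pcv(0.0, 4.0, 10.0)
        assert gcv == 0.0
        assert pcv == pytest.approx(20.0)

    def test_zero_mean_instructs_substitute(self):
        with pytest.raises(ValueError, match="substitute"):
            si.gcv_pcv(1.0, 2.0, 0.0)


class TestFoldChange:
    def test_printed_extremes(self):
        means = pd.DataFrame(
            {"genotype_id": ["G1", "G2"], "treatment": "WW", "A_n": [17.6, 39.3]}
        )
        assert si.fold_change(means, "A_n", "WW") == pytest.approx(2.23, abs=0.005)

    def test_equal_means_give_unity(self):
        means = pd.DataFrame(
            {"genotype_id": ["G1", "G2"], "treatment": "WW", "A_n": [5.0, 5.0]}
        )
        assert si.fold_change(means, "A_n", "WW") == 1.0

    def test_enumeration(self):
        means = pd.DataFrame(
            {"genotype_id": ["G1", "G2", "G3"], "treatment": "WS", "A_n": [2.0, 4.0, 8.0]}
        )
        assert si.fold_change(means, "A_n", "WS") == pytest.approx(4.0)

    def test_nonpositive_minimum_rejected(self):
        means = pd.DataFrame(
            {"genotype_id": ["G1", "G2"], "treatment": "WW", "A_n": [-1.0, 5.0]}
        )
        with pytest.raises(ValueError, match="minimum"):
            si.fold_change(means, "A_n", "WW")


class TestTraitSummary:
    def test_structure_and_hb2_range(self, derived, retained_means):
        table = si.trait_summary(derived, retained_means, ["A_n", "g_s", "iwue"])
        assert set(table["trait"]) == {"A_n", "g_s", "iwue"}
        assert ((table["H_b2"] >= 0) & (table["H_b2"] <= 1)).all()
        assert (table["PCV_pct"] >= table["GCV_pct"]).all()
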