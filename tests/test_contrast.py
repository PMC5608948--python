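"""Adjusted ANOVA, least-squares means, fold changes: oracles and golden values."""

import numpy as np
import pandas as pd
import pytest

from omicdiv.contrast import (
    anova_feature,
    fold_change,
    least_squares_means,
    platform_contrast,
)
from omicdiv.reference import MIRNA_FC_EXCLUDED, MIRNA_LSM, POPULATIONS


def one_way_anova_oracle(y, groups):
    """Textbook sums-of-squares one-way ANOVA F statistic."""
    y = np.asarray(y, float)
    grand = y.mean()
    levels = pd.unique(groups)
    ss_between = sum(
        len(y[groups == g]) * (y[groups == g].mean() - grand) ** 2 for g in levels
    )
    ss_within = sum(((y[groups == g] - y[groups == g].mean()) ** 2).sum() for g in levels)
    df_b, df_w = len(levels) - 1, len(y) - len(levels)
    return (ss_between / df_b) / (ss_within / df_w)


@pytest.mark.parametrize(
    "mirna,pop_index,expected",
    [
        (m, i, d["fc"][i - 1])
        for m, d in MIRNA_LSM.items()
        for i in (1, 2)
        if (m, POPULATIONS[i]) not in MIRNA_FC_EXCLUDED
    ],
)
def test_published_fold_changes_from_published_lsm(mirna, pop_index, expected):
    """2^(lsm_a - lsm_Chinese) reproduces every legible printed FC at 2 dp."""
    from helpers import matches_printed

    lsm = MIRNA_LSM[mirna]["lsm"]
    assert matches_printed(fold_change(lsm[pop_index], lsm[0]), expected, dp=2)


class TestFoldChange:
    def test_equal_means_give_unity(self):
        assert fold_change(18.0, 18.0) == 1.0

    def test_reciprocal_identity_exact(self, rng):
        for _ in range(50):
            a, b = rng.normal(18, 2, size=2)
            assert fold_change(a, b) * fold_change(b, a) == pytest.approx(1.0, abs=1e-15)

    def test_monotone_in_first_argument(self):
        assert fold_change(19.0, 18.0) > fold_change(18.5, 18.0)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            fold_change(np.nan, 18.0)


class TestAnovaFeature:
    def _balanced(self, rng, n=60, shift=0.0):
        pops = pd.Series(["A"] * n + ["B"] * n + ["C"] * n)
        y = pd.Series(rng.standard_normal(3 * n), name="f")
        y[pops == "C"] += shift
        return y, pops

    def test_matches_sums_of_squares_oracle(self, rng):
        y, pops = self._balanced(rng)
        fit = anova_feature(y, pops)
        oracle = one_way_anova_oracle(y.to_numpy(), pops.to_numpy())
        assert fit.f_stat == pytest.approx(oracle, abs=1e-10)

    def test_type_one_error_near_nominal(self, rng):
        rejections = 0
        n_sim = 400
        for _ in range(n_sim):
            y, pops = self._balanced(rng, n=20)
            if anova_feature(y, pops).p_raw < 0.05:
                rejections += 1
        assert 0.03 <= rejections / n_sim <= 0.07

    def test_power_for_planted_shift(self, rng):
        detected = sum(
            anova_feature(*self._balanced(rng, n=100, shift=1.0)).p_raw < 0.05
            for _ in range(50)
        )
        assert detected >= 49

    def test_missing_population_skipped(self, rng):
        y = pd.Series(rng.standard_normal(40), name="f")
        y[20:] = np.nan
        pops = pd.Series(["A"] * 10 + ["B"] * 10 + ["C"] * 20)
        fit = anova_feature(y, pops)
        assert fit.skipped and "C" in fit.skip_reason

    def test_collinear_covariate_raises_with_name(self, rng):
        pops = pd.Series(["A"] * 10 + ["B"] * 10)
        cov = pd.DataFrame({"site": ["x"] * 10 + ["y"] * 10})
        y = pd.Series(rng.standard_normal(20), name="f")
        with pytest.raises(ValueError, match="site"):
            anova_feature(y, pops, cov)

    def test_covariate_adjustment_removes_batch_bias(self, rng):
        # batch partially confounded with group (all of A in b1, all of C in
        # b2, B split): unadjusted ANOVA fires on the batch shift, adjusted not
        pops = pd.Series(["A"] * 50 + ["B"] * 50 + ["C"] * 50)
        batch = pd.DataFrame({"batch": ["b1"] * 75 + ["b2"] * 75})
        y = pd.Series(rng.standard_normal(150), name="f")
        y[batch["batch"] == "b2"] += 2.0
        raw = anova_feature(y, pops)
        adj = anova_feature(y, pops, batch)
        assert raw.p_raw < 1e-6
        assert adj.p_raw > 0.01


class TestLeastSquaresMeans:
    def test_no_covariates_equal_raw_group_means(self, rng):
        pops = pd.Series(["A"] * 30 + ["B"] * 30 + ["C"] * 30)
        y = pd.Series(rng.standard_normal(90), name="f")
        fit = anova_feature(y, pops)
        for g in ("A", "B", "C"):
            assert fit.lsm[g] == pytest.approx(y[pops == g].mean(), abs=1e-10)

    def test_balanced_batch_cancels(self, rng):
        pops = pd.Series((["A"] * 2 + ["B"] * 2 + ["C"] * 2) * 30)
        batch = pd.DataFrame({"batch": (["b1"] * 6 + ["b2"] * 6) * 15})
        y = pd.Series(rng.standard_normal(180), name="f")
        y[batch["batch"] == "b2"] += 1.5
        fit = anova_feature(y, pops, batch)
        raw_diff = y[pops == "A"].mean() - y[pops == "B"].mean()
        lsm_diff = fit.lsm["A"] - fit.lsm["B"]
        assert lsm_diff == pytest.approx(raw_diff, abs=1e-9)

    def test_unbalanced_matches_prediction_grid_oracle(self, rng):
        # batch partially confounded with group
        pops = pd.Series(["A"] * 40 + ["B"] * 40 + ["C"] * 40)
        batch = ["b1"] * 30 + ["b2"] * 10 + ["b1"] * 10 + ["b2"] * 30 + ["b1"] * 20 + ["b2"] * 20
        cov = pd.DataFrame({"batch": batch})
        y = pd.Series(rng.standard_normal(120), name="f")
        y[np.array(batch) == "b2"] += 1.0
        y[pops == "B"] += 0.5
        fit = anova_feature(y, pops, cov)

        # oracle: fit via statsmodels formula API, average predictions over
        # the balanced population x batch grid
        import statsmodels.formula.api as smf

        df = pd.DataFrame({"y": y, "pop": pops, "batch": batch})
        model = smf.ols("y ~ C(pop) + C(batch)", data=df).fit()
        for g in ("A", "B", "C"):
            grid = pd.DataFrame(
                {"pop": [g, g], "batch": ["b1", "b2"]}
            )
            expected = model.predict(grid).mean()
            assert fit.lsm[g] == pytest.approx(expected, abs=1e-9)


class TestPlatformContrast:
    def test_single_feature_bonferroni_is_identity(self, rng):
        m = pd.DataFrame({"f1": rng.standard_normal(90)})
        pops = pd.Series(["A"] * 30 + ["B"] * 30 + ["C"] * 30)
        out = platform_contrast(m, pops)
        assert out["p_bonferroni"].iloc[0] == pytest.approx(out["p_raw"].iloc[0])

    def test_bonferroni_scaling_exact(self, rng):
        m = pd.DataFrame(rng.standard_normal((60, 7)), columns=list("abcdefg"))
        pops = pd.Series(["A"] * 20 + ["B"] * 20 + ["C"] * 20)
        out = platform_contrast(m, pops)
        np.testing.assert_allclose(
            out["p_bonferroni"], np.minimum(1.0, 7 * out["p_raw"]), atol=1e-15
        )

    def test_planted_features_recovered_with_fwer_control(self, rng):
        all_recovered, no_false = 0, 0
        n_seeds = 10
        for seed in range(n_seeds):
            r = np.random.default_rng(seed)
            n, m = 300, 100
            pops = pd.Series(["A"] * 100 + ["B"] * 100 + ["C"] * 100)
            X = pd.DataFrame(
                r.standard_normal((n, m)), columns=[f"f{j:03d}" for j in range(m)]
            )
            planted = [f"f{j:03d}" for j in range(10)]
            for j, feat in enumerate(planted):
                X.loc[(pops == "ABC"[j % 3]).to_numpy(), feat] += 1.5
            out = platform_contrast(X, pops)
            sig = set(out.index[out["significant"]])
            if set(planted) <= sig:
                all_recovered += 1
            if not (sig - set(planted)):
                no_false += 1
        assert all_recovered >= 9
        assert no_false >= 9

    def test_null_platform_mostly_clean(self, rng):
        clean = 0
        for seed in range(10):
            r = np.random.default_rng(1000 + seed)
            X = pd.DataFrame(r.standard_normal((90, 50)))
            X.columns = [f"f{j}" for j in range(50)]
            pops = pd.Series(["A"] * 30 + ["B"] * 30 + ["C"] * 30)
            out = platform_contrast(X, pops)
            clean += not out["significant"].any()
        assert clean >= 9

    def test_driving_pair_uses_largest_lsm_gap(self, rng):
        pops = pd.Series(["A"] * 40 + ["B"] * 40 + ["C"] * 40)
        y = rng.standard_normal(120)
        y[80:] += 3.0  # C far from A and B; A-C listed before B-C
        m = pd.DataFrame({"f": y})
        out = platform_contrast(m, pops)
        lsm = out.iloc[0][["lsm_A", "lsm_B", "lsm_C"]]
        gaps = {
            "A-B": abs(lsm["lsm_A"] - lsm["lsm_B"]),
            "A-C": abs(lsm["lsm_A"] - lsm["lsm_C"]),
            "B-C": abs(lsm["lsm_B"] - lsm["lsm_C"]),
        }
        assert out["driving_pair"].iloc[0] == max(gaps, key=gaps.get)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            platform_contrast(pd.DataFrame(index=[1, 2]), pd.Series(["A", "B"]))
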