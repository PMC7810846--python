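import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from pairvox.ieg_stats import (
    FRAME_AREA_MM2,
    IEGError,
    bonferroni_posthoc,
    density_from_counts,
    f_survival,
    log_transform,
    mixed_anova,
    one_way_anova,
    pattern_profiles,
    pearson_corr,
    region_correlation_matrix,
    spearman_score_vs_counts,
    two_way_anova,
)


def _table(counts_by_cell):
    rows = []
    for (bird, group, region, ieg), counts in counts_by_cell.items():
        for i, c in enumerate(counts, start=1):
            rows.append(dict(bird_id=bird, group=group, region=region,
                             ieg=ieg, frame_index=i, count=c))
    return pd.DataFrame(rows)


class TestDensity:
    def test_frame_area_arithmetic(self):
        df = _table({("b1", "MATE", "CMM", "Zenk"): [13, 13, 13, 13]})
        out = density_from_counts(df)
        assert out.loc[0, "density_per_mm2"] == pytest.approx(13 / 0.1305)
        assert FRAME_AREA_MM2 == 0.290 * 0.450

    def test_mean_then_density(self):
        df = _table({("b1", "MATE", "CMM", "Zenk"): [10, 12, 14, 16]})
        out = density_from_counts(df)
        assert out.loc[0, "density_per_mm2"] == pytest.approx(13 / 0.1305)

    def test_zeros_and_missing_frames(self):
        df = _table({("b1", "SILENCE", "vNCM", "Fos"): [0, 0, 0, 0],
                     ("b2", "SILENCE", "vNCM", "Fos"): [3, 6]})
        out = density_from_counts(df).set_index("bird_id")
        assert out.loc["b1", "density_per_mm2"] == 0.0
        assert out.loc["b2", "density_per_mm2"] == pytest.approx(
            4.5 / 0.1305)
        assert out.loc["b2", "n_frames"] == 2

    def test_invalid_tables(self):
        df = _table({("b1", "MATE", "CMM", "Zenk"): [1, 1, 1, 1, 1]})
        with pytest.raises(IEGError):
            density_from_counts(df)
        df2 = _table({("b1", "MATE", "CMM", "Zenk"): [1, -2]})
        with pytest.raises(IEGError):
            density_from_counts(df2)


class TestLogTransform:
    def test_anchors(self):
        assert log_transform(0.0) == 0.0
        assert log_transform(math.e - 1) == pytest.approx(1.0)
        assert log_transform(99.0, base="log10") == pytest.approx(2.0)

    def test_preserves_rank_order(self, rng):
        x = rng.uniform(0, 500, 50)
        assert np.array_equal(np.argsort(x),
                              np.argsort(log_transform(x)))

    def test_negative_rejected(self):
        with pytest.raises(IEGError):
            log_transform(-1.0)


class TestFSurvival:
    @pytest.mark.parametrize("F,df1,df2,printed", [
        (9.197, 2, 9, 0.007),
        (1.898, 2, 9, 0.205),
        (10.058, 2, 9, 0.005),
    ])
    def test_matches_printed_tail_probabilities(self, F, df1, df2, printed):
        assert round(f_survival(F, df1, df2), 3) == printed

    def test_edge_cases(self):
        assert f_survival(0.0, 3, 10) == 1.0
        with pytest.raises(IEGError):
            f_survival(1.0, 0, 10)

    def test_df1_two_closed_form_identity(self):
        # P(F_{2,d2} > F) = (d2 / (d2 + 2F))^(d2/2)
        for d2 in (2, 5, 9, 20, 100):
            for F in np.linspace(0.0, 30.0, 61):
                closed = (d2 / (d2 + 2 * F)) ** (d2 / 2)
                assert abs(f_survival(F, 2, d2) - closed) < 1e-10


class TestOneWayAnova:
    def test_hand_computed(self):
        res = one_way_anova({"a": [1, 2, 3], "b": [2, 3, 4],
                             "c": [3, 4, 5]})
        assert res.F == pytest.approx(3.0)
        assert (res.df1, res.df2) == (2, 6)

    def test_zero_variance_policy(self):
        res = one_way_anova({"a": [1, 1], "b": [1, 1]})
        assert res.F == 0.0 and res.p == 1.0

    def test_matches_scipy_on_random_data(self, rng):
        groups = {k: rng.normal(k, 1.0, 7) for k in range(4)}
        res = one_way_anova(groups)
        ref = stats.f_oneway(*groups.values())
        assert res.F == pytest.approx(ref.statistic, rel=1e-12)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-9)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.lists(st.floats(min_value=-100, max_value=100),
                             min_size=2, max_size=8),
                    min_size=2, max_size=5))
    def test_sum_of_squares_decomposition(self, group_lists):
        """SS_between + SS_within = SS_total for any grouping."""
        groups = {i: np.array(g) for i, g in enumerate(group_lists)}
        pooled = np.concatenate(list(groups.values()))
        sst = ((pooled - pooled.mean()) ** 2).sum()
        ssb = sum(g.size * (g.mean() - pooled.mean()) ** 2
                  for g in groups.values())
        ssw = sum(((g - g.mean()) ** 2).sum() for g in groups.values())
        assert ssb + ssw == pytest.approx(sst, abs=1e-6 * max(1.0, sst))
        res = one_way_anova(groups)
        if ssw > 1e-9 * max(1.0, sst):
            assert res.F == pytest.approx(
                (ssb / res.df1) / (ssw / res.df2), rel=1e-9, abs=1e-9)

    def test_rejection_rate_matches_permutation_oracle(self):
        # group log-means 2.2 / 2.0 / 1.2, sd 0.25, n=4: the parametric
        # rejection rate at alpha=.05 should agree with a label-permuting
        # F oracle on the same datasets to within 2 points
        rng = np.random.default_rng(17)
        n, reps, nperm = 4, 1000, 240
        labels = np.repeat(np.arange(3), n)
        param_rej = perm_rej = 0
        for _ in range(reps):
            data = np.concatenate([rng.normal(2.2, 0.25, n),
                                   rng.normal(2.0, 0.25, n),
                                   rng.normal(1.2, 0.25, n)])
            groups = {g: data[labels == g] for g in range(3)}
            res = one_way_anova(groups)
            if res.p < 0.05:
                param_rej += 1
            # vectorized permutation F
            perms = np.array([rng.permutation(12) for _ in range(nperm)])
            d = data[perms]  # (nperm, 12)
            gm = d.reshape(nperm, 3, n).mean(axis=2)
            grand = d.mean(axis=1, keepdims=True)
            ssb = n * ((gm - grand) ** 2).sum(axis=1)
            ssw = ((d.reshape(nperm, 3, n)
                    - gm[:, :, None]) ** 2).sum(axis=(1, 2))
            fperm = (ssb / 2) / (ssw / 9)
            if (fperm >= res.F).mean() < 0.05:
                perm_rej += 1
        assert abs(param_rej - perm_rej) / reps < 0.02


class TestTwoWayAnova:
    def test_study_layout_dfs(self, rng):
        groups = np.repeat(["MATE", "UNFAMILIAR", "SILENCE"], 16)
        regions = np.tile(np.repeat(["CMM", "dNCM", "vNCM", "HP"], 4), 3)
        y = rng.normal(size=48)
        res = two_way_anova(y, groups, regions, names=("Stimulus", "Region"))
        assert (res["Stimulus"].df1, res["Stimulus"].df2) == (2, 36)
        assert (res["Region"].df1, res["Region"].df2) == (3, 36)
        assert (res["StimulusxRegion"].df1,
                res["StimulusxRegion"].df2) == (6, 36)

    def test_additive_data_zero_interaction(self):
        a_eff = {"a1": 0.0, "a2": 2.0}
        b_eff = {"b1": 0.0, "b2": 1.0, "b3": 3.0}
        rows = []
        for ai, bi in itertools.product(a_eff, b_eff):
            for r in range(3):
                rows.append((a_eff[ai] + b_eff[bi] + 0.1 * r, ai, bi))
        y, fa, fb = map(np.array, zip(*rows))
        res = two_way_anova(y.astype(float), fa, fb)
        assert res["AxB"].F == pytest.approx(0.0, abs=1e-20)

    def test_matches_statsmodels_oracle(self, rng):
        import statsmodels.api as sm
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        fa = np.repeat(["x", "y"], 6)
        fb = np.tile(np.repeat(["u", "v"], 3), 2)
        y = rng.normal(size=12)
        res = two_way_anova(y, fa, fb)
        df = pd.DataFrame(dict(y=y, A=fa, B=fb))
        fit = smf.ols("y ~ C(A) * C(B)", data=df).fit()
        tab = anova_lm(fit, typ=2)
        assert res["A"].F == pytest.approx(tab.loc["C(A)", "F"], rel=1e-9)
        assert res["B"].F == pytest.approx(tab.loc["C(B)", "F"], rel=1e-9)
        assert res["AxB"].F == pytest.approx(
            tab.loc["C(A):C(B)", "F"], rel=1e-9)

    def test_unbalanced_and_empty_cells_rejected(self, rng):
        fa = np.array(["x"] * 4 + ["y"] * 3)
        fb = np.array(["u", "v"] * 3 + ["u"])
        with pytest.raises(IEGError):
            two_way_anova(rng.normal(size=7), fa, fb)


class TestMixedAnova:
    def test_matches_pingouin_oracle(self, rng):
        pg = pytest.importorskip("pingouin")
        n_per, groups, levels = 4, ["g1", "g2", "g3"], ["w1", "w2"]
        rows = []
        for gi, g in enumerate(groups):
            for s in range(n_per):
                subj = f"{g}_s{s}"
                base = rng.normal(gi, 1.0)
                for wi, wlev in enumerate(levels):
                    rows.append((base + wi + rng.normal(0, 0.5),
                                 g, wlev, subj))
        y, gb, gw, su = map(np.array, zip(*rows))
        res = mixed_anova(y.astype(float), gb, gw, su)
        df = pd.DataFrame(dict(y=y.astype(float), g=gb, w=gw, s=su))
        tab = pg.mixed_anova(data=df, dv="y", between="g", within="w",
                             subject="s").set_index("Source")
        assert res["between"].F == pytest.approx(tab.loc["g", "F"], rel=1e-6)
        assert res["within"].F == pytest.approx(tab.loc["w", "F"], rel=1e-6)
        assert res["betweenxwithin"].F == pytest.approx(
            tab.loc["Interaction", "F"], rel=1e-6)


class TestBonferroni:
    def test_identical_groups_all_one(self):
        out = bonferroni_posthoc({"a": [1, 1, 2, 2], "b": [1, 2, 1, 2],
                                  "c": [2, 1, 2, 1]})
        assert all(v["p_adj"] == 1.0 for v in out.values())

    def test_adjustment_is_m_times_raw(self, rng):
        groups = {k: rng.normal(i * 0.3, 1.0, 5)
                  for i, k in enumerate("abc")}
        out = bonferroni_posthoc(groups)
        for v in out.values():
            assert v["p_adj"] == pytest.approx(min(1.0, 3 * v["p_raw"]))

    def test_single_shifted_group_pattern(self, rng):
        groups = {"a": rng.normal(0, 1, 6), "b": rng.normal(0, 1, 6),
                  "c": rng.normal(5, 1, 6)}
        out = bonferroni_posthoc(groups)
        assert out["a_vs_c"]["p_adj"] < 0.05
        assert out["b_vs_c"]["p_adj"] < 0.05
        assert out["a_vs_b"]["p_adj"] > 0.05

    def test_unknown_group_rejected(self):
        with pytest.raises(IEGError):
            bonferroni_posthoc({"a": [1, 2], "b": [2, 3]},
                               pairs=[("a", "z")])


class TestPearson:
    def test_printed_n4_value(self):
        # build a 4-point dataset with sample correlation exactly 0.753
        x = np.array([0.0, 1.0, 2.0, 3.0])
        y = _with_correlation(x, 0.753)
        res = pearson_corr(x, y)
        assert res.r == pytest.approx(0.753, abs=1e-12)
        assert round(res.p, 3) == 0.247

    def test_perfect_correlation(self):
        res = pearson_corr([1, 2, 3, 4], [2, 4, 6, 8])
        assert res.r == 1.0 and res.p == 0.0

    def test_zero_variance_undefined(self):
        res = pearson_corr([1, 1, 1, 1], [1, 2, 3, 4])
        assert res.undefined and np.isnan(res.r) and np.isnan(res.p)

    def test_small_n_rejected(self):
        with pytest.raises(IEGError):
            pearson_corr([1, 2], [3, 4])

    def test_n4_identity_p_equals_one_minus_abs_r(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        for r_target in np.linspace(-0.999, 0.999, 1000):
            y = _with_correlation(x, r_target)
            res = pearson_corr(x, y)
            assert abs(res.p - (1 - abs(res.r))) < 1e-12

    def test_matches_scipy(self, rng):
        x, y = rng.normal(size=20), rng.normal(size=20)
        res = pearson_corr(x, y)
        ref = stats.pearsonr(x, y)
        assert res.r == pytest.approx(ref.statistic, rel=1e-12)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-9)


def _with_correlation(x, r):
    """Construct y with exact sample correlation r against x."""
    n = len(x)
    z = np.linspace(-1, 1, n) ** 3  # any vector not collinear with x
    xc = (x - np.mean(x)) / np.linalg.norm(x - np.mean(x))
    zc = z - np.mean(z)
    zc -= (zc @ xc) * xc
    zc /= np.linalg.norm(zc)
    return r * xc + math.sqrt(1 - r * r) * zc


def _density_frame(values_by_region, group="MATE", ieg="Zenk"):
    rows = []
    for region, vals in values_by_region.items():
        for i, v in enumerate(vals):
            rows.append(dict(bird_id=f"b{i}", group=group, region=region,
                             ieg=ieg, density_per_mm2=v))
    return pd.DataFrame(rows)


class TestRegionCorrelations:
    def test_identical_vectors_unit_correlation(self):
        v = [10.0, 40.0, 90.0, 160.0]
        df = _density_frame({"CMM": v, "dNCM": v, "vNCM": v})
        out = region_correlation_matrix(df)
        assert all(res.r == pytest.approx(1.0) for res in out.values())

    def test_high_coupling_recovered(self):
        rng = np.random.default_rng(23)
        hits = 0
        reps = 1000
        for _ in range(reps):
            cov = np.full((3, 3), 0.95) + np.eye(3) * 0.05
            logd = rng.multivariate_normal([6, 6, 6], 0.25**2 * cov, 4)
            df = _density_frame({r: np.exp(logd[:, i])
                                 for i, r in enumerate(
                                     ("CMM", "dNCM", "vNCM"))})
            out = region_correlation_matrix(df)
            if all(res.r > 0.8 for res in out.values()):
                hits += 1
        assert hits >= 0.8 * reps  # >= 80% of replicates

    def test_missing_region_rejected(self):
        df = _density_frame({"CMM": [1, 2, 3, 4], "dNCM": [1, 2, 3, 4]})
        with pytest.raises(IEGError):
            region_correlation_matrix(df)


class TestPatternProfiles:
    def test_identical_profiles_concordant_w_one(self):
        v = [100.0, 80.0, 60.0, 40.0]
        prof = pattern_profiles(_density_frame(
            {"CMM": v, "dNCM": v, "vNCM": v}))
        assert prof.concordant
        assert prof.kendalls_w == pytest.approx(1.0)
        for region in prof.regions:
            assert max(prof.percent[region].values()) == 100.0

    def test_reversed_region_breaks_concordance(self):
        v = [10.0, 20.0, 30.0, 40.0]
        prof = pattern_profiles(_density_frame(
            {"CMM": v, "dNCM": v, "vNCM": v[::-1]}))
        assert not prof.concordant
        # hand-computed W = 12 S / (m^2 (k^3 - k)) for m=3 raters, k=4:
        # rank sums per bird: (4+4+1, 3+3+2, 2+2+3, 1+1+4) = (9,8,7,6)
        # S = sum (R - 7.5)^2 = 2.25+0.25+0.25+2.25 = 5 -> W = 60/540
        assert prof.kendalls_w == pytest.approx(12 * 5 / (9 * 60))

    def test_midrank_ties(self):
        prof = pattern_profiles(_density_frame(
            {"CMM": [5.0, 5.0, 1.0], "dNCM": [5.0, 5.0, 1.0],
             "vNCM": [5.0, 5.0, 1.0]}))
        assert prof.concordant
        assert prof.ranks["CMM"]["b0"] == 1.5


class TestSpearman:
    def test_perfect_monotone(self):
        res = spearman_score_vs_counts([1, 2, 3, 4], [10, 20, 40, 80])
        assert res.rho == pytest.approx(1.0)

    def test_d_squared_formula(self):
        # ranks (1,2,3,4) vs (1,2,4,3): rho = 1 - 6*2/60 = 0.8
        res = spearman_score_vs_counts([1, 2, 3, 4], [1, 2, 4, 3])
        assert res.rho == pytest.approx(0.8)

    def test_constant_scores_undefined(self):
        res = spearman_score_vs_counts([2, 2, 2, 2], [1, 2, 3, 4])
        assert res.undefined

    def test_exact_null_calibration(self):
        # at n=5 the exact permutation p is discrete; the rejection rate
        # at alpha=.05 under independence must not exceed the nominal
        # level and should be near the largest attainable level below it
        rng = np.random.default_rng(31)
        rej = 0
        reps = 400
        for _ in range(reps):
            res = spearman_score_vs_counts(rng.permutation(5),
                                           rng.normal(size=5))
            if res.p < 0.05:
                rej += 1
        assert rej / reps <= 0.05
        assert rej / reps >= 0.005
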