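"""Statistical battery: mixed ANCOVA, Duncan, Grubbs, demographics,
composite z-scores, Kruskal-Wallis, correlations, regressions, FDR."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from lewyeeg import stats as L
from lewyeeg.forward import ROI_NAMES
from lewyeeg.spectral import BAND_NAMES


def make_table(rng, n_low, n_high, bands=BAND_NAMES, rois=ROI_NAMES,
               effect=None, subj_sd=0.15, noise_sd=0.1, covariates=False):
    """Long table with optional per-(band) education effect on the high
    group."""
    rows = []
    for g, n in (("low", n_low), ("high", n_high)):
        for i in range(n):
            sid = f"{g}{i}"
            subj = rng.normal(0, subj_sd)
            extra = {}
            if covariates:
                extra = {"sex": "M" if rng.random() < 0.5 else "F",
                         "mmse": rng.normal(25, 3),
                         "unit": f"u{rng.integers(3)}"}
            for b in bands:
                delta = effect.get(b, 0.0) if (effect and g == "high") else 0.0
                for r in rois:
                    rows.append({"subject_id": sid, "edu": g, "band": b,
                                 "roi": r,
                                 "activity": subj + delta
                                 + rng.normal(0, noise_sd), **extra})
    t = pd.DataFrame(rows)
    t["band"] = pd.Categorical(t["band"], categories=list(bands), ordered=True)
    t["roi"] = pd.Categorical(t["roi"], categories=list(rois), ordered=True)
    return t


class TestRmAncova:
    def test_reduces_to_pooled_t_test(self):
        rng = np.random.default_rng(0)
        t = make_table(rng, 12, 15, bands=("alpha3",), rois=("occipital",))
        res = L.rm_ancova(t)
        x = t[t.edu == "low"].activity
        y = t[t.edu == "high"].activity
        tt, tp = sps.ttest_ind(x, y)
        e = res.effect("edu")
        assert e["F"] == pytest.approx(tt ** 2, rel=1e-10)
        assert e["p"] == pytest.approx(tp, rel=1e-10)
        assert (e["df1"], e["df2"]) == (1, 25)

    def test_within_df_structure_with_covariates(self):
        # Band stratum error df = (B-1)(N - groups - covariate columns)
        rng = np.random.default_rng(1)
        t = make_table(rng, 27, 27, covariates=True)
        res = L.rm_ancova(t, covariates=("sex", "mmse", "unit"))
        e = res.effect("edu x band")
        assert e["df1"] == 7
        # 1 intercept + 1 edu + 1 sex + 1 mmse + 2 unit dummies = 6
        assert e["df2"] == 7 * (54 - 6)

    def test_interaction_detected_and_eta(self):
        rng = np.random.default_rng(2)
        t = make_table(rng, 20, 20, effect={"alpha2": 0.3, "alpha3": 0.3})
        res = L.rm_ancova(t)
        assert res.effect("edu x band")["p"] < 1e-4
        assert 0 < res.effect("edu x band")["eta_p2"] <= 1

    def test_eta_invariant_to_affine_rescaling(self):
        rng = np.random.default_rng(3)
        t = make_table(rng, 10, 12, effect={"alpha3": 0.4})
        r1 = L.rm_ancova(t)
        t2 = t.copy()
        t2["activity"] = 5.0 * t2["activity"] - 3.0
        r2 = L.rm_ancova(t2)
        for term in ("edu", "edu x band", "band"):
            assert r1.effect(term)["eta_p2"] == pytest.approx(
                r2.effect(term)["eta_p2"], rel=1e-9)
            assert r1.effect(term)["p"] == pytest.approx(
                r2.effect(term)["p"], rel=1e-9)

    def test_incomplete_grid_errors(self):
        rng = np.random.default_rng(4)
        t = make_table(rng, 5, 5)
        t = t[~((t.subject_id == "low0") & (t.band == "gamma")
                & (t.roi == "limbic"))]
        with pytest.raises(ValueError, match="missing cells"):
            L.rm_ancova(t)

    def test_singular_design_errors(self):
        rng = np.random.default_rng(5)
        t = make_table(rng, 6, 6, covariates=True)
        t["unit"] = np.where(t["edu"] == "low", "u0", "u1")  # confounded
        with pytest.raises(ValueError, match="aliased|singular"):
            L.rm_ancova(t, covariates=("unit",))

    def test_single_between_level_errors(self):
        rng = np.random.default_rng(6)
        t = make_table(rng, 6, 6)
        t["edu"] = "low"
        with pytest.raises(ValueError, match="2 levels"):
            L.rm_ancova(t)


class TestDuncan:
    def test_two_groups_equals_t_test(self):
        rng = np.random.default_rng(7)
        x, y = rng.normal(size=12), rng.normal(0.7, 1, size=17)
        _, p_d = L.duncan_two_groups(x, y)
        _, p_t = sps.ttest_ind(x, y)
        assert p_d == pytest.approx(p_t, rel=1e-9)

    def test_posthoc_null_no_band_significant(self):
        rng = np.random.default_rng(8)
        t = make_table(rng, 15, 15)
        ph = L.duncan_posthoc(t)
        assert ph.corrected_threshold == pytest.approx(0.05 / 8)
        assert not ph.table["significant"].any()

    def test_posthoc_flags_the_loaded_band(self):
        rng = np.random.default_rng(9)
        t = make_table(rng, 25, 25, effect={"alpha3": 0.5}, noise_sd=0.05,
                       subj_sd=0.05)
        ph = L.duncan_posthoc(t)
        row = ph.table.set_index("band").loc["alpha3"]
        assert row["significant"]
        assert row["diff"] < 0                  # Edu- minus Edu+ < 0
        others = ph.table[ph.table.band != "alpha3"]
        assert not others["significant"].any()

    def test_familywise_error_controlled_under_null(self):
        rng = np.random.default_rng(10)
        reps, fw = 800, 0
        for _ in range(reps):
            ps = []
            for _ in range(8):
                x, y = rng.normal(size=(2, 14))
                ps.append(L.duncan_two_groups(x, y)[1])
            fw += min(ps) < 0.05 / 8
        rate = fw / reps
        assert rate <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / reps)

    def test_multiple_range_reduces_to_pairwise_t(self):
        rng = np.random.default_rng(11)
        a, b = rng.normal(size=10), rng.normal(size=10)
        res = L.duncan_multiple_range([a, b])
        _, p_t = sps.ttest_ind(a, b)
        assert res.iloc[0]["p"] == pytest.approx(p_t, rel=1e-6)

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError, match="variance"):
            L.duncan_two_groups(np.ones(5), np.ones(6))


class TestGrubbs:
    def test_direct_arithmetic(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 100.0])
        res = L.grubbs_test(x, alpha=0.001)
        s = x.std(ddof=1)
        assert res.g == pytest.approx((100.0 - x.mean()) / s)
        assert res.outlier_index == 4

    def test_critical_value_formula(self):
        n, alpha = 27, 0.001
        res = L.grubbs_test(np.arange(n, dtype=float), alpha)
        t = sps.t.ppf(1 - alpha / (2 * n), n - 2)
        expect = (n - 1) / math.sqrt(n) * math.sqrt(t * t / (n - 2 + t * t))
        assert res.critical == pytest.approx(expect)

    def test_power_on_large_outlier(self):
        rng = np.random.default_rng(12)
        hits = 0
        reps = 400
        for _ in range(reps):
            x = rng.normal(size=27)
            x[0] += 10.0
            hits += L.grubbs_test(x, alpha=0.001).is_outlier
        assert hits / reps > 0.99

    def test_zero_variance_flagged_not_error(self):
        res = L.grubbs_test(np.ones(10))
        assert res.degenerate and not res.is_outlier

    def test_screen_cells(self):
        rng = np.random.default_rng(13)
        t = make_table(rng, 8, 8)
        rep = L.grubbs_screen(t)
        assert set(rep.columns) >= {"edu", "roi", "band", "g", "critical"}
        assert len(rep) == 2 * 6 * 8


def fisher_exact_enumeration(table):
    """Brute-force two-sided Fisher p: sum hypergeometric probabilities of
    all tables with the same margins that are no more probable."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):
        return (math.comb(r1, x) * math.comb(r2, c1 - x)
                / math.comb(n, c1))

    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        if prob(x) <= p_obs * (1 + 1e-12):
            total += prob(x)
    return total


class TestDemographics:
    def test_fisher_matches_enumeration(self):
        for table in ([[5, 5], [1, 9]], [[3, 7], [6, 4]], [[10, 0], [2, 8]]):
            _, p = L.fisher_2x2(table)
            assert p == pytest.approx(fisher_exact_enumeration(table),
                                      rel=1e-9)

    def test_identical_groups_p_one(self):
        meta = pd.DataFrame({
            "grp": ["a"] * 6 + ["b"] * 6,
            "age": list(range(6)) * 2,
            "mmse": list(range(6)) * 2,
        })
        res = L.demographic_tests(meta, "grp", variables=["age", "mmse"])
        assert np.allclose(res["p"].to_numpy(), 1.0)

    def test_mannwhitney_full_separation(self):
        meta = pd.DataFrame({
            "grp": ["a"] * 5 + ["b"] * 5,
            "mmse": [1, 2, 3, 4, 5, 6, 7, 8, 9, 10],
        })
        res = L.demographic_tests(meta, "grp", variables=["mmse"])
        u = res.iloc[0]["statistic"]
        assert min(u, 25 - u) == 0
        assert res.iloc[0]["p"] < 0.02

    def test_dispatch_table(self):
        rng = np.random.default_rng(14)
        meta = pd.DataFrame({
            "grp": ["a"] * 10 + ["b"] * 10,
            "age": rng.normal(70, 5, 20),
            "sex": rng.choice(["M", "F"], 20),
            "mmse": rng.integers(15, 30, 20).astype(float),
            "vh": rng.random(20) < 0.5,
        })
        res = L.demographic_tests(meta, "grp").set_index("variable")
        assert res.loc["age", "test"] == "t"
        assert res.loc["sex", "test"] == "fisher"
        assert res.loc["mmse", "test"] == "mannwhitney"
        assert res.loc["vh", "test"] == "fisher"


class TestCompositeZ:
    def test_reference_subject_zero(self):
        scores = pd.DataFrame({"language": [10, 12, 14, 12],
                               "memory": [5, 7, 9, 7]})
        healthy = np.array([True, True, True, False])
        z = L.composite_zscores(scores, healthy, ("language", "memory"))
        assert z.loc[3, "z_language"] == pytest.approx(0.0)
        assert z.loc[3, "z_global"] == pytest.approx(0.0)

    def test_one_sd_below(self):
        scores = pd.DataFrame({"memory": [8.0, 10.0, 12.0, 8.0]})
        healthy = np.array([True, True, True, False])
        z = L.composite_zscores(scores, healthy, ("memory",))
        assert z.loc[3, "z_memory"] == pytest.approx(-1.0)

    def test_patient_deficit_recovered(self):
        rng = np.random.default_rng(15)
        n_h, n_p = 60, 60
        scores = pd.DataFrame({
            "memory": np.r_[rng.normal(0, 1, n_h), rng.normal(-2, 1, n_p)],
            "language": np.r_[rng.normal(0, 1, n_h), rng.normal(0, 1, n_p)],
        })
        healthy = np.r_[np.ones(n_h, bool), np.zeros(n_p, bool)]
        z = L.composite_zscores(scores, healthy, ("memory", "language"))
        assert z.loc[~healthy, "z_memory"].mean() == pytest.approx(-2.0,
                                                                   abs=0.4)
        assert abs(z.loc[~healthy, "z_language"].mean()) < 0.4

    def test_zero_reference_sd_errors(self):
        scores = pd.DataFrame({"memory": [5.0, 5.0, 5.0, 2.0]})
        healthy = np.array([True, True, True, False])
        with pytest.raises(ValueError, match="memory"):
            L.composite_zscores(scores, healthy, ("memory",))


class TestKruskal:
    def test_identical_groups(self):
        vals = np.tile([1.0, 2.0, 3.0], 3)
        groups = np.repeat(["a", "b", "c"], 3)
        res = L.kruskal_multigroup(np.ones(9), groups)
        assert res.h == 0.0 and res.p == 1.0
        res2 = L.kruskal_multigroup(vals, groups)
        assert res2.p > 0.9

    def test_two_groups_equals_mannwhitney_z_squared(self):
        rng = np.random.default_rng(16)
        x = np.r_[rng.integers(0, 6, 20), rng.integers(2, 8, 25)].astype(float)
        groups = np.r_[["a"] * 20, ["b"] * 25]
        res = L.kruskal_multigroup(x, groups)
        # tie-corrected normal approximation of Mann-Whitney
        u = sps.mannwhitneyu(x[:20], x[20:], alternative="two-sided",
                             method="asymptotic")
        n1, n2 = 20, 25
        n = n1 + n2
        _, counts = np.unique(x, return_counts=True)
        tie = ((counts ** 3 - counts).sum()) / (n * (n - 1))
        sigma = np.sqrt(n1 * n2 / 12 * ((n + 1) - tie))
        z = (u.statistic - n1 * n2 / 2) / sigma
        assert res.h == pytest.approx(z ** 2, rel=1e-9)

    def test_patient_deficit_pattern(self):
        rng = np.random.default_rng(17)
        vals = np.r_[rng.normal(0, 1, 50), rng.normal(-2, 1, 70),
                     rng.normal(-2, 1, 50)]
        groups = np.r_[["Healthy"] * 50, ["PDD"] * 70, ["DLB"] * 50]
        res = L.kruskal_multigroup(vals, groups)
        assert res.p < 0.01
        ph = res.posthoc.set_index(["group1", "group2"])
        assert ph.loc[("Healthy", "PDD"), "p_adj"] < 0.01
        assert ph.loc[("Healthy", "DLB"), "p_adj"] < 0.01
        assert ph.loc[("PDD", "DLB"), "p_adj"] > 0.05


def spearman_oracle(x, y):
    """Pearson correlation of mid-ranks, brute force."""
    def midranks(v):
        v = np.asarray(v, float)
        out = np.empty(len(v))
        for i, a in enumerate(v):
            less = (v < a).sum()
            eq = (v == a).sum()
            out[i] = less + (eq + 1) / 2.0
        return out
    rx, ry = midranks(x), midranks(y)
    return np.corrcoef(rx, ry)[0, 1]


class TestCorrelate:
    def test_monotone_limits(self):
        x = np.arange(10.0)
        assert L.correlate(x, np.exp(x))[0] == pytest.approx(1.0)
        assert L.correlate(x, -x ** 3)[0] == pytest.approx(-1.0)

    def test_ties_match_midrank_oracle(self):
        x = [1, 2, 2, 3, 3, 3, 4, 5]
        y = [2, 1, 3, 3, 5, 4, 4, 6]
        r, _ = L.correlate(x, y, "spearman")
        assert r == pytest.approx(spearman_oracle(x, y), rel=1e-9)

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError, match="4"):
            L.correlate([1, 2], [3, 4])
        with pytest.raises(ValueError, match="variance"):
            L.correlate([1, 1, 1, 1], [1, 2, 3, 4])


class TestFdr:
    def test_step_up_formula(self):
        adj = L.bh_fdr([0.01, 0.02, 0.03, 0.5])
        np.testing.assert_allclose(adj, [0.04, 0.04, 0.04, 0.5], rtol=1e-12)

    def test_monotone_in_raw_order(self):
        rng = np.random.default_rng(18)
        p = np.sort(rng.random(25))
        adj = L.bh_fdr(p)
        assert np.all(np.diff(adj) >= -1e-12)


def make_regression_df(rng, slope_low, slope_high, n_low=30, n_high=45,
                      act_sd=0.3, noise_sd=4.4):
    rows = []
    for g, n, slope in (("low", n_low, slope_low), ("high", n_high,
                                                    slope_high)):
        for i in range(n):
            a = rng.normal(0.35, act_sd)
            rows.append({
                "edu": g, "activity": a,
                "score": 2.0 + slope * a + rng.normal(0, noise_sd),
                "age": rng.normal(72, 6),
                "sex": "M" if rng.random() < 0.8 else "F",
                "unit": f"u{rng.integers(3)}"})
    return pd.DataFrame(rows)


class TestRegression:
    def test_noiseless_exact_recovery(self):
        rng = np.random.default_rng(19)
        df = make_regression_df(rng, 3.0, 3.0, noise_sd=0.0)
        df["score"] = 2.0 + 3.0 * df["activity"]
        res = L.regress_interaction(df, "score", "activity",
                                    covariates=())
        s = res.simple_slopes.set_index("edu")
        assert s.loc["low", "slope"] == pytest.approx(3.0, abs=1e-8)
        assert s.loc["high", "slope"] == pytest.approx(3.0, abs=1e-8)
        inter = [r for r in res.coefficients["name"] if ":" in r][0]
        beta_i = res.coefficients.set_index("name").loc[inter, "beta"]
        assert abs(beta_i) < 1e-8
        assert res.r2 == pytest.approx(1.0)

    def test_model_fit_metrics_match_statsmodels(self):
        rng = np.random.default_rng(20)
        df = make_regression_df(rng, 10.0, 0.0)
        res = L.regress_interaction(df, "score", "activity")
        assert res.adj_r2 <= res.r2
        s = res.simple_slopes
        assert (s["ci_low"] <= s["slope"]).all()
        assert (s["slope"] <= s["ci_high"]).all()
        assert set(res.diagnostics) >= {"breusch_pagan_p", "normality_p",
                                        "n_influential"}

    def test_rank_deficiency_names_columns(self):
        rng = np.random.default_rng(21)
        df = make_regression_df(rng, 1.0, 1.0)
        df["dup"] = df["activity"]
        import statsmodels.formula.api  # noqa: F401
        with pytest.raises(ValueError, match="aliased"):
            L._fit_ols("score ~ activity + dup", df)

    def test_education_trend_recovers_sign(self):
        rng = np.random.default_rng(22)
        hits = 0
        reps = 40
        for _ in range(reps):
            n = 54
            years = rng.uniform(2, 18, n)
            df = pd.DataFrame({
                "edu_years": years,
                "activity": 0.3 + 0.015 * years + rng.normal(0, 0.08, n),
                "age": rng.normal(70, 6, n),
                "sex": rng.choice(["M", "F"], n),
                "unit": rng.choice(["u0", "u1"], n)})
            res = L.education_trend(df, "activity")
            hits += res.simple_slopes.iloc[0]["slope"] > 0
        assert hits / reps >= 0.95

    def test_education_trend_null_coverage(self):
        rng = np.random.default_rng(23)
        cover = 0
        reps = 200
        for _ in range(reps):
            n = 40
            df = pd.DataFrame({
                "edu_years": rng.uniform(2, 18, n),
                "activity": rng.normal(0.3, 0.1, n)})
            res = L.education_trend(df, "activity", covariates=())
            s = res.simple_slopes.iloc[0]
            cover += s["ci_low"] <= 0.0 <= s["ci_high"]
        assert cover / reps == pytest.approx(0.95, abs=0.05)

    def test_constant_years_errors(self):
        df = pd.DataFrame({"edu_years": [5.0] * 10,
                           "activity": np.arange(10.0)})
        with pytest.raises(ValueError, match="variance"):
            L.education_trend(df, "activity", covariates=())
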