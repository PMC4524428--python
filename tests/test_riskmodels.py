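import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methrisk import globalmeth as gm
from methrisk import riskmodels as rm
from methrisk import synthdata as sd


def _pairs_frame(d_exposure, d_age=None):
    n = len(d_exposure)
    return pd.DataFrame(
        {
            "case_exposure": np.asarray(d_exposure, float),
            "control_exposure": np.zeros(n),
            "case_age": np.asarray(d_age, float) if d_age is not None else np.zeros(n),
            "control_age": np.zeros(n),
        },
        index=[f"p{i}" for i in range(n)],
    )


def _grid_mle(D, lo=-5.0, hi=5.0):
    """Dense grid-search maximiser of the 1:1 conditional likelihood."""
    grid = np.arange(lo, hi, 1e-3)
    ll = np.array([-np.logaddexp(0, -(D * b)).sum() for b in grid])
    b0 = grid[ll.argmax()]
    fine = np.arange(b0 - 2e-3, b0 + 2e-3, 1e-6)
    llf = np.array([-np.logaddexp(0, -(D * b)).sum() for b in fine])
    return fine[llf.argmax()]


class TestClogit:
    def test_symmetric_differences_give_zero(self):
        pairs = _pairs_frame([1, 1, 1, -1, -1, -1])
        est = rm.clogit_pairs(pairs, adjust=())
        assert est.coef == pytest.approx(0.0, abs=1e-8)
        assert est.n_informative == 6

    def test_zero_exposure_differences_flagged_not_fit(self):
        pairs = _pairs_frame([0, 0, 0, 0], d_age=[1, -1, 2, -2])
        est = rm.clogit_pairs(pairs, adjust=("age",))
        assert est.coef == 0.0
        assert not np.isfinite(est.se)
        assert any("degenerate" in f for f in est.flags)

    def test_all_differences_zero_is_an_error(self):
        pairs = _pairs_frame([0.0, 0.0, 0.0])
        with pytest.raises(ValueError, match="informative"):
            rm.clogit_pairs(pairs, adjust=())

    def test_one_signed_differences_raise_separation(self):
        pairs = _pairs_frame([0.5, 1.2, 0.1, 2.0])
        with pytest.raises(rm.SeparationError):
            rm.clogit_pairs(pairs, adjust=())

    def test_matches_dense_grid_oracle_on_20_pairs(self):
        rng = np.random.default_rng(51)
        d = rng.normal(-0.3, 1.0, 20)
        est = rm.clogit_pairs(_pairs_frame(d), adjust=())
        assert est.coef == pytest.approx(_grid_mle(d), abs=1e-4)

    def test_matches_statsmodels_conditional_logit(self):
        from statsmodels.discrete.conditional_models import ConditionalLogit

        rng = np.random.default_rng(52)
        n = 40
        d = rng.normal(0.2, 1.0, n)
        est = rm.clogit_pairs(_pairs_frame(d), adjust=())
        y = np.concatenate([np.ones(n), np.zeros(n)])
        x = np.concatenate([d, np.zeros(n)])[:, None]
        groups = np.concatenate([np.arange(n), np.arange(n)])
        sm_fit = ConditionalLogit(y, x, groups=groups).fit(disp=False)
        assert est.coef == pytest.approx(float(sm_fit.params[0]), abs=1e-4)
        assert est.se == pytest.approx(float(sm_fit.bse[0]), rel=1e-4)

    def test_coefficient_rescales_exactly_with_exposure_units(self):
        rng = np.random.default_rng(53)
        d = rng.normal(0.1, 1.0, 30)
        est1 = rm.clogit_pairs(_pairs_frame(d), adjust=())
        est2 = rm.clogit_pairs(_pairs_frame(10 * d), adjust=())
        assert est2.coef == pytest.approx(est1.coef / 10, rel=1e-6)

    def test_shift_invariance_of_per_sd_exposure(self, exposure):
        x, sheet = exposure
        est1 = rm.clogit_pairs(rm.make_matched_pairs(sheet, x))
        est2 = rm.clogit_pairs(rm.make_matched_pairs(sheet, x + 42.0))
        assert est1.coef == pytest.approx(est2.coef, abs=1e-9)


class TestQuartileORs:
    def _quartile_pairs(self, seed=54, n=120, effect=np.log(0.61)):
        ann = sd.generate_annotation(300, seed=1)
        cfg = sd.SimConfig(
            n_pairs=n, n_probes=300, seed=seed, effect_logor_per_sd=effect, missing_rate=0.0
        )
        beta, sheet = sd.generate_pairs(cfg, ann)
        means = gm.sample_mean_methylation(beta)
        controls = sheet.index[sheet["status"] == "control"]
        labels, _ = gm.quartile_categorize(means, controls)
        pairs = rm.make_matched_pairs(sheet, means)
        pairs["case_quartile"] = [
            labels[sheet.index[(sheet["pair_id"] == p) & (sheet["status"] == "case")][0]]
            for p in pairs.index
        ]
        pairs["control_quartile"] = [
            labels[sheet.index[(sheet["pair_id"] == p) & (sheet["status"] == "control")][0]]
            for p in pairs.index
        ]
        return pairs

    def test_reference_quartile_is_exactly_one(self):
        out = rm.or_by_quartile(self._quartile_pairs())
        assert out["Q1"].odds_ratio == 1.0

    def test_null_quartile_cis_cover_one(self):
        covered = 0
        total = 0
        for s in range(25):
            out = rm.or_by_quartile(self._quartile_pairs(seed=200 + s, effect=0.0))
            for q in ("Q2", "Q3", "Q4"):
                lo, hi = out[q].ci
                covered += lo <= 1.0 <= hi
                total += 1
        assert covered / total >= 0.85

    def test_true_effect_gives_decreasing_trend(self):
        ors = {"Q2": [], "Q3": [], "Q4": []}
        for s in range(15):
            out = rm.or_by_quartile(self._quartile_pairs(seed=300 + s, effect=np.log(0.4)))
            for q in ors:
                ors[q].append(out[q].odds_ratio)
        med = {q: np.median(v) for q, v in ors.items()}
        assert med["Q4"] < med["Q3"] < med["Q2"] < 1.0


class TestRobustLogistic:
    def test_balanced_null_estimate_near_zero(self, null_study):
        beta, sheet = null_study
        means = gm.sample_mean_methylation(beta)
        x = (means - means.mean()) / means.std(ddof=1)
        est = rm.robust_logistic(x, sheet["status"], sheet["pair_id"])
        assert abs(est.coef) < 3 * est.se

    def test_sandwich_reduces_to_ordinary_for_singleton_clusters(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(55)
        n = 200
        x = rng.normal(size=n)
        y = rng.random(n) < 1 / (1 + np.exp(-0.5 * x))
        status = pd.Series(np.where(y, "case", "control"))
        est = rm.robust_logistic(pd.Series(x), status, pd.Series(np.arange(n)))
        X = np.column_stack([np.ones(n), x])
        plain = sm.Logit(y.astype(float), X).fit(disp=False)
        assert est.coef == pytest.approx(float(plain.params[1]), abs=1e-6)
        # HC sandwich with singleton clusters differs from model SE only by
        # small-sample factors
        assert est.se == pytest.approx(float(plain.bse[1]), rel=0.15)

    def test_sandwich_wider_under_pair_correlation(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(56)
        n_pairs = 300
        # exposure shared within pairs, plus an unobserved pair effect on the
        # outcome: cluster scores are positively correlated
        x = np.repeat(rng.normal(size=n_pairs), 2) + rng.normal(0, 0.3, 2 * n_pairs)
        latent = np.repeat(rng.normal(0, 1.5, n_pairs), 2)
        y = rng.random(2 * n_pairs) < 1 / (1 + np.exp(-(0.8 * x + latent)))
        status = pd.Series(np.where(y, "case", "control"))
        est = rm.robust_logistic(pd.Series(x), status, pd.Series(np.repeat(np.arange(n_pairs), 2)))
        X = np.column_stack([np.ones(2 * n_pairs), x])
        plain = sm.Logit(y.astype(float), X).fit(disp=False)
        assert est.se > float(plain.bse[1])


class TestPairedWilcoxon:
    def test_all_positive_unit_differences_exact(self):
        case = np.arange(1.0, 7.0) + 1.0
        ctrl = np.arange(1.0, 7.0)
        _, p_one = rm.paired_wilcoxon(case, ctrl, alternative="greater")
        assert p_one == pytest.approx(1 / 64)
        _, p_two = rm.paired_wilcoxon(case, ctrl)
        assert p_two == pytest.approx(2 / 64)

    def test_antisymmetric_differences_give_p_one(self):
        case = np.array([1.0, -1.0, 2.0, -2.0])
        _, p = rm.paired_wilcoxon(case, np.zeros(4))
        assert p == pytest.approx(1.0)

    def test_matches_full_sign_enumeration(self):
        rng = np.random.default_rng(57)
        d = rng.normal(0.4, 1.0, 10)
        d[3] = d[7]  # force a tie in |d| handled by mid-ranks
        ranks = stats.rankdata(np.abs(d))
        w_obs = ranks[d > 0].sum()
        dist = [sum(r for r, s in zip(ranks, signs) if s) for signs in itertools.product([0, 1], repeat=10)]
        dist = np.asarray(dist, float)
        p_ge = np.mean(dist >= w_obs - 1e-9)
        p_le = np.mean(dist <= w_obs + 1e-9)
        expect = min(1.0, 2 * min(p_ge, p_le))
        _, p = rm.paired_wilcoxon(d, np.zeros(10))
        assert p == pytest.approx(expect, abs=1e-12)

    def test_matches_scipy_exact_when_untied(self):
        rng = np.random.default_rng(58)
        d = rng.normal(0.2, 1.0, 18)
        _, p = rm.paired_wilcoxon(d, np.zeros(18))
        assert p == pytest.approx(stats.wilcoxon(d, method="exact").pvalue, abs=1e-12)


class TestSplineRisk:
    def test_linear_truth_recovered_by_spline(self):
        ann = sd.generate_annotation(300, seed=2)
        cfg = sd.SimConfig(n_pairs=500, n_probes=300, seed=59, missing_rate=0.0)
        beta, sheet = sd.generate_pairs(cfg, ann)
        means = gm.sample_mean_methylation(beta)
        x = (means - means.mean()) / means.std(ddof=1)
        res = rm.spline_risk_distribution(x, sheet["status"], sheet["pair_id"], df=4)
        lin = rm.clogit_pairs(rm.make_matched_pairs(sheet, x), adjust=())
        eta_lin = lin.coef * x
        eta_lin = eta_lin - eta_lin.mean()
        # agreement over the central 95% of the exposure range
        core = (x > x.quantile(0.025)) & (x < x.quantile(0.975))
        dev = np.abs(res.log_rr[core] - eta_lin[core]).max()
        assert dev < 2 * lin.se * (x[core].max() - x[core].min())

    def test_centring_makes_mean_log_rr_zero(self, exposure):
        x, sheet = exposure
        res = rm.spline_risk_distribution(x, sheet["status"], sheet["pair_id"], df=4)
        assert res.log_rr.mean() == pytest.approx(0.0, abs=1e-12)

    def test_null_range_contains_one_and_is_narrower_than_alternative(self):
        ann = sd.generate_annotation(300, seed=2)
        widths = {}
        for label, effect in (("null", 0.0), ("effect", np.log(0.61))):
            cfg = sd.SimConfig(
                n_pairs=500, n_probes=300, seed=60, missing_rate=0.0, effect_logor_per_sd=effect
            )
            beta, sheet = sd.generate_pairs(cfg, ann)
            means = gm.sample_mean_methylation(beta)
            res = rm.spline_risk_distribution(means, sheet["status"], sheet["pair_id"], df=4)
            if label == "null":
                assert res.rr_lower < 1.0 < res.rr_upper
            widths[label] = np.log(res.rr_upper) - np.log(res.rr_lower)
        assert widths["null"] < widths["effect"]

    def test_too_few_distinct_values_rejected(self):
        x = pd.Series([0.1, 0.1, 0.2, 0.2], index=list("abcd"))
        status = pd.Series(["case", "control", "case", "control"], index=list("abcd"))
        pair = pd.Series(["p1", "p1", "p2", "p2"], index=list("abcd"))
        with pytest.raises(ValueError, match="distinct"):
            rm.spline_risk_distribution(x, status, pair, df=4)


class TestRocAuc:
    def test_perfect_separation(self):
        auc, _ = rm.roc_auc([1, 2, 3, 10, 11, 12], ["control"] * 3 + ["case"] * 3)
        assert auc == 1.0

    def test_identical_distributions_near_half(self):
        rng = np.random.default_rng(61)
        scores = rng.normal(size=400)
        status = np.array(["case", "control"] * 200)
        auc, (lo, hi) = rm.roc_auc(scores, status)
        assert lo < 0.5 < hi

    def test_matches_brute_force_concordance(self):
        rng = np.random.default_rng(62)
        scores = np.round(rng.normal(size=30), 1)  # ties likely
        status = np.array(["case"] * 14 + ["control"] * 16)
        auc, _ = rm.roc_auc(scores, status)
        pos, neg = scores[:14], scores[14:]
        conc = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg) / (14 * 16)
        assert auc == pytest.approx(conc, abs=1e-12)


class TestStratifiedAndKS:
    def test_identical_strata_give_zero_q(self):
        rng = np.random.default_rng(63)
        d = rng.normal(0.2, 1, 40)
        pairs = _pairs_frame(np.concatenate([d, d]))
        pairs["stratum"] = ["a"] * 40 + ["b"] * 40
        _, het = rm.stratified_analysis(pairs, "stratum", adjust=())
        assert het.Q == pytest.approx(0.0, abs=1e-10)
        assert het.p_value == pytest.approx(1.0)

    def test_two_stratum_hand_formula(self):
        rng = np.random.default_rng(64)
        pairs = _pairs_frame(rng.normal(0, 1, 60))
        pairs["stratum"] = ["a"] * 30 + ["b"] * 30
        ests, het = rm.stratified_analysis(pairs, "stratum", adjust=())
        (e1, e2) = ests.values()
        w1, w2 = 1 / e1.se**2, 1 / e2.se**2
        theta_bar = (w1 * e1.coef + w2 * e2.coef) / (w1 + w2)
        q_hand = w1 * (e1.coef - theta_bar) ** 2 + w2 * (e2.coef - theta_bar) ** 2
        assert het.Q == pytest.approx(q_hand, rel=1e-10)
        assert het.df == 1

    def test_homogeneous_simulation_p_roughly_uniform(self):
        rng = np.random.default_rng(65)
        ps = []
        for _ in range(300):
            d = rng.normal(0, 1, 80)
            pairs = _pairs_frame(d)
            pairs["stratum"] = ["a"] * 40 + ["b"] * 40
            _, het = rm.stratified_analysis(pairs, "stratum", adjust=())
            ps.append(het.p_value)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_ks_trivial_and_brute_force(self):
        d, p = rm.ks_compare([1.0, 2, 3], [1.0, 2, 3])
        assert d == 0.0
        d, _ = rm.ks_compare([1.0, 2, 3], [10.0, 11, 12])
        assert d == 1.0
        rng = np.random.default_rng(66)
        a, b = rng.normal(0, 1, 15), rng.normal(0.5, 1, 15)
        d, _ = rm.ks_compare(a, b)
        grid = np.concatenate([a, b])
        sup = max(abs(np.mean(a <= t) - np.mean(b <= t)) for t in grid)
        assert d == pytest.approx(sup, abs=1e-12)
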