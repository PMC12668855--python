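import numpy as np
import pytest
import statsmodels.api as sm

from mrmediate import (
    MRModel,
    cml_ma,
    conmix,
    ivw,
    mode_estimator,
    mr_egger,
    mr_raps,
    run_suite,
    wald_ratio,
    weighted_median,
)
from mrmediate.exceptions import InsufficientInstrumentsError, UndefinedRatioError
from mrmediate.mr import MRResults, MRReport

from conftest import make_pairs, random_pairs


class TestWaldRatio:
    def test_direct_formula(self):
        r = wald_ratio(0.5, 0.01, 0.1, 0.05)
        assert r.beta == pytest.approx(0.2)
        assert r.se == pytest.approx(0.1)

    def test_sign_respected(self):
        assert wald_ratio(-0.5, 0.01, 0.1, 0.05).beta == pytest.approx(-0.2)

    def test_zero_exposure_effect_errors(self):
        with pytest.raises(UndefinedRatioError):
            wald_ratio(0.0, 0.01, 0.1, 0.05)

    def test_delta_se_vs_monte_carlo(self):
        # small exposure-side uncertainty: delta SE ~ MC sd of the ratio
        rng = np.random.default_rng(0)
        bx, sx, by, sy = 0.5, 0.002, 0.1, 0.05
        draws = rng.normal(by, sy, 1_000_000) / rng.normal(bx, sx, 1_000_000)
        assert wald_ratio(bx, sx, by, sy).se == pytest.approx(draws.std(), rel=0.02)


class TestIVW:
    def test_equal_ratios_exact(self):
        bx = np.array([0.1, 0.2, 0.4])
        pairs = make_pairs(bx, [0.01] * 3, 0.3 * bx, [0.02, 0.03, 0.05])
        r = ivw(pairs)
        assert r.beta == pytest.approx(0.3)
        assert r.aux["Q"] == pytest.approx(0.0, abs=1e-20)
        assert r.aux["re_scale"] == 1.0

    def test_single_snp_reduces_to_wald(self):
        pairs = make_pairs([0.5], [0.01], [0.1], [0.05])
        r = ivw(pairs)
        w = wald_ratio(0.5, 0.01, 0.1, 0.05)
        assert (r.beta, r.se) == (w.beta, w.se)

    def test_matches_wls_through_origin_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            pairs = random_pairs(rng, j=8)
            bx, sx, by, sy = pairs.arrays()
            fit = sm.WLS(by, bx, weights=1.0 / sy**2).fit()
            r = ivw(pairs, model="fixed")
            assert r.beta == pytest.approx(fit.params[0], abs=1e-12)

    def test_re_never_shrinks_below_fixed(self):
        rng = np.random.default_rng(1)
        pairs = random_pairs(rng, j=15)
        assert ivw(pairs).se >= ivw(pairs, model="fixed").se


class TestEgger:
    def test_nested_under_no_pleiotropy(self):
        rng = np.random.default_rng(2)
        j = 200
        gamma = np.abs(rng.normal(0.15, 0.05, j))
        bx = gamma + rng.normal(0, 0.005, j)
        by = 0.3 * gamma + rng.normal(0, 0.02, j)
        pairs = make_pairs(bx, [0.005] * j, by, [0.02] * j)
        e = mr_egger(pairs)
        assert e.aux["intercept"] == pytest.approx(0.0, abs=2 * e.aux["intercept_se"])
        assert e.beta == pytest.approx(ivw(pairs).beta, abs=0.05)

    def test_constant_shift_becomes_intercept(self):
        rng = np.random.default_rng(3)
        bx = np.abs(rng.normal(0.2, 0.05, 20))  # all positive orientation
        by = 0.3 * bx + 0.05  # exact line: slope 0.3, intercept 0.05
        pairs = make_pairs(bx, [0.01] * 20, by, rng.uniform(0.01, 0.03, 20))
        e = mr_egger(pairs)
        assert e.beta == pytest.approx(0.3, abs=1e-10)
        assert e.aux["intercept"] == pytest.approx(0.05, abs=1e-10)

    def test_matches_wls_with_intercept_oracle(self):
        rng = np.random.default_rng(4)
        pairs = random_pairs(rng, j=12)
        bx, sx, by, sy = pairs.arrays()
        sign = np.where(bx < 0, -1.0, 1.0)  # same orientation the estimator uses
        bx, by = bx * sign, by * sign
        fit = sm.WLS(by, sm.add_constant(bx), weights=1.0 / sy**2).fit()
        e = mr_egger(pairs)
        assert e.beta == pytest.approx(fit.params[1], abs=1e-12)
        assert e.aux["intercept"] == pytest.approx(fit.params[0], abs=1e-12)

    def test_resists_directional_pleiotropy(self):
        # InSIDE holds: pleiotropy independent of instrument strength
        rng = np.random.default_rng(5)
        est_egger, est_ivw = [], []
        for _ in range(200):
            j = 50
            gamma = np.abs(rng.normal(0.15, 0.05, j))
            bx = gamma + rng.normal(0, 0.005, j)
            alpha = rng.normal(0.02, 0.005, j)
            by = 0.3 * gamma + alpha + rng.normal(0, 0.01, j)
            pairs = make_pairs(bx, [0.005] * j, by, [0.01] * j)
            est_egger.append(mr_egger(pairs).beta)
            est_ivw.append(ivw(pairs).beta)
        assert abs(np.mean(est_egger) - 0.3) < 0.03  # < 10% of truth
        assert abs(np.mean(est_ivw) - 0.3) > 0.05  # IVW visibly biased

    def test_too_few_instruments(self):
        with pytest.raises(InsufficientInstrumentsError):
            mr_egger(make_pairs([0.1, 0.2], [0.01] * 2, [0.0, 0.1], [0.02] * 2))


class TestWeightedMedian:
    def test_equal_weights_is_plain_median(self):
        bx = np.full(5, 0.2)
        by = np.array([0.02, 0.04, 0.06, 0.1, 0.2])
        pairs = make_pairs(bx, [0.01] * 5, by, [0.02] * 5)
        r = weighted_median(pairs, seed=0)
        assert r.beta == pytest.approx(np.median(by / bx))

    def test_lies_between_extreme_ratios(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            pairs = random_pairs(rng, j=9)
            bx, _, by, _ = pairs.arrays()
            ratios = by / bx
            r = weighted_median(pairs, seed=1)
            assert ratios.min() <= r.beta <= ratios.max()

    def test_bootstrap_se_converges(self):
        rng = np.random.default_rng(8)
        pairs = random_pairs(rng, j=10)
        se1 = weighted_median(pairs, n_boot=1000, seed=3).se
        se2 = weighted_median(pairs, n_boot=10_000, seed=3).se
        assert se1 == pytest.approx(se2, rel=0.10)


class TestMode:
    def test_identical_ratios_exact(self):
        bx = np.array([0.1, 0.2, 0.4])
        pairs = make_pairs(bx, [0.01] * 3, 0.25 * bx, [0.02] * 3)
        assert mode_estimator(pairs, seed=0).beta == pytest.approx(0.25)

    def test_majority_cluster_wins(self):
        rng = np.random.default_rng(9)
        bx = np.full(10, 0.5)
        ratios = np.r_[rng.normal(0.2, 0.01, 7), rng.normal(0.8, 0.01, 3)]
        pairs = make_pairs(bx, [0.01] * 10, ratios * bx, [0.02] * 10)
        r = mode_estimator(pairs, seed=0)
        assert abs(r.beta - 0.2) < 0.05

    def test_weighted_equals_simple_with_equal_weights(self):
        rng = np.random.default_rng(10)
        bx = np.full(8, 0.3)  # identical ratio SEs -> identical weights
        by = rng.normal(0.1, 0.02, 8)
        pairs = make_pairs(bx, [0.01] * 8, by, [0.02] * 8)
        w = mode_estimator(pairs, weighted=True, seed=1)
        s = mode_estimator(pairs, weighted=False, seed=1)
        assert w.beta == pytest.approx(s.beta)


class TestRAPS:
    def test_agrees_with_ivw_when_clean(self):
        rng = np.random.default_rng(11)
        diffs = []
        for _ in range(50):
            pairs = random_pairs(rng, j=30, se_exp=0.002)
            a = mr_raps(pairs, overdispersion=False, loss="l2").beta
            b = ivw(pairs).beta
            diffs.append(abs(a - b) / abs(b))
        assert np.mean(diffs) < 0.01

    def test_huber_resists_gross_outlier(self):
        rng = np.random.default_rng(12)
        pairs = random_pairs(rng, j=20)
        clean_l2 = mr_raps(pairs, overdispersion=False, loss="l2").beta
        df = pairs.df.copy()
        df.loc[0, "beta_out"] += 30 * df.loc[0, "se_out"]
        dirty = make_pairs(df["beta_exp"], df["se_exp"], df["beta_out"], df["se_out"])
        shift_l2 = abs(mr_raps(dirty, overdispersion=False, loss="l2").beta - clean_l2)
        shift_hu = abs(mr_raps(dirty, overdispersion=False, loss="huber").beta - clean_l2)
        assert shift_hu < 0.2 * shift_l2

    def test_overdispersion_recovery(self):
        rng = np.random.default_rng(13)
        tau = 0.01
        taus = []
        for _ in range(20):
            j = 100
            gamma = rng.normal(0, 0.15, j)
            bx = gamma + rng.normal(0, 0.005, j)
            by = 0.3 * gamma + rng.normal(0, tau, j) + rng.normal(0, 0.01, j)
            pairs = make_pairs(bx, [0.005] * j, by, [0.01] * j)
            taus.append(mr_raps(pairs, overdispersion=True, loss="l2").aux["tau2"])
        assert abs(np.mean(taus) - tau**2) < 0.5 * tau**2


class TestConMix:
    def test_single_snp_is_wald(self):
        pairs = make_pairs([0.5], [0.01], [0.1], [0.05])
        assert conmix(pairs).beta == pytest.approx(0.2)

    def test_agrees_with_ivw_when_all_valid(self):
        rng = np.random.default_rng(14)
        diffs = []
        for _ in range(50):
            pairs = random_pairs(rng, j=25, se_exp=0.002)
            diffs.append(conmix(pairs).beta - ivw(pairs).beta)
        assert abs(np.mean(diffs)) < 0.01

    def test_recovers_truth_with_invalid_cluster(self):
        rng = np.random.default_rng(15)
        est = []
        for _ in range(50):
            j = 30
            gamma = np.abs(rng.normal(0.2, 0.05, j))
            bx = gamma + rng.normal(0, 0.005, j)
            by = 0.3 * gamma + rng.normal(0, 0.01, j)
            by[:9] += 0.15  # 30% invalid, shifted cluster
            pairs = make_pairs(bx, [0.005] * j, by, [0.01] * j)
            r = conmix(pairs)
            est.append(r.beta)
        assert abs(np.mean(est) - 0.3) < 0.05


class TestCmlMa:
    def test_clean_data_prefers_zero_invalid(self):
        rng = np.random.default_rng(16)
        pairs = random_pairs(rng, j=20, se_exp=0.002)
        r = cml_ma(pairs)
        assert r.aux["k_best"] == 0
        assert r.beta == pytest.approx(ivw(pairs).beta, rel=0.05)
        assert r.aux["bic_weights"][0] > 0.5

    def test_identifies_planted_invalid_instruments(self):
        rng = np.random.default_rng(17)
        pairs = random_pairs(rng, j=20, se_exp=0.002)
        df = pairs.df.copy()
        df.loc[[3, 11], "beta_out"] += 0.2
        dirty = make_pairs(df["beta_exp"], df["se_exp"], df["beta_out"], df["se_out"],
                           snp_ids=list(df["snp_id"]))
        r = cml_ma(dirty)
        assert set(r.aux["invalid_snps"]) == {"snp3", "snp11"}

    def test_small_j_matches_bruteforce_subset_oracle(self):
        rng = np.random.default_rng(18)
        bx = np.array([0.2, 0.25, 0.3]) + rng.normal(0, 0.01, 3)
        by = 0.4 * bx + np.array([0.0, 0.0, 0.12])
        sx, sy = np.full(3, 0.01), np.full(3, 0.02)
        pairs = make_pairs(bx, sx, by, sy)

        def oracle_nll(invalid_mask):
            # profile the likelihood on a dense beta grid; gamma closed form
            best = np.inf
            for beta in np.linspace(-1, 1, 4001):
                gamma = (bx / sx**2 + beta * by / sy**2) / (1 / sx**2 + beta**2 / sy**2)
                # invalid SNPs: residual absorbed exactly by free pleiotropy
                gamma_inv = bx.copy()
                g = np.where(invalid_mask, gamma_inv, gamma)
                r = np.where(invalid_mask, by - beta * g, 0.0)
                nll = 0.5 * np.sum((bx - g) ** 2 / sx**2) + 0.5 * np.sum(
                    (by - beta * g - r) ** 2 / sy**2
                )
                best = min(best, nll)
            return best

        masks = [np.array(m) for m in
                 ([False] * 3, [True, False, False], [False, True, False], [False, False, True])]
        nlls = {tuple(m): oracle_nll(m) for m in masks}
        best_k1 = min((m for m in masks if m.sum() == 1), key=lambda m: nlls[tuple(m)])
        r = cml_ma(pairs, max_invalid=1)
        # coordinate descent selects the same invalid SNP as exhaustive search
        assert r.aux["k_best"] == 1
        assert r.aux["invalid_snps"] == [f"snp{int(np.flatnonzero(best_k1)[0])}"]


class TestRatioBoundsProperty:
    from hypothesis import given, settings, strategies as st

    @given(st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_weighted_median_within_ratio_range(self, seed):
        rng = np.random.default_rng(seed)
        pairs = random_pairs(rng, j=int(rng.integers(3, 15)))
        bx, _, by, _ = pairs.arrays()
        ratios = by / bx
        est = weighted_median(pairs, n_boot=50, seed=seed).beta
        assert ratios.min() - 1e-12 <= est <= ratios.max() + 1e-12


class TestSuiteAndInvariants:
    @pytest.mark.parametrize("method", ["ivw", "egger", "weighted_median",
                                        "weighted_mode", "raps", "conmix", "cml_ma"])
    def test_rescaling_equivariance(self, method):
        rng = np.random.default_rng(19)
        pairs = random_pairs(rng, j=15)
        c = 2.5
        scaled = make_pairs(
            c * pairs.df["beta_exp"], c * pairs.df["se_exp"],
            pairs.df["beta_out"], pairs.df["se_out"],
        )
        m1 = MRModel(pairs).fit(method, seed=5)
        m2 = MRModel(scaled).fit(method, seed=5)
        assert m2.beta == pytest.approx(m1.beta / c, rel=1e-6, abs=1e-9)

    def test_or_is_exp_beta(self):
        r = MRResults(method="ivw", beta=0.145, se=0.05, pvalue=0.01, n_snps=5,
                      outcome_binary=True)
        assert r.or_value == pytest.approx(np.exp(0.145))
        lo, hi = r.or_ci
        assert lo == pytest.approx(np.exp(r.ci_low))
        assert r.ci_low <= r.beta <= r.ci_high

    def test_direction_consistency_flag(self):
        mk = lambda m, b: MRResults(method=m, beta=b, se=0.1, pvalue=0.01, n_snps=5)
        rep = MRReport([mk("ivw", 0.2), mk("egger", -0.1), mk("weighted_median", 0.2),
                        mk("simple_mode", 0.2), mk("weighted_mode", 0.2)])
        assert rep.significant and not rep.direction_consistent

    def test_suite_on_strong_simulated_effect(self):
        rng = np.random.default_rng(20)
        pairs = random_pairs(rng, j=30, beta=0.3, se_exp=0.002)
        rep = run_suite(pairs, seed=21)
        assert rep.significant and rep.direction_consistent


class TestMVMR:
    def test_single_exposure_reduces_to_ivw(self):
        from mrmediate import mvmr_ivw

        rng = np.random.default_rng(22)
        pairs = random_pairs(rng, j=20)
        bx, sx, by, sy = pairs.arrays()
        uni = ivw(pairs)
        multi = mvmr_ivw(bx[:, None], by, sy)[0]
        assert multi.beta == pytest.approx(uni.beta, abs=1e-12)
        assert multi.se == pytest.approx(uni.se, abs=1e-12)

    def test_two_exposures_recovered(self):
        from mrmediate import mvmr_ivw

        rng = np.random.default_rng(23)
        hits = [0, 0]
        reps = 200
        for _ in range(reps):
            j = 100
            X = rng.normal(0, 0.1, (j, 2))
            by = X @ np.array([0.3, -0.2]) + rng.normal(0, 0.02, j)
            res = mvmr_ivw(X, by, np.full(j, 0.02))
            for i, truth in enumerate((0.3, -0.2)):
                lo, hi = res[i].conf_int()
                hits[i] += lo <= truth <= hi
        assert hits[0] / reps >= 0.9 and hits[1] / reps >= 0.9

    def test_duplicated_exposure_collinear(self):
        from mrmediate import mvmr_ivw
        from mrmediate.exceptions import CollinearityError

        rng = np.random.default_rng(24)
        x = rng.normal(0, 0.1, 30)
        with pytest.raises(CollinearityError):
            mvmr_ivw(np.c_[x, x], rng.normal(0, 0.02, 30), np.full(30, 0.02))
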