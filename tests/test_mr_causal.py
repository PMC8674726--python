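"""Instrument selection and causal estimation: IVW, Egger, weighted median,
Cochran's Q, pleiotropy exclusion and the implied-Wald consistency utility."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from gwasmr.mr_causal import (
    clump_instruments, cochran_q, egger_estimate, exclude_pleiotropic,
    harmonize_instruments, implied_wald_p, ivw_estimate, substitute_proxies,
    weighted_median_estimate,
)

from conftest import instruments_frame


class TestIVW:
    def test_single_instrument_wald_ratio(self):
        res = ivw_estimate(instruments_frame([0.2], [0.05], [0.01]))
        assert res.estimate == pytest.approx(0.25)
        assert res.method == "IVW"

    def test_two_instrument_worked_example(self):
        res = ivw_estimate(instruments_frame([0.1, 0.2], [0.02, 0.05], [0.01, 0.01]))
        assert res.estimate == pytest.approx(0.24)
        assert res.se == pytest.approx(500 ** -0.5)

    def test_shared_ratio_recovered_exactly(self):
        bx = np.array([0.1, 0.2, 0.3])
        res = ivw_estimate(instruments_frame(bx, 0.4 * bx, 0.01))
        assert res.estimate == pytest.approx(0.4, abs=1e-12)
        assert res.q_stat == pytest.approx(0.0, abs=1e-18)

    def test_through_origin_wls_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            j = rng.integers(2, 20)
            bx = rng.normal(0.05, 0.02, j)
            by = rng.normal(0.01, 0.02, j)
            sy = rng.uniform(0.005, 0.05, j)
            res = ivw_estimate(instruments_frame(bx, by, sy))
            fit = sm.WLS(by, bx[:, None], weights=1.0 / sy**2).fit()
            assert res.estimate == pytest.approx(fit.params[0], rel=1e-10)

    def test_ci_and_p_invariants(self):
        res = ivw_estimate(instruments_frame([0.1, 0.2], [0.03, 0.05], [0.01, 0.01]))
        assert res.ci_lower == pytest.approx(res.estimate - 1.959964 * res.se)
        assert res.ci_upper == pytest.approx(res.estimate + 1.959964 * res.se)
        from scipy import stats
        assert res.p == pytest.approx(2 * stats.norm.sf(abs(res.estimate / res.se)))

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            ivw_estimate(instruments_frame([], [], []))

    def test_zero_beta_x_single_instrument_errors(self):
        with pytest.raises(ValueError):
            ivw_estimate(instruments_frame([0.0], [0.1], [0.01]))


class TestEgger:
    def test_collinear_exact_fit(self):
        res = egger_estimate(
            instruments_frame([0.1, 0.2, 0.3], [0.03, 0.05, 0.07], 0.01))
        assert res.estimate == pytest.approx(0.2, abs=1e-10)
        assert res.egger_intercept == pytest.approx(0.01, abs=1e-10)

    def test_all_null_outcome(self):
        res = egger_estimate(instruments_frame([0.1, 0.2, 0.3], [0.0, 0.0, 0.0], 0.01))
        assert res.estimate == pytest.approx(0.0, abs=1e-12)
        assert res.egger_intercept == pytest.approx(0.0, abs=1e-12)

    def test_orientation_flips_negative_beta_x(self):
        # flipping the sign of (beta_x, beta_y) jointly must not change the fit
        a = egger_estimate(instruments_frame([0.1, 0.2, 0.3], [0.03, 0.05, 0.07], 0.01))
        b = egger_estimate(instruments_frame([0.1, -0.2, 0.3], [0.03, -0.05, 0.07], 0.01))
        assert b.estimate == pytest.approx(a.estimate, abs=1e-12)
        assert b.egger_intercept == pytest.approx(a.egger_intercept, abs=1e-12)

    def test_slope_equals_ivw_without_intercept(self):
        rng = np.random.default_rng(4)
        bx = np.abs(rng.normal(0.05, 0.02, 10)) + 0.01
        by = 0.3 * bx + rng.normal(0, 0.005, 10)
        sy = np.full(10, 0.01)
        frame = instruments_frame(bx, by, sy)
        ivw = ivw_estimate(frame).estimate
        refit = sm.WLS(by, bx[:, None], weights=1.0 / sy**2).fit()
        assert refit.params[0] == pytest.approx(ivw, rel=1e-10)

    def test_too_few_instruments(self):
        with pytest.raises(ValueError):
            egger_estimate(instruments_frame([0.1, 0.2], [0.03, 0.05], 0.01))


class TestWeightedMedian:
    def test_robust_to_outlier_ratio(self):
        frame = instruments_frame([0.1, 0.1, 0.1], [0.1, 0.2, 1.0], [0.01, 0.01, 0.01])
        res = weighted_median_estimate(frame, n_boot=50, seed=1)
        assert res.estimate == pytest.approx(2.0)

    def test_interpolated_weighted_median(self):
        # ratios (1,2,3) with weights (0.6,0.2,0.2): s=(0.3,0.7,0.9) -> 1.5
        # weights are (bx/sy)^2, so choose bx/sy in ratio sqrt((3,1,1))
        bx = np.array([np.sqrt(3), 1.0, 1.0]) * 0.01
        by = bx * np.array([1.0, 2.0, 3.0])
        res = weighted_median_estimate(
            instruments_frame(bx, by, 0.01), n_boot=50, seed=1)
        assert res.estimate == pytest.approx(1.5)

    def test_degenerate_limit(self):
        bx = np.array([0.1, 0.2, 0.3])
        frame = instruments_frame(bx, 0.7 * bx, 1e-8, sx=1e-8)
        res = weighted_median_estimate(frame, n_boot=100, seed=0)
        assert res.estimate == pytest.approx(0.7)
        assert res.se < 1e-5

    def test_seed_reproducible(self):
        frame = instruments_frame([0.1, 0.2, 0.3], [0.02, 0.05, 0.05], 0.01)
        a = weighted_median_estimate(frame, n_boot=200, seed=7)
        b = weighted_median_estimate(frame, n_boot=200, seed=7)
        assert a.se == b.se

    def test_equal_weights_odd_j_is_simple_median(self):
        rng = np.random.default_rng(6)
        ratios = rng.normal(0.2, 0.5, 5)
        bx = np.full(5, 0.1)
        res = weighted_median_estimate(
            instruments_frame(bx, bx * ratios, 0.01), n_boot=50, seed=0)
        assert res.estimate == pytest.approx(np.median(ratios))

    def test_too_few_instruments(self):
        with pytest.raises(ValueError):
            weighted_median_estimate(instruments_frame([0.1], [0.1], 0.01))


class TestCochranQ:
    def test_homogeneous_q_zero(self):
        bx = np.array([0.1, 0.2])
        q, df, p = cochran_q(instruments_frame(bx, 0.25 * bx, 0.01), 0.25)
        assert q == pytest.approx(0.0, abs=1e-18)
        assert df == 1
        assert p == pytest.approx(1.0)

    def test_two_instrument_worked_example(self):
        # ratios (0.2, 0.3), weights (100, 100), theta 0.25 -> Q = 0.5
        bx = np.array([0.1, 0.1])
        by = np.array([0.02, 0.03])
        q, df, _ = cochran_q(instruments_frame(bx, by, 0.01), 0.25)
        assert q == pytest.approx(0.5)
        assert df == 1

    def test_single_instrument_errors(self):
        with pytest.raises(ValueError):
            cochran_q(instruments_frame([0.1], [0.02], 0.01), 0.2)


class TestExcludePleiotropic:
    def test_homogeneous_retained(self):
        bx = np.array([0.1, 0.2, 0.3, 0.15])
        frame = instruments_frame(bx, 0.2 * bx, 0.01)
        retained, excluded = exclude_pleiotropic(frame)
        assert excluded == []
        assert len(retained) == 4

    def test_planted_outlier_excluded(self):
        bx = np.full(10, 0.1)
        by = 0.2 * bx
        by[9] = 10 * 0.2 * bx[9]  # ratio 2.0 vs 0.2 for the rest
        retained, excluded = exclude_pleiotropic(instruments_frame(bx, by, 0.01))
        assert excluded == ["iv9"]
        assert len(retained) == 9

    def test_equally_discordant_triplet_kept(self):
        # small symmetric spread around theta: contributions below the cutoff
        bx = np.array([0.1, 0.1, 0.1])
        by = np.array([0.019, 0.020, 0.021])
        retained, excluded = exclude_pleiotropic(instruments_frame(bx, by, 0.01))
        assert excluded == []
        assert len(retained) == 3

    def test_too_few_instruments(self):
        with pytest.raises(ValueError):
            exclude_pleiotropic(instruments_frame([0.1, 0.2], [0.02, 0.04], 0.01))


class TestImpliedWaldP:
    def test_null_midpoint(self):
        assert implied_wald_p(0.0, -1.959964, 1.959964) == pytest.approx(1.0)

    def test_zero_width_ci_errors(self):
        with pytest.raises(ValueError):
            implied_wald_p(0.1, 0.1, 0.1)


class TestClumping:
    def _sumstats(self, snps, pos, p, chrom=None):
        return pd.DataFrame({
            "SNP": snps, "CHR": chrom or ["1"] * len(snps), "POS": pos, "P": p,
        })

    def _ld(self, snps, r2):
        return pd.DataFrame(r2, index=snps, columns=snps, dtype=float)

    def test_linked_within_window_pruned(self):
        ss = self._sumstats(["a", "b"], [1_000_000, 1_100_000], [1e-12, 1e-10])
        ld = self._ld(["a", "b"], [[1, 0.5], [0.5, 1]])
        assert clump_instruments(ss, ld) == ["a"]

    def test_unlinked_within_window_kept(self):
        ss = self._sumstats(["a", "b"], [1_000_000, 1_100_000], [1e-12, 1e-10])
        ld = self._ld(["a", "b"], [[1, 0.0005], [0.0005, 1]])
        assert clump_instruments(ss, ld) == ["a", "b"]

    def test_different_chromosomes_kept(self):
        ss = self._sumstats(["a", "b"], [1_000_000, 1_000_000], [1e-12, 1e-10],
                            chrom=["1", "2"])
        ld = self._ld(["a", "b"], [[1, 0.0], [0.0, 1]])
        assert clump_instruments(ss, ld) == ["a", "b"]

    def test_linked_but_distant_kept(self):
        ss = self._sumstats(["a", "b"], [1_000_000, 2_000_000], [1e-12, 1e-10])
        ld = self._ld(["a", "b"], [[1, 0.9], [0.9, 1]])
        assert clump_instruments(ss, ld) == ["a", "b"]

    def test_snp_missing_from_ld_treated_unlinked(self, caplog):
        ss = self._sumstats(["a", "b"], [1_000_000, 1_100_000], [1e-12, 1e-10])
        ld = self._ld(["a"], [[1.0]])
        with caplog.at_level("WARNING"):
            assert clump_instruments(ss, ld) == ["a", "b"]
        assert "absent from the LD matrix" in caplog.text

    def test_pairwise_independence_property(self):
        rng = np.random.default_rng(21)
        n = 30
        snps = [f"s{i}" for i in range(n)]
        pos = np.sort(rng.choice(5_000_000, n, replace=False))
        W = rng.normal(size=(n, n))
        cov = W @ W.T + n * np.eye(n)
        d = np.sqrt(np.diag(cov))
        r2 = (cov / np.outer(d, d)) ** 2
        ss = self._sumstats(snps, pos, 10.0 ** -rng.uniform(9.5, 30, n))
        ld = self._ld(snps, r2)
        accepted = clump_instruments(ss, ld)
        for i, a in enumerate(accepted):
            for b in accepted[i + 1:]:
                pa = int(ss.set_index("SNP").loc[a, "POS"])
                pb = int(ss.set_index("SNP").loc[b, "POS"])
                assert ld.loc[a, b] < 0.001 or abs(pa - pb) > 250_000


class TestProxies:
    def test_present_instrument_unchanged(self):
        used = substitute_proxies(["a"], ["a", "b"])
        assert used == [("a", "a")]

    def test_missing_with_good_proxy(self):
        used = substitute_proxies(["a"], ["p1"], {"a": [("p1", 0.9)]})
        assert used == [("a", "p1")]

    def test_missing_with_weak_proxy_dropped(self):
        used = substitute_proxies(["a"], ["p1"], {"a": [("p1", 0.5)]})
        assert used == []

    def test_best_proxy_wins(self):
        used = substitute_proxies(["a"], ["p1", "p2"],
                                  {"a": [("p1", 0.85), ("p2", 0.95)]})
        assert used == [("a", "p2")]

    def test_dataframe_proxy_table(self):
        table = pd.DataFrame({"SNP": ["a"], "PROXY": ["p1"], "R2": [0.9]})
        assert substitute_proxies(["a"], ["p1"], table) == [("a", "p1")]


class TestHarmonizeInstruments:
    def _tables(self, out_ea="A", out_oa="G", out_beta=0.05):
        exposure = pd.DataFrame({
            "SNP": ["rs1"], "EA": ["A"], "OA": ["G"],
            "BETA": [0.2], "SE": [0.02],
        })
        outcome = pd.DataFrame({
            "SNP": ["rs1"], "EA": [out_ea], "OA": [out_oa],
            "BETA": [out_beta], "SE": [0.03],
        })
        return exposure, outcome

    def test_matching_alleles_pass_through(self):
        frame = harmonize_instruments(*self._tables())
        assert frame["beta_y"].iloc[0] == pytest.approx(0.05)

    def test_swapped_alleles_flip_outcome(self):
        frame = harmonize_instruments(*self._tables(out_ea="G", out_oa="A"))
        assert frame["beta_y"].iloc[0] == pytest.approx(-0.05)

    def test_irreconcilable_dropped(self):
        frame = harmonize_instruments(*self._tables(out_ea="A", out_oa="C"))
        assert len(frame) == 0
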