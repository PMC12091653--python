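"""MR estimators against independent oracles (WLS, grid search, brute force)."""

import numpy as np
import pytest
import statsmodels.api as sm
from scipy import stats

from medmr.harmonize import IVSet, SelectionParams
from medmr.mr import (
    DegenerateInstrumentError,
    InsufficientInstrumentsError,
    WaldRatio,
    beta_to_or,
    ci_to_se,
    ivw,
    max_likelihood,
    mr_egger,
    or_to_beta,
    run_all_methods,
    wald_ratios,
    weighted_median,
)

from helpers import rec, table
from medmr.harmonize import harmonize, HarmonizedPair, KEPT


def make_ivset(bx, sx, by, sy, exposure_id="exp"):
    pairs = [
        HarmonizedPair(
            variant_id=f"rs{i}", chrom="1", pos=1000 * (i + 1),
            effect_allele="A", other_allele="G",
            beta_exp=float(x), se_exp=float(s1), eaf_exp=0.3,
            beta_out=float(y), se_out=float(s2), eaf_out=0.3,
            pval_exp=1e-9, flipped=False, status=KEPT,
        )
        for i, (x, s1, y, s2) in enumerate(zip(bx, sx, by, sy))
    ]
    f = {p.variant_id: (p.beta_exp / p.se_exp) ** 2 for p in pairs}
    return IVSet(exposure_id, pairs, f, SelectionParams())


class TestWaldRatios:
    def test_direct_arithmetic(self):
        ivset = make_ivset([0.2], [0.02], [0.1], [0.05])
        (w,) = wald_ratios(ivset)
        assert w.ratio == pytest.approx(0.5)
        assert w.se_ratio == pytest.approx(0.25)

    def test_zero_outcome_gives_zero_ratio(self):
        (w,) = wald_ratios(make_ivset([0.2], [0.02], [0.0], [0.05]))
        assert w.ratio == 0.0

    def test_sign_symmetry(self):
        a = wald_ratios(make_ivset([0.2], [0.02], [0.1], [0.05]))[0]
        b = wald_ratios(make_ivset([-0.2], [0.02], [-0.1], [0.05]))[0]
        assert a.ratio == pytest.approx(b.ratio)

    def test_zero_exposure_effect_names_variant(self):
        with pytest.raises(DegenerateInstrumentError, match="rs1"):
            wald_ratios(make_ivset([0.2, 0.0], [0.02, 0.02], [0.1, 0.1], [0.05, 0.05]))


class TestIVW:
    def test_single_ratio_identity(self):
        est = ivw([WaldRatio("rs0", 0.5, 0.25)], mode="fixed")
        assert est.beta == pytest.approx(0.5)
        assert est.se == pytest.approx(0.25)

    def test_all_equal_ratios(self):
        ratios = [WaldRatio(f"rs{i}", 0.3, s) for i, s in enumerate([0.1, 0.2, 0.3])]
        fixed = ivw(ratios, mode="fixed")
        mre = ivw(ratios, mode="multiplicative_random")
        assert fixed.beta == pytest.approx(0.3)
        assert fixed.q == pytest.approx(0.0, abs=1e-12)
        assert mre.se == pytest.approx(fixed.se)  # scaling floored at 1

    def test_three_ratio_instance_closed_form(self):
        # zero-intercept WLS on the printed values, solved by hand:
        # beta = sum(w r)/sum(w) with w = 1/se^2
        ratios = [WaldRatio("a", 0.4, 0.1), WaldRatio("b", 0.6, 0.2), WaldRatio("c", 0.5, 0.05)]
        w = np.array([100.0, 25.0, 400.0])
        r = np.array([0.4, 0.6, 0.5])
        est = ivw(ratios, mode="fixed")
        assert est.beta == pytest.approx(np.sum(w * r) / np.sum(w), abs=1e-14)
        assert est.se == pytest.approx(1 / np.sqrt(np.sum(w)), abs=1e-14)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_statsmodels_wls_oracle(self, seed):
        rng = np.random.default_rng(seed)
        k = 10
        r = rng.normal(0.2, 0.3, k)
        s = rng.uniform(0.05, 0.4, k)
        ratios = [WaldRatio(f"rs{i}", ri, si) for i, (ri, si) in enumerate(zip(r, s))]
        fit = sm.WLS(r, np.ones((k, 1)), weights=1 / s**2).fit()
        est = ivw(ratios, mode="fixed")
        assert est.beta == pytest.approx(float(fit.params[0]), abs=1e-10)

    def test_empty_rejected(self):
        with pytest.raises(InsufficientInstrumentsError):
            ivw([], mode="fixed")


class TestEgger:
    def test_exact_line_recovered(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        by = 0.1 + 0.5 * bx
        est = mr_egger(make_ivset(bx, [0.01] * 4, by, [0.05] * 4))
        assert est.egger_intercept == pytest.approx(0.1, abs=1e-12)
        assert est.beta == pytest.approx(0.5, abs=1e-12)

    def test_four_point_normal_equations_oracle(self):
        bx = np.array([0.1, 0.25, 0.3, 0.5])
        by = np.array([0.06, 0.11, 0.18, 0.27])
        sy = np.array([0.05, 0.04, 0.06, 0.05])
        est = mr_egger(make_ivset(bx, [0.01] * 4, by, sy))
        # independent weighted normal equations
        w = 1 / sy**2
        X = np.column_stack([np.ones(4), bx])
        coef = np.linalg.solve(X.T @ (X * w[:, None]), X.T @ (w * by))
        assert est.egger_intercept == pytest.approx(coef[0], abs=1e-10)
        assert est.beta == pytest.approx(coef[1], abs=1e-10)

    def test_orientation_flips_negative_exposures(self):
        bx = np.array([0.1, -0.2, 0.3, -0.4])
        by = 0.5 * bx  # no pleiotropy
        est = mr_egger(make_ivset(bx, [0.01] * 4, by, [0.05] * 4))
        assert est.beta == pytest.approx(0.5, abs=1e-12)
        assert est.egger_intercept == pytest.approx(0.0, abs=1e-12)

    def test_zero_pleiotropy_slope_near_ivw(self):
        rng = np.random.default_rng(11)
        k = 50
        bx = rng.uniform(0.1, 0.4, k)
        sy = np.full(k, 0.02)
        by = 0.3 * bx + rng.normal(0, sy)
        ivset = make_ivset(bx, np.full(k, 1e-4), by, sy)
        egger = mr_egger(ivset)
        est = ivw(wald_ratios(ivset), mode="fixed")
        assert egger.beta == pytest.approx(est.beta, abs=3 * egger.se)
        assert abs(egger.egger_intercept) < 3 * egger.intercept_se

    def test_insufficient_instruments(self):
        with pytest.raises(InsufficientInstrumentsError):
            mr_egger(make_ivset([0.1, 0.2], [0.01] * 2, [0.05, 0.1], [0.05] * 2))

    def test_intercept_test_valid_under_null(self):
        # directional pleiotropy absent: the intercept test must not reject
        # above its nominal level. The SE floor max(1, sqrt(RSS/(k-2))) makes
        # the test conservative rather than exactly uniform, so the check is
        # one-sided validity plus non-degeneracy, not a KS uniformity test.
        rng = np.random.default_rng(5)
        k, reps = 10, 1000
        pvals = np.empty(reps)
        for i in range(reps):
            bx = rng.uniform(0.1, 0.5, k)
            sy = rng.uniform(0.02, 0.08, k)
            by = 0.2 * bx + rng.normal(0, sy)
            est = mr_egger(make_ivset(bx, np.full(k, 1e-4), by, sy))
            pvals[i] = est.intercept_pval
        rate = np.mean(pvals < 0.05)
        assert rate <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / reps)
        assert rate >= 0.005  # conservative, but not degenerate
        assert stats.kstest(pvals, "uniform").statistic < 0.12  # near-uniform


class TestWeightedMedian:
    def test_all_equal(self):
        ratios = [WaldRatio(f"r{i}", 0.7, s) for i, s in enumerate([0.1, 0.2, 0.3])]
        assert weighted_median(ratios, n_boot=100).beta == pytest.approx(0.7)

    def test_majority_weight_ratio_returned(self):
        ratios = [
            WaldRatio("a", 1.0, 1 / np.sqrt(0.3)),
            WaldRatio("b", 2.0, 1 / np.sqrt(0.6)),  # 60% of the weight
            WaldRatio("c", 3.0, 1 / np.sqrt(0.1)),
        ]
        assert weighted_median(ratios, n_boot=100).beta == pytest.approx(2.0)

    def test_five_ratio_brute_force_crossing(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(0.5, 0.4, 5)
        ses = rng.uniform(0.1, 0.6, 5)
        ratios = [WaldRatio(f"r{i}", v, s) for i, (v, s) in enumerate(zip(vals, ses))]
        # brute force: walk the sorted ratios accumulating normalized weight
        order = np.argsort(vals)
        w = (1 / ses**2)[order] / np.sum(1 / ses**2)
        acc, expected = 0.0, None
        for val, wi in zip(vals[order], w):
            acc += wi
            if acc >= 0.5:
                expected = val
                break
        est = weighted_median(ratios, n_boot=100)
        assert est.beta == pytest.approx(expected, abs=1e-12)

    def test_seeded_bootstrap_reproducible(self):
        ratios = [WaldRatio(f"r{i}", v, 0.2) for i, v in enumerate([0.1, 0.5, 0.9, 0.3])]
        a = weighted_median(ratios, n_boot=200, seed=42)
        b = weighted_median(ratios, n_boot=200, seed=42)
        assert a.se == b.se


class TestMaxLikelihood:
    def test_noiseless_proportional_exact(self):
        bx = np.array([0.1, 0.2, 0.3])
        est = max_likelihood(make_ivset(bx, [0.01] * 3, 0.42 * bx, [0.05] * 3))
        assert est.beta == pytest.approx(0.42, abs=1e-7)

    def test_grid_search_oracle(self):
        bx = np.array([0.15, 0.3, 0.22])
        sx = np.array([0.02, 0.03, 0.02])
        by = np.array([0.05, 0.13, 0.08])
        sy = np.array([0.04, 0.05, 0.04])
        grid = np.arange(-1.0, 1.5, 1e-6)
        nll = np.sum(
            (by[None, :] - grid[:, None] * bx[None, :]) ** 2
            / (sy[None, :] ** 2 + grid[:, None] ** 2 * sx[None, :] ** 2),
            axis=1,
        )
        theta_grid = grid[np.argmin(nll)]
        est = max_likelihood(make_ivset(bx, sx, by, sy))
        assert est.beta == pytest.approx(theta_grid, abs=2e-6)

    def test_small_exposure_se_limit_approaches_ivw(self):
        rng = np.random.default_rng(9)
        k = 20
        bx = rng.uniform(0.1, 0.4, k)
        sy = np.full(k, 0.03)
        by = 0.25 * bx + rng.normal(0, sy)
        ivset = make_ivset(bx, np.full(k, 1e-8), by, sy)
        ml = max_likelihood(ivset)
        fixed = ivw(wald_ratios(ivset), mode="fixed")
        assert abs(ml.beta - fixed.beta) < 1e-3


class TestConversions:
    @pytest.mark.parametrize(
        "or_value,beta_3dp",
        [(1.102, 0.097), (0.956, -0.045), (1.0, 0.0)],
    )
    def test_or_to_beta_printed_precision(self, or_value, beta_3dp):
        assert round(or_to_beta(or_value), 3) == pytest.approx(beta_3dp)

    def test_beta_or_roundtrip(self):
        assert beta_to_or(or_to_beta(0.513)) == pytest.approx(0.513)

    def test_ci_to_se(self):
        # symmetric log CI: se recovers the generating value
        se = 0.05
        lo, hi = np.exp(0.1 - 1.959964 * se), np.exp(0.1 + 1.959964 * se)
        assert ci_to_se(lo, hi) == pytest.approx(se, abs=1e-12)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            or_to_beta(0.0)
        with pytest.raises(ValueError):
            ci_to_se(0.9, 0.5)


def test_ivw_and_ml_bias_on_causal_chain():
    """On chain simulations with a true causal effect, IVW and maximum
    likelihood are unbiased to |bias| < 0.02 (n = 20,000 individuals, 20
    instruments, 400 sampled replicates via the analytic route)."""
    from medmr.gwas_io import compute_ld
    from medmr.harmonize import SelectionParams, select_instruments
    from medmr.simulate import (
        SimulationScenario, chain_true_betas, sample_summary_stats, simulate_panel,
    )

    theta = 0.097
    sc = SimulationScenario(
        name="bias", n_individuals=20_000, n_variants=200, ld_block_size=10,
        rho=0.6, maf_range=(0.1, 0.5), seed=202, c_prime=theta,
        exposure_causal=tuple(b * 10 + 3 for b in range(20)),
        exposure_effects=(0.18,) * 20,
    )
    panel = simulate_panel(sc)
    ld = compute_ld(panel)
    truths = chain_true_betas(sc, panel)
    rng = np.random.default_rng(17)
    est_ivw, est_ml = [], []
    for _ in range(400):
        e = sample_summary_stats(sc, panel, ld, truths["exposure"],
                                 "quantitative", "e", rng)
        o = sample_summary_stats(sc, panel, ld, truths["outcome"],
                                 "binary", "o", rng)
        ivset = select_instruments(e, o, ld, SelectionParams(p_threshold=1e-5))
        est_ivw.append(ivw(wald_ratios(ivset), mode="fixed").beta)
        est_ml.append(max_likelihood(ivset).beta)
    assert abs(np.mean(est_ivw) - theta) < 0.02
    assert abs(np.mean(est_ml) - theta) < 0.02


def test_run_all_methods_reports_five_rows():
    bx = np.linspace(0.1, 0.4, 6)
    by = 0.3 * bx
    ests = run_all_methods(make_ivset(bx, [0.01] * 6, by, [0.05] * 6))
    assert [e.method for e in ests] == [
        "ivw_mre", "ivw_fixed", "egger", "weighted_median", "max_likelihood"
    ]
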