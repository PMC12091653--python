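"""Synthetic cohort generator: LD calibration, chain semantics, marginal stats."""

import numpy as np
import pytest
from scipy import stats

from medmr.gwas_io import compute_ld, read_summary_table, write_summary_table
from medmr.simulate import (
    SimulationScenario,
    analytic_se,
    chain_true_betas,
    sample_summary_stats,
    scenario_presets,
    simulate_chain,
    simulate_panel,
    simulate_study,
    summary_stats,
    true_marginal_betas,
)


def small_scenario(**kw):
    base = dict(
        name="test", n_individuals=4000, n_variants=40, ld_block_size=8,
        rho=0.5, maf_range=(0.2, 0.4), seed=123,
    )
    base.update(kw)
    return SimulationScenario(**base)


class TestPanel:
    def test_same_seed_identical(self):
        sc = small_scenario()
        p1 = simulate_panel(sc)
        p2 = simulate_panel(sc)
        np.testing.assert_array_equal(p1.dosages, p2.dosages)

    def test_dosages_in_range_and_eaf_near_maf(self):
        sc = small_scenario(n_individuals=20_000)
        p = simulate_panel(sc)
        assert p.dosages.min() >= 0 and p.dosages.max() <= 2
        eaf = p.dosages.mean(axis=0) / 2
        assert np.all(eaf > 0.15) and np.all(eaf < 0.45)

    def test_rho_zero_gives_near_independent_variants(self):
        sc = small_scenario(rho=0.0, n_individuals=5000)
        ld = compute_ld(simulate_panel(sc))
        off = np.abs(ld.r[np.triu_indices(sc.n_variants, 1)])
        assert off.mean() < 3 / np.sqrt(sc.n_individuals)

    def test_block_rho_calibrated_to_dosage_scale(self):
        # latent correlation is inverted through the tetrachoric map, so the
        # realized dosage correlation should sit near the requested value
        sc = small_scenario(rho=0.9, n_individuals=10_000, maf_range=(0.25, 0.35))
        ld = compute_ld(simulate_panel(sc))
        within = []
        for blk in range(sc.n_variants // sc.ld_block_size):
            j0 = blk * sc.ld_block_size
            block = ld.r[j0:j0 + sc.ld_block_size, j0:j0 + sc.ld_block_size]
            within.extend(block[np.triu_indices(sc.ld_block_size, 1)])
        assert np.mean(within) == pytest.approx(0.9, abs=0.1)

    def test_degenerate_rho_rejected(self):
        with pytest.raises(ValueError):
            small_scenario(rho=1.0)

    def test_mafs_shared_across_cohorts(self):
        sc = small_scenario()
        rng_a = np.random.default_rng(1)
        rng_b = np.random.default_rng(2)
        ea = simulate_panel(sc, rng_a).dosages.mean(axis=0) / 2
        eb = simulate_panel(sc, rng_b).dosages.mean(axis=0) / 2
        # different individuals, same population frequencies
        assert np.max(np.abs(ea - eb)) < 0.05


class TestChain:
    def test_unattainable_prevalence_rejected(self):
        panel = simulate_panel(small_scenario())
        with pytest.raises(ValueError, match="prevalence"):
            simulate_chain(panel, small_scenario(prevalence=1 - 1e-15), None)

    def test_intercept_calibration_hits_prevalence(self):
        sc = small_scenario(n_individuals=20_000, prevalence=0.07)
        panel = simulate_panel(sc)
        traits = simulate_chain(panel, sc)
        prev = traits["outcome"].mean()
        se = np.sqrt(0.07 * 0.93 / sc.n_individuals)
        assert abs(prev - 0.07) < 4 * se

    def test_a_zero_mediator_independent_of_exposure_given_genotype(self):
        sc = small_scenario(
            n_individuals=20_000, a=0.0,
            exposure_causal=(0,), exposure_effects=(0.2,),
            mediator_causal=(8,), mediator_effects=(0.2,),
        )
        panel = simulate_panel(sc)
        t = simulate_chain(panel, sc)
        g = panel.dosages[:, [0, 8]]
        resid = lambda y: y - g @ np.linalg.lstsq(g, y, rcond=None)[0]
        r = np.corrcoef(resid(t["exposure"]), resid(t["mediator"]))[0, 1]
        assert abs(r) < 0.03

    def test_full_chain_recovers_a(self):
        sc = small_scenario(
            n_individuals=20_000, a=-0.3,
            exposure_causal=(0,), exposure_effects=(0.2,),
        )
        panel = simulate_panel(sc)
        t = simulate_chain(panel, sc)
        slope, _, _, _, stderr = stats.linregress(t["exposure"], t["mediator"])
        assert abs(slope - sc.a) < 1.96 * stderr + 0.01

    def test_traits_near_unit_variance(self):
        sc = small_scenario(n_individuals=20_000, a=-0.3,
                            exposure_causal=(0,), exposure_effects=(0.3,))
        t = simulate_chain(simulate_panel(sc), sc)
        assert np.std(t["exposure"]) == pytest.approx(1.0, abs=0.05)
        assert np.std(t["mediator"]) == pytest.approx(1.0, abs=0.05)


class TestSummaryStats:
    def test_eaf_is_exact_column_mean(self):
        sc = small_scenario()
        panel = simulate_panel(sc)
        t = simulate_chain(panel, sc)
        tbl = summary_stats(t["exposure"], panel, "quantitative", sc, "e")
        for j, recd in enumerate(tbl):
            assert recd.eaf == panel.dosages[:, j].mean() / 2

    def test_causal_beta_within_ci(self):
        sc = small_scenario(
            n_individuals=20_000,
            exposure_causal=(0,), exposure_effects=(0.2,),
        )
        panel = simulate_panel(sc)
        t = simulate_chain(panel, sc)
        tbl = summary_stats(t["exposure"], panel, "quantitative", sc, "e")
        truth = true_marginal_betas(panel, (0,), (0.2,))
        r0 = tbl.records[0]
        assert abs(r0.beta - truth[0]) < 3 * r0.se

    def test_permuted_trait_pvals_uniform(self):
        sc = small_scenario(n_individuals=5000, n_variants=100, ld_block_size=1, rho=0.0)
        panel = simulate_panel(sc)
        rng = np.random.default_rng(0)
        y = rng.standard_normal(sc.n_individuals)
        tbl = summary_stats(y, panel, "quantitative", sc, "perm")
        pvals = [r.pval for r in tbl]
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_logistic_route_agrees_with_statsmodels(self):
        import statsmodels.api as sm
        sc = small_scenario(n_individuals=3000, n_variants=8)
        panel = simulate_panel(sc)
        rng = np.random.default_rng(5)
        y = (rng.uniform(size=sc.n_individuals) < 0.1).astype(float)
        tbl = summary_stats(y, panel, "binary", sc, "d")
        j = 3
        X = sm.add_constant(panel.dosages[:, j])
        fit = sm.Logit(y, X).fit(disp=0)
        recd = tbl.records[j]
        assert recd.beta == pytest.approx(fit.params[1], abs=1e-5)
        assert recd.se == pytest.approx(fit.bse[1], rel=1e-4)

    def test_doubling_n_shrinks_median_se_sqrt2(self):
        ses = {}
        for n in (5000, 10_000):
            sc = small_scenario(n_individuals=n)
            panel = simulate_panel(sc)
            t = simulate_chain(panel, sc)
            tbl = summary_stats(t["exposure"], panel, "quantitative", sc, "e")
            ses[n] = np.median([r.se for r in tbl])
        assert ses[5000] / ses[10_000] == pytest.approx(np.sqrt(2), rel=0.1)

    def test_tables_pass_readback_bit_exactly(self, tmp_path):
        sc = small_scenario()
        study = simulate_study(sc, ref_n=500)
        for name, tbl in study.tables.items():
            path = tmp_path / f"{name}.tsv"
            write_summary_table(tbl, path)
            back = read_summary_table(path, trait_type=tbl.trait_type)
            assert back.n_dropped == 0
            assert len(back) == len(tbl)


class TestAnalyticRoute:
    def test_sampler_matches_regression_route_moments(self):
        # the fast path's truth and SEs must match what per-variant
        # regressions on simulated individuals actually produce
        sc = small_scenario(
            n_individuals=20_000,
            exposure_causal=(0, 8), exposure_effects=(0.2, 0.15),
        )
        panel = simulate_panel(sc)
        t = simulate_chain(panel, sc)
        tbl = summary_stats(t["exposure"], panel, "quantitative", sc, "e")
        truth = chain_true_betas(sc, panel)["exposure"]
        se_pred = analytic_se(panel, sc.n_individuals, "quantitative")
        betas = np.array([r.beta for r in tbl])
        ses = np.array([r.se for r in tbl])
        assert np.all(np.abs(betas - truth) < 4 * ses)
        np.testing.assert_allclose(ses, se_pred, rtol=0.05)

    def test_sampler_reproducible_and_centered(self):
        sc = small_scenario(exposure_causal=(0,), exposure_effects=(0.25,))
        panel = simulate_panel(sc)
        ld = compute_ld(panel)
        truth = chain_true_betas(sc, panel)["exposure"]
        reps = 200
        est = np.zeros(sc.n_variants)
        for i in range(reps):
            tbl = sample_summary_stats(
                sc, panel, ld, truth, "quantitative", "e",
                np.random.default_rng(i),
            )
            est += np.array([r.beta for r in tbl])
        est /= reps
        se = analytic_se(panel, sc.n_individuals, "quantitative") / np.sqrt(reps)
        assert np.all(np.abs(est - truth) < 4.5 * se)


class TestPresets:
    def test_preset_list_stable(self):
        a = scenario_presets()
        b = scenario_presets()
        assert list(a) == list(b)
        assert a["mediation_chain"] == b["mediation_chain"]

    def test_mediation_chain_encodes_published_arithmetic(self):
        sc = scenario_presets()["mediation_chain"]
        assert sc.a == pytest.approx(-0.045)
        assert sc.b == pytest.approx(-0.062)
        assert sc.c_prime + sc.a * sc.b == pytest.approx(0.097)

    def test_causal_indices_in_range(self):
        for sc in scenario_presets().values():
            for j in (*sc.exposure_causal, *sc.mediator_causal, *sc.outcome_causal):
                assert 0 <= j < sc.n_variants
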