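"""Monte Carlo loop, bootstrap, summaries and the conventional analysis."""

import numpy as np
import pandas as pd
import pytest

import pbastand as pb
from pbastand import (
    BiasPrior,
    ModelSpec,
    bootstrap_pbam,
    conventional_analysis,
    run_pbam,
    summarize_draws,
    summarize_per_bootstrap,
)

SPEC = ModelSpec()
POINT_MASS_PERFECT = BiasPrior("triangular", (1.0, 1.0, 1.0))


def priors_at_truth():
    sens = pb.fit_prior("triangular", pb.QuantileSpec(0.79, 0.72, 0.86))
    spec = pb.fit_prior("triangular", pb.QuantileSpec(0.84, 0.80, 0.89))
    return sens, spec


class TestRunPbam:
    def test_returns_exactly_n_iter_draws(self, small_study):
        data, sf, _, _ = small_study
        sens, spec = priors_at_truth()
        draws = run_pbam(data, sens, spec, sf, SPEC, n_iter=50, rng=3)
        assert len(draws) == 50
        assert all(np.isfinite(d.rr) and d.rr > 0 for d in draws)

    def test_degenerate_priors_reduce_to_conventional_mbs(self, small_study):
        data, sf, _, _ = small_study
        conv = conventional_analysis(data, SPEC, sf, n_boot=0, rng=0)
        draws = run_pbam(data, POINT_MASS_PERFECT, POINT_MASS_PERFECT,
                         sf, SPEC, n_iter=10, rng=5)
        for d in draws:
            assert d.rr == pytest.approx(conv.rr, rel=1e-12)
            assert d.rd == pytest.approx(conv.rd, rel=1e-12)

    def test_redraw_cap_reported_with_diagnostics(self, small_study):
        data, sf, _, _ = small_study
        # point mass barely above the identifiability boundary: corrected
        # cells are always negative for these counts
        bad = BiasPrior("triangular", (0.52, 0.52, 0.52))
        with pytest.raises(RuntimeError, match="attempts exhausted"):
            run_pbam(data, bad, bad, sf, SPEC, n_iter=1, rng=0, max_redraws=50)

    def test_n_iter_validation(self, small_study):
        data, sf, _, _ = small_study
        sens, spec = priors_at_truth()
        with pytest.raises(ValueError):
            run_pbam(data, sens, spec, sf, SPEC, n_iter=0, rng=0)


class TestBootstrap:
    def test_pooled_draw_count_is_product(self, small_study):
        data, sf, _, _ = small_study
        sens, spec = priors_at_truth()
        draws = bootstrap_pbam(data, sens, spec, sf, SPEC, n_boot=10, n_iter=20, rng=11)
        assert len(draws) == 200
        assert sorted(set(d.bootstrap_index for d in draws)) == list(range(1, 11))

    def test_seeded_run_is_bit_for_bit_reproducible(self, small_study):
        data, sf, _, _ = small_study
        sens, spec = priors_at_truth()
        a = bootstrap_pbam(data, sens, spec, sf, SPEC, n_boot=3, n_iter=5, rng=42)
        b = bootstrap_pbam(data, sens, spec, sf, SPEC, n_boot=3, n_iter=5, rng=42)
        assert a == b

    def test_bootstrap_interval_at_least_as_wide_as_mc_only(self, small_study):
        # random error adds dispersion: averaged over replicates the pooled
        # MC x bootstrap interval is wider than the MC-only interval
        data, sf, _, _ = small_study
        sens, spec = priors_at_truth()
        widths_boot, widths_mc = [], []
        for seed in range(20):
            boot = bootstrap_pbam(data, sens, spec, sf, SPEC,
                                  n_boot=5, n_iter=10, rng=seed)
            mc = run_pbam(data, sens, spec, sf, SPEC, n_iter=50, rng=seed + 1000)
            sb, sm = summarize_draws(boot, "rr"), summarize_draws(mc, "rr")
            widths_boot.append(np.log(sb.upper) - np.log(sb.lower))
            widths_mc.append(np.log(sm.upper) - np.log(sm.lower))
        assert np.mean(widths_boot) >= np.mean(widths_mc)

    def test_wider_priors_widen_the_interval(self, rng):
        # large confounder-free sample, so imputation randomness is small
        # and the prior's spread is the visible source of interval width
        n_case, n_ctrl = 4000, 16_000
        p_case, p_ctrl, se, sp = 0.33, 0.20, 0.79, 0.84
        true = np.r_[rng.uniform(size=n_case) < p_case,
                     rng.uniform(size=n_ctrl) < p_ctrl]
        u = rng.uniform(size=n_case + n_ctrl)
        data = pd.DataFrame({
            "outcome": np.r_[np.ones(n_case, int), np.zeros(n_ctrl, int)],
            "exposure": np.where(true, u < se, u >= sp).astype(int),
        })
        sf = pb.SamplingFractions(1.0, 0.05)
        spec = ModelSpec(confounder_terms=(), age_powers=())
        pm_sens = BiasPrior("triangular", (se, se, se))
        pm_spec = BiasPrior("triangular", (sp, sp, sp))
        wide_sens, wide_spec = priors_at_truth()
        narrow = summarize_draws(
            run_pbam(data, pm_sens, pm_spec, sf, spec, n_iter=150, rng=2), "rr")
        wide = summarize_draws(
            run_pbam(data, wide_sens, wide_spec, sf, spec, n_iter=150, rng=2), "rr")
        assert (np.log(wide.upper) - np.log(wide.lower)) > (
            np.log(narrow.upper) - np.log(narrow.lower))


class TestSummaries:
    def test_constant_draws(self, small_study):
        data, sf, _, _ = small_study
        draws = run_pbam(data, POINT_MASS_PERFECT, POINT_MASS_PERFECT,
                         sf, SPEC, n_iter=5, rng=0)
        s = summarize_draws(draws, "rr")
        assert s.point == s.lower == s.upper

    def test_median_of_small_set(self):
        frame = pd.DataFrame({"rr": [1.0, 2.0, 3.0]})
        assert summarize_draws(frame, "rr").point == 2.0

    def test_normal_sample_percentiles(self, rng):
        frame = pd.DataFrame({"rr": rng.standard_normal(100_000)})
        s = summarize_draws(frame, "rr")
        assert s.lower == pytest.approx(-1.96, abs=0.02)
        assert s.upper == pytest.approx(1.96, abs=0.02)
        assert s.point == pytest.approx(0.0, abs=0.02)

    def test_empty_draws_rejected(self):
        with pytest.raises(ValueError):
            summarize_draws([], "rr")

    def test_per_bootstrap_summary_collapses_replicates(self, small_study):
        data, sf, _, _ = small_study
        sens, spec = priors_at_truth()
        draws = bootstrap_pbam(data, sens, spec, sf, SPEC, n_boot=4, n_iter=10, rng=9)
        s = summarize_per_bootstrap(draws, "rr")
        assert s.n_draws == 4


class TestConventional:
    def test_recovers_known_conditional_odds_ratio(self):
        from test_outcome_model import simulate_logistic

        df = simulate_logistic(10_000, seed=8, b_exposure=np.log(2.0))
        sf = pb.SamplingFractions(1.0, 1.0)
        spec = ModelSpec(confounder_terms=("z",), age_powers=(1.0,))
        res = conventional_analysis(df, spec, sf, n_boot=0, rng=0)
        log_se = (np.log(res.or_upper) - np.log(res.odds_ratio)) / 1.96
        assert abs(np.log(res.odds_ratio) - np.log(2.0)) < 3 * log_se

    def test_wald_interval_is_symmetric_on_log_scale(self, small_study):
        data, sf, _, _ = small_study
        res = conventional_analysis(data, SPEC, sf, n_boot=0, rng=0)
        assert np.log(res.odds_ratio) == pytest.approx(
            0.5 * (np.log(res.or_lower) + np.log(res.or_upper)), abs=1e-9)

    def test_bootstrap_cis_are_ordered_and_finite(self, small_study):
        data, sf, _, _ = small_study
        res = conventional_analysis(data, SPEC, sf, n_boot=30, rng=4)
        assert res.n_boot == 30
        for lo, hi in (res.rr_ci, res.rd_ci, res.paf_ci):
            assert np.isfinite(lo) and np.isfinite(hi) and lo <= hi

    def test_constant_exposure_rejected(self, small_study):
        data, sf, _, _ = small_study
        bad = data.copy()
        bad["exposure"] = 1
        with pytest.raises(ValueError):
            conventional_analysis(bad, SPEC, sf, n_boot=0, rng=0)
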