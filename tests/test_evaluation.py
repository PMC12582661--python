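"""Flagging behaviour of the five threshold families on serial results."""

import math
from datetime import datetime, timedelta

import numpy as np
import pytest

from pebri.bv import BVEstimates, bv_to_peb
from pebri.errors import DataError
from pebri.evaluation import (
    MODES,
    compare_methods,
    flag_series,
    flagging_summary,
    rcv_ratio_interval,
)
from pebri.lis import ResultPair, build_pairs
from pebri.model import PEBParameters, classic_rcv_interval, prediction_halfwidth
from pebri.series import SubjectSeries
from pebri.simulate import SimulationConfig, simulate_cohort


def _series(values, sid="s1"):
    t0 = datetime(2023, 1, 1, 9, 0)
    ts = [t0 + timedelta(days=7 * i) for i in range(len(values))]
    return SubjectSeries(sid, ts, np.asarray(values, float))


@pytest.fixture
def log_params(phosphate_bv):
    return bv_to_peb(phosphate_bv)


class TestFlagSeries:
    def test_single_result_dynamic_equals_population(self, log_params):
        s = _series([3.3])
        dyn = flag_series(s, log_params, "ri_per_dynamic")
        pop = flag_series(s, log_params, "ri_pop")
        assert len(dyn) == 1 and dyn[0].n_prior == 0
        assert dyn[0].lower == pop[0].lower and dyn[0].upper == pop[0].upper

    def test_constant_series_at_population_mean_never_flags(self, log_params, phosphate_bv):
        s = _series([phosphate_bv.mu_pop_original] * 8)
        band = (0.5, 2.0)
        for mode in MODES:
            decisions = flag_series(
                s, log_params, mode, bv=phosphate_bv, ratio_band=band
            )
            assert all(d.flagged is False for d in decisions)

    def test_extreme_value_flagged_everywhere(self, log_params, phosphate_bv):
        s = _series([3.3, 3.3, 3.3, 300.0])
        for mode in MODES:
            decisions = flag_series(
                s, log_params, mode, bv=phosphate_bv, ratio_band=(0.5, 2.0)
            )
            assert decisions[-1].flagged is True

    def test_pair_mode_skips_first_result(self, log_params):
        decisions = flag_series(_series([3.1, 3.2, 3.3]), log_params, "rcv_pair")
        assert len(decisions) == 2
        assert all(d.n_prior == 1 for d in decisions)

    def test_dynamic_mode_increments_n(self, log_params):
        decisions = flag_series(_series([3.1, 3.2, 3.3, 3.4]), log_params, "ri_per_dynamic")
        assert [d.n_prior for d in decisions] == [0, 1, 2, 3]

    def test_unknown_mode_rejected(self, log_params):
        with pytest.raises(DataError):
            flag_series(_series([3.0]), log_params, "nonsense")

    def test_interval_nesting_across_modes(self, log_params):
        # from the second follow-up on: dynamic width <= pair width < population
        s = _series([3.0, 3.1, 3.2, 3.3, 3.4, 3.5])
        pop = flag_series(s, log_params, "ri_pop")
        pair = flag_series(s, log_params, "rcv_pair")
        dyn = flag_series(s, log_params, "ri_per_dynamic")
        for i in range(2, len(s)):
            w_pop = math.log(pop[i].upper / pop[i].lower)
            w_pair = math.log(pair[i - 1].upper / pair[i - 1].lower)
            w_dyn = math.log(dyn[i].upper / dyn[i].lower)
            assert w_dyn <= w_pair < w_pop

    def test_regression_toward_mean_correction(self, log_params, phosphate_bv):
        # an extreme baseline: the PEB pair interval recenters toward the
        # population mean while the classic RCV stays centered on the baseline
        baseline = float(np.exp(log_params.mu_pop + 2.5 * log_params.sigma_pop))
        dec = flag_series(_series([baseline, baseline]), log_params, "rcv_pair")[0]
        peb_center = math.sqrt(dec.lower * dec.upper)  # log-midpoint
        lo, hi = classic_rcv_interval(
            phosphate_bv.cv_i_pct, phosphate_bv.cv_a_pct, baseline
        )
        classic_center = math.sqrt(lo * hi)
        mu_orig = float(np.exp(log_params.mu_pop))
        assert classic_center == pytest.approx(baseline, rel=1e-9)
        assert mu_orig < peb_center < baseline


class TestFlaggingSummary:
    def test_calibrated_cohort_flags_about_five_percent(self, phosphate_bv):
        flagged = evaluated = 0
        for seed in range(30):
            cfg = SimulationConfig(
                mu_pop_original=phosphate_bv.mu_pop_original,
                cv_g_pct=phosphate_bv.cv_g_pct,
                cv_i_pct=phosphate_bv.cv_i_pct,
                cv_a_pct=phosphate_bv.cv_a_pct,
                seed=seed,
            )
            cohort = simulate_cohort(cfg)
            rep = flagging_summary(cohort.series, cfg.true_parameters(), "ri_per_dynamic")
            flagged += rep.n_flagged
            evaluated += rep.n_evaluated
        prop = flagged / evaluated
        se = math.sqrt(0.05 * 0.95 / evaluated)
        assert abs(prop - 0.05) < 4 * se

    def test_overwide_interval_underflags(self, phosphate_bv):
        cfg = SimulationConfig(
            mu_pop_original=phosphate_bv.mu_pop_original,
            cv_g_pct=phosphate_bv.cv_g_pct,
            cv_i_pct=phosphate_bv.cv_i_pct,
            cv_a_pct=phosphate_bv.cv_a_pct,
            seed=0,
        )
        cohort = simulate_cohort(cfg)
        true = cfg.true_parameters()
        inflated = PEBParameters(
            mu_pop=true.mu_pop, sigma_pop=10 * true.sigma_pop, b1=true.b1, scale="log"
        )
        rep = flagging_summary(cohort.series, inflated, "ri_per_dynamic")
        assert rep.proportion_pct < 0.5

    def test_report_bookkeeping(self, log_params):
        cohort = [_series([3.1, 3.2], sid="a"), _series([3.0, 300.0], sid="b")]
        rep = flagging_summary(cohort, log_params, "rcv_pair")
        assert rep.n_evaluated == 2
        assert rep.proportion_pct == pytest.approx(100 * rep.n_flagged / rep.n_evaluated)
        assert dict(rep.per_subject)["b"] == 1

    def test_empty_cohort_rejected(self, log_params):
        with pytest.raises(DataError):
            flagging_summary([], log_params, "ri_pop")


class TestRcvRatioInterval:
    def test_identity_pairs_collapse(self):
        pairs = [ResultPair("a", v, v, 48.0) for v in np.linspace(1, 2, 300)]
        assert rcv_ratio_interval(pairs) == (1.0, 1.0)

    def test_lognormal_band_matches_closed_form(self):
        rng = np.random.default_rng(0)
        sigma_diff = 0.2
        prev = np.exp(rng.normal(1.0, 0.3, 20_000))
        nxt = prev * np.exp(rng.normal(0.0, sigma_diff, 20_000))
        pairs = [ResultPair("a", float(p), float(n), 48.0) for p, n in zip(prev, nxt)]
        lo, hi = rcv_ratio_interval(pairs)
        assert lo == pytest.approx(math.exp(-1.96 * sigma_diff), rel=0.02)
        assert hi == pytest.approx(math.exp(1.96 * sigma_diff), rel=0.02)

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        prev = np.exp(rng.normal(0.0, 0.2, 500))
        nxt = prev * np.exp(rng.normal(0.0, 0.1, 500))
        p1 = [ResultPair("a", float(p), float(n), 48.0) for p, n in zip(prev, nxt)]
        p10 = [ResultPair("a", float(10 * p), float(10 * n), 48.0) for p, n in zip(prev, nxt)]
        assert rcv_ratio_interval(p1) == pytest.approx(rcv_ratio_interval(p10))

    def test_nonpositive_values_rejected(self):
        with pytest.raises(Exception):
            rcv_ratio_interval([ResultPair("a", -1.0, 2.0, 48.0)] * 300)


@pytest.fixture(scope="module")
def calibrated(phosphate_bv):
    cfg = SimulationConfig(
        mu_pop_original=phosphate_bv.mu_pop_original,
        cv_g_pct=phosphate_bv.cv_g_pct,
        cv_i_pct=phosphate_bv.cv_i_pct,
        cv_a_pct=phosphate_bv.cv_a_pct,
        n_subjects=500, seed=2,
    )
    cohort = simulate_cohort(cfg)
    # a separate calibration cohort supplies the ratio band
    calib = simulate_cohort(
        SimulationConfig(
            mu_pop_original=phosphate_bv.mu_pop_original,
            cv_g_pct=phosphate_bv.cv_g_pct,
            cv_i_pct=phosphate_bv.cv_i_pct,
            cv_a_pct=phosphate_bv.cv_a_pct,
            n_subjects=500, seed=3,
        )
    )
    calib_pairs = build_pairs(calib.series, min_gap_hours=0.0)
    return cfg, cohort, calib_pairs


class TestCompareMethods:
    def test_all_modes_near_nominal(self, calibrated, phosphate_bv):
        cfg, cohort, calib_pairs = calibrated
        reports = compare_methods(
            cohort.series, cfg.true_parameters(), phosphate_bv,
            ratio_calibration=calib_pairs,
        )
        assert set(reports) == set(MODES)
        for mode, rep in reports.items():
            se = math.sqrt(0.05 * 0.95 / rep.n_evaluated)
            # population-interval flags cluster within subjects, so allow a
            # design-effect margin on top of the binomial SE
            tol = 6 * se if mode == "ri_pop" else 4 * se
            assert abs(rep.proportion_pct / 100 - 0.05) < tol, mode

    def test_heteroscedastic_cohort_overflags_dynamic_mode(self, phosphate_bv):
        flagged = evaluated = 0
        for seed in range(10):
            cfg = SimulationConfig(
                mu_pop_original=phosphate_bv.mu_pop_original,
                cv_g_pct=phosphate_bv.cv_g_pct,
                cv_i_pct=phosphate_bv.cv_i_pct,
                cv_a_pct=phosphate_bv.cv_a_pct,
                heteroscedastic_multiplier=3.0, affected_fraction=0.5, seed=seed,
            )
            cohort = simulate_cohort(cfg)
            # evaluate with the population-level parameters, which assume a
            # common within-subject variation the affected half violates
            rep = flagging_summary(cohort.series, cfg.true_parameters(), "ri_per_dynamic")
            flagged += rep.n_flagged
            evaluated += rep.n_evaluated
        assert flagged / evaluated > 0.10

    def test_series_band_plot_renders(self, log_params, tmp_path):
        from pebri.plotting import plot_series_with_bands

        s = _series([3.2, 3.3, 3.1, 9.0, 3.2])
        ax = plot_series_with_bands(s, log_params)
        # one band, the series, and the flagged marker layer
        assert len(ax.lines) >= 2
        ax.figure.savefig(tmp_path / "band.png")

    def test_peb_pair_band_narrower_than_ln_formula_band(self, phosphate_bv):
        params = bv_to_peb(phosphate_bv)
        # at a baseline on the population mean the two bands share a center
        # and the PEB band nests strictly inside the classic one
        mu = phosphate_bv.mu_pop_original
        dec = flag_series(_series([mu, mu]), params, "rcv_pair")[0]
        lo, hi = classic_rcv_interval(phosphate_bv.cv_i_pct, phosphate_bv.cv_a_pct, mu)
        assert lo < dec.lower and dec.upper < hi
        # off-center baselines recenter the PEB band toward the mean, but its
        # width (log ratio) stays strictly smaller for any baseline
        base = mu * 1.3
        dec = flag_series(_series([base, base]), params, "rcv_pair")[0]
        lo, hi = classic_rcv_interval(phosphate_bv.cv_i_pct, phosphate_bv.cv_a_pct, base)
        assert math.log(dec.upper / dec.lower) < math.log(hi / lo)
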