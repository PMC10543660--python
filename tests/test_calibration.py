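"""Learn-Then-Test core: p-values, selection rules and the calibrator."""

import numpy as np
import pytest

from alarmcal.calibration import (
    CalibrationConfig,
    RiskSample,
    bonferroni_select,
    calibrate,
    clt_pvalue,
    empirical_unit_risk,
    event_unit_risk,
    fst_select,
)
from alarmcal.errors import InvalidInputError, UndefinedMetricError
from alarmcal.postprocess import PostprocessParams
from alarmcal.series import BinarySeries
from alarmcal.synthetic import SyntheticParams, generate_dataset


class TestUnitRisk:
    def test_no_alarms_zero_risk(self):
        pred = BinarySeries(np.zeros(50, dtype=int))
        lab = BinarySeries((np.arange(50) < 10).astype(int))
        assert empirical_unit_risk(pred, lab) == 0.0

    def test_perfect_prediction_zero_risk(self):
        lab = BinarySeries((np.arange(50) % 7 == 0).astype(int))
        assert empirical_unit_risk(lab, lab) == 0.0

    def test_direct_count_over_exposure(self):
        lab = BinarySeries(np.zeros(100, dtype=int))
        pred_values = np.zeros(100, dtype=int)
        pred_values[[3, 40, 77]] = 1
        assert empirical_unit_risk(BinarySeries(pred_values), lab) == pytest.approx(0.03)

    def test_zero_exposure_undefined(self):
        ones = BinarySeries(np.ones(10, dtype=int))
        with pytest.raises(UndefinedMetricError):
            empirical_unit_risk(ones, ones)

    def test_event_rate_counts_events_per_hour(self):
        # two alarm events over 3600 non-preictal seconds -> 2 per hour
        lab = BinarySeries(np.zeros(3600, dtype=int), sample_period=1.0)
        values = np.zeros(3600, dtype=int)
        values[10:20] = 1
        values[100:101] = 1
        assert event_unit_risk(BinarySeries(values, 1.0), lab) == pytest.approx(2.0)


class TestCltPvalue:
    def test_mean_equal_alpha_gives_half(self):
        risks = RiskSample(np.array([0.04, 0.06, 0.05, 0.03, 0.07]))
        assert clt_pvalue(risks, 0.05) == pytest.approx(0.5)

    def test_all_zero_risks_fully_significant(self):
        assert clt_pvalue(RiskSample(np.zeros(10)), 0.01) == 0.0

    def test_degenerate_above_alpha(self):
        assert clt_pvalue(RiskSample(np.full(10, 0.2)), 0.1) == 1.0

    def test_hand_computed_normal_tail(self):
        # mean 0.02, sample sd 0.05, n = 25, alpha 0.05 -> z = -3
        risks = RiskSample(np.array([0.26] + [0.01] * 24))
        assert np.mean(risks.per_unit_risks) == pytest.approx(0.02)
        assert np.std(risks.per_unit_risks, ddof=1) == pytest.approx(0.05)
        assert clt_pvalue(risks, 0.05) == pytest.approx(1.3498980316301e-3, abs=1e-6)

    def test_requires_two_units(self):
        with pytest.raises(InvalidInputError):
            RiskSample(np.array([0.1]))


class TestSelection:
    def test_bonferroni_threshold(self):
        p = {0.6: 0.001, 0.7: 0.2, 0.8: 0.004}
        assert bonferroni_select(p, 0.05) == {0.6, 0.8}

    def test_bonferroni_nothing_significant(self):
        assert bonferroni_select({0.6: 1.0, 0.7: 1.0}, 0.05) == set()

    def test_bonferroni_single_hypothesis(self):
        assert bonferroni_select({0.9: 0.04}, 0.05) == {0.9}

    def test_fst_stops_at_first_failure(self):
        ordered = {0.9: 0.001, 0.8: 0.03, 0.7: 0.2, 0.6: 0.01}
        assert fst_select(ordered, 0.05) == {0.9, 0.8}

    def test_fst_immediate_stop(self):
        assert fst_select({0.9: 0.2, 0.8: 0.001}, 0.05) == set()

    def test_fst_full_grid(self):
        ordered = {0.9: 0.01, 0.8: 0.02, 0.7: 0.03}
        assert fst_select(ordered, 0.05) == {0.9, 0.8, 0.7}

    def test_fst_exhaustive_small_grids(self, rng):
        """Agreement with an explicit prefix scan on random small grids."""
        for _ in range(200):
            m = rng.integers(1, 7)
            grid = sorted(rng.random(m), reverse=True)
            pv = {lam: float(rng.random()) for lam in grid}
            delta = float(rng.random())
            expected = set()
            for lam in grid:
                if pv[lam] <= delta:
                    expected.add(lam)
                else:
                    break
            assert fst_select(pv, delta) == expected
            assert bonferroni_select(pv, delta) == {
                lam for lam in grid if pv[lam] <= delta / m
            }


def _config(**kw):
    base = dict(
        alpha=0.05,
        delta=0.1,
        postprocess=PostprocessParams(vote_window_len=10, pool_size=10, pooling_enabled=True),
    )
    base.update(kw)
    return CalibrationConfig(**base)


class TestCalibrate:
    def test_perfect_oracle_controls_trivially(self):
        labels, preds = generate_dataset(
            SyntheticParams(flip_prob=0.0, n_series=20, series_len=500, seed=5)
        )
        result = calibrate(labels, preds, _config(alpha=0.01))
        assert result.valid_set
        assert result.mean_risks[result.chosen_lambda] == 0.0

    def test_constant_alarms_on_empty_labels_not_controllable(self):
        labels = [BinarySeries(np.zeros(200, dtype=int)) for _ in range(10)]
        preds = [BinarySeries(np.ones(200, dtype=int)) for _ in range(10)]
        result = calibrate(labels, preds, _config(alpha=0.01, lambda_grid=(0.51, 0.7, 0.9)))
        assert result.valid_set == ()
        assert result.chosen_lambda is None

    def test_degenerate_grid_point_one_silences(self):
        labels = [BinarySeries(np.zeros(200, dtype=int)) for _ in range(10)]
        preds = [BinarySeries(np.ones(200, dtype=int)) for _ in range(10)]
        result = calibrate(labels, preds, _config(alpha=0.01, lambda_grid=(0.51, 1.0)))
        assert result.valid_set == (1.0,)
        assert result.chosen_lambda == 1.0

    def test_deterministic(self):
        labels, preds = generate_dataset(SyntheticParams(n_series=30, series_len=400, seed=9))
        a = calibrate(labels, preds, _config())
        b = calibrate(labels, preds, _config())
        assert a.p_values == b.p_values
        assert a.chosen_lambda == b.chosen_lambda

    def test_bonferroni_subset_of_fst_under_monotone_pvalues(self):
        labels, preds = generate_dataset(SyntheticParams(n_series=200, series_len=1000, seed=11))
        bon = calibrate(labels, preds, _config(mhc_method="bonferroni"))
        fst = calibrate(labels, preds, _config(mhc_method="fixed_sequence"))
        pv = [bon.p_values[lam] for lam in bon.config.lambda_grid]
        assert all(a >= b for a, b in zip(pv, pv[1:]))  # non-increasing in lambda
        assert set(bon.valid_set) <= set(fst.valid_set)
        if bon.chosen_lambda is not None:
            assert fst.chosen_lambda <= bon.chosen_lambda

    def test_rcp_coverage_over_replicates(self):
        """Over 200 independent replicates (fresh calibration set each
        time, risk scored on a held-out set), the fraction whose realized
        risk at the chosen lambda exceeds alpha stays within the FWER
        budget delta plus three binomial standard errors."""
        from alarmcal.experiments import StudyConfig, run_synthetic_study

        cfg = StudyConfig(
            alphas=(0.01,),
            n_experiments=200,
            synthetic=SyntheticParams(n_series=200, series_len=300, seed=0),
            pooling_variants=(True,),
            mhc_methods=("fixed_sequence",),
            delta=0.1,
            seed=99,
        )
        cell = run_synthetic_study(cfg).cell(0.01, True, "fixed_sequence")
        fars = np.array([f for f in cell.fars if np.isfinite(f)])
        assert fars.size >= 150
        bound = cfg.delta + 3 * np.sqrt(cfg.delta * (1 - cfg.delta) / fars.size)
        assert (fars > 0.01).mean() <= bound

    def test_secondary_metric_hook(self):
        labels, preds = generate_dataset(
            SyntheticParams(flip_prob=0.0, n_series=10, series_len=300, seed=2)
        )
        result = calibrate(labels, preds, _config(), select_fn=lambda valid: valid[-1])
        assert result.chosen_lambda == result.valid_set[-1]

    def test_matrix_and_list_paths_agree(self):
        labels, preds = generate_dataset(SyntheticParams(n_series=12, series_len=240, seed=4))
        cfg = _config()
        from_lists = calibrate(labels, preds, cfg)
        from_arrays = calibrate(
            np.stack([s.values for s in labels]),
            np.stack([s.values for s in preds]),
            cfg,
        )
        assert from_lists.p_values == from_arrays.p_values
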