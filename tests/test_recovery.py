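"""Recovery pipeline orchestration and the bias regressions."""

import numpy as np
import pytest

from rtnoise import (
    NoiseSpec,
    meta_regression_wls,
    regress_noisy_on_clean,
    run_noise_sweep,
    run_recovery,
)
from rtnoise.recovery import RecoveryRecord


def _identity_records(values):
    return [
        RecoveryRecord(i, {"mu": v}, {"mu": v}, {"mu": v}, True, True)
        for i, v in enumerate(values)
    ]


class TestRegression:
    def test_identity_records_give_exact_null_result(self):
        reg = regress_noisy_on_clean(_identity_records([480.0, 500.0, 520.0, 540.0, 560.0]), "mu")
        assert reg.intercept == pytest.approx(0.0, abs=1e-10)
        assert reg.slope == pytest.approx(1.0, abs=1e-12)
        assert not reg.intercept_significant and not reg.slope_significant

    def test_matches_closed_form_normal_equations(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.1, 2.9, 4.2, 4.8, 6.1])
        records = [
            RecoveryRecord(i, {"mu": np.nan}, {"mu": xi}, {"mu": yi}, True, True)
            for i, (xi, yi) in enumerate(zip(x, y))
        ]
        reg = regress_noisy_on_clean(records, "mu")
        design = np.column_stack([np.ones_like(x), x])
        beta = np.linalg.solve(design.T @ design, design.T @ y)
        assert reg.intercept == pytest.approx(beta[0], abs=1e-10)
        assert reg.slope == pytest.approx(beta[1], abs=1e-10)

    def test_failed_fits_dropped_pairwise_and_counted(self):
        records = _identity_records([480.0, 500.0, 520.0, 540.0])
        records.append(RecoveryRecord(4, {"mu": 1.0}, {"mu": 1.0}, {"mu": 99.0}, True, False))
        reg = regress_noisy_on_clean(records, "mu")
        assert reg.n_excluded == 1 and reg.nobs == 4
        assert reg.slope == pytest.approx(1.0, abs=1e-12)

    def test_degenerate_predictor_rejected(self):
        with pytest.raises(ValueError):
            regress_noisy_on_clean(_identity_records([500.0] * 5), "mu")
        with pytest.raises(ValueError):
            regress_noisy_on_clean(_identity_records([1.0, 2.0]), "mu")


class TestWLS:
    def test_equal_weights_reduce_to_ols(self):
        levels = np.array([50.0, 100.0, 150.0, 200.0])
        est = np.array([20.0, 50.0, 85.0, 110.0])
        b0, b1 = meta_regression_wls(levels, est, np.ones(4))
        design = np.column_stack([np.ones(4), levels])
        beta = np.linalg.solve(design.T @ design, design.T @ est)
        assert (b0, b1) == pytest.approx(tuple(beta), abs=1e-10)

    def test_dominant_weight_pins_the_line(self):
        levels = [1.0, 2.0, 3.0]
        est = [10.0, 0.0, 30.0]
        b0, b1 = meta_regression_wls(levels, est, [1.0, 1e-6, 1.0])  # width 1e-6 -> weight 1e6
        assert b0 + b1 * 2.0 == pytest.approx(0.0, abs=1e-4)

    def test_matches_hand_computed_weighted_normal_equations(self):
        levels = np.array([1.0, 2.0, 3.0, 4.0])
        est = np.array([1.2, 1.9, 3.4, 3.9])
        widths = np.array([0.5, 1.0, 0.25, 2.0])
        w = 1.0 / widths
        design = np.column_stack([np.ones(4), levels])
        beta = np.linalg.solve(design.T @ (w[:, None] * design), design.T @ (w * est))
        assert meta_regression_wls(levels, est, widths) == pytest.approx(tuple(beta), abs=1e-10)

    def test_bad_inputs_rejected(self):
        with pytest.raises(ValueError):
            meta_regression_wls([1.0, 2.0], [1.0, 2.0], [1.0, 1.0])
        with pytest.raises(ValueError):
            meta_regression_wls([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], [1.0, 0.0, 1.0])


class TestRunRecovery:
    def test_identity_noise_gives_identical_fits(self):
        study = run_recovery(model="exgauss", noise=NoiseSpec(0.0, 0.0), iterations=5, seed=3)
        for rec in study.records:
            assert rec.clean == rec.noisy

    def test_reproducible_from_master_seed(self):
        s1 = run_recovery(model="exgauss", iterations=4, seed=9)
        s2 = run_recovery(model="exgauss", iterations=4, seed=9)
        for a, b in zip(s1.records, s2.records):
            assert a.clean == b.clean and a.noisy == b.noisy and a.veridical == b.veridical

    def test_record_structure_and_frame(self):
        study = run_recovery(model="exgauss", iterations=3, seed=1)
        frame = study.to_frame()
        assert len(frame) == 3
        for col in ("veridical_mu", "clean_sigma", "noisy_tau", "clean_converged"):
            assert col in frame.columns

    def test_ddm_pipeline_runs_and_respects_trial_count(self):
        study = run_recovery(model="ddm", iterations=2, seed=5)
        assert study.param_names == ("a", "v", "ter")
        assert len(study.records) == 2

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            run_recovery(model="lba", iterations=2)
        with pytest.raises(ValueError):
            run_recovery(model="exgauss", iterations=0)


class TestNoiseSweep:
    def test_shape_and_reproducibility(self):
        t1 = run_noise_sweep(upper_bounds=(50, 100), iterations_per_level=30, seed=2)
        t2 = run_noise_sweep(upper_bounds=(50, 100), iterations_per_level=30, seed=2)
        assert len(t1) == 2 * 3  # levels x parameters
        assert t1.equals(t2)

    def test_lower_bound_violation_rejected(self):
        with pytest.raises(ValueError):
            run_noise_sweep(upper_bounds=(5,), iterations_per_level=5)

    def test_mu_intercept_trend_positive(self):
        # reduced-scale sweep: the mean added delay grows with the upper
        # bound, so the mu intercept trend must be positive
        table = run_noise_sweep(upper_bounds=(50, 100, 150, 200), iterations_per_level=120, seed=6)
        mu = table[table.parameter == "mu"]
        widths = mu.intercept_ci_high - mu.intercept_ci_low
        _, slope = meta_regression_wls(mu.noise_upper, mu.intercept, widths)
        assert slope > 0
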