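"""Two-state occupancy model: solver, oracles, free energy, diffusion, batches."""

import math

import numpy as np
import pytest

from condensate_proximity.calibration import FunctionCurve, power_law_curve
from condensate_proximity.occupancy import (
    KB_KCAL_PER_MOL_K,
    DropletMeasurement,
    batch_solve,
    binding_free_energy,
    cm2_per_s_to_um2_per_s,
    diffusion_length,
    observed_over_expected,
    solve_occupancy,
    summarize_batch,
)
from condensate_proximity.synthetic_data import (
    MeasurementTruth,
    TetramerEquilibrium,
    generate_droplet_measurements,
    tetramer_signal,
)


class TestSolveOccupancy:
    @pytest.mark.parametrize("n", [1.5, 2.0, 3.0, 4.0])
    @pytest.mark.parametrize("ratio", np.geomspace(1.1, 50.0, 8).tolist())
    def test_power_law_closed_form_oracle(self, n, ratio):
        # independent oracle: for I = a*c^n, I(c/f)*f = I(c)*f^(1-n), so
        # enhancement = 1/f = ratio^(1/(n-1)) in closed form
        curve = power_law_curve(3.0, n, c_min=0.0, c_max=np.inf)
        c_actual = 4.0
        i_expected = 3.0 * c_actual**n
        m = DropletMeasurement(c_actual=c_actual, i_observed=ratio * i_expected)
        sol = solve_occupancy(m, curve)
        assert sol.status == "ok"
        assert sol.enhancement == pytest.approx(ratio ** (1.0 / (n - 1.0)), rel=1e-6)
        # model closures
        assert sol.c_occupy * sol.f_occupy == pytest.approx(c_actual, rel=1e-8)
        assert float(curve(sol.c_occupy)) * sol.f_occupy == pytest.approx(
            m.i_observed, rel=1e-6
        )

    def test_quadratic_worked_case(self):
        curve = power_law_curve(1.0, 2.0)
        sol = solve_occupancy(DropletMeasurement(c_actual=4.0, i_observed=32.0), curve)
        assert sol.f_occupy == pytest.approx(0.5, rel=1e-9)
        assert sol.c_occupy == pytest.approx(8.0, rel=1e-9)
        assert sol.enhancement == pytest.approx(2.0, rel=1e-9)

    def test_quartic_worked_case(self):
        curve = power_law_curve(1.0, 4.0)
        sol = solve_occupancy(DropletMeasurement(c_actual=2.0, i_observed=128.0), curve)
        assert sol.enhancement == pytest.approx(8.0 ** (1.0 / 3.0), rel=1e-9)
        assert sol.f_occupy == pytest.approx(0.5, rel=1e-9)

    def test_observed_at_expected_means_no_enhancement(self, exact_curve):
        c = 5.0
        i_exp = float(exact_curve(c))
        sol = solve_occupancy(DropletMeasurement(c_actual=c, i_observed=i_exp), exact_curve)
        assert sol.status == "no_enhancement"
        assert sol.f_occupy == 1.0
        assert sol.enhancement == 1.0
        assert sol.epsilon_kcal_mol == 0.0

    def test_linear_reporter_is_non_identifiable(self):
        curve = FunctionCurve(lambda c: 10.0 * c, c_min=0.0, c_max=50.0)
        sol = solve_occupancy(DropletMeasurement(c_actual=4.0, i_observed=60.0), curve)
        assert sol.status == "non_identifiable"
        assert sol.f_occupy is None

    def test_out_of_range_when_c_occupy_exceeds_limit(self, anchored_curve):
        # the worked strong-client droplet: implied effective concentration
        # ~93 uM exceeds the 50 uM calibration limit, so no factor is reported
        m = DropletMeasurement(c_actual=4.87, i_observed=15582.0)
        sol = solve_occupancy(m, anchored_curve)
        assert sol.status == "out_of_range"
        assert sol.f_occupy is None and sol.enhancement is None

    def test_c_actual_outside_curve_range_rejected(self, exact_curve):
        with pytest.raises(ValueError, match="outside the calibration range"):
            solve_occupancy(DropletMeasurement(c_actual=0.5, i_observed=10.0), exact_curve)

    def test_enhancement_monotone_in_observed_signal(self, exact_curve):
        c = 2.5
        i_exp = float(exact_curve(c))
        enhancements = []
        for ratio in [1.2, 2.0, 3.5, 5.0]:
            sol = solve_occupancy(
                DropletMeasurement(c_actual=c, i_observed=ratio * i_exp), exact_curve
            )
            assert sol.status == "ok"
            enhancements.append(sol.enhancement)
        assert np.all(np.diff(enhancements) > 0)


class TestObservedOverExpected:
    def test_worked_example_nineteen_fold(self, anchored_curve):
        m = DropletMeasurement(c_actual=4.87, i_observed=15582.0)
        assert observed_over_expected(m, anchored_curve) == pytest.approx(19.05, abs=0.01)

    def test_equal_signals_give_unity(self, exact_curve):
        i_exp = float(exact_curve(3.0))
        m = DropletMeasurement(c_actual=3.0, i_observed=i_exp)
        assert observed_over_expected(m, exact_curve) == pytest.approx(1.0)

    def test_equals_enhancement_under_quadratic_reporter(self):
        curve = power_law_curve(5.0, 2.0)
        m = DropletMeasurement(c_actual=3.0, i_observed=4.0 * 5.0 * 9.0)
        sol = solve_occupancy(m, curve)
        assert observed_over_expected(m, curve) == pytest.approx(sol.enhancement, rel=1e-9)

    def test_linear_reporter_blindness(self):
        # with an exactly linear reporter the droplet signal carries no
        # localization information: I(c/f)*f = I(c) for every f
        curve = FunctionCurve(lambda c: 7.0 * c, c_min=0.0)
        for f_true in [0.05, 0.25, 1.0]:
            c_actual = 2.0
            i_observed = 7.0 * (c_actual / f_true) * f_true
            m = DropletMeasurement(c_actual=c_actual, i_observed=i_observed)
            assert observed_over_expected(m, curve) == pytest.approx(1.0, rel=1e-12)

    def test_generator_with_nearly_linear_reporter_is_blind(self):
        # saturated equilibrium (all tetramer) => signal ~ brightness*c: the
        # generated droplet signal is independent of f_true to within ~1%
        eq = TetramerEquilibrium(k_tet=1e9, brightness=1.0)
        ratios = []
        for f_true in [0.1, 0.5, 1.0]:
            truth = MeasurementTruth(
                c_added=1.0, enrichment_true=5.0, f_occupy_true=f_true
            )
            meas = generate_droplet_measurements(truth, eq, n_droplets=1)
            plain = float(tetramer_signal(eq, meas["c_actual_uM_true"].iloc[0]))
            ratios.append(meas["i_observed_au"].iloc[0] / plain)
        np.testing.assert_allclose(ratios, 1.0, rtol=0.01)


class TestBindingFreeEnergy:
    def test_unity_occupancy_is_zero_energy(self):
        assert binding_free_energy(1.0) == 0.0

    def test_sixteen_fold_magnitude(self):
        eps = binding_free_energy(1.0 / 16.0, temperature_K=300.0)
        assert eps < 0
        assert abs(eps) == pytest.approx(1.65, abs=0.01)

    def test_four_and_a_half_fold_magnitude(self):
        eps = binding_free_energy(1.0 / 4.5, temperature_K=300.0)
        assert abs(eps) == pytest.approx(0.896, abs=0.005)

    def test_magnitude_is_kbt_log_enhancement(self):
        kbt = KB_KCAL_PER_MOL_K * 300.0
        for enh in [1.5, 4.5, 16.0, 100.0]:
            assert abs(binding_free_energy(1.0 / enh, 300.0)) == pytest.approx(
                kbt * math.log(enh), rel=1e-12
            )

    def test_strictly_decreasing_in_enhancement(self):
        vals = [binding_free_energy(1.0 / enh) for enh in [1.0, 2.0, 8.0, 32.0]]
        assert np.all(np.diff(vals) < 0)

    def test_domain_errors(self):
        for bad in [0.0, -0.1, 1.5]:
            with pytest.raises(ValueError):
                binding_free_energy(bad)


class TestDiffusionLength:
    def test_fast_protein_reaches_sub_mm_in_a_minute(self):
        d = cm2_per_s_to_um2_per_s(1e-6)
        assert d == pytest.approx(100.0)
        est = diffusion_length(d, 60.0)
        assert est.mean_displacement_um == pytest.approx(189.7, abs=0.05)
        assert round(est.mean_displacement_um, -1) == 190

    def test_zero_diffusion(self):
        assert diffusion_length(0.0, 60.0).mean_displacement_um == 0.0

    def test_unit_case(self):
        assert diffusion_length(1.0, 1.0 / 6.0).mean_displacement_um == pytest.approx(1.0)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            diffusion_length(-1.0, 5.0)


class TestBatchSolve:
    def test_noiseless_generator_round_trip(self, eq, exact_curve):
        truth = MeasurementTruth(
            c_added=0.5, enrichment_true=5.0, f_occupy_true=1 / 16, noise_cv=0.0
        )
        meas = generate_droplet_measurements(truth, eq, n_droplets=5)
        sols = batch_solve(meas, exact_curve)
        assert (sols["status"] == "ok").all()
        np.testing.assert_allclose(sols["enhancement"], 16.0, rtol=1e-6)

    def test_noiseless_recovery_through_interpolated_curve(self, eq, interp_curve):
        # solving against the interpolant (not the true surrogate) stays
        # within the < 2% bias expected from < 1% curve error
        truth = MeasurementTruth(
            c_added=0.5, enrichment_true=5.0, f_occupy_true=1 / 16, noise_cv=0.0
        )
        meas = generate_droplet_measurements(truth, eq, n_droplets=5)
        sols = batch_solve(meas, interp_curve)
        assert (sols["status"] == "ok").all()
        np.testing.assert_allclose(sols["enhancement"], 16.0, rtol=0.02)

    def test_noisy_recovery_within_ten_percent(self, eq, exact_curve):
        truth = MeasurementTruth(
            c_added=0.5, enrichment_true=5.0, f_occupy_true=0.1, noise_cv=0.05, seed=0
        )
        meas = generate_droplet_measurements(truth, eq, n_droplets=33)
        sols = batch_solve(meas, exact_curve)
        summary = summarize_batch(sols)
        assert summary["mean_enhancement"] == pytest.approx(10.0, rel=0.10)

    def test_out_of_range_rows_counted_not_solved(self, eq, exact_curve):
        # f small enough that c_occupy would exceed the 50 uM limit
        truth = MeasurementTruth(
            c_added=1.0, enrichment_true=5.0, f_occupy_true=1 / 16, noise_cv=0.0
        )
        meas = generate_droplet_measurements(truth, eq, n_droplets=4)
        sols = batch_solve(meas, exact_curve)
        assert (sols["status"] == "out_of_range").all()
        summary = summarize_batch(sols)
        assert summary["status_counts"]["out_of_range"] == 4
        assert summary["n_ok"] == 0

    def test_mixed_statuses_do_not_abort_batch(self, eq, exact_curve):
        i_exp = float(exact_curve(2.5))
        ms = [
            DropletMeasurement(2.5, 3.0 * i_exp, droplet_id="ok"),
            DropletMeasurement(2.5, 0.5 * i_exp, droplet_id="none"),
            DropletMeasurement(2.5, 1e9, droplet_id="oor"),
        ]
        sols = batch_solve(ms, exact_curve)
        assert list(sols["status"]) == ["ok", "no_enhancement", "out_of_range"]
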