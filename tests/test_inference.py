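"""Calibration: bin averaging, profiled-S fitting, sweeps, peak placement."""

import numpy as np
import pytest

import nscglioma as ng
from nscglioma.inference import is_feasible
from tests.conftest import STUDY, STUDY_K


def fixed_kwargs(coarse_grid):
    return dict(u=STUDY["u"], N0=STUDY["N0"], grid=coarse_grid)


class TestBinAverage:
    def test_constant_curve(self, coarse_grid, default_table, fitted):
        curves = fitted.curves
        flat = ng.ModelCurves(
            t=curves.t, r=curves.r, D=curves.D, lam=curves.lam, N=curves.N,
            P1=curves.P1, P=curves.P, prevalence=curves.prevalence,
            incidence=np.full_like(curves.t, 4.2),
            grid=curves.grid, schedule=curves.schedule, pop=curves.pop, mut=curves.mut,
        )
        assert np.allclose(ng.bin_average_incidence(flat, default_table), 4.2)

    def test_linear_ramp_bin_mean(self, coarse_grid, fitted):
        curves = fitted.curves
        ramp = ng.ModelCurves(
            t=curves.t, r=curves.r, D=curves.D, lam=curves.lam, N=curves.N,
            P1=curves.P1, P=curves.P, prevalence=curves.prevalence,
            incidence=curves.t.copy(),
            grid=curves.grid, schedule=curves.schedule, pop=curves.pop, mut=curves.mut,
        )
        table = ng.IncidenceTable(age_lo=[0.0], age_hi=[10.0], rate=[0.0])
        assert ng.bin_average_incidence(ramp, table) == pytest.approx([5.0])

    def test_bin_outside_grid_rejected(self, fitted):
        table = ng.IncidenceTable(age_lo=[90.0], age_hi=[150.0], rate=[1.0])
        with pytest.raises(ValueError, match="beyond"):
            ng.bin_average_incidence(fitted.curves, table)


class TestFit:
    def test_noiseless_recovery_at_default_conditions(self, fitted):
        assert fitted.k_hat == pytest.approx(STUDY_K, rel=0.05)
        assert fitted.S_hat == pytest.approx(STUDY["S"], rel=0.10)
        assert fitted.feasible

    def test_noiseless_recovery_fast_decay(self, coarse_grid):
        # faster decay: validity limit ~ n_min/k = 71 y, so bin to 70
        edges = tuple(float(a) for a in range(0, 75, 5))
        table = ng.generate_synthetic_table(
            ng.SyntheticTableSpec(k=0.07, S=30.0, bin_edges=edges, open_ended=False)
        )
        res = ng.fit(table, 5, **fixed_kwargs(coarse_grid))
        assert res.k_hat == pytest.approx(0.07, rel=0.05)
        assert res.S_hat == pytest.approx(30.0, rel=0.10)

    def test_noisy_recovery_median_error(self, coarse_grid):
        errs = []
        for seed in range(20):
            table = ng.generate_synthetic_table(
                ng.SyntheticTableSpec(
                    noise="multiplicative-lognormal", sigma=0.1, seed=seed
                )
            )
            res = ng.fit(table, 5, **fixed_kwargs(coarse_grid))
            errs.append(abs(res.k_hat - STUDY_K) / STUDY_K)
        assert np.median(errs) < 0.10

    def test_objective_minimal_at_generating_parameters(self, coarse_grid, default_table, fitted):
        """Noise-free table: the fitted optimum beats every +/-20%
        perturbation of (k, S)."""

        def objective_at(k, S):
            mut = ng.MutationParams(u=STUDY["u"], n_min=5, S=S)
            curves = ng.run_model(
                coarse_grid, ng.DivisionSchedule(),
                ng.PopulationParams(N0=STUDY["N0"], k=k), mut,
            )
            m = ng.bin_average_incidence(curves, default_table)
            return float(np.sum(fitted.weights * (m - default_table.rate) ** 2))

        base = fitted.objective
        for fk in (0.8, 1.2):
            for fS in (0.8, 1.2):
                if fk == fS == 1.0:
                    continue
                assert base <= objective_at(fitted.k_hat * fk, min(fitted.S_hat * fS, 120.0)) + 1e-12

    def test_profiled_S_closed_form_single_bin(self, coarse_grid):
        # one bin: S_hat scales the unit-S model rate exactly onto the obs
        table = ng.IncidenceTable(age_lo=[60.0], age_hi=[70.0], rate=[5.0])
        res = ng.fit(table, 5, **fixed_kwargs(coarse_grid))
        assert res.model_rates[0] == pytest.approx(5.0, rel=1e-3)
        mut1 = ng.MutationParams(u=STUDY["u"], n_min=5, S=1.0)
        curves1 = ng.run_model(
            coarse_grid, ng.DivisionSchedule(),
            ng.PopulationParams(N0=STUDY["N0"], k=res.k_hat), mut1,
        )
        m1 = ng.bin_average_incidence(curves1, table)[0]
        assert res.S_hat == pytest.approx(5.0 / m1, rel=1e-3)

    def test_refit_of_fitted_curve_reaches_same_minimum(self, coarse_grid, fitted, default_table):
        refit = ng.fit(default_table, 5, **fixed_kwargs(coarse_grid))
        assert refit.objective == pytest.approx(fitted.objective, abs=1e-8)
        assert refit.k_hat == pytest.approx(fitted.k_hat, rel=1e-4)

    def test_all_zero_observations_rejected(self, coarse_grid):
        table = ng.IncidenceTable(age_lo=[0.0, 10.0], age_hi=[10.0, 20.0], rate=[0.0, 0.0])
        with pytest.raises(ValueError, match="zero"):
            ng.fit(table, 5, **fixed_kwargs(coarse_grid))

    def test_out_of_range_n_min_rejected(self, coarse_grid, default_table):
        with pytest.raises(ValueError, match="n_min"):
            ng.fit(default_table, 0, **fixed_kwargs(coarse_grid))
        with pytest.raises(ValueError, match="n_min"):
            ng.fit(default_table, 30, **fixed_kwargs(coarse_grid))

    def test_fit_logs_identifiability_note(self, coarse_grid, default_table, caplog):
        import logging

        with caplog.at_level(logging.INFO, logger="nscglioma.inference"):
            ng.fit(default_table, 5, **fixed_kwargs(coarse_grid))
        assert any("N0" in rec.message for rec in caplog.records)


class TestSweep:
    def test_best_objective_at_generating_n_min(self, coarse_grid, default_table):
        results = ng.nmin_sweep(default_table, range(2, 8), **fixed_kwargs(coarse_grid))
        assert results[0].n_min == 5
        by_n = {r.n_min: r.objective for r in results}
        assert by_n[2] > by_n[5]

    def test_empty_range_is_vacuous(self, coarse_grid, default_table):
        assert ng.nmin_sweep(default_table, range(5, 5), **fixed_kwargs(coarse_grid)) == []

    def test_report_is_objective_ordered(self, coarse_grid, default_table):
        results = ng.nmin_sweep(default_table, [2, 5], **fixed_kwargs(coarse_grid))
        report = ng.sweep_report(results)
        assert list(report.columns) == [
            "n_min", "k_hat", "S_hat", "objective", "peak_age_hat", "feasible"
        ]
        assert report["objective"].is_monotonic_increasing


def test_feasibility_monotone_in_tolerance():
    for obj in (0.01, 0.3, 2.0):
        flags = [is_feasible(obj, 80.0, n_bins=10, tol=tol) for tol in (1e-4, 1e-2, 1.0)]
        # once feasible, stays feasible as the tolerance grows
        assert flags == sorted(flags)


def test_peak_placement_by_decay_search(coarse_grid):
    k_hat, peak, curves = ng.calibrate_peak_age(
        80.0, n_min=5, S=STUDY["S"], u=STUDY["u"], N0=STUDY["N0"], grid=coarse_grid
    )
    assert abs(peak - 80.0) <= 1.0
    assert 1e-4 <= k_hat <= 1.0
    assert curves.incidence.max() > 0


def test_peak_target_outside_range_rejected(coarse_grid):
    with pytest.raises(ValueError, match="attainable"):
        ng.calibrate_peak_age(
            5.0, n_min=5, S=STUDY["S"], u=STUDY["u"], N0=STUDY["N0"],
            grid=coarse_grid, k_bounds=(1e-4, 0.01),
        )
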