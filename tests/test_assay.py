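"""Saturation curves, reciprocal transforms, line-family classification,
Hill fits, and the assay CSV dialect."""

import io

import numpy as np
import pytest

from grxkinetics import (
    AssayDataset,
    InsufficientDataError,
    KineticParameters,
    build_wildtype_core,
    classify_line_family,
    fit_hill,
    read_assay_csv,
    reciprocal_coefficients,
    saturation_curve,
    to_reciprocal,
    v_wt,
    write_assay_csv,
)
from grxkinetics.assay import fit_line, quadratic_term


def _analytic_wt_dataset(pssg_grid, gsh, params=None):
    p = params or KineticParameters(k1=0.1, k2_wt=1e-5, grx_tot=1.0)
    points = [(x, v_wt(p.k1, p.k2_wt, p.grx_tot, x, gsh)) for x in pssg_grid]
    return AssayDataset(points=points, varied_species="PSSG", fixed={"GSH": gsh})


class TestToReciprocal:
    def test_point_transform(self):
        ds = AssayDataset(
            points=[(2.0, 4.0), (1.0, 2.0), (4.0, 8.0)],
            varied_species="PSSG",
        )
        rec = to_reciprocal(ds)
        assert rec.n_excluded == 0
        assert rec.inv_x[0] == 0.5
        assert rec.inv_rate[0] == 0.25

    def test_zero_points_excluded_and_counted(self):
        ds = AssayDataset(
            points=[(0.0, 0.0), (1.0, 2.0), (2.0, 3.0), (4.0, 5.0)],
            varied_species="PSSG",
        )
        rec = to_reciprocal(ds)
        assert rec.n_excluded == 1
        assert len(rec.inv_x) == 3

    def test_fewer_than_three_usable_raises(self):
        ds = AssayDataset(points=[(0.0, 0.0), (1.0, 1.0), (2.0, 2.0)],
                          varied_species="PSSG")
        with pytest.raises(InsufficientDataError):
            to_reciprocal(ds)


class TestReciprocalLineOnAnalyticData:
    def test_ols_recovers_closed_form_coefficients(self):
        p = KineticParameters(k1=0.1, k2_wt=1e-5, grx_tot=1.0)
        grid = np.logspace(-1, np.log10(20.0), 15)
        ds = _analytic_wt_dataset(grid, gsh=1000.0, params=p)
        rec = to_reciprocal(ds)
        slope, intercept, r2 = fit_line(rec.inv_x, rec.inv_rate)
        expected = reciprocal_coefficients(p.k1, p.k2_wt, p.grx_tot, 1000.0)
        assert slope == pytest.approx(expected.slope_vs_invPSSG, rel=1e-8)
        assert intercept == pytest.approx(expected.intercept, rel=1e-8)
        assert r2 > 0.9999

    def test_intercepts_scale_as_inverse_square_of_gsh(self):
        p = KineticParameters(k1=0.1, k2_wt=1e-5, grx_tot=1.0)
        grid = np.logspace(-1, np.log10(20.0), 15)
        gsh_values = np.array([150.0, 250.0, 500.0, 1000.0])
        intercepts = []
        for gsh in gsh_values:
            rec = to_reciprocal(_analytic_wt_dataset(grid, gsh, p))
            _, intercept, _ = fit_line(rec.inv_x, rec.inv_rate)
            intercepts.append(intercept)
        slope, _, _ = fit_line(np.log(gsh_values), np.log(intercepts))
        assert slope == pytest.approx(-2.0, abs=0.01)


class TestSaturationCurve:
    def test_matches_analytic_pointwise(self):
        p = KineticParameters(k1=0.1, k2_wt=1e-5, grx_tot=1.0)
        model = build_wildtype_core(p, 5.0, 500.0)
        grid = np.logspace(0, 3, 10)
        ds = saturation_curve(model, "GSH", grid)
        for x, rate in zip(ds.x, ds.rates):
            assert rate == pytest.approx(v_wt(p.k1, p.k2_wt, p.grx_tot, 5.0, x), rel=1e-6)

    def test_gsh_response_is_sigmoidal(self):
        # positive curvature below the half-saturation point, negative above
        p = KineticParameters(k1=0.1, k2_wt=1e-5, grx_tot=1.0)
        model = build_wildtype_core(p, 5.0, 500.0)
        k_half = np.sqrt(p.k1 * 5.0 / p.k2_wt)
        grid = np.linspace(k_half / 20.0, 3.0 * k_half, 60)
        ds = saturation_curve(model, "GSH", grid)
        rates = ds.rates
        assert np.all(np.diff(rates) > 0)
        second = np.diff(rates, 2)
        assert second[0] > 0 and second[-1] < 0

    def test_records_fixed_concentrations(self):
        p = KineticParameters()
        model = build_wildtype_core(p, 5.0, 500.0)
        ds = saturation_curve(model, "GSH", [100.0, 200.0, 400.0])
        assert ds.fixed["PSSG"] == 5.0
        assert "GSH" not in ds.fixed


class TestClassifyLineFamily:
    def test_two_identical_datasets_are_parallel_with_zero_spread(self):
        grid = np.logspace(-1, 1, 8)
        a = _analytic_wt_dataset(grid, gsh=500.0)
        b = AssayDataset(points=list(a.points), varied_species="PSSG",
                         fixed={"GSH": 600.0})
        result = classify_line_family([a, b])
        assert result.classification == "parallel"
        assert result.slope_spread == pytest.approx(0.0, abs=1e-12)

    def test_invariant_to_dataset_order_and_rate_rescaling(self):
        grid = np.logspace(-1, np.log10(20.0), 12)
        family = [_analytic_wt_dataset(grid, g) for g in (150.0, 250.0, 1000.0)]
        forward = classify_line_family(family)
        backward = classify_line_family(family[::-1])
        scaled = classify_line_family(
            [
                AssayDataset(
                    points=[(x, 60.0 * r) for x, r in ds.points],
                    varied_species="PSSG", fixed=dict(ds.fixed),
                )
                for ds in family
            ]
        )
        assert forward.classification == backward.classification == scaled.classification
        assert forward.slope_spread == pytest.approx(backward.slope_spread)
        assert forward.slope_spread == pytest.approx(scaled.slope_spread, rel=1e-9)

    def test_missing_gsh_metadata_rejected(self):
        grid = np.logspace(-1, 1, 8)
        ds = _analytic_wt_dataset(grid, gsh=500.0)
        bare = AssayDataset(points=list(ds.points), varied_species="PSSG")
        with pytest.raises(ValueError, match="GSH"):
            classify_line_family([ds, bare])


class TestFitHill:
    def test_exact_hill_data_recovered(self):
        x = np.logspace(-1, 3, 20)
        y = 1.0 * (x / 10.0) ** 2 / (1.0 + (x / 10.0) ** 2)
        ds = AssayDataset(points=list(zip(x, y)), varied_species="GSH")
        fit = fit_hill(ds)
        assert fit.converged
        assert fit.V == pytest.approx(1.0, rel=1e-6)
        assert fit.K_half == pytest.approx(10.0, rel=1e-6)
        assert fit.n == pytest.approx(2.0, rel=1e-6)

    def test_fixed_exponent_is_held(self):
        x = np.logspace(-1, 3, 20)
        y = 1.0 * (x / 10.0) ** 2 / (1.0 + (x / 10.0) ** 2)
        ds = AssayDataset(points=list(zip(x, y)), varied_species="GSH")
        fit = fit_hill(ds, fix_n=1.0)
        assert fit.n == 1.0

    def test_too_few_points_rejected(self):
        ds = AssayDataset(points=[(1.0, 0.1), (2.0, 0.2), (3.0, 0.3), (4.0, 0.35)],
                          varied_species="GSH")
        with pytest.raises(InsufficientDataError):
            fit_hill(ds)


class TestQuadraticTerm:
    def test_detects_curvature(self):
        x = np.linspace(0.1, 2.0, 20)
        coeff, p = quadratic_term(x, 1.0 + 2.0 * x + 3.0 * x ** 2)
        assert coeff == pytest.approx(3.0, rel=1e-8)
        assert p < 1e-10

    def test_linear_data_not_significant(self, rng):
        x = np.linspace(0.1, 2.0, 30)
        y = 1.0 + 2.0 * x + rng.normal(0, 0.05, size=x.size)
        _, p = quadratic_term(x, y)
        assert p > 0.01


class TestCsvDialect:
    def test_round_trip_exact(self):
        ds = AssayDataset(
            points=[(0.1, 1.234567890123456e-3, 5e-5), (2.0, 0.25, 0.01)],
            varied_species="HED",
            fixed={"GSH": 998.0, "NADPH": 250.0},
            meta="synthetic fixture\nsecond line",
        )
        buf = io.StringIO()
        write_assay_csv(ds, buf)
        back = read_assay_csv(io.StringIO(buf.getvalue()))
        assert back.points == ds.points
        assert back.varied_species == "HED"
        assert back.fixed == ds.fixed
        assert back.meta == ds.meta

    def test_missing_varied_species_header_rejected(self):
        with pytest.raises(ValueError, match="varied_species"):
            read_assay_csv(io.StringIO("x_uM,rate_uM_per_s\n1.0,2.0\n"))
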