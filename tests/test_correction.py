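"""Thin/thick dispatch, bilinear interpolation, leave-one-out validation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from brachyhet.correction import (
    ThinLayerModel,
    apply_correction,
    fit_thin_layer_model,
    interpolate_delta,
    loo_predict,
    thin_layer_factor,
    validate_loo,
)
from brachyhet.dose_tables import DoseDifferenceTable
from brachyhet.fixtures import generate_fixture_table


class TestThinLayerFactor:
    def test_constant_term_at_origin(self):
        model = ThinLayerModel(validity_range=(0.0, 10.0))
        assert thin_layer_factor(0.0, model) == pytest.approx(0.956)

    def test_closed_form_at_10cm(self):
        assert thin_layer_factor(10.0) == pytest.approx(
            -0.00003 * 1000 + 0.006 * 10 + 0.956)
        assert thin_layer_factor(10.0) == pytest.approx(0.986)

    def test_closed_form_at_5cm(self):
        assert thin_layer_factor(5.0) == pytest.approx(0.98225)

    def test_no_extrapolation(self):
        with pytest.raises(ValueError, match="range"):
            thin_layer_factor(10.5)
        with pytest.raises(ValueError, match="range"):
            thin_layer_factor(0.05)

    @given(st.floats(0.1, 10.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_positive_over_validity_range(self, x):
        assert thin_layer_factor(x) > 0


def _manual_bilinear(table, d, t):
    """Independent 4-corner bilinear formula (test oracle)."""
    i = np.searchsorted(table.distances, d) - 1
    i = np.clip(i, 0, table.distances.size - 2)
    j = np.searchsorted(table.thicknesses, t) - 1
    j = np.clip(j, 0, table.thicknesses.size - 2)
    d0, d1 = table.distances[i], table.distances[i + 1]
    t0, t1 = table.thicknesses[j], table.thicknesses[j + 1]
    wd = (d - d0) / (d1 - d0)
    wt = (t - t0) / (t1 - t0)
    v = table.values
    return ((1 - wd) * (1 - wt) * v[i, j] + (1 - wd) * wt * v[i, j + 1]
            + wd * (1 - wt) * v[i + 1, j] + wd * wt * v[i + 1, j + 1])


@pytest.fixture(scope="module")
def table():
    return generate_fixture_table("cubic", seed=2)


@pytest.fixture(scope="module")
def null_table():
    d = np.arange(1.0, 9.01, 1.0)
    t = np.arange(0.4, 1.81, 0.2)
    return DoseDifferenceTable(d, t, np.zeros((d.size, t.size)),
                               np.zeros((d.size, t.size)))


class TestInterpolateDelta:

    def test_identity_at_nodes(self, table):
        for i in (0, 2, len(table.distances) - 1):
            for j in (0, 1, len(table.thicknesses) - 1):
                got = interpolate_delta(table, table.distances[i],
                                        table.thicknesses[j])
                assert got == pytest.approx(table.values[i, j], rel=1e-12)

    def test_cell_center_is_mean_of_corners(self, table):
        d = 0.5 * (table.distances[1] + table.distances[2])
        t = 0.5 * (table.thicknesses[0] + table.thicknesses[1])
        corners = table.values[1:3, 0:2]
        assert interpolate_delta(table, d, t) == pytest.approx(
            corners.mean(), rel=1e-12)

    @given(st.floats(1.0, 9.0), st.floats(0.4, 1.8))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_matches_manual_bilinear_everywhere(self, d, t):
        table = generate_fixture_table("cubic", seed=2)
        assert interpolate_delta(table, d, t) == pytest.approx(
            _manual_bilinear(table, d, t), rel=1e-10, abs=1e-10)

    def test_bounded_by_bracketing_nodes(self, table):
        rng = np.random.default_rng(5)
        for _ in range(100):
            d = rng.uniform(1.0, 9.0)
            t = rng.uniform(0.4, 1.8)
            i = np.searchsorted(table.distances, d) - 1
            j = np.searchsorted(table.thicknesses, t) - 1
            corners = table.values[i:i + 2, j:j + 2]
            got = interpolate_delta(table, d, t)
            assert corners.min() - 1e-9 <= got <= corners.max() + 1e-9

    def test_monotone_between_monotone_nodes(self):
        table = generate_fixture_table("bilinear", seed=0)
        ds = np.linspace(table.distances[0], table.distances[-1], 40)
        vals = [interpolate_delta(table, d, 1.0) for d in ds]
        assert np.all(np.diff(vals) > 0)  # bilinear surface increases in d

    def test_degenerate_grid_rejected(self):
        t = DoseDifferenceTable(np.array([1.0, 2.0]), np.array([0.5]),
                                np.zeros((2, 1)), np.zeros((2, 1)))
        with pytest.raises(ValueError, match="degenerate"):
            interpolate_delta(t, 1.5, 0.5)


class TestApplyCorrection:

    def test_null_table_leaves_dose_unchanged(self, null_table):
        res = apply_correction(2.5, 5.0, 1.0, null_table)
        assert res.corrected_dose == pytest.approx(2.5)
        assert res.path == "thick"

    def test_thin_path_uses_polynomial(self):
        res = apply_correction(1.0, 5.0, 0.2)
        assert res.path == "thin"
        assert res.corrected_dose == pytest.approx(-0.00375 + 0.03 + 0.956)

    def test_threshold_routes_thick(self, null_table):
        res = apply_correction(1.0, 5.0, 0.4, null_table)
        assert res.path == "thick"

    def test_homogeneous_degree_one_in_dose(self, null_table):
        table = generate_fixture_table("paper_like", seed=1)
        r1 = apply_correction(1.0, 4.2, 1.1, table)
        r2 = apply_correction(2.0, 4.2, 1.1, table)
        assert r2.corrected_dose == pytest.approx(2 * r1.corrected_dose)

    def test_clamping_flagged_and_warned(self):
        table = generate_fixture_table("paper_like", seed=1)
        with pytest.warns(UserWarning, match="clamped"):
            res = apply_correction(1.0, 20.0, 1.0, table)
        assert res.clamped
        edge = apply_correction(1.0, table.distances[-1], 1.0, table)
        assert res.applied_delta_pct == pytest.approx(edge.applied_delta_pct)

    def test_provenance_populated(self, null_table):
        thick = apply_correction(1.0, 5.0, 1.0, null_table)
        assert len(thick.provenance["bracketing_nodes"]) == 4
        thin = apply_correction(1.0, 5.0, 0.2)
        assert "coefficients" in thin.provenance

    def test_invalid_inputs_rejected(self, null_table):
        with pytest.raises(ValueError):
            apply_correction(0.0, 5.0, 1.0, null_table)
        with pytest.raises(ValueError):
            apply_correction(1.0, -5.0, 1.0, null_table)
        with pytest.raises(ValueError, match="table"):
            apply_correction(1.0, 5.0, 1.0, None)

    def test_thin_thick_seam_is_reported_not_hidden(self):
        # the dispatch is discontinuous at t = 0.4 by construction; both
        # paths must be inspectable around the seam
        table = generate_fixture_table("paper_like", seed=1)
        below = apply_correction(1.0, 5.0, 0.399, table)
        at = apply_correction(1.0, 5.0, 0.4, table)
        assert below.path == "thin" and at.path == "thick"
        assert below.applied_factor > 0 and at.applied_factor > 0


def _brute_force_loo(table):
    """Independent leave-one-out oracle: explicit 4-corner bilinear."""
    nd, nt = table.values.shape
    worst = 0.0
    for i in range(1, nd - 1):
        for j in range(1, nt - 1):
            d, t = table.distances[i], table.thicknesses[j]
            d0, d1 = table.distances[i - 1], table.distances[i + 1]
            t0, t1 = table.thicknesses[j - 1], table.thicknesses[j + 1]
            wd, wt = (d - d0) / (d1 - d0), (t - t0) / (t1 - t0)
            v = table.values
            pred = ((1 - wd) * (1 - wt) * v[i - 1, j - 1]
                    + (1 - wd) * wt * v[i - 1, j + 1]
                    + wd * (1 - wt) * v[i + 1, j - 1]
                    + wd * wt * v[i + 1, j + 1])
            worst = max(worst, abs(pred - v[i, j]))
    return worst


class TestValidateLoo:
    def test_bilinear_surface_reproduced_exactly(self):
        table = generate_fixture_table("bilinear", seed=0)
        assert validate_loo(table) == pytest.approx(0.0, abs=1e-10)

    def test_matches_brute_force_oracle(self):
        table = generate_fixture_table("cubic", noise_sd=0.8, seed=4)
        assert validate_loo(table) == pytest.approx(
            _brute_force_loo(table), rel=1e-12)

    def test_cubic_surface_within_analytic_bound(self):
        # leave-one-out spans 2 grid steps per axis; for the cubic fixture
        # f_dd = 0.3 d - 1.2 and f_tt = 3.0, and the d*t term is exactly
        # bilinear, so |error| <= (1/8) hd^2 max|f_dd| + (1/8) ht^2 max|f_tt|
        table = generate_fixture_table("cubic", seed=0)
        hd = 2.0 * np.diff(table.distances).max()
        ht = 2.0 * np.diff(table.thicknesses).max()
        m_dd = max(abs(0.3 * d - 1.2) for d in table.distances)
        bound = hd**2 * m_dd / 8 + ht**2 * 3.0 / 8
        assert validate_loo(table) <= bound

    def test_degenerate_grid_rejected(self):
        t = generate_fixture_table("cubic", distances=[1.0, 2.0],
                                   thicknesses=[0.4, 0.8, 1.2], seed=0)
        with pytest.raises(ValueError):
            validate_loo(t)

    def test_details_include_noise_floor(self):
        table = generate_fixture_table("cubic", noise_sd=0.5, seed=9)
        max_err, details = validate_loo(table, return_details=True)
        assert max_err == max(r["abs_error"] for r in details)
        assert all(r["noise_floor"] >= 0.5 for r in details)

    def test_loo_predict_interior_only(self):
        table = generate_fixture_table("cubic", seed=0)
        with pytest.raises(ValueError, match="interior"):
            loo_predict(table, 0, 1)


class TestFitThinLayerModel:
    def test_recovers_exact_constrained_cubic(self):
        x = np.array([1.0, 3.0, 5.0, 7.0, 9.0])
        truth = ThinLayerModel()
        y = truth.c3 * x**3 + truth.c1 * x + truth.c0
        fit = fit_thin_layer_model(x, y)
        assert fit.c3 == pytest.approx(truth.c3, abs=1e-12)
        assert fit.c1 == pytest.approx(truth.c1, abs=1e-12)
        assert fit.c0 == pytest.approx(truth.c0, abs=1e-12)

    def test_quadratic_term_absent_from_model(self):
        # a pure x^2 signal must project onto the (x^3, x, 1) basis, not
        # be reproduced
        x = np.linspace(1, 9, 9)
        fit = fit_thin_layer_model(x, x**2)
        pred = fit.c3 * x**3 + fit.c1 * x + fit.c0
        assert np.max(np.abs(pred - x**2)) > 1.0

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_thin_layer_model([1.0, 2.0], [1.0, 1.0])
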