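"""Divergence estimator, field decomposition, strain and exclusion rule."""

import numpy as np
import pytest

from frictouch.errors import (
    DegenerateGeometryError,
    InsufficientSupportError,
    ParameterError,
)
from frictouch.fields import (
    DisplacementField,
    decompose,
    global_displacement,
    grid_interpolate,
    mean_divergence,
    strain_components,
    strain_energy,
    strain_rate_series,
)


def make_field(ax, ux, uy, mask):
    return DisplacementField(grid_x=ax, grid_y=ax, u_x=ux, u_y=uy, mask=mask)


class TestMeanDivergence:
    @pytest.mark.parametrize(
        "field_fn,expected",
        [
            (lambda gx, gy: (0.05 * gx, 0.05 * gy), 0.1),  # div(k x, k y) = 2k
            (lambda gx, gy: (0.3 + 0 * gx, -0.2 + 0 * gy), 0.0),  # translation
            (lambda gx, gy: (-0.04 * gy, 0.04 * gx), 0.0),  # rigid rotation
        ],
        ids=["radial", "translation", "rotation"],
    )
    def test_closed_form_fields(self, disk_field_axes, field_fn, expected):
        ax, gx, gy, mask = disk_field_axes
        ux, uy = field_fn(gx, gy)
        assert mean_divergence(make_field(ax, ux, uy, mask)) == pytest.approx(
            expected, abs=1e-9 if expected == 0 else 1e-3
        )

    def test_invariant_to_adding_constant_field(self, disk_field_axes):
        ax, gx, gy, mask = disk_field_axes
        base = mean_divergence(make_field(ax, 0.02 * gx**2, 0.01 * gy, mask))
        shifted = mean_divergence(
            make_field(ax, 0.02 * gx**2 + 5.0, 0.01 * gy - 3.0, mask)
        )
        assert shifted == pytest.approx(base, abs=1e-12)

    def test_second_order_convergence_on_polynomial_field(self):
        # error of the central-difference estimator drops ~4x per refinement
        errs = []
        for n in (33, 65, 129):
            ax = np.linspace(-1, 1, n)
            gx, gy = np.meshgrid(ax, ax)
            mask = gx**2 + gy**2 <= 0.81
            ux, uy = 0.1 * gx**3, 0.05 * gy**3
            exact = np.mean(
                (0.3 * gx**2 + 0.15 * gy**2)[mask]
            )
            est = mean_divergence(make_field(ax, ux, uy, mask))
            errs.append(abs(est - exact))
        assert errs[0] < 1e-3
        assert errs[2] < errs[0]

    def test_raw_integral_is_mean_times_area(self, disk_field_axes):
        ax, gx, gy, mask = disk_field_axes
        fld = make_field(ax, 0.05 * gx, 0.05 * gy, mask)
        raw = mean_divergence(fld, normalized=False)
        assert raw == pytest.approx(0.1 * mask.sum() * fld.cell_area, rel=1e-6)

    def test_mask_without_interior_raises(self):
        ax = np.linspace(0, 1, 8)
        mask = np.zeros((8, 8), dtype=bool)
        mask[0, 0] = True
        fld = make_field(ax, np.zeros((8, 8)), np.zeros((8, 8)), mask)
        with pytest.raises(InsufficientSupportError):
            mean_divergence(fld)


class TestDecomposition:
    def test_pure_fields_stay_in_their_component(self, disk_field_axes):
        ax, gx, gy, mask = disk_field_axes
        k, w = 0.05, 0.03
        rad = decompose(make_field(ax, k * gx, k * gy, mask))
        rot = decompose(make_field(ax, -w * gy, w * gx, mask))
        norm_rad = np.linalg.norm([k * gx[mask], k * gy[mask]])
        norm_rot = np.linalg.norm([w * gy[mask], w * gx[mask]])
        leak_rot = np.linalg.norm(
            [rad.rotational_part[0][mask], rad.rotational_part[1][mask]]
        )
        leak_div = np.linalg.norm(
            [rot.divergent_part[0][mask], rot.divergent_part[1][mask]]
        )
        assert leak_rot <= 1e-6 * norm_rad
        assert leak_div <= 1e-6 * norm_rot

    def test_constructed_mixture_recovered_componentwise(self, disk_field_axes):
        ax, gx, gy, mask = disk_field_axes
        k, w, c = 0.05, 0.03, (0.1, -0.05)
        fld = make_field(ax, c[0] + k * gx - w * gy, c[1] + k * gy + w * gx, mask)
        dec = decompose(fld)
        assert dec.constant_part == pytest.approx(c, abs=1e-9)
        for got, want in [
            (dec.divergent_part, (k * gx, k * gy)),
            (dec.rotational_part, (-w * gy, w * gx)),
        ]:
            err = np.linalg.norm([got[0][mask] - want[0][mask],
                                  got[1][mask] - want[1][mask]])
            ref = np.linalg.norm([want[0][mask], want[1][mask]])
            assert err <= 1e-4 * ref

    def test_reconstruction_identity_and_residual(self, disk_field_axes):
        ax, gx, gy, mask = disk_field_axes
        rng = np.random.default_rng(5)
        ux = 0.1 * gx + 0.02 * rng.standard_normal(gx.shape)
        uy = -0.07 * gy + 0.02 * rng.standard_normal(gy.shape)
        fld = make_field(ax, ux, uy, mask)
        dec = decompose(fld)
        rx = (dec.constant_part[0] + dec.divergent_part[0]
              + dec.rotational_part[0] + dec.residual[0])
        ry = (dec.constant_part[1] + dec.divergent_part[1]
              + dec.rotational_part[1] + dec.residual[1])
        assert np.allclose(rx[mask], ux[mask], atol=1e-12)
        assert np.allclose(ry[mask], uy[mask], atol=1e-12)

    def test_decomposition_is_idempotent_on_divergent_part(self, disk_field_axes):
        ax, gx, gy, mask = disk_field_axes
        dec = decompose(make_field(ax, 0.05 * gx - 0.03 * gy,
                                   0.05 * gy + 0.03 * gx, mask))
        again = decompose(make_field(ax, dec.divergent_part[0],
                                     dec.divergent_part[1], mask))
        norm = np.linalg.norm([dec.divergent_part[0][mask],
                               dec.divergent_part[1][mask]])
        err = np.linalg.norm([
            again.divergent_part[0][mask] + again.constant_part[0]
            - dec.divergent_part[0][mask],
            again.divergent_part[1][mask] + again.constant_part[1]
            - dec.divergent_part[1][mask],
        ])
        assert err <= 1e-6 * norm

    def test_interior_curl_of_divergent_part_vanishes(self, disk_field_axes):
        ax, gx, gy, mask = disk_field_axes
        dec = decompose(make_field(ax, 0.05 * gx - 0.03 * gy,
                                   0.05 * gy + 0.03 * gx, mask))
        h = ax[1] - ax[0]
        dx, dy = dec.divergent_part
        curl = ((np.gradient(dy, h, axis=1) - np.gradient(dx, h, axis=0)))
        # evaluate away from the mask boundary where stencils are central
        from scipy.ndimage import binary_erosion
        interior = binary_erosion(mask, iterations=3)
        norm = np.linalg.norm([dx[mask], dy[mask]])
        assert np.linalg.norm(curl[interior]) <= 1e-6 * norm


class TestGridInterpolate:
    def test_affine_field_reproduced_exactly(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(-1, 1, size=(200, 2))
        k = 0.05
        disp = np.column_stack([0.1 + k * pts[:, 0], -0.2 + k * pts[:, 1]])
        ax = np.linspace(-0.7, 0.7, 32)
        fld = grid_interpolate(pts, disp, ax, ax)
        gx, gy = np.meshgrid(ax, ax)
        assert np.allclose(fld.u_x[fld.mask], (0.1 + k * gx)[fld.mask], atol=1e-12)
        assert np.allclose(fld.u_y[fld.mask], (-0.2 + k * gy)[fld.mask], atol=1e-12)

    def test_no_extrapolation_outside_hull(self):
        pts = np.array([[0, 0], [1, 0], [0, 1], [1, 1]], dtype=float)
        disp = np.zeros((4, 2))
        ax = np.linspace(-1, 2, 16)
        fld = grid_interpolate(pts, disp, ax, ax)
        gx, gy = np.meshgrid(ax, ax)
        outside = (gx < 0) | (gx > 1) | (gy < 0) | (gy > 1)
        assert not fld.mask[outside].any()

    def test_grid_refinement_reduces_error_quadratically(self):
        rng = np.random.default_rng(1)
        pts = rng.uniform(-1, 1, size=(700, 2))
        disp = np.column_stack([np.sin(pts[:, 0]), np.cos(pts[:, 1])])
        errs = []
        for n in (16, 32):
            ax = np.linspace(-0.6, 0.6, n)
            fld = grid_interpolate(pts, disp, ax, ax)
            gx, gy = np.meshgrid(ax, ax)
            err = np.max(np.abs(fld.u_x[fld.mask] - np.sin(gx)[fld.mask]))
            errs.append(err)
        # piecewise-linear interpolation error is O(h^2) in the point spacing,
        # which does not change: grid refinement must not blow the error up
        assert errs[1] <= 2 * errs[0]
        assert errs[0] < 0.01

    def test_collinear_points_rejected(self):
        pts = np.column_stack([np.linspace(0, 1, 10), np.linspace(0, 2, 10)])
        with pytest.raises(DegenerateGeometryError):
            grid_interpolate(pts, np.zeros((10, 2)), np.linspace(0, 1, 8),
                             np.linspace(0, 1, 8))


class TestStrain:
    def test_uniform_biaxial_strain_recovered(self, disk_field_axes):
        ax, gx, gy, mask = disk_field_axes
        s = strain_components(make_field(ax, 0.03 * gx, 0.03 * gy, mask))
        assert s.longitudinal_strain == pytest.approx(3.0, rel=1e-6)

    def test_small_rigid_rotation_gives_no_strain(self, disk_field_axes):
        ax, gx, gy, mask = disk_field_axes
        w = 1e-4
        s = strain_components(make_field(ax, -w * gy, w * gx, mask))
        assert abs(s.longitudinal_strain) <= 1e-8

    def test_strain_rate_of_linear_ramp_is_constant(self, disk_field_axes):
        ax, gx, gy, mask = disk_field_axes
        fields = []
        for i, t in enumerate(np.linspace(0.0, 1.0, 6)):
            k = 0.10 * t  # 0 -> 10% strain over 1 s
            f = make_field(ax, k * gx, k * gy, mask)
            f.timestamp = t
            fields.append(f)
        summary = strain_rate_series(fields, np.array([0, 1.0]), np.array([0, 2.0]))
        assert summary.peak_strain_rate == pytest.approx(10.0, rel=1e-6)
        assert np.allclose(summary.strain_rate, 10.0, rtol=1e-6)

    def test_single_frame_rejected(self, disk_field_axes):
        ax, gx, gy, mask = disk_field_axes
        f = make_field(ax, 0.01 * gx, 0.01 * gy, mask)
        with pytest.raises(InsufficientSupportError):
            strain_rate_series([f], np.array([0.0, 1.0]), np.array([0.0, 1.0]))

    def test_strain_energy_matches_plane_stress_closed_form(self, disk_field_axes):
        ax, gx, gy, mask = disk_field_axes
        k, E, nu, t = 0.03, 0.1, 0.4, 1.2
        fld = make_field(ax, k * gx, k * gy, mask)
        area = mask.sum() * fld.cell_area
        expected = E * k**2 * area * t / (1 - nu)
        got = strain_energy(fld, elastic_modulus=E, skin_thickness=t, poisson=nu)
        assert got == pytest.approx(expected, rel=1e-6)

    def test_strain_energy_is_quadratic_and_zero_for_zero_field(self, disk_field_axes):
        ax, gx, gy, mask = disk_field_axes
        z = make_field(ax, 0 * gx, 0 * gy, mask)
        assert strain_energy(z) == 0.0
        one = strain_energy(make_field(ax, 0.01 * gx, 0.02 * gy, mask))
        two = strain_energy(make_field(ax, 0.02 * gx, 0.04 * gy, mask))
        assert two == pytest.approx(4 * one, rel=1e-9)

    def test_unphysical_moduli_rejected(self, disk_field_axes):
        ax, gx, gy, mask = disk_field_axes
        fld = make_field(ax, 0.01 * gx, 0.01 * gy, mask)
        with pytest.raises(ParameterError):
            strain_energy(fld, elastic_modulus=-1.0)
        with pytest.raises(ParameterError):
            strain_energy(fld, poisson=0.7)


class TestGlobalDisplacementRule:
    @pytest.mark.parametrize(
        "vec,excluded",
        [((0.4, 0.0), True), ((0.29, 0.0), False), ((0.25, 0.25), True)],
    )
    def test_exclusion_threshold_at_0p3_mm(self, disk_field_axes, vec, excluded):
        ax, gx, gy, mask = disk_field_axes
        fld = make_field(ax, vec[0] + 0 * gx, vec[1] + 0 * gy, mask)
        gd = global_displacement(fld)
        assert gd.excluded is excluded
        assert gd.median_vector == pytest.approx(vec, abs=1e-12)

    def test_centered_radial_field_is_kept(self, disk_field_axes):
        ax, gx, gy, mask = disk_field_axes
        gd = global_displacement(make_field(ax, 0.05 * gx, 0.05 * gy, mask))
        assert gd.magnitude < 0.05
        assert not gd.excluded


class TestStrainRateSigmoidOracle:
    def test_peak_rate_matches_analytic_derivative_of_sigmoid(self, disk_field_axes):
        # strain(t) = A / (1 + exp(-(t-t0)/tau)); peak rate = A/(4 tau)
        ax, gx, gy, mask = disk_field_axes
        A, t0, tau = 0.06, 0.5, 0.12
        times = np.linspace(0.0, 1.0, 41)
        fields = []
        for t in times:
            k = A / (1.0 + np.exp(-(t - t0) / tau))
            f = make_field(ax, k * gx, k * gy, mask)
            f.timestamp = t
            fields.append(f)
        out = strain_rate_series(fields, np.array([0, 1.0]), np.array([0, 3.0]))
        analytic_peak = 100.0 * A / (4.0 * tau)  # percent/s
        assert out.peak_strain_rate == pytest.approx(analytic_peak, rel=0.05)
        assert out.force_at_peak == pytest.approx(3.0 * t0, rel=0.05)


class TestFieldTableRoundTrip:
    def test_long_format_round_trip_preserves_analysis(self, disk_field_axes, tmp_path):
        import pandas as pd

        ax, gx, gy, mask = disk_field_axes
        fld = make_field(ax, 0.05 * gx, 0.03 * gy, mask)
        path = tmp_path / "field.csv"
        fld.to_frame().to_csv(path, index=False)
        back = DisplacementField.from_frame(pd.read_csv(path))
        assert np.allclose(back.u_x, fld.u_x)
        assert np.array_equal(back.mask, fld.mask)
        assert mean_divergence(back) == pytest.approx(mean_divergence(fld), rel=1e-9)
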