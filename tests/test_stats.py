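"""Ensemble statistics and differential operators: phase averaging,
RMS fluctuations, shear-rate scalars, flow-rate integrals, kinetic
energies, windowed metrics and dimensionless numbers."""

import dataclasses

import numpy as np
import pytest

from rootflow import (
    Grid,
    analytic_field,
    gamma_2d,
    gamma_3d,
    kinetic_energies,
    net_flow_rate,
    phase_average,
    rf_flow_rate,
    u_rms,
    velocity_gradient,
    window_metrics,
    dimensionless_numbers,
)
from rootflow.stats import (
    MeanField,
    RmsField,
    phase_statistics,
    rate_of_strain,
)


def _uniform_fields(shape, values):
    """One phase with one field per value: U_x = value everywhere."""
    out = []
    for v in values:
        u = np.zeros((3, *shape))
        u[0] = v
        out.append(u)
    return [out]


class TestPhaseAverage:
    def test_identical_replicates(self, stub_ensemble_factory):
        ens = stub_ensemble_factory(_uniform_fields((4, 4, 4), [0.7, 0.7, 0.7]))
        mean = phase_average(ens, 0)
        np.testing.assert_allclose(mean.u[0], 0.7)

    def test_opposite_pair_cancels(self, stub_ensemble_factory):
        ens = stub_ensemble_factory(_uniform_fields((4, 4, 4), [1.0, -1.0]))
        mean = phase_average(ens, 0)
        np.testing.assert_allclose(mean.u, 0.0)

    def test_monte_carlo_mean(self, stub_ensemble_factory):
        rng = np.random.default_rng(5)
        vals = rng.normal(0.5, 0.1, size=16)
        ens = stub_ensemble_factory(_uniform_fields((3, 3, 3), vals))
        mean = phase_average(ens, 0)
        assert abs(mean.u[0, 0, 0, 0] - 0.5) < 0.1 * 3 / np.sqrt(16)


class TestUrms:
    def test_identical_replicates_zero(self, stub_ensemble_factory):
        ens = stub_ensemble_factory(_uniform_fields((4, 4, 4), [0.3] * 5))
        mean = phase_average(ens, 0)
        rms = u_rms(ens, mean, 0)
        np.testing.assert_allclose(rms.urms, 0.0)

    def test_alternating_pm_sigma(self, stub_ensemble_factory):
        sigma = 0.25
        ens = stub_ensemble_factory(
            _uniform_fields((4, 4, 4), [sigma, -sigma, sigma, -sigma])
        )
        mean = phase_average(ens, 0)
        rms = u_rms(ens, mean, 0)
        np.testing.assert_allclose(rms.urms, sigma)

    def test_requires_two_replicates(self, stub_ensemble_factory):
        ens = stub_ensemble_factory(_uniform_fields((4, 4, 4), [1.0]))
        mean = phase_average(ens, 0)
        with pytest.raises(ValueError, match="N < 2"):
            u_rms(ens, mean, 0)

    def test_one_pass_matches_two_pass(self, small_ensemble):
        mean1 = phase_average(small_ensemble, 7)
        rms1 = u_rms(small_ensemble, mean1, 7)
        mean2, rms2 = phase_statistics(small_ensemble, 7)
        np.testing.assert_allclose(mean1.u, mean2.u, atol=1e-12)
        np.testing.assert_allclose(rms1.urms, rms2.urms, atol=1e-9)


class TestVelocityGradient:
    def test_linear_field_exact(self):
        grid = Grid(origin=(-4, -4, -4), spacing=(1, 1, 1), counts=(9, 9, 9))
        f = analytic_field("pure-shear", 100.0, grid)
        g = velocity_gradient(f)
        interior = np.s_[1:-1, 1:-1, 1:-1]
        np.testing.assert_allclose(g[1, 2][interior], 100.0, rtol=1e-12)
        np.testing.assert_allclose(g[0, 0][interior], 0.0, atol=1e-12)

    def test_quadratic_central_difference_exact(self):
        grid = Grid(origin=(0, 0, 0), spacing=(0.5, 0.5, 0.5), counts=(5, 5, 7))
        f = analytic_field("pure-shear", 0.0, grid)
        _, _, z = grid.meshgrid()
        u = np.zeros_like(f.u)
        u[1] = 1e-3 * z**2  # m/s with z in mm
        f = dataclasses.replace(f, u=u)
        g = velocity_gradient(f)
        # d(z^2)/dz = 2z exactly for the central stencil
        expect = 2.0 * z[2:-2, 2:-2, 1:-1]
        np.testing.assert_allclose(g[1, 2][2:-2, 2:-2, 1:-1], expect, rtol=1e-10)

    def test_constant_field_zero(self):
        grid = Grid(origin=(0, 0, 0), spacing=(1, 1, 1), counts=(5, 5, 5))
        f = analytic_field("pure-shear", 0.0, grid)
        f.u += 0.37
        g = velocity_gradient(f)
        np.testing.assert_allclose(np.nan_to_num(g), 0.0, atol=1e-12)

    def test_one_sided_at_mask_boundary(self):
        grid = Grid(origin=(0, 0, 0), spacing=(1, 1, 1), counts=(5, 5, 5))
        f = analytic_field("pure-shear", 100.0, grid)
        mask = f.mask.copy()
        mask[:, :, 0] = False  # boundary voxel at z index 1 now one-sided
        f = dataclasses.replace(f, mask=mask)
        g = velocity_gradient(f)
        # one-sided first-order difference is still exact for linear fields
        np.testing.assert_allclose(g[1, 2][:, :, 1], 100.0, rtol=1e-12)
        assert np.isnan(g[1, 2][:, :, 0]).all()

    def test_isolated_voxel_undefined(self):
        grid = Grid(origin=(0, 0, 0), spacing=(1, 1, 1), counts=(5, 5, 5))
        f = analytic_field("pure-shear", 100.0, grid)
        mask = np.zeros(grid.shape, bool)
        mask[2, 2, 2] = True
        f = dataclasses.replace(f, mask=mask)
        g = velocity_gradient(f)
        assert np.isnan(g[1, 2][2, 2, 2])

    def test_too_few_voxels(self):
        grid = Grid(origin=(0, 0, 0), spacing=(1, 1, 1), counts=(2, 5, 5))
        f = analytic_field("pure-shear", 1.0, grid)
        with pytest.raises(ValueError, match="3 voxels"):
            velocity_gradient(f)


def _char_poly_eigen_spread(tensors):
    """Independent oracle: eigenvalues via the characteristic polynomial
    roots of each symmetric 3x3 tensor."""
    out = np.empty(len(tensors))
    for i, s in enumerate(tensors):
        c2 = -np.trace(s)
        c1 = 0.5 * (np.trace(s) ** 2 - np.trace(s @ s))
        c0 = -np.linalg.det(s)
        roots = np.roots([1.0, c2, c1, c0])
        roots = np.sort(roots.real)
        out[i] = roots[-1] - roots[0]
    return out


class TestGamma3D:
    @pytest.mark.parametrize(
        "kind, rate, expect",
        [
            ("pure-shear", 100.0, 100.0),  # eigenvalues +-k/2, 0
            ("uniaxial-strain", 100.0, 150.0),  # a - (-a/2)
            ("rigid-rotation", 100.0, 0.0),  # S = 0
        ],
    )
    def test_analytic_oracles(self, kind, rate, expect):
        grid = Grid(origin=(-3, -3, -3), spacing=(1, 1, 1), counts=(7, 7, 7))
        f = analytic_field(kind, rate, grid)
        g3 = gamma_3d(rate_of_strain(velocity_gradient(f)))
        np.testing.assert_allclose(g3, expect, atol=1e-10 * max(rate, 1.0))

    def test_matches_characteristic_polynomial_oracle(self):
        rng = np.random.default_rng(17)
        a = rng.normal(size=(1000, 3, 3))
        sym = 0.5 * (a + np.swapaxes(a, 1, 2))
        tensors = np.moveaxis(sym, 0, -1).reshape(3, 3, 1000, 1, 1)
        ours = gamma_3d(tensors).ravel()
        oracle = _char_poly_eigen_spread(sym)
        np.testing.assert_allclose(ours, oracle, rtol=1e-9)

    def test_nan_propagates(self):
        t = np.full((3, 3, 2, 2, 2), np.nan)
        assert np.isnan(gamma_3d(t)).all()

    def test_nonnegative(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=(200, 3, 3))
        sym = 0.5 * (a + np.swapaxes(a, 1, 2))
        tensors = np.moveaxis(sym, 0, -1).reshape(3, 3, 200, 1, 1)
        assert (gamma_3d(tensors) >= 0).all()


class TestGamma2D:
    def _grid(self):
        return Grid(origin=(-4, -4, -4), spacing=(1, 1, 1), counts=(9, 9, 9))

    def test_in_plane_shear(self):
        f = analytic_field("pure-shear", 100.0, self._grid())
        g2 = gamma_2d(f)
        np.testing.assert_allclose(g2[1:-1, 1:-1], 100.0, rtol=1e-12)

    def test_out_of_plane_shear_invisible(self):
        """U_x = k*z has gamma_2D = 0 on a Y-Z slice but gamma_3D = k:
        planar data underestimate the true shear rate."""
        f = analytic_field("pure-shear", 100.0, self._grid())
        u = np.zeros_like(f.u)
        u[0] = f.u[1]
        f = dataclasses.replace(f, u=u)
        g2 = gamma_2d(f)
        g3 = gamma_3d(rate_of_strain(velocity_gradient(f)))
        np.testing.assert_allclose(g2, 0.0, atol=1e-12)
        np.testing.assert_allclose(g3[1:-1, 1:-1, 1:-1], 100.0, rtol=1e-10)

    def test_interlacing_on_random_smooth_fields(self):
        """gamma_2D <= gamma_3D voxelwise (Cauchy interlacing of the
        principal 2x2 submatrix)."""
        from scipy.ndimage import gaussian_filter

        rng = np.random.default_rng(23)
        grid = Grid(origin=(-6, -6, -6), spacing=(1, 1, 1), counts=(13, 13, 13))
        f = analytic_field("pure-shear", 0.0, grid)
        u = gaussian_filter(rng.normal(size=(3, 13, 13, 13)), 1.5, axes=(1, 2, 3))
        f = dataclasses.replace(f, u=u)
        x_index = 6
        g2 = gamma_2d(f, x_index=x_index)
        g3 = gamma_3d(rate_of_strain(velocity_gradient(f)))[x_index]
        ok = np.isfinite(g2) & np.isfinite(g3)
        assert ok.any()
        assert (g2[ok] <= g3[ok] + 1e-9).all()

    def test_slice_out_of_grid(self):
        f = analytic_field("pure-shear", 1.0, self._grid())
        with pytest.raises(ValueError):
            gamma_2d(f, x_index=99)


def _flat_mean_field(uy, spacing=1.0, mask=None):
    shape = uy.shape
    grid = Grid(origin=(0, 0, 0), spacing=(spacing,) * 3, counts=shape)
    u = np.zeros((3, *shape))
    u[1] = uy
    if mask is None:
        mask = np.ones(shape, bool)
    return MeanField(grid, u, mask, 0.0, 1, flow_origin_y=grid.coords(1)[shape[1] // 2])


class TestFlowRates:
    def test_uniform_profile(self):
        uy = np.full((6, 5, 6), 0.8)
        mf = _flat_mean_field(uy)
        # 36 pixels of 1 mm^2 at 0.8 m/s
        assert net_flow_rate(mf, 0.0) == pytest.approx(0.8 * 36e-6)
        assert rf_flow_rate(mf, 0.0) == 0.0

    def test_antisymmetric_profile_cancels(self):
        uy = np.zeros((6, 5, 6))
        uy[:3] = 1.0
        uy[3:] = -1.0
        mf = _flat_mean_field(uy)
        assert net_flow_rate(mf, 0.0) == pytest.approx(0.0, abs=1e-15)
        assert rf_flow_rate(mf, 0.0) == pytest.approx(18e-6)

    def test_sign_split_identity(self):
        rng = np.random.default_rng(2)
        uy = rng.normal(size=(6, 5, 6))
        mf = _flat_mean_field(uy)
        q_net = net_flow_rate(mf, 0.0)
        q_rf = rf_flow_rate(mf, 0.0)
        q_fwd = float(np.maximum(uy[:, 2, :], 0).sum() * 1e-6)
        assert q_net == pytest.approx(q_fwd - q_rf, rel=1e-12)

    def test_section_at_grid_edge_rejected(self):
        uy = np.zeros((4, 4, 4))
        mf = _flat_mean_field(uy)
        with pytest.raises(ValueError):
            net_flow_rate(mf, 10.0)
        with pytest.raises(ValueError, match="edge"):
            net_flow_rate(mf, -2.0)


class TestKineticEnergies:
    def _fields(self, speed, urms, shape=(5, 5, 5), spacing=2.0):
        grid = Grid(origin=(0, 0, 0), spacing=(spacing,) * 3, counts=shape)
        mask = np.ones(shape, bool)
        u = np.zeros((3, *shape))
        u[1] = speed
        mean = MeanField(grid, u, mask, 0.0, 2)
        rms = RmsField(grid, np.full(shape, urms), mask, 0.0, 2)
        return mean, rms, mask

    def test_uniform_energy_value(self):
        # 1 m/s over 125 voxels of 8 mm^3 = 1 cm^3 at rho 1200 -> 0.6 mJ
        mean, rms, mask = self._fields(1.0, 0.0)
        e_mk, e_fk = kinetic_energies(mean, rms, mask, rho=1200.0)
        assert e_mk == pytest.approx(0.5 * 1200.0 * 1.0 * 1e-6)
        assert e_fk == 0.0

    def test_linearity_in_volume(self):
        mean, rms, mask = self._fields(1.0, 0.2)
        half = mask.copy()
        half[:, :2] = False
        e_mk_full, e_fk_full = kinetic_energies(mean, rms, mask, 1200.0)
        e_mk_h, e_fk_h = kinetic_energies(mean, rms, half, 1200.0)
        assert e_mk_full == pytest.approx(e_mk_h * 125 / 75)
        assert e_fk_full == pytest.approx(e_fk_h * 125 / 75)

    def test_empty_mask_warns(self):
        mean, rms, mask = self._fields(1.0, 0.1)
        with pytest.warns(UserWarning, match="empty"):
            e = kinetic_energies(mean, rms, np.zeros_like(mask), 1200.0)
        assert e == (0.0, 0.0)

    def test_energy_decomposition_is_exact(self, small_ensemble):
        """Ensemble total kinetic energy splits exactly into mean +
        fluctuating parts with the population (N) divisor."""
        mean, rms = phase_statistics(small_ensemble, 7)
        mask = small_ensemble.mask
        rho = 1200.0
        dv = small_ensemble.grid.voxel_volume * 1e-9
        total = 0.0
        for f in small_ensemble.iter_phase(7):
            total += 0.5 * rho * float((f.u**2).sum(axis=0)[mask].sum()) * dv
        total /= small_ensemble.n_replicates
        e_mk, e_fk = kinetic_energies(mean, rms, mask, rho)
        assert total == pytest.approx(e_mk + e_fk, rel=1e-12)


class TestWindowMetrics:
    times = 0.03 * np.arange(13)

    def test_constant_series(self):
        s = np.full(13, 4.2)
        assert window_metrics(self.times, s, 0.18, 0.36) == pytest.approx(4.2)

    def test_linear_series_exact(self):
        a = 3.0
        s = a * self.times
        got = window_metrics(self.times, s, 0.15, 0.30)
        assert got == pytest.approx(a * (0.15 + 0.30) / 2, rel=1e-12)

    def test_uses_exactly_the_window_samples(self):
        rng = np.random.default_rng(0)
        s = rng.normal(size=13)
        got = window_metrics(self.times, s, 0.18, 0.36)
        expect = np.trapezoid(s[6:], self.times[6:]) / (0.36 - 0.18)
        assert got == pytest.approx(expect, rel=1e-12)

    def test_uncovered_window_rejected(self):
        with pytest.raises(ValueError):
            window_metrics(self.times, np.zeros(13), 0.3, 0.5)


class TestDimensionlessNumbers:
    def test_reynolds_number(self):
        """Re = 4 Q_max / (pi d_jet nu) ~ 6000 for the experimental
        constants (20 l/min, 15 mm, 4.7 mm^2/s)."""
        d = dimensionless_numbers(Q_max_lmin=20.0, d_jet_mm=15.0, nu_mm2s=4.7)
        assert d.Re == pytest.approx(6020.0, abs=1.0)

    def test_womersley_number(self):
        d = dimensionless_numbers(d_jet_mm=15.0)
        assert d.alpha == pytest.approx(13.93, abs=0.01)

    def test_jet_diameter_from_orifice_area(self):
        d = dimensionless_numbers(A_poa_mm2=np.pi * 7.5**2)
        assert d.d_jet_mm == pytest.approx(15.0, rel=1e-12)

    def test_particle_relaxation_and_stokes(self):
        """tau = rho_p d_p^2 / (18 rho nu) ~ 21 us at d_p = 42 um; the
        Stokes number tau U / d_p stays order one across the seeded
        particle sizes."""
        d42 = dimensionless_numbers(d_jet_mm=15.0, d_p_um=42.0)
        assert d42.tau_s * 1e6 == pytest.approx(21.0, rel=0.03)
        d50 = dimensionless_numbers(d_jet_mm=15.0, d_p_um=50.0)
        assert d50.St == pytest.approx(0.8, abs=0.4)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            dimensionless_numbers(d_jet_mm=-1.0)
        with pytest.raises(ValueError):
            dimensionless_numbers(A_poa_mm2=0.0)
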