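import numpy as np
import pytest
from scipy.ndimage import map_coordinates

from menpi.efield import (
    CurrentSourceMap,
    FiringSource,
    conservation_residual,
    efield_from_potential,
    firing_to_source,
    solve_potential,
)
from menpi.errors import ConfigurationError, GeometryError, SolverError
from menpi.phantom import TissuePhantom, assign_conductivities, make_layered_phantom

SIGMA = 0.33


def uniform_cube(n: int, sigma: float = SIGMA) -> TissuePhantom:
    labels = np.ones((n, n, n), np.int16)
    return assign_conductivities(
        TissuePhantom(labels=labels, voxel_size=1.0), {1: sigma}
    )


def monopole_pair(phantom, src_idx, snk_idx, current_a=1e-6) -> CurrentSourceMap:
    density = np.zeros(phantom.shape)
    vol_m3 = phantom.voxel_volume_mm3 * 1e-9
    density[src_idx] = current_a / vol_m3
    density[snk_idx] = -current_a / vol_m3
    return CurrentSourceMap(density=density, voxel_size=phantom.voxel_size)


def neumann_images_potential(shape, centers_and_currents, sigma, order=2):
    """Closed-form oracle: superposed point-source potentials I/(4 pi sigma r),
    including the mirror images across the insulating box faces (method of
    images for the Neumann problem; reflections up to `order`)."""
    n = np.asarray(shape, dtype=float)
    axes = [np.arange(s) + 0.5 for s in shape]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij", sparse=True)
    total = np.zeros(shape)
    for (ci, cj, ck), current in centers_and_currents:
        c = (ci + 0.5, cj + 0.5, ck + 0.5)
        coords = [
            [s * c[a] + 2 * k * n[a] for k in range(-order, order + 1) for s in (1, -1)]
            for a in range(3)
        ]
        for cx in coords[0]:
            dx2 = (xx - cx) ** 2
            for cy in coords[1]:
                dxy = dx2 + (yy - cy) ** 2
                for cz in coords[2]:
                    with np.errstate(divide="ignore"):
                        total += current / np.sqrt(dxy + (zz - cz) ** 2) * 1e3
    return total / (4 * np.pi * sigma)


class TestFiringToSource:
    def test_zero_current_gives_zero_map(self, default_phantom):
        f = FiringSource(center_mm=(32, 32, 32), current_density_per_capacitance=0.0)
        src = firing_to_source(f, default_phantom)
        assert not src.density.any()

    def test_unit_conversion_pa_pf_to_a_m3(self):
        # 70e-12 A/pF x 1e4 pF/mm^3 x 1e9 mm^3/m^3 = 700 A/m^3
        f = FiringSource(center_mm=(32, 32, 32), capacitance_density=1.0e4)
        assert f.volumetric_density_a_m3 == pytest.approx(700.0)

    def test_source_is_balanced(self, default_phantom):
        f = FiringSource(center_mm=(32, 32, 32))
        src = firing_to_source(f, default_phantom)
        gross = np.abs(src.density).sum() * default_phantom.voxel_volume_mm3 * 1e-9
        assert abs(src.total_current_a) / gross < 1e-12

    def test_spot_outside_tissue_rejected(self, default_phantom):
        with pytest.raises(GeometryError):
            firing_to_source(FiringSource(center_mm=(1, 1, 1)), default_phantom)

    def test_coincident_sink_rejected(self):
        with pytest.raises(GeometryError):
            FiringSource(center_mm=(32, 32, 32), sink_offset_voxels=(0, 0, 0))


class TestSolvePotential:
    def test_zero_source_zero_potential(self, small_phantom):
        src = CurrentSourceMap(
            density=np.zeros(small_phantom.shape), voxel_size=small_phantom.voxel_size
        )
        pot = solve_potential(small_phantom, src)
        assert not pot.phi.any()

    def test_unbalanced_source_rejected(self, small_phantom):
        density = np.zeros(small_phantom.shape)
        density[16, 16, 16] = 1.0
        src = CurrentSourceMap(density=density, voxel_size=small_phantom.voxel_size)
        with pytest.raises(SolverError, match="unbalanced"):
            solve_potential(small_phantom, src)

    def test_linearity_in_source_strength(self):
        ph = uniform_cube(24)
        src1 = monopole_pair(ph, (8, 12, 12), (16, 12, 12))
        src2 = CurrentSourceMap(density=2 * src1.density, voxel_size=ph.voxel_size)
        phi1 = solve_potential(ph, src1).phi
        phi2 = solve_potential(ph, src2).phi
        assert np.allclose(phi2, 2 * phi1, rtol=1e-6, atol=1e-12)

    def test_superposition(self):
        ph = uniform_cube(24)
        a = monopole_pair(ph, (8, 8, 12), (16, 8, 12))
        b = monopole_pair(ph, (8, 16, 12), (16, 16, 12))
        both = CurrentSourceMap(density=a.density + b.density, voxel_size=ph.voxel_size)
        phi_sum = solve_potential(ph, a).phi + solve_potential(ph, b).phi
        phi_both = solve_potential(ph, both).phi
        scale = np.abs(phi_both).max()
        assert np.allclose(phi_both, phi_sum, atol=1e-6 * scale)

    def test_discrete_current_conservation(self, default_phantom):
        f = FiringSource(center_mm=(32, 32, 32))
        src = firing_to_source(f, default_phantom)
        pot = solve_potential(default_phantom, src, tolerance=1e-8)
        assert conservation_residual(default_phantom, pot, src) < 1e-8

    def test_matches_analytic_point_source_potential(self):
        """Monopole pair in a uniform volume: the solution matches the
        superposed analytic I/(4 pi sigma r) potentials within 5% away from
        the sources, the boundary and the dipole null surface."""
        n, sep = 64, 20
        ph = uniform_cube(n)
        si = (n // 2 - sep // 2, n // 2, n // 2)
        ki = (n // 2 + sep // 2, n // 2, n // 2)
        current = 1e-6
        pot = solve_potential(ph, monopole_pair(ph, si, ki, current))
        phi_a = neumann_images_potential(
            ph.shape, [(si, current), (ki, -current)], SIGMA
        )
        phi_a[si] = np.nan
        phi_a[ki] = np.nan
        phi_a -= np.nanmean(phi_a)

        xx, yy, zz = np.meshgrid(*[np.arange(n) + 0.5] * 3, indexing="ij")
        r_src = np.sqrt((xx - si[0] - 0.5) ** 2 + (yy - si[1] - 0.5) ** 2 + (zz - si[2] - 0.5) ** 2)
        r_snk = np.sqrt((xx - ki[0] - 0.5) ** 2 + (yy - ki[1] - 0.5) ** 2 + (zz - ki[2] - 0.5) ** 2)
        border = np.minimum.reduce([xx, yy, zz, n - xx, n - yy, n - zz])
        qualifying = (r_src >= 3) & (r_snk >= 3) & (border >= 5)

        err = np.abs(pot.phi - phi_a)
        # everywhere qualifying: error below 5% of the peak analytic value
        assert np.nanmax(err[qualifying]) < 0.05 * np.nanmax(np.abs(phi_a[qualifying]))
        # pointwise 5% off the null surface (where relative error is defined)
        strong = qualifying & (np.abs(phi_a) >= 0.1 * np.nanmax(np.abs(phi_a[qualifying])))
        assert np.nanmax(err[strong] / np.abs(phi_a[strong])) < 0.05

    def test_refinement_converges_at_first_order_or_better(self):
        """Halving the voxel size changes the potential at fixed world points
        by a decreasing amount, with observed order >= 1."""
        world, radii, c = 24.0, (6.0, 8.0, 10.0), 12.0
        p_src = np.array([c + 7.0, c, c])
        p_snk = np.array([c + 3.0, c, c])
        current = 1e-6
        phis = {}
        for vs in (1.5, 0.75, 0.375):
            n = int(round(world / vs))
            ph = assign_conductivities(make_layered_phantom((n, n, n), vs, radii))
            ax = [(np.arange(n) + 0.5) * vs] * 3
            xx, yy, zz = np.meshgrid(*ax, indexing="ij", sparse=True)

            def ball(p):
                return ((xx - p[0]) ** 2 + (yy - p[1]) ** 2 + (zz - p[2]) ** 2) <= 1.5**2

            bs = ball(p_src) & ph.tissue_mask
            bk = ball(p_snk) & ph.tissue_mask
            density = np.zeros((n, n, n))
            vol = (vs * 1e-3) ** 3
            density[bs] = current / (bs.sum() * vol)
            density[bk] = -current / (bk.sum() * vol)
            src = CurrentSourceMap(density=density, voxel_size=ph.voxel_size)
            phis[vs] = solve_potential(ph, src, tolerance=1e-10).phi

        rng = np.random.default_rng(0)
        dirs = rng.normal(size=(200, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        pts = 0.5 * (p_src + p_snk) + 4.0 * dirs

        def sample(vs):
            return map_coordinates(phis[vs], (pts / vs - 0.5).T, order=1)

        d1 = np.sqrt(np.mean((sample(1.5) - sample(0.75)) ** 2))
        d2 = np.sqrt(np.mean((sample(0.75) - sample(0.375)) ** 2))
        assert d2 < d1
        assert np.log2(d1 / d2) >= 1.0


class TestEFieldFromPotential:
    def test_linear_potential_gives_constant_field(self):
        ph = uniform_cube(16)
        x = (np.arange(16) + 0.5) * 1e-3  # m
        phi = np.broadcast_to(x[:, None, None], ph.shape).copy()  # 1 V/m slope
        from menpi.efield import PotentialMap

        pot = PotentialMap(phi=phi, mask=ph.tissue_mask, voxel_size=ph.voxel_size)
        e = efield_from_potential(pot)
        assert np.allclose(e.components[..., 0], -1.0)
        assert np.allclose(e.components[..., 1:], 0.0)

    def test_constant_potential_gives_zero_field(self, small_phantom):
        from menpi.efield import PotentialMap

        phi = np.where(small_phantom.tissue_mask, 3.0, 0.0)
        pot = PotentialMap(
            phi=phi, mask=small_phantom.tissue_mask, voxel_size=small_phantom.voxel_size
        )
        e = efield_from_potential(pot)
        assert np.allclose(e.magnitude[small_phantom.tissue_mask], 0.0)

    def test_zero_outside_tissue(self, pipeline_result):
        e = pipeline_result.efield
        assert np.all(e.magnitude[~pipeline_result.phantom.tissue_mask] == 0.0)

    def test_point_source_inverse_square_decay(self):
        """|E| around a monopole decays as 1/r^2: log-log slope -2 +/- 0.1."""
        n, sep = 64, 20
        ph = uniform_cube(n)
        si = (n // 2 - sep // 2, n // 2, n // 2)
        ki = (n // 2 + sep // 2, n // 2, n // 2)
        pot = solve_potential(ph, monopole_pair(ph, si, ki))
        e = efield_from_potential(pot)
        xx, yy, zz = np.meshgrid(*[np.arange(n) + 0.5] * 3, indexing="ij")
        r = np.sqrt((xx - si[0] - 0.5) ** 2 + (yy - si[1] - 0.5) ** 2 + (zz - si[2] - 0.5) ** 2)
        border = np.minimum.reduce([xx, yy, zz, n - xx, n - yy, n - zz])
        shell = (r >= 3) & (r <= 8) & (border >= 5)
        slope = np.polyfit(np.log(r[shell]), np.log(e.magnitude[shell]), 1)[0]
        assert slope == pytest.approx(-2.0, abs=0.1)

    def test_bad_voxel_size_rejected(self, small_phantom):
        from menpi.efield import PotentialMap

        pot = PotentialMap(
            phi=np.zeros(small_phantom.shape),
            mask=small_phantom.tissue_mask,
            voxel_size=small_phantom.voxel_size,
        )
        with pytest.raises(ConfigurationError):
            efield_from_potential(pot, voxel_size_mm=0.0)


class TestDefaultCalibration:
    def test_peak_field_in_working_range(self, pipeline_result):
        """Default firing spot drives a peak |E| inside the 5-100 V/m range
        of endogenous brain fields, near the 100 V/m calibration point."""
        peak = pipeline_result.peak_e_v_per_m
        assert 5.0 <= peak <= 100.0
        assert peak == pytest.approx(100.0, rel=0.1)
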