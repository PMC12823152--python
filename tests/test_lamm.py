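"""Physics of the finite-volume Lamm solver."""

import numpy as np
import pytest

from sedgrid import (
    CellGeometry,
    Scan,
    ScanSet,
    SVEDBERG,
    simulate_mixture,
    simulate_solute,
    solute_from_mass,
)
from sedgrid.hydro import SoluteHydro


def _artificial_solute(s_sv, D, vbar=0.98):
    """A solute with prescribed transport coefficients (the remaining fields
    are irrelevant to the transport equation)."""
    return SoluteHydro(M=1e8, vbar=vbar, alpha=1.1, s=s_sv * SVEDBERG, D=D,
                       f=1e-7, V=1e-16, R0=3e-6, f0=1e-7, Rh=3e-6)


class TestConservationAndPositivity:
    @pytest.mark.parametrize("s_sv,D", [
        (100.0, 1e-8), (-100.0, 1e-8), (20.0, 5e-7), (-5.0, 1e-7),
    ])
    def test_mass_conserved_over_ten_hours(self, geometry, omega, s_sv, D):
        sol = _artificial_solute(s_sv, D)
        ss = simulate_solute(sol, geometry, omega,
                             np.linspace(0.0, 36000.0, 13))
        m = ss.total_mass()
        assert np.max(np.abs(m / m[0] - 1)) < 1e-3

    def test_no_negative_concentrations(self, geometry, omega):
        sol = _artificial_solute(60.0, 1e-9)
        ss = simulate_solute(sol, geometry, omega,
                             np.linspace(300.0, 36000.0, 10))
        assert ss.signal_matrix().min() > -1e-6

    def test_sign_symmetry_of_transport(self, geometry, omega):
        """Sedimenting and floating runs deplete the interior and pile up
        mass at opposite cell ends."""
        t = np.linspace(300.0, 20000.0, 5)
        down = simulate_solute(_artificial_solute(30.0, 1e-7), geometry,
                               omega, t).signal_matrix()[-1]
        up = simulate_solute(_artificial_solute(-30.0, 1e-7), geometry,
                             omega, t).signal_matrix()[-1]
        n = len(down)
        assert down[-n // 10:].sum() > down[: n // 10].sum()
        assert up[: n // 10].sum() > up[-n // 10:].sum()


class TestClosedFormLimits:
    def test_nondiffusing_boundary_tracks_exponential(self, geometry, omega):
        """With D -> 0 the boundary midpoint follows r = m*exp(s w^2 t) and
        the plateau follows the radial-dilution law exp(-2 s w^2 t)."""
        s = 20.0 * SVEDBERG
        sol = _artificial_solute(20.0, 1e-12)
        times = np.linspace(300.0, 3000.0, 7)
        ss = simulate_solute(sol, geometry, omega, times, cells_per_step=1.0)
        col = geometry.bottom - geometry.meniscus
        for t, sc in zip(times, ss.scans):
            plateau = np.exp(-2 * s * omega**2 * t)
            r_true = geometry.meniscus * np.exp(s * omega**2 * t)
            idx = int(np.argmax(sc.signal > plateau / 2))
            r_num = np.interp(plateau / 2,
                              sc.signal[idx - 1: idx + 1],
                              ss.radius[idx - 1: idx + 1])
            assert abs(r_num - r_true) / col < 5e-3
            mid = int(0.75 * len(ss.radius))
            assert sc.signal[mid] == pytest.approx(plateau, rel=1e-3)

    def test_long_time_profile_is_equilibrium_exponential(self, omega, water):
        """At low speed the solution relaxes to C(r) ~ exp(s w^2 r^2 / 2D),
        the sedimentation-equilibrium distribution."""
        geom = CellGeometry(meniscus=6.9, bottom=7.15)
        om = omega / 6.0  # 5 krpm
        sol = solute_from_mass(5e6, 0.96, 1.1, water)
        t_end = 4.0 * (geom.bottom - geom.meniscus) ** 2 / sol.D
        ss = simulate_solute(sol, geom, om, [0.0, t_end, 1.25 * t_end],
                             n_radial=200)
        c = ss.signal_matrix()[-1]
        r = ss.radius
        expected = np.exp(sol.s / sol.D * om**2 * r**2 / 2.0)
        expected *= c.mean() / expected.mean()
        assert np.sqrt(np.mean((c - expected) ** 2)) / c.mean() < 0.01
        # and the profile has stopped evolving
        assert np.allclose(ss.signal_matrix()[-2], c, rtol=1e-3, atol=1e-6)


class TestSuperposition:
    def test_two_identical_solutes_equal_one_with_summed_amplitude(
            self, geometry, omega, scan_times):
        sol = _artificial_solute(15.0, 1e-7)
        a = simulate_mixture([sol, sol], [0.3, 0.5], geometry, omega,
                             scan_times, n_radial=150)
        b = simulate_mixture([sol], [0.8], geometry, omega, scan_times,
                             n_radial=150)
        assert np.allclose(a.signal_matrix(), b.signal_matrix(),
                           rtol=0, atol=1e-12)

    def test_empty_mixture_is_zero(self, geometry, omega, scan_times):
        ss = simulate_mixture([], [], geometry, omega, scan_times)
        assert np.all(ss.signal_matrix() == 0)

    def test_mixed_buoyancy_sample_moves_toward_both_ends(
            self, geometry, omega):
        """A mixture straddling the solvent density shows boundaries moving
        to both cell ends in one scan set."""
        t = np.linspace(300.0, 25000.0, 6)
        ss = simulate_mixture(
            [_artificial_solute(12.0, 1e-7), _artificial_solute(-12.0, 1e-7)],
            [0.5, 0.5], geometry, omega, t, n_radial=300)
        first, last = ss.signal_matrix()[0], ss.signal_matrix()[-1]
        n = len(first)
        tenth = n // 10
        # both ends gain signal relative to the first scan, interior drains
        assert last[:tenth].mean() > first[:tenth].mean()
        assert last[-tenth:].mean() > first[-tenth:].mean()
        assert last[4 * tenth: 6 * tenth].mean() < \
            first[4 * tenth: 6 * tenth].mean()

    def test_mismatched_lengths_rejected(self, geometry, omega, scan_times):
        with pytest.raises(ValueError):
            simulate_mixture([_artificial_solute(10, 1e-7)], [0.1, 0.2],
                             geometry, omega, scan_times)


class TestNumerics:
    def test_self_convergence_under_grid_refinement(self, geometry, omega):
        """On a diffusion-resolved profile, doubling the radial resolution
        changes the solution by < 1e-3 RMS, and the change shrinks at least
        first-order under further refinement."""
        sol = _artificial_solute(10.0, 5e-7)
        t = np.linspace(300.0, 20000.0, 5)
        runs = {
            n: simulate_solute(sol, geometry, omega, t, n_radial=n,
                               cells_per_step=0.5)
            for n in (300, 600, 1200)
        }

        def diff(a, b):
            interp = np.stack([
                np.interp(runs[a].radius, runs[b].radius, row)
                for row in runs[b].signal_matrix()
            ])
            return np.sqrt(np.mean((runs[a].signal_matrix() - interp) ** 2))

        d_coarse = diff(300, 600)
        d_fine = diff(600, 1200)
        assert d_fine < 1e-3
        assert d_coarse / d_fine > 1.5


class TestScanSetValidation:
    def test_radius_must_increase(self, geometry, water_spec):
        with pytest.raises(ValueError, match="increasing"):
            ScanSet(geometry=geometry, buffer=water_spec,
                    radius=np.array([6.0, 5.9, 6.1]),
                    scans=[Scan(t=1.0, omega=3000.0, T=293.15,
                                signal=np.zeros(3))])

    def test_scan_times_must_increase(self, geometry, water_spec):
        scans = [Scan(t=10.0, omega=3000.0, T=293.15, signal=np.zeros(3)),
                 Scan(t=5.0, omega=3000.0, T=293.15, signal=np.zeros(3))]
        with pytest.raises(ValueError, match="time"):
            ScanSet(geometry=geometry, buffer=water_spec,
                    radius=np.array([5.9, 6.0, 6.1]), scans=scans)

    def test_geometry_requires_meniscus_below_bottom(self):
        with pytest.raises(ValueError):
            CellGeometry(meniscus=7.3, bottom=7.2)
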