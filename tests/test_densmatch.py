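"""Density matching: fraction integration, extrapolation, derived values."""

import numpy as np
import pandas as pd
import pytest

from sedgrid import (
    BufferSpec,
    DensityMatching,
    FitError,
    boundary_fractions,
    buffer_state,
    extrapolate_vbar,
    solute_from_mass,
    viscosity_correct,
)
from sedgrid.twodsa import FitError as TwoDSAFitError


def _buffers(fracs, increment=0.0046):
    return {
        phi: buffer_state(BufferSpec(d2o_fraction=phi,
                                     base_density_increment=increment))
        for phi in fracs
    }


class TestViscosityCorrection:
    def test_identity_when_buffers_match(self, water):
        s = np.array([-3.0, 1.0, 10.0])
        assert np.array_equal(viscosity_correct(s, water, water), s)

    def test_linear_scaling_preserves_signs(self, water):
        ref = water
        buf = type(water)(rho=water.rho, eta=1.1 * water.eta, T=water.T)
        out = viscosity_correct(np.array([-2.0, 5.0]), buf, ref)
        assert out == pytest.approx([-2.2, 5.5])

    def test_corrected_s_is_linear_in_density(self):
        """After dividing out viscosity, an ideal species' s is an exact
        linear function of solvent density across the D2O series."""
        bufs = _buffers([0.0, 0.10, 0.15, 0.20])
        ref = bufs[0.0]
        rows = []
        for phi, b in bufs.items():
            sol = solute_from_mass(2e7, 0.98, 1.1, b)
            rows.append((b.rho, viscosity_correct([sol.s], b, ref)[0]))
        rhos, s_corr = map(np.array, zip(*rows))
        slope, intercept = np.polyfit(rhos, s_corr, 1)
        resid = s_corr - (slope * rhos + intercept)
        assert np.abs(resid).max() < 1e-10 * np.abs(s_corr).max()


class TestBoundaryFractions:
    def test_single_solute_fills_every_fraction(self):
        tab = pd.DataFrame({"s_svedberg": [12.0], "amplitude": [1.0]})
        fr = boundary_fractions(tab, 5, tail_exclusion=0.0)
        assert np.allclose(fr["s_svedberg"], 12.0)
        assert fr["weight"].sum() == pytest.approx(1.0)

    def test_two_equal_solutes_split_cleanly(self):
        tab = pd.DataFrame({"s_svedberg": [50.0, 10.0],
                            "amplitude": [0.5, 0.5]})
        fr = boundary_fractions(tab, 2, tail_exclusion=0.0)
        assert fr["s_svedberg"].tolist() == [10.0, 50.0]

    def test_fraction_means_are_nondecreasing(self):
        rng = np.random.default_rng(0)
        tab = pd.DataFrame({"s_svedberg": rng.normal(5, 10, 50),
                            "amplitude": rng.uniform(0.1, 1, 50)})
        fr = boundary_fractions(tab, 10)
        assert np.all(np.diff(fr["s_svedberg"]) >= -1e-12)

    def test_weights_sum_to_analyzed_mass(self):
        tab = pd.DataFrame({"s_svedberg": np.linspace(1, 20, 30),
                            "amplitude": np.ones(30)})
        fr = boundary_fractions(tab, 8, tail_exclusion=0.02)
        assert fr["weight"].sum() == pytest.approx(0.96)

    def test_empty_distribution_rejected(self):
        with pytest.raises(TwoDSAFitError, match="empty"):
            boundary_fractions(
                pd.DataFrame({"s_svedberg": [], "amplitude": []}), 4)


class TestExtrapolation:
    def test_two_point_closed_form(self):
        """For one ideal species, vbar = (s1-s2)/(s1*rho2 - s2*rho1)."""
        bufs = _buffers([0.0, 0.20])
        ref = bufs[0.0]
        vbar_true = 0.981
        pts = []
        for phi, b in bufs.items():
            sol = solute_from_mass(3e7, vbar_true, 1.1, b)
            pts.append((b.rho, viscosity_correct([sol.s], b, ref)[0]))
        (r1, s1), (r2, s2) = pts
        closed = (s1 - s2) / (s1 * r2 - s2 * r1)
        rho_m, vbar, ok = extrapolate_vbar([r1, r2], [s1, s2])
        assert ok
        assert vbar == pytest.approx(closed, rel=1e-12)
        assert vbar == pytest.approx(vbar_true, rel=1e-10)

    def test_four_densities_crossing_to_flotation(self):
        """A species that sediments at low D2O and floats at 20% still
        extrapolates to its true vbar."""
        bufs = _buffers([0.0, 0.10, 0.15, 0.20])
        ref = bufs[0.0]
        vbar_true = 0.9805
        rhos, s_corr = [], []
        for phi, b in bufs.items():
            sol = solute_from_mass(2e7, vbar_true, 1.1, b)
            rhos.append(b.rho)
            s_corr.append(viscosity_correct([sol.s], b, ref)[0])
        assert min(s_corr) < 0 < max(s_corr)
        _, vbar, ok = extrapolate_vbar(rhos, s_corr)
        assert ok
        assert vbar == pytest.approx(vbar_true, abs=1e-10)

    def test_equal_densities_rejected(self):
        with pytest.raises(TwoDSAFitError, match="distinct"):
            extrapolate_vbar([1.0, 1.0], [5.0, 4.0])

    def test_positive_slope_flagged_unmatchable(self):
        rho_m, vbar, ok = extrapolate_vbar([1.0, 1.02], [4.0, 5.0])
        assert not ok and np.isnan(vbar)

    def test_far_crossing_flagged_unmatchable(self):
        # shallow slope -> crossing far outside plausible particle densities
        _, vbar, ok = extrapolate_vbar([1.0, 1.02], [5.0, 4.999])
        assert not ok


class TestDensityMatchingModel:
    @staticmethod
    def _tables(vbars, masses, amps, fracs):
        bufs = _buffers(fracs)
        tables = {}
        for phi, b in bufs.items():
            sols = [solute_from_mass(m, v, 1.1, b)
                    for m, v in zip(masses, vbars)]
            tables[phi] = pd.DataFrame({
                "s_svedberg": [s.s_sv for s in sols],
                "D": [s.D for s in sols],
                "amplitude": amps,
            })
        return tables, bufs

    def test_single_species_recovers_point_values(self):
        tables, bufs = self._tables([0.98], [2e7], [1.0],
                                    [0.0, 0.10, 0.15, 0.20])
        res = DensityMatching(tables, buffers=bufs).fit(n_fractions=5)
        t = res.matched
        assert len(t) == 5
        assert np.allclose(t["vbar"], 0.98, atol=1e-6)
        assert np.allclose(t["M_Da"], 2e7, rtol=1e-4)
        sol = solute_from_mass(2e7, 0.98, 1.1, bufs[0.0])
        assert np.allclose(t["Rh_nm"], sol.Rh_nm, rtol=1e-4)

    def test_three_species_mixture_recovered(self):
        vbars = [0.978, 0.981, 0.984]
        masses = [1e7, 3e7, 8e7]
        tables, bufs = self._tables(vbars, masses, [0.3, 0.4, 0.3],
                                    [0.0, 0.10, 0.15, 0.20])
        res = DensityMatching(tables, buffers=bufs).fit(
            n_fractions=6, tail_exclusion=0.0)
        t = res.matched
        assert len(t) >= 5
        assert t["vbar"].min() == pytest.approx(min(vbars), abs=5e-3)
        assert t["vbar"].max() == pytest.approx(max(vbars), abs=5e-3)

    def test_results_invariant_to_condition_order(self):
        tables, bufs = self._tables([0.98], [2e7], [1.0], [0.0, 0.15, 0.20])
        fwd = DensityMatching(tables, buffers=bufs).fit(n_fractions=4)
        rev_tables = dict(reversed(list(tables.items())))
        rev = DensityMatching(rev_tables, buffers=bufs).fit(n_fractions=4)
        pd.testing.assert_frame_equal(fwd.table, rev.table)

    def test_requires_two_conditions(self):
        tables, bufs = self._tables([0.98], [2e7], [1.0], [0.0])
        with pytest.raises(TwoDSAFitError, match=">= 2"):
            DensityMatching(tables, buffers=bufs)

    def test_summary_reports_distribution_stats(self):
        tables, bufs = self._tables([0.98], [2e7], [1.0], [0.0, 0.20])
        res = DensityMatching(tables, buffers=bufs).fit(n_fractions=4)
        s = res.summary()
        assert "vbar" in s and "Rh" in s
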