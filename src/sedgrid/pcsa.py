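"""Parametrically constrained spectrum analysis with straight-line vbar(s).

Instead of a free 2-D grid, PCSA restricts the basis to solutes lying on a
univalued functional relationship in the (s, vbar) plane -- here a straight
line vbar(s) = a + b*s.  A K x K family of candidate lines is built from
endpoint grids at s_min and s_max, each line is discretized into L solutes
and NNLS-fitted, and the line with minimal rmsd wins (deterministic argmin;
ties broken by smallest |slope|, then smallest intercept).  A second pass
refines a K x K neighbourhood of endpoint space around the winner at half
the spacing.

Because any line's solutes form a subset of a sufficiently fine 2-D custom
grid, the unconstrained custom-grid fit can never be worse than PCSA on the
same data; PCSA serves as an orthogonal, lower-variance validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import SVEDBERG
from .hydro import (
    DEFAULT_BUOYANCY_EXCLUSION,
    BuoyancyError,
    buoyancy,
    solute_from_s_vbar,
)
from .lamm import ScanSet
from .twodsa import BasisContext, FitError, GridFitResults, alternating_nnls

__all__ = ["LineFamilySpec", "PCSAModel", "PCSAResults", "compare_models",
           "ModelComparison"]


@dataclass(frozen=True)
class LineFamilySpec:
    """A family of straight lines vbar(s) over a fixed s range.

    Endpoint grids: K vbar values at s_min crossed with K vbar values at
    s_max; each line carries L solutes at evenly spaced s (Svedberg).
    """

    s_min_sv: float
    s_max_sv: float
    vbar_at_smin: tuple[float, float]
    vbar_at_smax: tuple[float, float]
    K: int = 10
    L: int = 20
    alpha: float = 1.1

    def __post_init__(self) -> None:
        if self.K < 2 or self.L < 2:
            raise ValueError("need K >= 2 endpoint points and L >= 2 solutes")
        if not self.s_min_sv < self.s_max_sv:
            raise ValueError("need s_min < s_max")


class PCSAModel:
    """Straight-line constrained spectrum model of one scan set."""

    def __init__(
        self,
        data: ScanSet,
        family: LineFamilySpec,
        fit_ti: bool = False,
        fit_ri: bool = False,
        exclusion: float = DEFAULT_BUOYANCY_EXCLUSION,
        cells_per_step: float = 2.0,
        min_steps: int = 150,
    ) -> None:
        self.data = data
        self.family = family
        self.fit_ti = fit_ti
        self.fit_ri = fit_ri
        self.exclusion = exclusion
        self.buffer = data.buffer.state()
        self.Y = data.signal_matrix()
        self.cache = BasisContext(
            data.geometry, data.omega, data.times, data.radius,
            cells_per_step=cells_per_step, min_steps=min_steps,
        )

    def _line_solutes(self, v0: float, v1: float):
        """Solutes along the line through (s_min, v0), (s_max, v1); None if
        any point violates the buoyancy sign/exclusion rule."""
        fam = self.family
        s_pts = np.linspace(fam.s_min_sv, fam.s_max_sv, fam.L) * SVEDBERG
        slope = (v1 - v0) / ((fam.s_max_sv - fam.s_min_sv) * SVEDBERG)
        sols = []
        for s in s_pts:
            v = v0 + slope * (s - fam.s_min_sv * SVEDBERG)
            b = buoyancy(v, self.buffer.rho)
            if abs(b) < self.exclusion or s * b <= 0:
                return None
            try:
                sols.append(solute_from_s_vbar(s, v, fam.alpha, self.buffer,
                                               exclusion=self.exclusion))
            except BuoyancyError:
                return None
        return sols

    def _fit_line(self, v0: float, v1: float):
        sols = self._line_solutes(v0, v1)
        if sols is None:
            return None
        A = self.cache.design_matrix(sols)
        amps, ti, ri, rmsd, _ = alternating_nnls(
            A, self.Y, self.fit_ti, self.fit_ri)
        return sols, amps, ti, ri, rmsd

    def _sweep(self, v0_grid: np.ndarray, v1_grid: np.ndarray):
        rows = []
        best = None
        for v0 in v0_grid:
            for v1 in v1_grid:
                out = self._fit_line(v0, v1)
                if out is None:
                    rows.append((v0, v1, np.nan))
                    continue
                sols, amps, ti, ri, rmsd = out
                rows.append((v0, v1, rmsd))
                fam = self.family
                slope_sv = (v1 - v0) / (fam.s_max_sv - fam.s_min_sv)
                intercept = v0 - slope_sv * fam.s_min_sv
                key = (rmsd, abs(slope_sv), intercept)
                if best is None or key < best[0]:
                    best = (key, (v0, v1, sols, amps, ti, ri, rmsd))
        return best, rows

    def fit(self, refine: bool = True) -> "PCSAResults":
        """Evaluate the K x K line family (plus one refinement pass)."""
        fam = self.family
        v0_grid = np.linspace(*fam.vbar_at_smin, fam.K)
        v1_grid = np.linspace(*fam.vbar_at_smax, fam.K)
        best, rows = self._sweep(v0_grid, v1_grid)
        if best is None:
            raise FitError(
                "no candidate line is buoyancy-valid for this buffer/family")
        if refine:
            dv0 = (v0_grid[-1] - v0_grid[0]) / (fam.K - 1)
            dv1 = (v1_grid[-1] - v1_grid[0]) / (fam.K - 1)
            v0c, v1c = best[1][0], best[1][1]
            r0 = np.linspace(v0c - dv0, v0c + dv0, fam.K)
            r1 = np.linspace(v1c - dv1, v1c + dv1, fam.K)
            best2, rows2 = self._sweep(r0, r1)
            if best2 is not None and best2[0] <= best[0]:
                best = best2
            rows = rows + rows2
        v0, v1, sols, amps, ti, ri, rmsd = best[1]
        slope_sv = (v1 - v0) / (fam.s_max_sv - fam.s_min_sv)
        intercept = v0 - slope_sv * fam.s_min_sv
        return PCSAResults(
            model=self, solutes=sols, amplitudes=amps, ti_noise=ti,
            ri_noise=ri, rmsd=rmsd, vbar_endpoints=(v0, v1),
            intercept=intercept, slope_per_sv=slope_sv,
            candidates=pd.DataFrame(rows, columns=["vbar_at_smin",
                                                   "vbar_at_smax", "rmsd"]),
        )


@dataclass
class PCSAResults:
    """Winning line + its fitted spectrum."""

    model: PCSAModel
    solutes: list
    amplitudes: np.ndarray
    ti_noise: np.ndarray
    ri_noise: np.ndarray
    rmsd: float
    vbar_endpoints: tuple[float, float]
    intercept: float
    slope_per_sv: float
    candidates: pd.DataFrame = field(repr=False, default=None)

    @property
    def nonzero(self) -> pd.DataFrame:
        keep = self.amplitudes > 0
        sols = [s for s, k in zip(self.solutes, keep) if k]
        return pd.DataFrame(
            {
                "s_svedberg": [s.s / SVEDBERG for s in sols],
                "vbar": [s.vbar for s in sols],
                "D": [s.D for s in sols],
                "M": [s.M for s in sols],
                "Rh_nm": [s.Rh_nm for s in sols],
                "amplitude": self.amplitudes[keep],
            }
        ).sort_values("s_svedberg", ignore_index=True)

    @property
    def total_signal(self) -> float:
        return float(self.amplitudes.sum())

    def vbar_of_s(self, s_sv) -> np.ndarray:
        """Evaluate the winning line vbar(s) at s in Svedberg."""
        return self.intercept + self.slope_per_sv * np.asarray(s_sv)

    def summary(self) -> str:
        return "\n".join([
            "PCSA straight-line spectrum fit",
            "=" * 64,
            f"line: vbar(s) = {self.intercept:.6f} "
            f"{self.slope_per_sv:+.3e} * s[S]",
            f"endpoints: vbar({self.model.family.s_min_sv:g} S) = "
            f"{self.vbar_endpoints[0]:.6f}, "
            f"vbar({self.model.family.s_max_sv:g} S) = "
            f"{self.vbar_endpoints[1]:.6f}",
            f"rmsd: {self.rmsd:.6g}   total signal: {self.total_signal:.5g}",
            f"non-zero solutes: {int((self.amplitudes > 0).sum())} "
            f"of {len(self.solutes)}",
        ])


def _s_histogram(tab: pd.DataFrame, edges: np.ndarray) -> np.ndarray:
    h, _ = np.histogram(tab["s_svedberg"], bins=edges, weights=tab["amplitude"])
    return h


@dataclass
class ModelComparison:
    """Custom-grid vs PCSA comparison on the same data."""

    rmsd_cg: float
    rmsd_pcsa: float
    s_edges: np.ndarray
    s_hist_cg: np.ndarray
    s_hist_pcsa: np.ndarray
    scatter_cg: pd.DataFrame
    scatter_pcsa: pd.DataFrame

    @property
    def rmsd_ratio(self) -> float:
        return self.rmsd_cg / self.rmsd_pcsa

    @property
    def distribution_distance(self) -> float:
        """Integrated |difference| of the s-distributions over total signal."""
        total = max(self.s_hist_cg.sum(), self.s_hist_pcsa.sum(), 1e-300)
        return float(np.abs(self.s_hist_cg - self.s_hist_pcsa).sum() / total)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        mid = 0.5 * (self.s_edges[:-1] + self.s_edges[1:])
        ax.plot(mid, self.s_hist_cg, color="C0", label="custom grid")
        ax.plot(mid, self.s_hist_pcsa, color="C3", label="PCSA")
        ax.set_xlabel("s [S]")
        ax.set_ylabel("signal")
        ax.legend()
        return ax


def compare_models(
    cg: GridFitResults, pcsa: PCSAResults, n_bins: int = 60
) -> ModelComparison:
    """Overlay the two estimators fitted to the same scan set."""
    if cg.model.data is not pcsa.model.data:
        same = (
            cg.model.data.radius.shape == pcsa.model.data.radius.shape
            and np.array_equal(cg.model.data.radius, pcsa.model.data.radius)
            and np.array_equal(cg.model.data.signal_matrix(),
                               pcsa.model.data.signal_matrix())
        )
        if not same:
            raise FitError("models were fitted to different data")
    t_cg = cg.nonzero
    t_p = pcsa.nonzero
    lo = min(t_cg["s_svedberg"].min(), t_p["s_svedberg"].min())
    hi = max(t_cg["s_svedberg"].max(), t_p["s_svedberg"].max())
    pad = 0.02 * (hi - lo) if hi > lo else 1.0
    edges = np.linspace(lo - pad, hi + pad, n_bins + 1)
    return ModelComparison(
        rmsd_cg=cg.rmsd,
        rmsd_pcsa=pcsa.rmsd,
        s_edges=edges,
        s_hist_cg=_s_histogram(t_cg, edges),
        s_hist_pcsa=_s_histogram(t_p, edges),
        scatter_cg=t_cg[["s_svedberg", "vbar", "amplitude"]],
        scatter_pcsa=t_p[["s_svedberg", "vbar", "amplitude"]],
    )
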