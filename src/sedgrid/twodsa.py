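"""Two-dimensional spectrum analysis over a custom grid.

Fits a sedimentation-velocity scan set as a non-negative linear combination
of simulated single-solute Lamm solutions (one per grid solute), optionally
with time-invariant (per-radius) and radially-invariant (per-scan) noise
vectors, iterative subgrid refinement, meniscus/bottom refinement, and a
Monte Carlo error analysis.

The public surface follows the Model/Results convention: build a
:class:`CustomGridModel` from a :class:`~sedgrid.lamm.ScanSet` and a
:class:`~sedgrid.grids.CombinedGrid`, call :meth:`~CustomGridModel.fit`, and
inspect the returned :class:`GridFitResults` (amplitudes, noise vectors,
rmsd, ``summary()``, diagnostics, ``monte_carlo()``).

Identifiability: a constant offset can be moved freely between the TI and RI
vectors, so the RI vector is constrained to zero mean with the offset
absorbed into the TI vector.  This changes the noise vectors, never the
modeled signal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .constants import SVEDBERG
from .grids import CombinedGrid, partition_for_refinement
from .lamm import CellGeometry, ScanSet, lamm_basis

__all__ = ["CustomGridModel", "GridFitResults", "MCEnsemble", "BasisContext",
           "alternating_nnls", "FitError"]


class FitError(RuntimeError):
    """Spectrum fit failure (dimension mismatch, non-convergence...)."""


class BasisContext:
    """Cache of simulated basis Lamm solutions for one data context.

    Keyed by (solute s, D) within a fixed (geometry, omega, times, radii);
    basis columns are simulated on demand in batches and retained, so
    repeated fits (refinement rounds, Monte Carlo iterations) never
    re-simulate a solute.
    """

    def __init__(
        self,
        geometry: CellGeometry,
        omega: float,
        times: np.ndarray,
        radii: np.ndarray,
        cells_per_step: float = 2.0,
        min_steps: int = 150,
        n_radial: int | None = None,
    ) -> None:
        self.geometry = geometry
        self.omega = float(omega)
        self.times = np.asarray(times, dtype=float)
        self.radii = np.asarray(radii, dtype=float)
        self.cells_per_step = cells_per_step
        self.min_steps = min_steps
        self.n_radial = n_radial or max(400, 2 * len(self.radii))
        self._columns: dict[tuple[float, float], np.ndarray] = {}

    def design_matrix(self, solutes) -> np.ndarray:
        """(n_scans*n_radii, n_solutes) matrix of unit-loading solutions."""
        missing = [sol for sol in solutes if (sol.s, sol.D) not in self._columns]
        if missing:
            _, prof = lamm_basis(
                missing, self.geometry, self.omega, self.times,
                radii=self.radii, n_radial=self.n_radial,
                cells_per_step=self.cells_per_step, min_steps=self.min_steps,
            )
            for sol, p in zip(missing, prof):
                self._columns[(sol.s, sol.D)] = p.ravel()
        return np.column_stack([self._columns[(s.s, s.D)] for s in solutes])


def _runs_zscores(resid: np.ndarray) -> np.ndarray:
    """Wald-Wolfowitz runs z-score of the residual signs, per scan.

    Near-zero values indicate pattern-free (random) residuals; large
    negative values indicate systematic stripes (too few sign runs).
    """
    out = []
    for row in resid:
        signs = np.sign(row)
        signs = signs[signs != 0]
        n1 = int(np.sum(signs > 0))
        n2 = int(np.sum(signs < 0))
        n = n1 + n2
        if n1 == 0 or n2 == 0 or n < 10:
            out.append(0.0)
            continue
        runs = 1 + int(np.sum(signs[1:] != signs[:-1]))
        mu = 2.0 * n1 * n2 / n + 1.0
        var = 2.0 * n1 * n2 * (2.0 * n1 * n2 - n) / (n**2 * (n - 1.0))
        out.append((runs - mu) / np.sqrt(var) if var > 0 else 0.0)
    return np.array(out)


def alternating_nnls(
    A: np.ndarray,
    Y: np.ndarray,
    fit_ti: bool = False,
    fit_ri: bool = False,
    rmsd_tol: float = 1e-6,
    max_rounds: int = 20,
    polish_tol: float = 1e-5,
):
    """Non-negative spectrum fit with optional TI/RI noise decomposition.

    Alternates (1) NNLS on the noise-corrected data, (2) TI = per-radius mean
    of the residuals, (3) RI = per-scan mean of the TI-removed residuals,
    re-centred to zero mean with the offset absorbed into TI, until the rmsd
    change falls below ``rmsd_tol`` (at most ``max_rounds`` rounds; a single
    NNLS when both noise flags are off).  A final polish refits the pruned
    support, removing sub-ppm amplitude leakage between nearly collinear
    columns.

    Returns ``(amplitudes, ti, ri, rmsd, n_rounds)``.
    """

    def _nnls(M, y):
        try:
            x, _ = nnls(M, y)
        except RuntimeError as exc:  # pragma: no cover
            raise FitError(f"NNLS failed to converge: {exc}") from exc
        return x

    n_scans, n_r = Y.shape
    ti = np.zeros(n_r)
    ri = np.zeros(n_scans)
    prev_rmsd = np.inf
    rounds = max_rounds if (fit_ti or fit_ri) else 1
    for rnd in range(rounds):
        Yc = Y - ti[None, :] - ri[:, None]
        amps = _nnls(A, Yc.ravel())
        pred = (A @ amps).reshape(n_scans, n_r)
        R = Y - pred
        if fit_ti:
            ti = R.mean(axis=0)
        if fit_ri:
            ri = (R - ti[None, :]).mean(axis=1)
            offset = ri.mean()
            ri = ri - offset
            if fit_ti:
                ti = ti + offset
        resid = R - ti[None, :] - ri[:, None]
        rmsd = float(np.sqrt(np.mean(resid**2)))
        if abs(prev_rmsd - rmsd) < rmsd_tol:
            prev_rmsd = rmsd
            break
        prev_rmsd = rmsd
    total = amps.sum()
    if total > 0:
        keep = amps > polish_tol * total
        if keep.any() and not keep.all():
            amps2 = np.zeros_like(amps)
            Yc = Y - ti[None, :] - ri[:, None]
            amps2[keep] = _nnls(A[:, keep], Yc.ravel())
            pred = (A @ amps2).reshape(n_scans, n_r)
            resid = Y - pred - ti[None, :] - ri[:, None]
            rmsd2 = float(np.sqrt(np.mean(resid**2)))
            if rmsd2 <= prev_rmsd * (1 + 1e-9) or rmsd2 < prev_rmsd + 1e-12:
                amps, prev_rmsd = amps2, min(rmsd2, prev_rmsd)
    return amps, ti, ri, prev_rmsd, rnd + 1


class CustomGridModel:
    """NNLS spectrum model of one scan set over a combined custom grid.

    Parameters
    ----------
    data : ScanSet
        The experiment to fit.
    grid : CombinedGrid
        Basis solutes; must have been built for the data's buffer.
    fit_ti, fit_ri : bool
        Estimate time-invariant / radially-invariant noise vectors jointly
        with the spectrum (RI requires >= 3 scans).
    cache : BasisContext, optional
        Shared basis cache; by default a fresh one per model.
    """

    def __init__(
        self,
        data: ScanSet,
        grid: CombinedGrid,
        fit_ti: bool = False,
        fit_ri: bool = False,
        cells_per_step: float = 2.0,
        min_steps: int = 150,
        cache: BasisContext | None = None,
    ) -> None:
        if len(grid) == 0:
            raise FitError("empty grid")
        if fit_ri and len(data.scans) < 3:
            raise FitError("radially-invariant noise requires at least 3 scans")
        self.data = data
        self.grid = grid
        self.fit_ti = fit_ti
        self.fit_ri = fit_ri
        self.Y = data.signal_matrix()
        self.cache = cache or BasisContext(
            data.geometry, data.omega, data.times, data.radius,
            cells_per_step=cells_per_step, min_steps=min_steps,
        )
        self._cells_per_step = cells_per_step
        self._min_steps = min_steps

    # ---------------------------------------------------------------- core
    def _fit_subset(
        self, indices: np.ndarray, Y: np.ndarray, cache: BasisContext | None = None
    ):
        """Alternating NNLS + TI/RI estimation on a solute subset.

        Returns (amplitudes, ti, ri, rmsd, n_rounds).
        """
        cache = cache or self.cache
        solutes = self.grid.subset(indices)
        A = cache.design_matrix(solutes)
        return alternating_nnls(A, Y, self.fit_ti, self.fit_ri)

    # ----------------------------------------------------------------- fit
    def fit(
        self,
        method: str = "nnls",
        n_partitions: int | None = None,
        max_rounds: int = 5,
        amplitude_tol: float = 1e-10,
    ) -> "GridFitResults":
        """Fit the spectrum.

        method="nnls": one NNLS over the whole grid.
        method="iterative": partition the grid into coarse interleaved
        subgrids, fit them in sequence while carrying the accumulated
        non-zero solute set, and sweep until the set stops changing (or
        ``max_rounds``); memory-bounded equivalent of the full fit.
        """
        if method not in ("nnls", "iterative"):
            raise FitError(f"unknown method {method!r}")
        prov: dict = {"method": method, "fit_ti": self.fit_ti,
                      "fit_ri": self.fit_ri}
        if method == "nnls" or (n_partitions or 1) == 1:
            indices = np.arange(len(self.grid))
            amps, ti, ri, rmsd, rounds = self._fit_subset(indices, self.Y)
            prov["noise_rounds"] = rounds
            return self._results(indices, amps, ti, ri, rmsd, prov)

        n_partitions = n_partitions or max(1, len(self.grid) // 300)
        parts = partition_for_refinement(self.grid, n_partitions)
        prov["n_partitions"] = len(parts)
        support: np.ndarray = np.array([], dtype=np.int64)
        history = []
        last = None
        for sweep in range(max_rounds):
            prev_support = set(support.tolist())
            for p in parts:
                indices = np.union1d(support, p)
                amps, ti, ri, rmsd, _ = self._fit_subset(indices, self.Y)
                keep = amps > amplitude_tol * max(amps.max(), 1e-300)
                support = indices[keep]
                last = (indices, amps, ti, ri, rmsd)
                history.append(rmsd)
            if set(support.tolist()) == prev_support:
                break
        prov["sweeps"] = sweep + 1
        prov["rmsd_history"] = history
        indices, amps, ti, ri, rmsd = last
        return self._results(indices, amps, ti, ri, rmsd, prov)

    def fit_boundary(
        self,
        meniscus_range: tuple[float, float] | None = None,
        bottom_range: tuple[float, float] | None = None,
        n_candidates: int = 5,
        method: str = "nnls",
        **fit_kw,
    ) -> "GridFitResults":
        """Refine meniscus and/or bottom by rmsd grid search.

        Fits the full model at each candidate position, locates the rmsd
        minimum, refines it by parabolic interpolation through the three
        bracketing candidates, and returns the fit at the refined geometry.
        A minimum on a range edge is flagged as not bracketed in the
        provenance (``meniscus_bracketed`` / ``bottom_bracketed``).
        """
        r = self.data.radius
        geom = self.data.geometry
        prov_flags = {}

        def _fit_at(m: float, b: float):
            g = CellGeometry(meniscus=m, bottom=b,
                             sector_angle=geom.sector_angle,
                             pathlength=geom.pathlength)
            mask = (r >= m) & (r <= b)
            cache = BasisContext(
                g, self.data.omega, self.data.times, r[mask],
                cells_per_step=self._cells_per_step,
                min_steps=self._min_steps,
            )
            saved = (self.cache, self.Y)
            self.cache, self.Y = cache, self.data.signal_matrix()[:, mask]
            try:
                indices = np.arange(len(self.grid))
                amps, ti, ri, rmsd, _ = self._fit_subset(indices, self.Y, cache)
            finally:
                self.cache, self.Y = saved
            return rmsd

        def _search(axis: str, lo: float, hi: float, other: float):
            if axis == "meniscus":
                if not (r[0] - 0.05 <= lo and hi < other):
                    raise FitError("meniscus range outside the data's radial span")
                cand = np.linspace(lo, hi, n_candidates)
                rmsds = np.array([_fit_at(m, other) for m in cand])
            else:
                if not (other < lo and hi <= r[-1] + 0.05):
                    raise FitError("bottom range outside the data's radial span")
                cand = np.linspace(lo, hi, n_candidates)
                rmsds = np.array([_fit_at(other, b) for b in cand])
            k = int(np.argmin(rmsds))
            bracketed = 0 < k < n_candidates - 1
            if bracketed:
                x0, x1, x2 = cand[k - 1: k + 2]
                y0, y1, y2 = rmsds[k - 1: k + 2]
                denom = (y0 - 2 * y1 + y2)
                best = x1 if denom <= 0 else x1 + 0.5 * (x1 - x0) * (y0 - y2) / denom
                best = min(max(best, x0), x2)
            else:
                best = cand[k]
            return best, bracketed, cand, rmsds

        m_best, b_best = geom.meniscus, geom.bottom
        if meniscus_range is not None:
            m_best, brk, cand, rmsds = _search(
                "meniscus", *meniscus_range, b_best)
            prov_flags["meniscus_bracketed"] = brk
            prov_flags["meniscus_candidates"] = cand.tolist()
            prov_flags["meniscus_rmsds"] = rmsds.tolist()
        if bottom_range is not None:
            b_best, brk, cand, rmsds = _search("bottom", *bottom_range, m_best)
            prov_flags["bottom_bracketed"] = brk

        # final fit at the refined geometry
        g = CellGeometry(meniscus=m_best, bottom=b_best,
                         sector_angle=geom.sector_angle,
                         pathlength=geom.pathlength)
        mask = (r >= m_best) & (r <= b_best)
        cache = BasisContext(
            g, self.data.omega, self.data.times, r[mask],
            cells_per_step=self._cells_per_step, min_steps=self._min_steps,
        )
        saved = (self.cache, self.Y)
        self.cache, self.Y = cache, self.data.signal_matrix()[:, mask]
        try:
            res = self.fit(method=method, **fit_kw)
        finally:
            self.cache, self.Y = saved
        res.meniscus = m_best
        res.bottom = b_best
        res.provenance.update(prov_flags)
        res._radial_mask = mask
        return res

    # -------------------------------------------------------------- helpers
    def _results(self, indices, amps, ti, ri, rmsd, prov) -> "GridFitResults":
        return GridFitResults(
            model=self,
            fitted_indices=np.asarray(indices, dtype=np.int64),
            fitted_amplitudes=np.asarray(amps, dtype=float),
            ti_noise=ti,
            ri_noise=ri,
            rmsd=rmsd,
            meniscus=self.data.geometry.meniscus,
            bottom=self.data.geometry.bottom,
            provenance=prov,
        )


@dataclass
class GridFitResults:
    """Fitted spectrum: non-negative amplitudes over grid solutes + noise."""

    model: CustomGridModel
    fitted_indices: np.ndarray
    fitted_amplitudes: np.ndarray
    ti_noise: np.ndarray
    ri_noise: np.ndarray
    rmsd: float
    meniscus: float
    bottom: float
    provenance: dict = field(default_factory=dict)
    _radial_mask: np.ndarray | None = None
    _masked_cache: BasisContext | None = None

    # ------------------------------------------------------------ accessors
    @property
    def grid(self) -> CombinedGrid:
        return self.model.grid

    @property
    def amplitudes(self) -> np.ndarray:
        """Amplitudes over the *full* grid (zeros off the fitted subset)."""
        full = np.zeros(len(self.grid))
        full[self.fitted_indices] = self.fitted_amplitudes
        return full

    @property
    def nonzero(self) -> pd.DataFrame:
        """Table of solutes carrying signal, in reporting units."""
        amps = self.fitted_amplitudes
        keep = amps > 0
        sols = self.grid.subset(self.fitted_indices[keep])
        return pd.DataFrame(
            {
                "s_svedberg": [s.s / SVEDBERG for s in sols],
                "vbar": [s.vbar for s in sols],
                "D": [s.D for s in sols],
                "M": [s.M for s in sols],
                "Rh_nm": [s.Rh_nm for s in sols],
                "amplitude": amps[keep],
            }
        ).sort_values("s_svedberg", ignore_index=True)

    @property
    def total_signal(self) -> float:
        return float(self.fitted_amplitudes.sum())

    def predicted(self, include_noise: bool = True) -> np.ndarray:
        """Modeled scans (n_scans, n_radii); optionally + TI/RI vectors."""
        solutes = self.grid.subset(self.fitted_indices)
        A = self._cache().design_matrix(solutes)
        pred = (A @ self.fitted_amplitudes).reshape(self._Y().shape)
        if include_noise:
            pred = pred + self.ti_noise[None, :] + self.ri_noise[:, None]
        return pred

    def residuals(self) -> np.ndarray:
        return self._Y() - self.predicted()

    def _cache(self) -> BasisContext:
        if self._radial_mask is None:
            return self.model.cache
        if self._masked_cache is None:
            g = CellGeometry(meniscus=self.meniscus, bottom=self.bottom,
                             sector_angle=self.model.data.geometry.sector_angle,
                             pathlength=self.model.data.geometry.pathlength)
            self._masked_cache = BasisContext(
                g, self.model.data.omega, self.model.data.times,
                self.model.data.radius[self._radial_mask],
                cells_per_step=self.model._cells_per_step,
                min_steps=self.model._min_steps,
            )
        return self._masked_cache

    def _Y(self) -> np.ndarray:
        Y = self.model.data.signal_matrix()
        if self._radial_mask is not None:
            Y = Y[:, self._radial_mask]
        return Y

    # ---------------------------------------------------------- diagnostics
    def runs_zscores(self) -> np.ndarray:
        """Per-scan runs-randomness z-scores of the residuals."""
        return _runs_zscores(self.residuals())

    def s_distribution(
        self, bins: np.ndarray | None = None, weights: np.ndarray | None = None
    ) -> pd.DataFrame:
        """Amplitude vs sedimentation coefficient (Svedberg)."""
        tab = self.nonzero
        if bins is None:
            return tab[["s_svedberg", "amplitude"]]
        hist, edges = np.histogram(
            tab["s_svedberg"], bins=bins,
            weights=weights if weights is not None else tab["amplitude"],
        )
        mid = 0.5 * (edges[:-1] + edges[1:])
        return pd.DataFrame({"s_svedberg": mid, "amplitude": hist})

    def summary(self) -> str:
        tab = self.nonzero
        lines = [
            "Custom-grid spectrum fit",
            "=" * 64,
            f"scans: {len(self.model.data.scans)}   "
            f"radial points: {self._Y().shape[1]}   "
            f"grid solutes: {len(self.grid)}",
            f"meniscus: {self.meniscus:.4f} cm   bottom: {self.bottom:.4f} cm",
            f"TI noise: {self.model.fit_ti}   RI noise: {self.model.fit_ri}",
            f"rmsd: {self.rmsd:.6g}   total signal: {self.total_signal:.5g}",
            f"non-zero solutes: {len(tab)}",
            "-" * 64,
        ]
        show = tab.sort_values("amplitude", ascending=False).head(12)
        lines.append(f"{'s [S]':>9} {'vbar':>8} {'M [Da]':>11} "
                     f"{'Rh [nm]':>8} {'signal':>10} {'%':>6}")
        for _, row in show.iterrows():
            lines.append(
                f"{row.s_svedberg:9.3f} {row.vbar:8.4f} {row.M:11.3e} "
                f"{row.Rh_nm:8.2f} {row.amplitude:10.4g} "
                f"{100 * row.amplitude / max(self.total_signal, 1e-300):6.2f}"
            )
        return "\n".join(lines)

    # -------------------------------------------------------------- exports
    def to_dict(self) -> dict:
        idx = self.fitted_indices
        amps = self.fitted_amplitudes
        keep = amps > 0
        sols = self.grid.subset(idx[keep])
        return {
            "rmsd": self.rmsd,
            "meniscus": self.meniscus,
            "bottom": self.bottom,
            "ti_noise": self.ti_noise.tolist(),
            "ri_noise": self.ri_noise.tolist(),
            "solutes": [
                {"s_svedberg": s.s / SVEDBERG, "vbar": s.vbar,
                 "alpha": s.alpha, "D": s.D, "M": s.M, "Rh_nm": s.Rh_nm,
                 "amplitude": float(a)}
                for s, a in zip(sols, amps[keep])
            ],
            "provenance": {
                k: v for k, v in self.provenance.items()
                if isinstance(v, (int, float, str, bool, list))
            },
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    # --------------------------------------------------------------- plots
    def plot_fit(self, ax=None, stride: int = 1):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        r = self.model.data.radius
        if self._radial_mask is not None:
            r = r[self._radial_mask]
        pred = self.predicted()
        for y, p in zip(self._Y()[::stride], pred[::stride]):
            ax.plot(r, y, lw=0.6, color="0.4")
            ax.plot(r, p, lw=0.9, color="C3")
        ax.set_xlabel("radius [cm]")
        ax.set_ylabel("signal")
        return ax

    def plot_residual_bitmap(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        res = self.residuals()
        lim = 3 * self.rmsd if self.rmsd > 0 else 1e-9
        ax.imshow(res, aspect="auto", cmap="gray", vmin=-lim, vmax=lim)
        ax.set_xlabel("radial index")
        ax.set_ylabel("scan")
        return ax

    # ---------------------------------------------------------- monte carlo
    def monte_carlo(
        self, n_iterations: int = 100, seed: int = 0,
        noise: str = "gaussian",
    ) -> "MCEnsemble":
        """Monte Carlo error analysis.

        Each iteration builds synthetic data = fitted model prediction plus
        noise with sigma equal to the fit rmsd -- i.i.d. Gaussian by default,
        or resampled residuals (``noise="residuals"``) -- and refits the same
        solute basis.  Deterministic for a given seed.
        """
        if n_iterations < 2:
            raise FitError("Monte Carlo requires at least 2 iterations")
        if noise not in ("gaussian", "residuals"):
            raise FitError(f"unknown noise model {noise!r}")
        rng = np.random.default_rng(seed)
        base = self.predicted(include_noise=True)
        resid = self.residuals().ravel()
        models = []
        mdl = self.model
        saved_Y = mdl.Y
        saved_cache = mdl.cache
        mdl.cache = self._cache()
        try:
            for it in range(n_iterations):
                if noise == "gaussian":
                    eps = rng.normal(0.0, self.rmsd, size=base.shape)
                else:
                    eps = rng.choice(resid, size=base.shape, replace=True)
                mdl.Y = base + eps
                amps, ti, ri, rmsd, _ = mdl._fit_subset(
                    self.fitted_indices, mdl.Y)
                models.append(
                    GridFitResults(
                        model=mdl, fitted_indices=self.fitted_indices,
                        fitted_amplitudes=amps, ti_noise=ti, ri_noise=ri,
                        rmsd=rmsd, meniscus=self.meniscus, bottom=self.bottom,
                        provenance={"mc_iteration": it, "seed": seed},
                        _radial_mask=self._radial_mask,
                    )
                )
        finally:
            mdl.Y = saved_Y
            mdl.cache = saved_cache
        return MCEnsemble(reference=self, models=models, seed=seed)


@dataclass
class MCEnsemble:
    """Monte Carlo ensemble of refitted spectra sharing grid and geometry."""

    reference: GridFitResults
    models: list[GridFitResults]
    seed: int

    def __len__(self) -> int:
        return len(self.models)

    def amplitude_matrix(self) -> np.ndarray:
        """(n_iterations, n_basis) fitted amplitudes."""
        return np.stack([m.fitted_amplitudes for m in self.models])

    def amplitude_stats(self) -> pd.DataFrame:
        amp = self.amplitude_matrix()
        sols = self.reference.grid.subset(self.reference.fitted_indices)
        return pd.DataFrame(
            {
                "s_svedberg": [s.s / SVEDBERG for s in sols],
                "vbar": [s.vbar for s in sols],
                "mean": amp.mean(axis=0),
                "sd": amp.std(axis=0, ddof=1),
                "p2.5": np.percentile(amp, 2.5, axis=0),
                "p97.5": np.percentile(amp, 97.5, axis=0),
            }
        )

    def weighted_mean(self, attr: str = "s_sv") -> tuple[float, float]:
        """Ensemble mean and sd of the signal-weighted mean of a solute
        attribute (default: sedimentation coefficient in Svedberg)."""
        sols = self.reference.grid.subset(self.reference.fitted_indices)
        vals = np.array([getattr(s, attr) for s in sols])
        amp = self.amplitude_matrix()
        w = amp.sum(axis=1)
        means = (amp @ vals) / np.where(w > 0, w, np.nan)
        return float(np.nanmean(means)), float(np.nanstd(means, ddof=1))

    def solute_table(self) -> pd.DataFrame:
        """Ensemble-pooled (solute, amplitude) rows for distribution work.

        Amplitudes are averaged across iterations, which is how the ensemble
        enters the density-matching integration.
        """
        amp = self.amplitude_matrix().mean(axis=0)
        sols = self.reference.grid.subset(self.reference.fitted_indices)
        keep = amp > 0
        return pd.DataFrame(
            {
                "s_svedberg": np.array([s.s / SVEDBERG for s in sols])[keep],
                "vbar": np.array([s.vbar for s in sols])[keep],
                "D": np.array([s.D for s in sols])[keep],
                "amplitude": amp[keep],
            }
        ).sort_values("s_svedberg", ignore_index=True)
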