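"""Density matching: vbar, molar mass and Rh distributions from D2O series.

Sedimentation experiments at several solvent densities (graded D2O) are
combined per *boundary fraction*: the fitted sedimentation-coefficient
distribution of each condition is integrated into cumulative-signal
quantile slices, and corresponding slices are paired across conditions by
quantile rank (assuming the species order in s is preserved across
densities, which holds exactly when species share vbar and approximately for
narrow vbar distributions).  Each fraction's viscosity-corrected mean s is
regressed on solvent density; the zero crossing identifies the density that
matches the analyte, i.e. rho_m = 1/vbar.

The viscosity correction s' = s * eta/eta_ref removes the only other
solvent dependence of s, so for an ideal species s' is exactly linear in
rho (Svedberg relation: s' proportional to 1 - vbar*rho).  The solvent
*density* is deliberately not corrected for -- it is the abscissa of the
extrapolation.

Molar mass and hydrodynamic radius then follow from the reference-condition
(default: lowest density, largest |s| signal) fit: M = s*R*T/(D*(1-vbar*rho))
and Rh = f/(6*pi*eta) with f = RT/(N*D).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import N_AVOGADRO, R_GAS, SVEDBERG
from .hydro import (
    DEFAULT_BUOYANCY_EXCLUSION,
    BufferState,
    D_from_s_alpha_vbar,
    buoyancy,
)
from .twodsa import FitError, GridFitResults, MCEnsemble

__all__ = [
    "DensityMatching",
    "DensityMatchResults",
    "viscosity_correct",
    "boundary_fractions",
    "extrapolate_vbar",
]


def viscosity_correct(
    s_values, buffer: BufferState, reference: BufferState
) -> np.ndarray:
    """Scale sedimentation coefficients by eta_buffer/eta_reference.

    Signs are preserved; densities are untouched by design (see module
    docstring).
    """
    return np.asarray(s_values, dtype=float) * (buffer.eta / reference.eta)


def boundary_fractions(
    table: pd.DataFrame,
    n_fractions: int,
    tail_exclusion: float = 0.02,
    value_columns: tuple[str, ...] = ("s_svedberg",),
) -> pd.DataFrame:
    """Split a discrete s-distribution into equal-signal quantile slices.

    ``table`` needs columns ``s_svedberg`` and ``amplitude`` (plus any extra
    ``value_columns`` to average, e.g. ``D``).  Solutes are ordered by signed
    s; the central (1 - 2*tail_exclusion) cumulative-signal mass is cut into
    ``n_fractions`` equal-weight slices; point masses straddling a cut are
    split exactly.  Returns one row per fraction with the signal-weighted
    mean of each value column and the slice weight.
    """
    if n_fractions < 2:
        raise FitError("need at least 2 boundary fractions")
    if not 0.0 <= tail_exclusion < 0.5:
        raise FitError("tail_exclusion must be in [0, 0.5)")
    tab = table.sort_values("s_svedberg", kind="stable", ignore_index=True)
    w = tab["amplitude"].to_numpy(dtype=float)
    if len(w) == 0 or w.sum() <= 0:
        raise FitError("empty sedimentation distribution")
    vals = {c: tab[c].to_numpy(dtype=float) for c in value_columns}
    total = w.sum()
    lo = tail_exclusion * total
    hi = (1.0 - tail_exclusion) * total
    cuts = np.linspace(lo, hi, n_fractions + 1)
    cum_hi = np.cumsum(w)
    cum_lo = cum_hi - w
    rows = []
    for j in range(n_fractions):
        a, b = cuts[j], cuts[j + 1]
        # overlap of each point mass [cum_lo, cum_hi] with the slice [a, b]
        ov = np.clip(np.minimum(cum_hi, b) - np.maximum(cum_lo, a), 0.0, None)
        wsum = ov.sum()
        row = {"fraction": j,
               "quantile": 0.5 * (a + b) / total,
               "weight": wsum / total}
        for c in value_columns:
            row[c] = float(ov @ vals[c] / wsum) if wsum > 0 else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def extrapolate_vbar(
    rhos: np.ndarray, s_corrected: np.ndarray,
    rho_window: tuple[float, float] = (0.9, 1.3),
) -> tuple[float, float, bool]:
    """OLS of viscosity-corrected s on solvent density; zero crossing.

    Returns ``(rho_match, vbar, matched)``.  The fit must slope downward
    (s decreases as the solvent gets denser) and cross zero inside
    ``rho_window``, otherwise the fraction is flagged unmatchable.
    """
    rhos = np.asarray(rhos, dtype=float)
    s_corrected = np.asarray(s_corrected, dtype=float)
    if len(np.unique(rhos)) < 2:
        raise FitError("need at least 2 distinct solvent densities")
    slope, intercept = np.polyfit(rhos, s_corrected, 1)
    if slope >= 0:
        return np.nan, np.nan, False
    rho_m = -intercept / slope
    if not rho_window[0] < rho_m < rho_window[1]:
        return rho_m, np.nan, False
    return float(rho_m), float(1.0 / rho_m), True


class DensityMatching:
    """Model combining spectrum fits across solvent densities.

    Parameters
    ----------
    conditions : dict
        Maps a condition key (e.g. the D2O fraction) to the fit at that
        density: an :class:`MCEnsemble`, a :class:`GridFitResults`, or a
        DataFrame with columns ``s_svedberg``, ``D``, ``amplitude``.
    buffers : dict, optional
        Condition key -> :class:`BufferState`.  Taken from each fit's data
        when omitted.
    reference : key, optional
        Condition whose sedimentation coefficients anchor the molar-mass and
        Rh derivation; defaults to the lowest-density condition (largest |s|
        signal).
    alpha : float
        Fixed frictional ratio used to constrain the diffusion coefficient
        as a function of (s, vbar) when deriving M and Rh (default 1.1,
        near-spherical particles; should match the fitting grid's value).
    """

    def __init__(
        self,
        conditions: dict,
        buffers: dict | None = None,
        reference=None,
        alpha: float = 1.1,
    ) -> None:
        if len(conditions) < 2:
            raise FitError("density matching needs >= 2 density conditions")
        self.tables: dict = {}
        self.buffers: dict = {}
        for key, cond in conditions.items():
            if isinstance(cond, MCEnsemble):
                tab = cond.solute_table()
                buf = cond.reference.model.data.buffer.state()
            elif isinstance(cond, GridFitResults):
                tab = cond.nonzero[["s_svedberg", "vbar", "D", "amplitude"]]
                buf = cond.model.data.buffer.state()
            else:
                tab = pd.DataFrame(cond)
                buf = None
            if buffers is not None and key in buffers:
                buf = buffers[key]
            if buf is None:
                raise FitError(f"no buffer state for condition {key!r}")
            for col in ("s_svedberg", "D", "amplitude"):
                if col not in tab.columns:
                    raise FitError(f"condition {key!r} lacks column {col!r}")
            self.tables[key] = tab
            self.buffers[key] = buf
        if reference is None:
            reference = min(self.buffers, key=lambda k: self.buffers[k].rho)
        if reference not in self.tables:
            raise FitError(f"reference condition {reference!r} not supplied")
        self.reference = reference
        self.alpha = alpha

    def fit(
        self,
        n_fractions: int = 100,
        tail_exclusion: float = 0.02,
        exclusion: float = DEFAULT_BUOYANCY_EXCLUSION,
        d_source: str = "constrained",
    ) -> "DensityMatchResults":
        """Run the per-fraction extrapolation and derive distributions.

        ``d_source`` selects the diffusion coefficient entering the M and Rh
        derivation: ``"constrained"`` (default) rebuilds D from the
        reference-condition mean s, the extrapolated vbar and the fixed
        frictional ratio -- the same constraint the fitting grid imposes --
        while ``"fit"`` uses the signal-weighted mean fitted D of the
        reference condition directly (coarser: quantized by the grid's vbar
        resolution).
        """
        if d_source not in ("constrained", "fit"):
            raise FitError(f"unknown d_source {d_source!r}")
        ref_buf = self.buffers[self.reference]
        frac_by_key = {}
        for key, tab in self.tables.items():
            fr = boundary_fractions(
                tab, n_fractions, tail_exclusion,
                value_columns=("s_svedberg", "D"),
            )
            # Fractions must pair across densities by *species* rank.  For a
            # sedimenting condition ascending s orders species from small to
            # large; flotation inverts that order (the largest particles are
            # the most negative), so predominantly floating conditions are
            # reversed before pairing.  Mixed conditions sit near the match
            # point where |s| is small and orientation matters little.
            w = tab["amplitude"].to_numpy(dtype=float)
            mean_s = float(w @ tab["s_svedberg"].to_numpy()) / w.sum()
            if mean_s < 0:
                fr = fr.iloc[::-1].reset_index(drop=True)
                fr["fraction"] = np.arange(n_fractions)
            fr["s_corrected"] = viscosity_correct(
                fr["s_svedberg"], self.buffers[key], ref_buf)
            frac_by_key[key] = fr
        keys = sorted(self.tables, key=lambda k: self.buffers[k].rho)
        rhos = np.array([self.buffers[k].rho for k in keys])
        ref_fr = frac_by_key[self.reference]
        rows = []
        n_skipped = 0
        for j in range(n_fractions):
            s_corr = np.array(
                [frac_by_key[k].loc[j, "s_corrected"] for k in keys])
            rho_m, vbar, matched = extrapolate_vbar(rhos, s_corr)
            s_ref = ref_fr.loc[j, "s_svedberg"] * SVEDBERG
            M = Rh = np.nan
            if matched:
                b = buoyancy(vbar, ref_buf.rho)
                if abs(b) < exclusion or s_ref * b <= 0:
                    matched = False
                    n_skipped += 1
                else:
                    if d_source == "constrained":
                        D_ref = D_from_s_alpha_vbar(
                            s_ref, self.alpha, vbar, ref_buf,
                            exclusion=exclusion)
                    else:
                        D_ref = ref_fr.loc[j, "D"]
                    M = s_ref * R_GAS * ref_buf.T / (D_ref * b)
                    f = R_GAS * ref_buf.T / (N_AVOGADRO * D_ref)
                    Rh = f / (6.0 * np.pi * ref_buf.eta) / 1e-7
            rows.append({
                "fraction": j,
                "quantile": ref_fr.loc[j, "quantile"],
                "weight": ref_fr.loc[j, "weight"],
                "s_ref_svedberg": ref_fr.loc[j, "s_svedberg"],
                "rho_match": rho_m,
                "vbar": vbar,
                "M_Da": M,
                "Rh_nm": Rh,
                "matched": matched,
            })
        table = pd.DataFrame(rows)
        return DensityMatchResults(
            model=self, table=table, n_fractions=n_fractions,
            tail_exclusion=tail_exclusion, n_skipped=n_skipped,
            fractions_by_condition=frac_by_key,
        )


@dataclass
class DensityMatchResults:
    """Per-boundary-fraction matching densities and derived distributions."""

    model: DensityMatching
    table: pd.DataFrame
    n_fractions: int
    tail_exclusion: float
    n_skipped: int
    fractions_by_condition: dict = field(repr=False, default_factory=dict)

    @property
    def matched(self) -> pd.DataFrame:
        return self.table[self.table["matched"]]

    def weighted_stats(self, column: str) -> tuple[float, float]:
        """Signal-weighted mean and sd of a derived column over matched
        fractions."""
        t = self.matched
        w = t["weight"].to_numpy()
        x = t[column].to_numpy()
        mean = float(np.average(x, weights=w))
        var = float(np.average((x - mean) ** 2, weights=w))
        return mean, np.sqrt(var)

    def histogram(self, column: str, bins=30) -> pd.DataFrame:
        """Signal-weighted histogram of vbar / M_Da / Rh_nm."""
        t = self.matched
        h, edges = np.histogram(t[column], bins=bins,
                                weights=t["weight"].to_numpy())
        return pd.DataFrame({
            column: 0.5 * (edges[:-1] + edges[1:]),
            "weight": h,
        })

    def summary(self) -> str:
        vb = self.weighted_stats("vbar")
        m = self.weighted_stats("M_Da")
        rh = self.weighted_stats("Rh_nm")
        t = self.matched
        return "\n".join([
            "Density-matching analysis",
            "=" * 64,
            f"conditions: {len(self.model.tables)} solvent densities "
            f"(reference: {self.model.reference!r})",
            f"fractions: {self.n_fractions} "
            f"(tails excluded: {self.tail_exclusion:.0%} each side; "
            f"matched: {len(t)}, skipped near match point: {self.n_skipped})",
            f"vbar  : {vb[0]:.4f} +/- {vb[1]:.4f} mL/g "
            f"[{t['vbar'].min():.4f}, {t['vbar'].max():.4f}]",
            f"M     : {m[0]:.3e} +/- {m[1]:.2e} Da "
            f"[{t['M_Da'].min():.2e}, {t['M_Da'].max():.2e}]",
            f"Rh    : {rh[0]:.2f} +/- {rh[1]:.2f} nm "
            f"[{t['Rh_nm'].min():.2f}, {t['Rh_nm'].max():.2f}]",
        ])

    def plot_distributions(self, axes=None):
        import matplotlib.pyplot as plt

        if axes is None:
            _, axes = plt.subplots(1, 3, figsize=(11, 3))
        for ax, col, label in zip(
            axes, ("vbar", "Rh_nm", "M_Da"),
            ("vbar [mL/g]", "Rh [nm]", "M [Da]"),
        ):
            h = self.histogram(col)
            ax.plot(h[col], h["weight"], drawstyle="steps-mid")
            ax.set_xlabel(label)
        axes[0].set_ylabel("signal")
        return axes

    def save(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False,
                          float_format="%.8g")
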