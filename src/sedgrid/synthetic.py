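"""Synthetic LNP-like density-matching experiments with known ground truth.

Generates particle populations with narrow normal distributions of apparent
partial specific volume (particle densities just below the solvent's) and
broad lognormal size (Rh) distributions, then simulates the same population
at several D2O fractions.  Each species keeps its intrinsic (M, vbar, alpha)
across conditions while its (s, D) are recomputed for each buffer, so one
population naturally crosses from all-sedimenting in light water through the
mixed sedimenting/floating regime to all-floating at high D2O -- the regime
the combined custom grid is designed for.

Every injected quantity (component parameters, individual draws, per-buffer
transport coefficients, noise realizations' seed) is captured in a ground
truth structure sufficient to recompute the experiment exactly.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from .buffers import BufferSpec, buffer_state
from .constants import NM, SVEDBERG
from .hydro import BufferState, SoluteHydro, solute_from_mass, solute_from_radius
from .lamm import CellGeometry, Scan, ScanSet, simulate_mixture

__all__ = [
    "ComponentSpec",
    "PopulationSpec",
    "NoiseSpec",
    "Population",
    "sample_population",
    "make_density_series",
    "presets",
]


# M from (Rh, vbar, alpha) is buffer-independent; any valid state will do
_ANY_BUFFER = BufferState(rho=1.0, eta=0.01, T=293.15)


@dataclass(frozen=True)
class ComponentSpec:
    """One population component.

    Rh is lognormal with median ``median_Rh_nm`` and log-sd ``Rh_log_sd``,
    clipped to ``Rh_bounds_nm``; vbar is normal (``mean_vbar``,
    ``vbar_sd``) truncated to ``vbar_bounds``; the frictional ratio is fixed
    per component.  ``signal`` is the component's total loading signal.
    """

    median_Rh_nm: float
    Rh_log_sd: float
    mean_vbar: float
    vbar_sd: float
    alpha: float = 1.1
    signal: float = 1.0
    Rh_bounds_nm: tuple[float, float] | None = None
    vbar_bounds: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.Rh_log_sd < 0 or self.vbar_sd < 0 or self.signal < 0:
            raise ValueError("sds and signal must be non-negative")


@dataclass(frozen=True)
class PopulationSpec:
    components: tuple[ComponentSpec, ...]
    n_draws: int = 100
    seed: int = 0


@dataclass(frozen=True)
class NoiseSpec:
    """Additive measurement artifacts for generated scan sets.

    sigma: i.i.d. Gaussian noise per point; ti_amplitude: amplitude of a
    Gaussian radial bump (time-invariant baseline); ri_amplitude: sd of
    zero-mean per-scan offsets (radially invariant).
    """

    sigma: float = 0.003
    ti_amplitude: float = 0.0
    ri_amplitude: float = 0.0


@dataclass
class Population:
    """Realized population: intrinsic particle parameters + amplitudes."""

    M: np.ndarray
    vbar: np.ndarray
    alpha: np.ndarray
    Rh_nm: np.ndarray
    amplitude: np.ndarray
    spec: PopulationSpec

    def __len__(self) -> int:
        return len(self.M)

    def solutes(self, buffer) -> list[SoluteHydro]:
        """Transport coefficients of every draw in the given buffer state."""
        return [
            solute_from_mass(m, v, a, buffer)
            for m, v, a in zip(self.M, self.vbar, self.alpha)
        ]

    def weighted_vbar(self) -> float:
        return float(np.average(self.vbar, weights=self.amplitude))

    def to_dict(self) -> dict:
        return {
            "spec": {
                "n_draws": self.spec.n_draws,
                "seed": self.spec.seed,
                "components": [asdict(c) for c in self.spec.components],
            },
            "draws": {
                "M": self.M.tolist(),
                "vbar": self.vbar.tolist(),
                "alpha": self.alpha.tolist(),
                "Rh_nm": self.Rh_nm.tolist(),
                "amplitude": self.amplitude.tolist(),
            },
        }


def _truncated(draw, lo, hi, rng, max_tries: int = 1000):
    """Redraw until inside [lo, hi]; deterministic given the rng state."""
    x = draw(rng)
    for _ in range(max_tries):
        bad = (x < lo) | (x > hi)
        if not bad.any():
            return x
        x[bad] = draw(rng, int(bad.sum()))
    raise ValueError(
        f"truncation to [{lo}, {hi}] unsatisfiable after {max_tries} redraws")


def sample_population(spec: PopulationSpec) -> Population:
    """Draw the population; deterministic for a given spec (incl. seed)."""
    rng = np.random.default_rng(spec.seed)
    M, vb, al, rh, amp = [], [], [], [], []
    for comp in spec.components:
        n = spec.n_draws
        rlo, rhi = comp.Rh_bounds_nm or (0.0, np.inf)
        vlo, vhi = comp.vbar_bounds or (
            comp.mean_vbar - 2 * comp.vbar_sd - 1e-12,
            comp.mean_vbar + 2 * comp.vbar_sd + 1e-12,
        )
        Rh_nm = _truncated(
            lambda r, k=n: comp.median_Rh_nm * np.exp(
                r.normal(0.0, comp.Rh_log_sd, size=k)),
            rlo, rhi, rng,
        )
        vbar = _truncated(
            lambda r, k=n: r.normal(comp.mean_vbar, comp.vbar_sd, size=k),
            vlo, vhi, rng,
        )
        for r_nm, v in zip(Rh_nm, vbar):
            # invert Rh = alpha*R0 and V = 4/3 pi R0^3 = M vbar / N
            sol = solute_from_radius(r_nm * NM, v, comp.alpha,
                                     _ANY_BUFFER)
            M.append(sol.M)
        vb.extend(vbar)
        al.extend([comp.alpha] * n)
        rh.extend(Rh_nm)
        amp.extend([comp.signal / n] * n)
    return Population(
        M=np.array(M), vbar=np.array(vb), alpha=np.array(al),
        Rh_nm=np.array(rh), amplitude=np.array(amp), spec=spec,
    )




def make_density_series(
    population: Population,
    d2o_fractions,
    geometry: CellGeometry | None = None,
    omega: float = 2.0 * np.pi * 30000 / 60.0,
    times=None,
    noise: NoiseSpec | None = None,
    seed: int = 0,
    T: float = 293.15,
    base_density_increment: float | None = None,
    n_radial: int = 240,
    loading_norm: bool = False,
) -> tuple[dict[float, ScanSet], dict]:
    """Simulate the population at each D2O fraction and add noise.

    Returns ``(scansets, ground_truth)`` where ``scansets`` maps the D2O
    fraction to a noisy :class:`ScanSet` and ``ground_truth`` records the
    population, per-buffer (rho, eta) and per-solute (s, D), the noise spec
    and all seeds.
    """
    geometry = geometry or CellGeometry()
    times = np.asarray(
        times if times is not None else np.linspace(600.0, 30000.0, 25),
        dtype=float,
    )
    noise = noise or NoiseSpec()
    rng = np.random.default_rng(seed)
    scansets: dict[float, ScanSet] = {}
    truth: dict = {
        "population": population.to_dict(),
        "noise": asdict(noise),
        "seed": seed,
        "omega": omega,
        "times": times.tolist(),
        "geometry": {"meniscus": geometry.meniscus, "bottom": geometry.bottom},
        "conditions": {},
    }
    for phi in d2o_fractions:
        kw = {} if base_density_increment is None else {
            "base_density_increment": base_density_increment}
        bspec = BufferSpec(d2o_fraction=float(phi), T=T, **kw)
        buf = buffer_state(bspec)
        sols = population.solutes(buf)
        clean = simulate_mixture(
            sols, population.amplitude, geometry, omega, times,
            buffer=bspec, n_radial=n_radial,
        )
        r = clean.radius
        mid = 0.5 * (geometry.meniscus + geometry.bottom)
        width = 0.05 * (geometry.bottom - geometry.meniscus)
        ti = noise.ti_amplitude * np.exp(-0.5 * ((r - mid) / width) ** 2)
        ri = rng.normal(0.0, noise.ri_amplitude, size=len(times)) \
            if noise.ri_amplitude > 0 else np.zeros(len(times))
        ri -= ri.mean()
        eps = rng.normal(0.0, noise.sigma, size=(len(times), len(r))) \
            if noise.sigma > 0 else 0.0
        Y = clean.signal_matrix() + ti[None, :] + ri[:, None] + eps
        scans = [
            Scan(t=sc.t, omega=sc.omega, T=sc.T, signal=y)
            for sc, y in zip(clean.scans, Y)
        ]
        scansets[float(phi)] = ScanSet(
            geometry=geometry, buffer=bspec, radius=r, scans=scans,
            wavelength=clean.wavelength,
            meta={"d2o_fraction": float(phi), "synthetic": True},
        )
        truth["conditions"][str(phi)] = {
            "rho": buf.rho,
            "eta": buf.eta,
            "s_svedberg": [s.s / SVEDBERG for s in sols],
            "D": [s.D for s in sols],
            "ti_noise": ti.tolist(),
            "ri_noise": ri.tolist(),
        }
    return scansets, truth


def presets() -> dict[str, PopulationSpec]:
    """Named LNP-like populations for the four cargo-loading states.

    vbar centres/ranges follow the reported density windows for each state
    (empty 0.990-0.992, protein-conjugated 0.980-0.990, mRNA-loaded
    0.974-0.985, protein+mRNA 0.972-0.985 mL/g); sizes are lognormal with
    the empty particles far more heterogeneous (20-110 nm diameter) than
    the loaded/conjugated ones.  Frictional ratio fixed at 1.1 throughout
    (near-spherical particles).
    """
    return {
        "empty": PopulationSpec(components=(
            ComponentSpec(median_Rh_nm=26.0, Rh_log_sd=0.32,
                          mean_vbar=0.9910, vbar_sd=0.0004,
                          Rh_bounds_nm=(10.0, 55.0),
                          vbar_bounds=(0.9900, 0.9920), signal=0.58),
        )),
        "lnp-p": PopulationSpec(components=(
            ComponentSpec(median_Rh_nm=19.5, Rh_log_sd=0.12,
                          mean_vbar=0.9850, vbar_sd=0.0020,
                          Rh_bounds_nm=(15.0, 25.0),
                          vbar_bounds=(0.9800, 0.9900), signal=0.83),
        )),
        "lnp-mrna": PopulationSpec(components=(
            ComponentSpec(median_Rh_nm=21.0, Rh_log_sd=0.15,
                          mean_vbar=0.9805, vbar_sd=0.0015,
                          Rh_bounds_nm=(15.0, 30.0),
                          vbar_bounds=(0.9770, 0.9840), signal=0.83),
        )),
        "lnp-p-mrna": PopulationSpec(components=(
            ComponentSpec(median_Rh_nm=14.0, Rh_log_sd=0.15,
                          mean_vbar=0.9785, vbar_sd=0.0025,
                          Rh_bounds_nm=(10.0, 20.0),
                          vbar_bounds=(0.9725, 0.9845), signal=0.83),
        )),
    }
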