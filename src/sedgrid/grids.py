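"""Custom-grid construction over (s, vbar) with a fixed frictional ratio.

The fitting basis is a Cartesian grid of hypothetical solutes.  Rather than
the traditional (s, f/f0)-at-fixed-vbar parameterization, the default here
spans sedimentation coefficient and partial specific volume at a fixed
frictional ratio, which lets one basis cover particles both denser and
lighter than the solvent: a sedimenting block (s > 0, vbar < 1/rho) and a
floating block (s < 0, vbar > 1/rho) are built separately and combined into
one grid that is fitted as a whole.  Alternative axis pairs (s, f/f0) and
(s, M) at fixed vbar are provided for generality.

Grids are split into coarse interleaved subgrid partitions for iterative
refinement: each partition is a strided sample across both axes, so every
partition spans the full parameter range at reduced resolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import SVEDBERG
from .hydro import (
    DEFAULT_BUOYANCY_EXCLUSION,
    BufferState,
    SoluteHydro,
    buoyancy,
    solute_from_s_vbar,
)

__all__ = [
    "GridError",
    "GridAxisSpec",
    "CombinedGrid",
    "build_subgrid",
    "build_subgrid_auto_sign",
    "build_subgrid_ff0",
    "combine_grids",
    "partition_for_refinement",
    "mixed_buoyancy_grid",
]


class GridError(ValueError):
    """Invalid grid specification (sign inconsistency, buoyancy exclusion...)."""


@dataclass(frozen=True)
class GridAxisSpec:
    """One grid axis: parameter name, range, resolution and spacing.

    ``s`` axes are specified in Svedberg.  Logarithmic spacing requires a
    range that does not contain zero; on a strictly negative (flotation)
    range it is logarithmic in magnitude, mirrored.
    """

    name: str
    min: float
    max: float
    n_points: int
    spacing: str = "linear"

    def __post_init__(self) -> None:
        if self.name not in ("s", "vbar", "ff0", "M", "D"):
            raise GridError(f"unknown axis parameter {self.name!r}")
        if self.n_points < 1:
            raise GridError("n_points must be >= 1")
        if self.n_points > 1 and not self.min < self.max:
            raise GridError(f"need min < max, got [{self.min}, {self.max}]")
        if self.spacing not in ("linear", "logarithmic"):
            raise GridError(f"unknown spacing {self.spacing!r}")
        if self.spacing == "logarithmic" and self.min <= 0 < self.max:
            raise GridError(
                "logarithmic spacing requires a range not containing zero")

    def points(self) -> np.ndarray:
        if self.n_points == 1:
            return np.array([self.min])
        if self.spacing == "logarithmic":
            if self.max < 0:
                # flotation axis: logarithmic in magnitude, mirrored
                return -np.geomspace(-self.min, -self.max, self.n_points)
            return np.geomspace(self.min, self.max, self.n_points)
        return np.linspace(self.min, self.max, self.n_points)


@dataclass
class _Subgrid:
    """Provenance + index layout of one rectangular block of the grid."""

    s_axis: GridAxisSpec
    vbar_axis: GridAxisSpec
    index: np.ndarray  # (n_s, n_vbar) global solute indices


@dataclass
class CombinedGrid:
    """The realized basis: solute list plus per-subgrid provenance."""

    solutes: list[SoluteHydro]
    subgrids: list[_Subgrid]
    alpha: float
    buffer: BufferState

    def __len__(self) -> int:
        return len(self.solutes)

    @property
    def s_sv(self) -> np.ndarray:
        return np.array([sol.s for sol in self.solutes]) / SVEDBERG

    @property
    def vbar(self) -> np.ndarray:
        return np.array([sol.vbar for sol in self.solutes])

    def to_dataframe(self) -> pd.DataFrame:
        """One solute per row, in reporting units."""
        return pd.DataFrame(
            {
                "s_svedberg": [sol.s / SVEDBERG for sol in self.solutes],
                "vbar": [sol.vbar for sol in self.solutes],
                "alpha": [sol.alpha for sol in self.solutes],
                "D": [sol.D for sol in self.solutes],
                "M": [sol.M for sol in self.solutes],
                "Rh_nm": [sol.Rh_nm for sol in self.solutes],
            }
        )

    def subset(self, indices) -> list[SoluteHydro]:
        return [self.solutes[i] for i in indices]


def build_subgrid(
    s_axis: GridAxisSpec,
    vbar_axis: GridAxisSpec,
    alpha: float,
    buffer: BufferState,
    exclusion: float = DEFAULT_BUOYANCY_EXCLUSION,
    invalid: str = "error",
) -> CombinedGrid:
    """Cartesian (s, vbar) block converted to full solutes.

    Every (s, vbar) pair must satisfy sign(s) == sign(1 - vbar*rho) and stay
    outside the buoyancy-exclusion band.  With ``invalid="error"`` (default)
    any violation is reported with its coordinates; ``invalid="drop"``
    silently masks violating points instead, which is how one grid
    *specification* is reused across solvent densities whose match point
    moves through the vbar range.
    """
    if s_axis.name != "s" or vbar_axis.name != "vbar":
        raise GridError("build_subgrid expects an s axis and a vbar axis")
    if invalid not in ("error", "drop"):
        raise GridError(f"invalid must be 'error' or 'drop', got {invalid!r}")
    s_pts = s_axis.points() * SVEDBERG
    v_pts = vbar_axis.points()
    ok = np.ones((len(s_pts), len(v_pts)), dtype=bool)
    for j, v in enumerate(v_pts):
        b = buoyancy(v, buffer.rho)
        for i, s in enumerate(s_pts):
            ok[i, j] = abs(b) >= exclusion and s * b > 0
    if not ok.all():
        if invalid == "error":
            bad = [
                (s_pts[i] / SVEDBERG, v_pts[j])
                for i, j in zip(*np.nonzero(~ok))
            ]
            head = ", ".join(f"(s={s:.4g} S, vbar={v:.6g})" for s, v in bad[:5])
            raise GridError(
                f"{len(bad)} grid points violate the buoyancy sign/exclusion "
                f"rule: {head}{'...' if len(bad) > 5 else ''}"
            )
    solutes = []
    index = np.full((len(s_pts), len(v_pts)), -1, dtype=np.int64)
    for i, s in enumerate(s_pts):
        for j, v in enumerate(v_pts):
            if not ok[i, j]:
                continue
            index[i, j] = len(solutes)
            solutes.append(
                solute_from_s_vbar(s, v, alpha, buffer, exclusion=exclusion)
            )
    return CombinedGrid(
        solutes=solutes,
        subgrids=[_Subgrid(s_axis, vbar_axis, index)],
        alpha=alpha,
        buffer=buffer,
    )


def build_subgrid_auto_sign(
    abs_s_axis: GridAxisSpec,
    vbar_axis: GridAxisSpec,
    alpha: float,
    buffer: BufferState,
    exclusion: float = DEFAULT_BUOYANCY_EXCLUSION,
) -> CombinedGrid:
    """(|s|, vbar) block whose sedimentation signs follow the buoyancy term.

    The s axis holds magnitudes (must be positive); each vbar column is
    assigned sign(s) = sign(1 - vbar*rho), so one grid *specification*
    remains physically valid at every solvent density -- the match point
    1/rho may move through the vbar range and simply flips the affected
    columns from sedimenting to floating.  Columns inside the buoyancy
    exclusion band are dropped.
    """
    if abs_s_axis.min <= 0:
        raise GridError("auto-sign grids take an |s| axis with min > 0")
    s_mag = abs_s_axis.points() * SVEDBERG
    v_pts = vbar_axis.points()
    solutes = []
    index = np.full((len(s_mag), len(v_pts)), -1, dtype=np.int64)
    for j, v in enumerate(v_pts):
        b = buoyancy(v, buffer.rho)
        if abs(b) < exclusion:
            continue
        sign = 1.0 if b > 0 else -1.0
        for i, s in enumerate(s_mag):
            index[i, j] = len(solutes)
            solutes.append(
                solute_from_s_vbar(sign * s, v, alpha, buffer,
                                   exclusion=exclusion)
            )
    if not solutes:
        raise GridError("all vbar columns fall in the buoyancy exclusion band")
    return CombinedGrid(
        solutes=solutes,
        subgrids=[_Subgrid(abs_s_axis, vbar_axis, index)],
        alpha=alpha,
        buffer=buffer,
    )


def build_subgrid_ff0(
    s_axis: GridAxisSpec,
    ff0_axis: GridAxisSpec,
    vbar: float,
    buffer: BufferState,
    exclusion: float = DEFAULT_BUOYANCY_EXCLUSION,
) -> CombinedGrid:
    """Traditional (s, f/f0) block at fixed vbar."""
    if s_axis.name != "s" or ff0_axis.name != "ff0":
        raise GridError("build_subgrid_ff0 expects an s axis and an ff0 axis")
    if ff0_axis.min < 1.0:
        raise GridError("frictional ratio axis must start at >= 1")
    s_pts = s_axis.points() * SVEDBERG
    a_pts = ff0_axis.points()
    b = buoyancy(vbar, buffer.rho)
    if abs(b) < exclusion or any(s * b <= 0 for s in s_pts):
        raise GridError("s range inconsistent with the buoyancy of fixed vbar")
    solutes = []
    index = np.empty((len(s_pts), len(a_pts)), dtype=np.int64)
    for i, s in enumerate(s_pts):
        for j, a in enumerate(a_pts):
            index[i, j] = len(solutes)
            solutes.append(solute_from_s_vbar(s, vbar, a, buffer,
                                              exclusion=exclusion))
    return CombinedGrid(
        solutes=solutes,
        subgrids=[_Subgrid(s_axis, ff0_axis, index)],
        alpha=float("nan"),
        buffer=buffer,
    )


def _same_buffer(b1: BufferState, b2: BufferState) -> bool:
    return b1.rho == b2.rho and b1.eta == b2.eta and b1.T == b2.T


def combine_grids(*grids: CombinedGrid) -> CombinedGrid:
    """Union of subgrid blocks sharing buffer and fixed parameters.

    Duplicate (s, vbar) coordinates are stored once; provenance (the axis
    specs of every block) is retained.
    """
    if not grids:
        raise GridError("no grids to combine")
    first = grids[0]
    for g in grids[1:]:
        if not _same_buffer(g.buffer, first.buffer):
            raise GridError("subgrids must share the buffer state")
        if not (g.alpha == first.alpha or (np.isnan(g.alpha) and np.isnan(first.alpha))):
            raise GridError(
                f"conflicting fixed frictional ratios: {first.alpha} vs {g.alpha}"
            )
    solutes: list[SoluteHydro] = []
    seen: dict[tuple[float, float, float], int] = {}
    subgrids = []
    for g in grids:
        remap = {-1: -1}
        for local_idx, sol in enumerate(g.solutes):
            key = (sol.s, sol.vbar, sol.alpha)
            if key not in seen:
                seen[key] = len(solutes)
                solutes.append(sol)
            remap[local_idx] = seen[key]
        for sg in g.subgrids:
            new_index = np.vectorize(remap.get)(sg.index).astype(np.int64)
            subgrids.append(_Subgrid(sg.s_axis, sg.vbar_axis, new_index))
    return CombinedGrid(solutes=solutes, subgrids=subgrids,
                        alpha=first.alpha, buffer=first.buffer)


def _factor_pair(n: int, n_s: int, n_v: int) -> tuple[int, int]:
    """Factor n = a*b with a<=n_s, b<=n_v, as square as possible."""
    best = None
    for a in range(1, n + 1):
        if n % a:
            continue
        b = n // a
        if a <= n_s and b <= n_v:
            score = abs(np.log(a / b))
            if best is None or score < best[0]:
                best = (score, a, b)
    if best is None:
        raise GridError(f"cannot stride {n} partitions over a {n_s}x{n_v} block")
    return best[1], best[2]


def partition_for_refinement(grid: CombinedGrid, n_partitions: int) -> list[np.ndarray]:
    """Split a grid into coarse interleaved partitions for iterative fitting.

    Each partition takes every a-th s index and every b-th vbar index
    (a*b = n_partitions) from every subgrid block, so all partitions span the
    full (s, vbar) range.  Every solute lands in exactly one partition;
    returns global solute-index arrays.
    """
    if n_partitions < 1:
        raise GridError("n_partitions must be >= 1")
    if n_partitions > len(grid):
        raise GridError(
            f"n_partitions = {n_partitions} exceeds grid size {len(grid)}"
        )
    parts: list[list[int]] = [[] for _ in range(n_partitions)]
    assigned = set()
    for sg in grid.subgrids:
        n_s, n_v = sg.index.shape
        try:
            a, b = _factor_pair(n_partitions, n_s, n_v)
        except GridError:
            # block too small for a 2-D stride: round-robin its points
            a = b = None
        for i in range(n_s):
            for j in range(n_v):
                gidx = int(sg.index[i, j])
                if gidx < 0 or gidx in assigned:
                    continue
                assigned.add(gidx)
                if a is None:
                    p = (i * n_v + j) % n_partitions
                else:
                    p = (i % a) * b + (j % b)
                parts[p].append(gidx)
    return [np.array(sorted(p), dtype=np.int64) for p in parts if len(p)]


def mixed_buoyancy_grid(
    buffer: BufferState,
    alpha: float = 1.1,
    s_min_sv: float = 1.0,
    s_max_sv: float = 100.0,
    n_s: int = 200,
    sed_vbar: tuple[float, float] = (0.94, 0.999),
    flo_vbar: tuple[float, float] = (1.003, 1.05),
    n_vbar: int = 120,
    spacing: str = "linear",
) -> CombinedGrid:
    """The two-block sedimenting + floating grid used for LNP analysis.

    A nominally sedimenting block (vbar below ~1/rho of light water) and a
    nominally floating block (vbar above it) are combined, each carrying the
    full |s| axis with per-column signs assigned from the buoyancy term (see
    :func:`build_subgrid_auto_sign`) -- so the same grid specification stays
    valid at every solvent density even as the match point 1/rho moves
    through the vbar ranges.  Defaults reproduce the 24 000-solute
    configuration: 200 s-points per block and 120 vbar points split evenly
    between the blocks.
    """
    n_v_half = n_vbar // 2
    sed = build_subgrid_auto_sign(
        GridAxisSpec("s", s_min_sv, s_max_sv, n_s, spacing),
        GridAxisSpec("vbar", sed_vbar[0], sed_vbar[1], n_v_half),
        alpha,
        buffer,
    )
    flo = build_subgrid_auto_sign(
        GridAxisSpec("s", s_min_sv, s_max_sv, n_s, spacing),
        GridAxisSpec("vbar", flo_vbar[0], flo_vbar[1], n_vbar - n_v_half),
        alpha,
        buffer,
    )
    return combine_grids(sed, flo)
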