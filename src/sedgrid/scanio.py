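"""Columnar text formats and run configuration.

Scan sets are stored as a self-describing text format: ``key: value``
header lines (geometry, rotor speed, temperature, buffer composition,
wavelength), then one block per scan introduced by ``scan: <n>`` (1-based)
and ``time_s: <t>``, followed by ``radius signal`` pairs, one per line.
Radii are in cm, signals in (unitless) OD; values round-trip at full double
precision.  All scans must share one strictly increasing radius vector.

The run configuration is a YAML mapping validated against a small schema;
see :class:`RunConfig`.  Raw vendor/third-party scan files are out of
format; :func:`import_adapter_stub` documents the mapping a converter needs
to perform.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .buffers import PBS_DENSITY_INCREMENT, BufferSpec
from .lamm import CellGeometry, Scan, ScanSet

__all__ = ["ParseError", "ConfigError", "read_scanset", "write_scanset",
           "RunConfig", "load_config", "config_hash"]

_FMT_TAG = "sedgrid scan set v1"


class ParseError(ValueError):
    """Malformed scan-set file; message names the offending line."""


class ConfigError(ValueError):
    """Invalid or incomplete run configuration; message names the key."""


def write_scanset(scanset: ScanSet, path) -> None:
    """Serialize a :class:`ScanSet`; see module docstring for the format."""
    buf = scanset.buffer
    lines = [
        f"# {_FMT_TAG}",
        f"meniscus_cm: {float(scanset.geometry.meniscus)!r}",
        f"bottom_cm: {float(scanset.geometry.bottom)!r}",
        f"temperature_K: {float(scanset.temperature)!r}",
        f"omega_rad_s: {float(scanset.omega)!r}",
        f"wavelength_nm: {float(scanset.wavelength)!r}",
        f"d2o_fraction: {float(buf.d2o_fraction)!r}",
        f"base_density_increment: {float(buf.base_density_increment)!r}",
        f"viscosity_multiplier: {float(buf.viscosity_multiplier)!r}",
        f"n_scans: {len(scanset.scans)}",
    ]
    for k, v in scanset.meta.items():
        if isinstance(v, (int, float, str, bool)):
            lines.append(f"meta.{k}: {v}")
    for i, sc in enumerate(scanset.scans, start=1):
        lines.append(f"scan: {i}")
        lines.append(f"time_s: {float(sc.t)!r}")
        for r, y in zip(scanset.radius, sc.signal):
            lines.append(f"{float(r)!r} {float(y)!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_scanset(path) -> ScanSet:
    """Parse a scan-set file written by :func:`write_scanset`."""
    text = Path(path).read_text().splitlines()
    header: dict[str, float] = {}
    meta: dict = {}
    i = 0
    n = len(text)
    while i < n:
        line = text[i].strip()
        i += 1
        if not line or line.startswith("#"):
            continue
        if ":" not in line:
            raise ParseError(f"{path}:{i}: expected 'key: value', got {line!r}")
        key, _, val = line.partition(":")
        key, val = key.strip(), val.strip()
        if key == "scan":
            i -= 1
            break
        if key.startswith("meta."):
            meta[key[5:]] = val
        else:
            try:
                header[key] = float(val)
            except ValueError as exc:
                raise ParseError(f"{path}:{i}: bad number {val!r}") from exc
    for req in ("meniscus_cm", "bottom_cm", "temperature_K", "omega_rad_s",
                "n_scans"):
        if req not in header:
            raise ParseError(f"{path}: missing header key {req!r}")
    scans_raw = []
    radius_ref = None
    while i < n:
        line = text[i].strip()
        if not line:
            i += 1
            continue
        key, _, val = line.partition(":")
        if key.strip() != "scan":
            raise ParseError(f"{path}:{i + 1}: expected 'scan: <n>'")
        i += 1
        key, _, val = text[i].strip().partition(":")
        if key.strip() != "time_s":
            raise ParseError(f"{path}:{i + 1}: expected 'time_s: <t>'")
        t = float(val)
        i += 1
        radii, sig = [], []
        while i < n:
            row = text[i].strip()
            if not row:
                i += 1
                continue
            if row.startswith("scan"):
                break
            parts = row.split()
            if len(parts) != 2:
                raise ParseError(
                    f"{path}:{i + 1}: expected 'radius signal', got {row!r}")
            try:
                r, y = float(parts[0]), float(parts[1])
            except ValueError as exc:
                raise ParseError(f"{path}:{i + 1}: bad number in {row!r}") from exc
            if radii and r <= radii[-1]:
                raise ParseError(
                    f"{path}:{i + 1}: radius not strictly increasing "
                    f"({r!r} after {radii[-1]!r})")
            radii.append(r)
            sig.append(y)
            i += 1
        radii = np.array(radii)
        if radius_ref is None:
            radius_ref = radii
        elif len(radii) != len(radius_ref) or not np.array_equal(radii, radius_ref):
            raise ParseError(
                f"{path}:{i}: scan radius vector differs from the first scan")
        scans_raw.append((t, np.array(sig)))
    if len(scans_raw) != int(header["n_scans"]):
        raise ParseError(
            f"{path}: n_scans = {int(header['n_scans'])} but found "
            f"{len(scans_raw)} scan blocks")
    geometry = CellGeometry(meniscus=header["meniscus_cm"],
                            bottom=header["bottom_cm"])
    buffer = BufferSpec(
        d2o_fraction=header.get("d2o_fraction", 0.0),
        base_density_increment=header.get("base_density_increment",
                                          PBS_DENSITY_INCREMENT),
        viscosity_multiplier=header.get("viscosity_multiplier", 1.0),
        T=header["temperature_K"],
    )
    scans = [
        Scan(t=t, omega=header["omega_rad_s"], T=header["temperature_K"],
             signal=y)
        for t, y in scans_raw
    ]
    return ScanSet(geometry=geometry, buffer=buffer, radius=radius_ref,
                   scans=scans, wavelength=header.get("wavelength_nm", 300.0),
                   meta=meta)


def import_adapter_stub(path) -> None:
    """Placeholder for importing third-party raw AUC scan files.

    Vendor and archive deposits store one scan per file with an instrument
    header (cell, channel, rotor speed in rpm, elapsed time, temperature in
    Celsius) followed by radius/absorbance(/sd) rows.  A converter must
    (1) group files by cell/channel, (2) convert rpm to rad/s and Celsius to
    Kelvin, (3) intersect the per-scan radius vectors onto a common grid,
    and (4) write the result with :func:`write_scanset`.  Not implemented
    here; raw-format ingestion is outside the text formats this package
    maintains.
    """
    raise NotImplementedError(
        "raw vendor scan import is documented but not implemented; "
        "convert to the sedgrid scan-set format instead"
    )


# --------------------------------------------------------------------- config


def _require(cfg: dict, key: str, section: str = ""):
    if key not in cfg:
        where = f" in section {section!r}" if section else ""
        raise ConfigError(f"missing config key {key!r}{where}")
    return cfg[key]


@dataclass
class RunConfig:
    """Validated pipeline configuration (see ``examples`` in the README)."""

    seed: int
    output_dir: Path
    d2o_fractions: list[float]
    geometry: CellGeometry
    omega: float
    temperature_K: float
    times: np.ndarray
    n_radial: int
    population: dict | str
    noise: dict
    grid: dict
    fit: dict
    densmatch: dict
    raw: dict = field(repr=False, default_factory=dict)

    def buffer_spec(self, phi: float) -> BufferSpec:
        b = self.raw.get("buffer", {})
        return BufferSpec(
            d2o_fraction=phi,
            base_density_increment=b.get("base_density_increment",
                                         PBS_DENSITY_INCREMENT),
            viscosity_multiplier=b.get("viscosity_multiplier", 1.0),
            T=self.temperature_K,
            rho_override=b.get("rho_override"),
            eta_override=b.get("eta_override"),
        )


def load_config(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError(f"config {path} is not a mapping")
    seed = int(_require(raw, "seed"))
    out = Path(_require(raw, "output_dir"))
    fracs = [float(x) for x in _require(raw, "d2o_fractions")]
    g = raw.get("geometry", {})
    geometry = CellGeometry(meniscus=g.get("meniscus", 5.9),
                            bottom=g.get("bottom", 7.2))
    rpm = raw.get("rotor_speed_rpm", 30000.0)
    omega = 2.0 * np.pi * rpm / 60.0
    T = raw.get("temperature_C", 20.0) + 273.15
    t = raw.get("times", {})
    times = np.linspace(t.get("start", 600.0), t.get("end", 32000.0),
                        int(t.get("n", 25)))
    return RunConfig(
        seed=seed,
        output_dir=out,
        d2o_fractions=fracs,
        geometry=geometry,
        omega=omega,
        temperature_K=T,
        times=times,
        n_radial=int(raw.get("n_radial", 240)),
        population=_require(raw, "population"),
        noise=raw.get("noise", {}),
        grid=raw.get("grid", {}),
        fit=raw.get("fit", {}),
        densmatch=raw.get("densmatch", {}),
        raw=raw,
    )


def config_hash(cfg: RunConfig) -> str:
    """Short stable digest of the raw config, stamped into all outputs."""
    canon = json.dumps(cfg.raw, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]
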