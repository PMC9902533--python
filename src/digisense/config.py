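"""Run configuration with explicit units.

Quantification errors are overwhelmingly unit errors, so every physical
quantity in a run-configuration file carries its unit as part of the
value (``"31.7 um"``, ``"70 uL/h"``, ``"50 nM"``).  A small unit table
converts to the package's canonical units (µm, s, µL/h, molar); unknown
units and unknown configuration keys are rejected rather than ignored.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .burstsearch import IntensityBurstParams, IptBurstParams
from .electropherogram import RegionSelection
from .errors import ConfigurationError
from .quantify import ExperimentGeometry

# unit -> (dimension, factor to the canonical unit of that dimension)
# canonical: length µm, time s, flow µL/h, concentration M, mass g/mol
_UNITS = {
    "um": ("length", 1.0), "µm": ("length", 1.0), "mm": ("length", 1e3),
    "nm": ("length", 1e-3), "m": ("length", 1e6),
    "s": ("time", 1.0), "ms": ("time", 1e-3), "us": ("time", 1e-6),
    "µs": ("time", 1e-6), "ns": ("time", 1e-9), "min": ("time", 60.0), "h": ("time", 3600.0),
    "uL/h": ("flow", 1.0), "µL/h": ("flow", 1.0), "mL/h": ("flow", 1e3),
    "uL/min": ("flow", 60.0),
    "M": ("concentration", 1.0), "mM": ("concentration", 1e-3),
    "uM": ("concentration", 1e-6), "µM": ("concentration", 1e-6),
    "nM": ("concentration", 1e-9), "pM": ("concentration", 1e-12),
    "fM": ("concentration", 1e-15),
    "g/mol": ("mass", 1.0), "Da": ("mass", 1.0), "kDa": ("mass", 1e3),
}


def parse_quantity(text, dimension: str) -> float:
    """Parse ``"<number> <unit>"`` into the canonical unit of ``dimension``."""
    if isinstance(text, (int, float)):
        raise ConfigurationError(
            f"bare number {text!r}: physical quantities must carry a unit "
            f"(expected a {dimension})"
        )
    parts = str(text).split()
    if len(parts) != 2:
        raise ConfigurationError(f"cannot parse quantity {text!r} (want '<number> <unit>')")
    try:
        value = float(parts[0])
    except ValueError as exc:
        raise ConfigurationError(f"cannot parse number in {text!r}") from exc
    unit = parts[1]
    if unit not in _UNITS:
        raise ConfigurationError(f"unknown unit {unit!r} in {text!r}")
    dim, factor = _UNITS[unit]
    if dim != dimension:
        raise ConfigurationError(
            f"{text!r} is a {dim}, expected a {dimension}"
        )
    return value * factor


def _check_keys(block: dict, allowed: set, context: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ConfigurationError(f"unknown key(s) {sorted(unknown)} in {context}")


@dataclass(frozen=True)
class RunConfig:
    """A validated, unit-resolved run configuration."""

    assay: str
    seed: int
    geometry: ExperimentGeometry
    burst_params: Optional[object] = None          # Ipt- or IntensityBurstParams
    region: Optional[RegionSelection] = None
    counts: Optional[dict] = None                  # n_sample, n_sample_sd, n_control, n_control_sd
    binding: Optional[dict] = None                 # K_d, probe_total (M), valency, mode
    recovery_factor: float = 1.0
    config_hash: str = ""

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        path = Path(path)
        raw_bytes = path.read_bytes()
        data = yaml.safe_load(raw_bytes)
        if not isinstance(data, dict):
            raise ConfigurationError(f"{path}: top level must be a mapping")
        _check_keys(
            data,
            {"assay", "seed", "geometry", "burst", "region", "counts", "binding", "options"},
            str(path),
        )
        for key in ("assay", "seed", "geometry"):
            if key not in data:
                raise ConfigurationError(f"{path}: missing required key {key!r}")

        g = data["geometry"]
        _check_keys(g, {"h", "d_step", "z", "w", "Q_sample", "t"}, "geometry")
        geometry = ExperimentGeometry(
            h=parse_quantity(g.get("h"), "length"),
            d_step=parse_quantity(g.get("d_step"), "length"),
            z=parse_quantity(g.get("z"), "length"),
            w=parse_quantity(g.get("w"), "length"),
            Q_sample=parse_quantity(g.get("Q_sample"), "flow"),
            t=parse_quantity(g.get("t"), "time"),
        )

        burst_params = None
        if "burst" in data:
            b = dict(data["burst"])
            kind = b.pop("kind", "ipt")
            if kind == "ipt":
                _check_keys(b, {"ipt_threshold", "min_photons", "lee_window_n", "lee_sigma0"},
                            "burst")
                burst_params = IptBurstParams(
                    ipt_threshold=parse_quantity(b["ipt_threshold"], "time"),
                    min_photons=int(b["min_photons"]),
                    lee_window_n=int(b.get("lee_window_n", 4)),
                    lee_sigma0=(parse_quantity(b["lee_sigma0"], "time")
                                if "lee_sigma0" in b else None),
                )
            elif kind == "intensity":
                _check_keys(b, {"bin_width", "sd_multiplier"}, "burst")
                burst_params = IntensityBurstParams(
                    bin_width=parse_quantity(b.get("bin_width", "1 ms"), "time"),
                    sd_multiplier=float(b.get("sd_multiplier", 5.0)),
                )
            else:
                raise ConfigurationError(f"burst kind must be 'ipt' or 'intensity', got {kind!r}")

        region = None
        if "region" in data:
            r = data["region"]
            _check_keys(r, {"x_min", "x_max"}, "region")
            region = RegionSelection(
                x_min=parse_quantity(r["x_min"], "length"),
                x_max=parse_quantity(r["x_max"], "length"),
            )

        counts = None
        if "counts" in data:
            c = data["counts"]
            _check_keys(c, {"n_sample", "n_sample_sd", "n_control", "n_control_sd"}, "counts")
            counts = {k: float(v) for k, v in c.items()}

        binding = None
        if "binding" in data:
            b = data["binding"]
            _check_keys(b, {"K_d", "probe_total", "valency", "mode"}, "binding")
            binding = {
                "K_d": parse_quantity(b["K_d"], "concentration"),
                "probe_total": parse_quantity(b["probe_total"], "concentration"),
                "valency": float(b.get("valency", 1.0)),
                "mode": b.get("mode", "target"),
            }
            if binding["mode"] not in ("target", "binding_sites"):
                raise ConfigurationError("binding mode must be 'target' or 'binding_sites'")

        recovery = 1.0
        if "options" in data:
            o = data["options"]
            _check_keys(o, {"recovery_factor"}, "options")
            recovery = float(o.get("recovery_factor", 1.0))

        return cls(
            assay=str(data["assay"]),
            seed=int(data["seed"]),
            geometry=geometry,
            burst_params=burst_params,
            region=region,
            counts=counts,
            binding=binding,
            recovery_factor=recovery,
            config_hash=hashlib.sha256(raw_bytes).hexdigest(),
        )
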