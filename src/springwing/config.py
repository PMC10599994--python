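"""Run configuration: structured-text (YAML) blocks tying modules together.

Angles are stored in radians and forces in newtons internally; degrees and
millinewtons appear only at the I/O boundary (keys suffixed _deg / _mN are
converted at parse time).  Every stochastic operation draws from a named
seed in the registry so runs are reproducible from the file alone.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field

import yaml

from springwing.engine import SimConfig
from springwing.mechanics import (
    MechanicalPlant,
    hawkmoth_plant,
    plant_from_params,
    roboflapper_plant,
)

_KNOWN_BLOCKS = {"plant", "forcing", "sim", "sweep", "phylo", "seeds", "output_dir"}


@dataclass
class RunConfig:
    """Parsed run configuration with provenance metadata."""

    plant: MechanicalPlant
    forcing: dict
    sim: SimConfig
    sweep: dict
    phylo: dict
    seeds: dict
    output_dir: str
    config_hash: str
    raw: dict = field(repr=False, default_factory=dict)

    def seed(self, name: str, default: int = 0) -> int:
        return int(self.seeds.get(name, default))


def _convert_units(block: dict) -> dict:
    out = {}
    for key, value in block.items():
        if key.endswith("_deg"):
            out[key[:-4] + "_rad"] = math.radians(float(value))
        elif key.endswith("_mN"):
            out[key[:-3] + "_N"] = float(value) * 1e-3
        else:
            out[key] = value
    return out


def load_config(path_or_text: str) -> RunConfig:
    """Load and validate a YAML run configuration.

    Unknown top-level keys are rejected; the plant block may either name a
    shipped parameter set (``preset: hawkmoth`` / ``roboflapper``) or give
    explicit unit-suffixed values.
    """
    if "\n" in str(path_or_text) or ":" in str(path_or_text) and "{" in str(path_or_text):
        text = path_or_text
    else:
        try:
            with open(path_or_text) as fh:
                text = fh.read()
        except (OSError, ValueError):
            text = path_or_text
    raw = yaml.safe_load(text) or {}
    unknown = set(raw) - _KNOWN_BLOCKS
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
    plant_block = raw.get("plant", {"preset": "hawkmoth"})
    if "preset" in plant_block:
        preset = plant_block["preset"]
        if preset == "hawkmoth":
            plant = hawkmoth_plant()
        elif preset == "roboflapper":
            plant = roboflapper_plant()
        else:
            raise ValueError(f"unknown plant preset {preset!r}")
    else:
        plant = plant_from_params(plant_block)
    sim_block = raw.get("sim", {})
    sim = SimConfig(
        dt=float(sim_block.get("dt", 1e-4)),
        duration=float(sim_block.get("duration", 5.0)),
        phi0=float(sim_block.get("phi0", 0.1)),
        v0=float(sim_block.get("v0", 0.0)),
        integrator=sim_block.get("integrator", "rk4"),
        seed=sim_block.get("seed"),
    )
    digest = hashlib.sha256(
        yaml.safe_dump(raw, sort_keys=True).encode()
    ).hexdigest()[:16]
    return RunConfig(
        plant=plant,
        forcing=_convert_units(raw.get("forcing", {})),
        sim=sim,
        sweep=_convert_units(raw.get("sweep", {})),
        phylo=raw.get("phylo", {}),
        seeds=raw.get("seeds", {}),
        output_dir=raw.get("output_dir", "."),
        config_hash=digest,
        raw=raw,
    )


def reproducibility_block(config: RunConfig) -> dict:
    """Metadata written alongside every run's outputs."""
    import numpy
    import scipy

    import springwing

    return {
        "config_hash": config.config_hash,
        "dt": config.sim.dt,
        "integrator": config.sim.integrator,
        "springwing_version": springwing.__version__,
        "numpy_version": numpy.__version__,
        "scipy_version": scipy.__version__,
    }
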