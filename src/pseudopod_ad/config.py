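"""Simulation configuration: dataclasses, YAML round-trip, named profiles.

A :class:`SimConfig` gathers the geometry, flow, kinetic and engine
parameters of one run.  Two named profiles ship with the package:

``default_profile``
    The full study conditions: 384-element QUAD9 mesh, dt = 1 us,
    x_stop = 150 um, 25,100 receptors, bond cap 200.

``reduced_profile``
    A coarse, fast profile for tests and desk-scale sweeps: 96-element
    mesh, dt = 5 us (the coarsest step at which ensemble behaviour
    fractions are converged) and a proportionally reduced bond cap (40)
    so that the cap still plays its role of "large enough not to limit
    spontaneous formation" at a tractable simulated duration.  Physical
    constants (shear, kinetics, receptor count, steric layers, the
    150-um stop line) are unchanged.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .geometry import CellShapeParams
from .kinetics import KineticParams

__all__ = ["SimConfig", "default_profile", "reduced_profile",
           "load_config", "dump_config"]


@dataclass
class SimConfig:
    """Complete configuration of a single adhesive-dynamics run."""

    geometry: CellShapeParams = field(default_factory=CellShapeParams)
    kinetics: KineticParams = field(default_factory=KineticParams)

    # flow
    shear_rate: float = 1000.0        # 1/s
    viscosity: float = 1.0            # fN*s/um^2 (1 cP)

    # initial pose
    initial_gap: float = 0.5          # um, min steric-surface separation
    initial_orientation: tuple[float, float, float] = (0.0, 0.0, 0.0)  # z-y-z
    # fixed centroid height (um) overriding the per-pose gap adjustment;
    # used by the orientation grid so that rotated poses can penetrate
    initial_centroid_height: float | None = None

    # contact / binding geometry
    wall_steric_layer: float = 0.35   # um
    reactive_distance: float = 0.58   # um, from the wall steric surface

    # steric repulsion F = f0 * exp(-gap/lambda) for gap < 0
    steric_f0: float = 1.0e4          # fN
    steric_lambda: float = 0.01       # um

    # receptors / bonds
    total_receptors: int = 25_100
    max_bonds: int = 200

    # integration
    dt: float = 1.0e-6                # s
    max_steps: int = 2_000_000
    x_stop: float = 150.0             # um
    substep_threshold: float = 0.1    # max k*dt before kinetic sub-stepping
    # adaptive coarsening of bond-free flight: when no bonds exist and the
    # steric gap exceeds the threshold (well outside binding range), the
    # step is stretched by this factor
    coarse_dt_factor: int = 4
    coarse_gap_threshold: float = 0.5  # um
    regularization: float = 0.15      # stokes blob / sqrt(element area)
    adhesion_enabled: bool = True

    # firm-adhesion operationalisation
    firm_fraction: float = 0.5        # bonds >= fraction*max_bonds and ...
    stall_speed_fraction: float = 0.01  # |U| < fraction*shear*R_eq ...
    stall_time: float = 0.01          # ... sustained this long (s)

    # bookkeeping
    seed: int = 0
    record_every: int = 10            # full-state snapshot stride

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.x_stop <= 0:
            raise ValueError("x_stop must be positive")
        if self.max_bonds < 1:
            raise ValueError("max_bonds must be >= 1")
        if self.max_steps < 1:
            raise ValueError("max_steps must be >= 1")
        if self.total_receptors < 0:
            raise ValueError("total_receptors must be >= 0")

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["initial_orientation"] = list(self.initial_orientation)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "geometry" in d and isinstance(d["geometry"], dict):
            d["geometry"] = CellShapeParams(**d["geometry"])
        if "kinetics" in d and isinstance(d["kinetics"], dict):
            d["kinetics"] = KineticParams(**d["kinetics"])
        if "initial_orientation" in d:
            d["initial_orientation"] = tuple(d["initial_orientation"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


def default_profile(**overrides) -> SimConfig:
    """Full-resolution study conditions."""
    return SimConfig(**overrides) if overrides else SimConfig()


def reduced_profile(**overrides) -> SimConfig:
    """Coarse, fast profile for tests and desk-scale sweeps."""
    cfg = SimConfig(
        geometry=CellShapeParams(mesh_resolution=96),
        dt=5.0e-6,
        max_bonds=40,
        max_steps=80_000,
        record_every=20,
    )
    return cfg.replace(**overrides) if overrides else cfg


def load_config(path) -> SimConfig:
    """Read a YAML config file into a :class:`SimConfig`."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return SimConfig.from_dict(data)


def dump_config(cfg: SimConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)
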