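"""The four in-silico experiments: shear-rate sweep, bond-formation-rate
sweep, receptor-count sensitivity, and the initial-orientation grid.

Each sweep runs ``runs_per_value`` independently seeded simulations per
condition (seed = seed_base + run index, so results are independent of
execution order) and reduces them with :func:`metrics.sweep_summary`.
Failed runs are recorded and the sweep continues.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import SimConfig
from .engine import Trajectory, initial_state, run
from .geometry import build_cell_mesh, wall_gap
from .metrics import BehaviorSummary, summarize, sweep_summary

__all__ = [
    "SweepSpec",
    "SweepResult",
    "run_sweep",
    "shear_sweep",
    "onrate_sweep",
    "receptor_sweep",
    "orientation_grid",
    "PAPER_SHEAR_RATES",
    "PAPER_ONRATES",
    "PAPER_RECEPTOR_FRACTIONS",
]

#: conditions studied in the source experiments
PAPER_SHEAR_RATES = (100.0, 250.0, 500.0, 1000.0, 1500.0, 2000.0)  # 1/s
PAPER_ONRATES = (1.0, 5.0, 10.0, 15.0, 20.0)                       # 1/s
PAPER_RECEPTOR_FRACTIONS = (0.25, 0.5, 1.0, 2.0, 3.0)


@dataclass
class SweepSpec:
    """One-variable sweep over independently seeded repeats."""

    variable: str                      # shear_rate | kf2D0 | receptor_fraction
    values: tuple
    base_config: SimConfig = field(default_factory=SimConfig)
    runs_per_value: int = 10
    seed_base: int = 0

    def __post_init__(self) -> None:
        if not self.values:
            raise ValueError("values must be non-empty")
        if self.runs_per_value < 1:
            raise ValueError("runs_per_value must be >= 1")
        if self.variable not in ("shear_rate", "kf2D0", "receptor_fraction"):
            raise ValueError(f"unknown sweep variable {self.variable!r}")


@dataclass
class SweepResult:
    spec: SweepSpec
    trajectories: dict          # value -> list[Trajectory]
    summaries: dict             # value -> list[BehaviorSummary]
    failures: list              # (value, seed, message)
    table: pd.DataFrame


def _condition_config(spec: SweepSpec, value, seed: int) -> SimConfig:
    cfg = spec.base_config
    if spec.variable == "shear_rate":
        cfg = cfg.replace(shear_rate=float(value), seed=seed)
    elif spec.variable == "kf2D0":
        cfg = cfg.replace(kinetics=dataclasses.replace(cfg.kinetics, kf2D0=float(value)),
                          seed=seed)
    else:  # receptor_fraction scales the total receptor count
        total = int(round(value * cfg.total_receptors))
        cfg = cfg.replace(total_receptors=total, seed=seed)
    return cfg


def run_sweep(spec: SweepSpec) -> SweepResult:
    """Execute a sweep; one mesh is shared across all runs of a condition."""
    trajectories: dict = {}
    summaries: dict = {}
    failures = []
    for value in spec.values:
        trajs, summs = [], []
        for i in range(spec.runs_per_value):
            seed = spec.seed_base + i
            cfg = _condition_config(spec, value, seed)
            try:
                traj = run(cfg)
            except Exception as exc:  # noqa: BLE001 - sweep must continue
                failures.append((value, seed, str(exc)))
                continue
            trajs.append(traj)
            summs.append(summarize(traj))
        trajectories[value] = trajs
        summaries[value] = summs
    table = sweep_summary({v: s for v, s in summaries.items() if s})
    return SweepResult(spec=spec, trajectories=trajectories,
                       summaries=summaries, failures=failures, table=table)


def shear_sweep(base_config: SimConfig, values=PAPER_SHEAR_RATES,
                runs_per_value: int = 10, seed_base: int = 0) -> SweepResult:
    return run_sweep(SweepSpec("shear_rate", tuple(values), base_config,
                               runs_per_value, seed_base))


def onrate_sweep(base_config: SimConfig, values=PAPER_ONRATES,
                 runs_per_value: int = 10, seed_base: int = 0) -> SweepResult:
    return run_sweep(SweepSpec("kf2D0", tuple(values), base_config,
                               runs_per_value, seed_base))


def receptor_sweep(base_config: SimConfig, values=PAPER_RECEPTOR_FRACTIONS,
                   runs_per_value: int = 10, seed_base: int = 0) -> SweepResult:
    return run_sweep(SweepSpec("receptor_fraction", tuple(values), base_config,
                               runs_per_value, seed_base))


def orientation_angles(step: float = np.pi / 4, stop: float = np.pi):
    """The z-y-z angle grid: each angle spans [0, stop] inclusive."""
    vals = np.arange(0.0, stop + 1e-12, step)
    return [(a, b, c) for a in vals for b in vals for c in vals]


def orientation_grid(base_config: SimConfig, angles=None,
                     initial_gap: float = 1.0):
    """Initial-orientation experiment.

    The centroid height is fixed at the value that gives the default pose
    the requested initial gap; rotated poses whose steric surface then
    overlaps the wall are excluded and reported.  One simulation runs per
    admissible angle triple and per-node contact-time maps are pooled
    into bonded and non-bonded groups.

    Returns a dict with keys ``results`` (angle -> BehaviorSummary),
    ``trajectories``, ``excluded`` (angle list), ``contact_map_bonded``,
    ``contact_map_no_bonds`` and ``summaries_by_group``.
    """
    if angles is None:
        angles = orientation_angles()
    base = base_config.replace(initial_gap=initial_gap)
    mesh = build_cell_mesh(base.geometry)
    # height of the default pose at the requested gap, held fixed
    z_c = float(initial_state(mesh, base.replace(
        initial_orientation=(0.0, 0.0, 0.0))).centroid[2])
    base = base.replace(initial_centroid_height=z_c)

    results, trajectories, excluded = {}, {}, []
    map_bonded = np.zeros(mesh.n_nodes)
    map_none = np.zeros(mesh.n_nodes)
    for ang in angles:
        cfg = base.replace(initial_orientation=tuple(ang))
        state = initial_state(mesh, cfg)
        min_gap, _ = wall_gap(mesh, state, cfg.wall_steric_layer)
        if min_gap < 0.0:
            excluded.append(tuple(ang))
            continue
        traj = run(cfg, mesh=mesh)
        summ = summarize(traj)
        results[tuple(ang)] = summ
        trajectories[tuple(ang)] = traj
        if summ.category == "no_bonds":
            map_none += traj.per_node_contact_time
        else:
            map_bonded += traj.per_node_contact_time
    groups = {
        "bonds": [s for s in results.values() if s.category != "no_bonds"],
        "no_bonds": [s for s in results.values() if s.category == "no_bonds"],
    }
    table = sweep_summary({k: v for k, v in groups.items() if v})
    return {
        "results": results,
        "trajectories": trajectories,
        "excluded": excluded,
        "contact_map_bonded": map_bonded,
        "contact_map_no_bonds": map_none,
        "summaries_by_group": groups,
        "table": table,
        "mesh": mesh,
    }
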