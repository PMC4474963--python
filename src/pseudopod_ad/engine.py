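"""Time-stepping engine coupling hydrodynamics, contact and bond kinetics.

Each explicit step advances the rigid cell through a fixed sequence:

1. transform receptor sites to the world frame and find binding candidates
   (unbound receptors whose tips lie within the reactive distance of the
   wall steric surface);
2. draw Monte-Carlo bond formation/breakage events (kinetics module), with
   sub-stepping when rate * dt exceeds the configured threshold;
3. assemble the external load set: spring forces of surviving + new bonds
   and the short-range steric wall repulsion;
4. solve the wall-bounded mobility problem for (U, Omega);
5. advance the centroid by U*dt and the orientation by the quaternion
   exponential of Omega*dt.

The run terminates when the centroid passes ``x_stop``, when the cell is
firmly adhered (bond count at the cap, or at least ``firm_fraction`` of
the cap while effectively stalled for ``stall_time``), or when
``max_steps`` is exhausted (reported, not silent).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .config import SimConfig
from .geometry import CellMesh, ReceptorSet, allocate_receptors, build_cell_mesh
from .kinetics import Bond, BondEvent, dissociation_rate, formation_rate
from .stokes import FlowConfig, LoadSet, MobilitySolver, RigidState

__all__ = ["Trajectory", "steric_force", "initial_state", "step", "run"]

# Bell formation exponent below which a candidate cannot realistically bind
# (k_f suppressed by > e^-30); pruning these receptors leaves the event
# statistics unchanged while keeping the candidate list short.
_FORMATION_EXP_CUTOFF = -30.0


@dataclass
class Trajectory:
    """Per-step record of one simulation run."""

    config: SimConfig
    times: np.ndarray             # (n_steps,)
    dts: np.ndarray               # (n_steps,) per-step durations
    centroid: np.ndarray          # (n_steps, 3)
    bond_counts: np.ndarray       # (n_steps,) int
    contact_area: np.ndarray      # (n_steps,) um^2
    any_contact: np.ndarray       # (n_steps,) bool
    min_gap: np.ndarray           # (n_steps,)
    speed: np.ndarray             # (n_steps,) |U|
    events: list[BondEvent]
    termination_reason: str       # reached_x_stop | firm_adhesion | max_steps
    per_node_contact_time: np.ndarray  # (n_nodes,) s
    # snapshots at record stride
    snapshot_times: np.ndarray
    snapshot_quat: np.ndarray     # (n_snap, 4) scipy xyzw
    snapshot_U: np.ndarray
    snapshot_Omega: np.ndarray
    snapshot_contact: np.ndarray  # (n_snap, n_nodes) bool

    @property
    def dt(self) -> float:
        """Base (fine) step; bonded and near-wall phases always use it."""
        return self.config.dt

    @property
    def n_steps(self) -> int:
        return len(self.times)

    @property
    def final_time(self) -> float:
        return float(self.times[-1]) if self.n_steps else 0.0


def steric_force(per_node_gap: np.ndarray, world_nodes: np.ndarray,
                 centroid: np.ndarray, f0: float, lam: float) -> LoadSet:
    """Short-range wall-normal repulsion on sterically overlapping nodes.

    Each node with a negative steric gap receives an upward force
    f0 * exp(-gap/lam); the torque uses the node position as the lever.
    Zero where no node overlaps.
    """
    overlapping = np.flatnonzero(per_node_gap < 0.0)
    load = LoadSet()
    if overlapping.size == 0:
        return load
    mag = f0 * np.exp(np.minimum(-per_node_gap[overlapping] / lam, 20.0))
    load.total_force = np.array([0.0, 0.0, mag.sum()])
    lever = world_nodes[overlapping] - centroid
    # torque = sum lever x (mag * z_hat)
    load.total_torque = np.einsum(
        "ni,n->i", np.cross(lever, np.array([0.0, 0.0, 1.0])), mag)
    return load


def initial_state(mesh: CellMesh, config: SimConfig) -> RigidState:
    """Default pose: pseudopod axis downstream (+x), major axis parallel to
    the wall, centred laterally, at the configured initial steric gap.

    ``initial_orientation`` applies an intrinsic z-y-z rotation on top of
    the default pose before the height is set.
    """
    angles = config.initial_orientation
    rot = Rotation.from_euler("ZYZ", angles) if any(angles) else Rotation.identity()
    if config.initial_centroid_height is not None:
        z_c = config.initial_centroid_height
    else:
        lowest = rot.apply(mesh.nodes)[:, 2].min()
        z_c = (config.initial_gap + config.wall_steric_layer
               + mesh.shape.cell_steric_layer - lowest)
    return RigidState(centroid=np.array([0.0, 0.0, z_c]), rotation=rot)


class _Engine:
    """Mutable per-run machinery shared by :func:`step` and :func:`run`."""

    def __init__(self, config: SimConfig, mesh: CellMesh | None = None,
                 receptors: ReceptorSet | None = None):
        self.config = config
        self.mesh = mesh if mesh is not None else build_cell_mesh(config.geometry)
        if receptors is None:
            receptors = allocate_receptors(self.mesh, config.total_receptors)
        self.receptors = receptors
        self.solver = MobilitySolver(self.mesh, config.regularization)
        self.flow = FlowConfig(shear_rate=config.shear_rate,
                               viscosity=config.viscosity)
        p = config.kinetics
        # receptor-tip height (above the wall steric surface) beyond which
        # the Bell formation exponent drops below the cutoff; tips lower
        # than lb can always reach a laterally offset ligand at natural
        # length, so there is no lower cutoff
        half_width = math.sqrt(max(
            -2.0 * _FORMATION_EXP_CUTOFF * p.kBT / p.sigma, 0.0)) if p.sigma > 0 else np.inf
        self.bind_hi = p.lb + half_width + p.gamma_f
        # receptors grouped by element (receptor arrays are element-sorted)
        counts = np.bincount(receptors.element_index,
                             minlength=self.mesh.n_elements)
        ends = np.cumsum(counts)
        self._rec_start = ends - counts
        self._rec_end = ends
        self.cell_steric = config.geometry.cell_steric_layer
        self.contact_z = config.wall_steric_layer + config.reactive_distance

    # -- geometry helpers -------------------------------------------------
    def world_nodes(self, state: RigidState, rot: np.ndarray | None = None) -> np.ndarray:
        if rot is None:
            rot = state.rotation.as_matrix()
        return self.mesh.nodes @ rot.T + state.centroid

    def candidate_receptors(self, state: RigidState, bound_idx: set[int],
                            rot: np.ndarray | None = None):
        """Unbound receptors whose tips are within reactive range.

        Returns (indices, tips, deviations) pruned to tips whose Bell
        exponent is above the cutoff (others have vanishing rates).
        """
        cfg = self.config
        rec = self.receptors
        if rot is None:
            rot = state.rotation.as_matrix()
        # cheap pre-cull by element: only elements dipping near the wall
        el_z = self.mesh.element_centroids @ rot[2] + state.centroid[2]
        el_r = np.sqrt(self.mesh.element_areas)  # element size scale
        low = np.flatnonzero(el_z - 1.5 * el_r - self.cell_steric < self.contact_z)
        if low.size == 0:
            return np.empty(0, np.intp), np.empty((0, 3)), np.empty(0)
        idx = np.concatenate([np.arange(self._rec_start[e], self._rec_end[e])
                              for e in low])
        tips = (rec.positions[idx] + self.cell_steric * rec.normals[idx]) @ rot.T \
            + state.centroid
        zt = tips[:, 2] - cfg.wall_steric_layer
        keep = (zt <= cfg.reactive_distance) & (zt <= self.bind_hi)
        if bound_idx:
            keep &= ~np.isin(idx, np.fromiter(bound_idx, dtype=np.intp))
        idx, tips, zt = idx[keep], tips[keep], zt[keep]
        # deviation of the deviation-minimising bond: a tip below the
        # natural length binds an anchor at lateral offset sqrt(lb^2-zt^2)
        # with zero stretch; higher tips need a vertical, stretched bond
        dev = np.maximum(zt - cfg.kinetics.lb, 0.0)
        return idx, tips, dev

    def receptor_tips(self, state: RigidState, indices: np.ndarray,
                      rot: np.ndarray | None = None) -> np.ndarray:
        if rot is None:
            rot = state.rotation.as_matrix()
        rec = self.receptors
        return (rec.positions[indices] + self.cell_steric * rec.normals[indices]) \
            @ rot.T + state.centroid


def _bond_loads(bonds: list[Bond], tips: np.ndarray, centroid: np.ndarray,
                sigma: float, lb: float) -> tuple[LoadSet, np.ndarray]:
    """Spring loads of all bonds; also refreshes each bond's xb/force."""
    load = LoadSet()
    if not bonds:
        return load, np.empty(0)
    anchors = np.array([b.wall_anchor for b in bonds])
    d = anchors - tips
    xb = np.linalg.norm(d, axis=1)
    xb_safe = np.where(xb > 0, xb, 1.0)
    fvec = sigma * (xb - lb)[:, None] * d / xb_safe[:, None]
    for b, x, f in zip(bonds, xb, sigma * np.abs(xb - lb)):
        b.xb = float(x)
        b.deviation = abs(float(x) - lb)
        b.force = float(f)
    load.total_force = fvec.sum(axis=0)
    load.total_torque = np.cross(tips - centroid, fvec).sum(axis=0)
    return load, np.abs(sigma * (xb - lb))


def step(state: RigidState, bonds: list[Bond], engine: _Engine,
         rng: np.random.Generator, time: float, dt: float | None = None):
    """Advance one time step; returns (new_state, bonds, events, info)."""
    cfg = engine.config
    if dt is None:
        dt = cfg.dt
    p = cfg.kinetics
    mesh = engine.mesh

    rot = state.rotation.as_matrix()
    nodes_w = engine.world_nodes(state, rot)
    per_node_gap = nodes_w[:, 2] - cfg.wall_steric_layer - engine.cell_steric
    contact = nodes_w[:, 2] <= engine.contact_z

    events: list[BondEvent] = []
    if cfg.adhesion_enabled and p.kf2D0 >= 0:
        bound_idx = {b.receptor_index for b in bonds}
        cand_idx, cand_tips, cand_dev = engine.candidate_receptors(state, bound_idx, rot)
        # slip velocity of candidate receptor sites (previous step's motion)
        if cand_idx.size:
            v = state.point_velocity(cand_tips)
            cand_vs = np.hypot(v[:, 0], v[:, 1])
        else:
            cand_vs = np.empty(0)

        # current forces on existing bonds (tips move with the body)
        if bonds:
            btips = engine.receptor_tips(
                state, np.array([b.receptor_index for b in bonds], dtype=np.intp), rot)
            _, bforce = _bond_loads(bonds, btips, state.centroid, p.sigma, p.lb)
        else:
            bforce = np.empty(0)

        # kinetic sub-stepping keeps Bernoulli probabilities faithful
        kf = formation_rate(cand_dev, cand_vs, p) if cand_idx.size else np.empty(0)
        kr = dissociation_rate(bforce, p) if len(bonds) else np.empty(0)
        kmax = max(kf.max() if kf.size else 0.0, kr.max() if kr.size else 0.0)
        nsub = min(int(math.ceil(kmax * dt / cfg.substep_threshold)), 100) or 1
        dts = dt / nsub

        free = np.ones(len(cand_idx), dtype=bool)
        for _ in range(nsub):
            # formation draws
            if cand_idx.size:
                pf = -np.expm1(-kf * dts)
                hits = (rng.random(len(cand_idx)) < pf) & free
                for j in np.flatnonzero(hits):
                    if len(bonds) >= cfg.max_bonds:
                        break
                    tip = cand_tips[j]
                    zt = float(tip[2] - cfg.wall_steric_layer)
                    # deviation-minimising anchor on the wall steric plane:
                    # vertical when the tip is above the natural length,
                    # laterally offset (random azimuth) when below
                    rho = math.sqrt(max(p.lb**2 - zt**2, 0.0))
                    if rho > 0.0:
                        phi = rng.uniform(0.0, 2.0 * np.pi)
                        anchor = np.array([tip[0] + rho * math.cos(phi),
                                           tip[1] + rho * math.sin(phi),
                                           cfg.wall_steric_layer])
                    else:
                        anchor = np.array([tip[0], tip[1], cfg.wall_steric_layer])
                    xb = float(np.linalg.norm(anchor - tip))
                    b = Bond(receptor_index=int(cand_idx[j]), wall_anchor=anchor,
                             xb=xb, deviation=abs(xb - p.lb),
                             force=p.sigma * abs(xb - p.lb), t_formed=time)
                    bonds.append(b)
                    events.append(BondEvent("formation", b, time))
                    free[j] = False
            # breakage draws (forces frozen over the step)
            if bonds:
                bf = np.array([b.force for b in bonds])
                pr = -np.expm1(-dissociation_rate(bf, p) * dts)
                breaks = rng.random(len(bonds)) < pr
                for j in sorted(np.flatnonzero(breaks), reverse=True):
                    events.append(BondEvent("breakage", bonds[j], time))
                    del bonds[j]

    # loads: surviving + new bonds, then steric repulsion
    if bonds:
        btips = engine.receptor_tips(
            state, np.array([b.receptor_index for b in bonds], dtype=np.intp), rot)
        bond_load, _ = _bond_loads(bonds, btips, state.centroid, p.sigma, p.lb)
    else:
        bond_load = LoadSet()
    ster = steric_force(per_node_gap, nodes_w, state.centroid,
                        cfg.steric_f0, cfg.steric_lambda)
    loads = bond_load + ster

    U, Omega = engine.solver.solve(state, engine.flow, loads)
    state.U, state.Omega = U, Omega
    new_state = state.advance(dt)
    # guard: a single explicit step must not carry the surface through the
    # wall plane; if it would, shrink the advance so the lowest node stays
    # just above it (the steric repulsion resolves the overlap next steps)
    floor = 0.02
    new_low = engine.world_nodes(new_state)[:, 2].min()
    if new_low < floor:
        old_low = nodes_w[:, 2].min()
        frac = max((old_low - floor) / max(old_low - new_low, 1e-12), 0.0)
        new_state = state.advance(dt * frac)

    info = {
        "per_node_gap": per_node_gap,
        "contact": contact,
        "min_gap": float(per_node_gap.min()),
        "loads": loads,
    }
    return new_state, bonds, events, info


def run(config: SimConfig, mesh: CellMesh | None = None,
        receptors: ReceptorSet | None = None) -> Trajectory:
    """Run a full simulation and return its :class:`Trajectory`."""
    engine = _Engine(config, mesh, receptors)
    mesh = engine.mesh
    rng = np.random.default_rng(config.seed)
    state = initial_state(mesh, config)

    # element -> contact area bookkeeping
    elements = mesh.elements
    areas = mesh.element_areas

    times, dts, cx, counts, careas, anyc, mingap, speeds = \
        [], [], [], [], [], [], [], []
    snap_t, snap_q, snap_u, snap_w, snap_c = [], [], [], [], []
    node_contact_time = np.zeros(mesh.n_nodes)
    all_events: list[BondEvent] = []
    bonds: list[Bond] = []

    stall_speed = config.stall_speed_fraction * config.shear_rate * \
        config.geometry.equivalent_radius
    firm_count = math.ceil(config.firm_fraction * config.max_bonds)
    stall_time = 0.0

    reason = "max_steps"
    t = 0.0
    prev_gap = config.initial_gap
    for istep in range(config.max_steps):
        # bond-free flight well outside binding range integrates coarsely
        dt_step = config.dt
        if (config.coarse_dt_factor > 1 and not bonds
                and prev_gap > config.coarse_gap_threshold):
            dt_step = config.dt * config.coarse_dt_factor
        state, bonds, events, info = step(state, bonds, engine, rng, t, dt_step)
        all_events.extend(events)
        prev_gap = info["min_gap"]

        contact = info["contact"]
        in_contact = bool(contact.any())
        area = float(areas[contact[elements].any(axis=1)].sum()) if in_contact else 0.0
        node_contact_time[contact] += dt_step

        times.append(t)
        dts.append(dt_step)
        cx.append(state.centroid.copy())
        counts.append(len(bonds))
        careas.append(area)
        anyc.append(in_contact)
        mingap.append(info["min_gap"])
        spd = float(np.linalg.norm(state.U))
        speeds.append(spd)

        if istep % config.record_every == 0:
            snap_t.append(t)
            snap_q.append(state.rotation.as_quat())
            snap_u.append(state.U.copy())
            snap_w.append(state.Omega.copy())
            snap_c.append(contact.copy())

        t += dt_step

        # termination checks
        if len(bonds) >= config.max_bonds:
            reason = "firm_adhesion"
            break
        if len(bonds) >= firm_count and spd < stall_speed:
            stall_time += dt_step
            if stall_time >= config.stall_time:
                reason = "firm_adhesion"
                break
        else:
            stall_time = 0.0
        if state.centroid[0] >= config.x_stop:
            reason = "reached_x_stop"
            break

    return Trajectory(
        config=config,
        times=np.asarray(times),
        dts=np.asarray(dts),
        centroid=np.asarray(cx),
        bond_counts=np.asarray(counts, dtype=np.int64),
        contact_area=np.asarray(careas),
        any_contact=np.asarray(anyc, dtype=bool),
        min_gap=np.asarray(mingap),
        speed=np.asarray(speeds),
        events=all_events,
        termination_reason=reason,
        per_node_contact_time=node_contact_time,
        snapshot_times=np.asarray(snap_t),
        snapshot_quat=np.asarray(snap_q),
        snapshot_U=np.asarray(snap_u),
        snapshot_Omega=np.asarray(snap_w),
        snapshot_contact=np.asarray(snap_c, dtype=bool),
    )
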