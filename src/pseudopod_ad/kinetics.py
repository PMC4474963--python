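"""P-selectin/PSGL-1 bond kinetics: formation, catch-slip dissociation,
Monte-Carlo event sampling and spring forces.

Bonds are linearly elastic springs of stiffness ``sigma`` and equilibrium
length ``lb``; the instantaneous bond force is f = sigma * |xb - lb| where
xb is the receptor-tip-to-anchor distance.

Formation follows Bell's expression for the equilibrium constant of
cell-cell bridging, evaluated with the transition-state spring:

    kf(xb) = kf2D0 * exp( sigma * |xb - lb| * (gamma_f - 0.5 |xb - lb|) / kBT )

so an unstressed encounter (xb == lb) forms at the intrinsic 2-D rate
kf2D0.  ``gamma_f`` is the reactive compliance; for deviations beyond
~2*gamma_f the quadratic term dominates and the rate falls off as a
Gaussian of width sqrt(2 kBT / sigma) (~6 nm with the default stiffness),
which restricts binding to receptors whose tips sit near the natural bond
length above the wall.  An optional multiplicative slip-velocity
attenuation exists (``slip_velocity_scale``); by default it is off and the
rate is purely length-dependent.

Dissociation follows the two-pathway (catch-slip) model: the bond
population is split between a native conformation (N) whose rupture rate
is force-independent and an intermediate conformation (I) whose rupture
rate grows exponentially with force (Bell slip).  The force-dependent
population ratio Phi = [I]/[N] interpolates the two:

    kr(f) = kN/(1 + Phi) + Phi * kI(f)/(1 + Phi)
    kI(f) = kI_off0 * exp(yI * f / kBT)
    Phi(f) = phi0 * exp(gamma_prime * f / kBT)

Per time step, each eligible free receptor forms a bond with probability
1 - exp(-kf dt) and each existing bond breaks with probability
1 - exp(-kr dt), with independent draws from the run's RNG.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from . import units

__all__ = [
    "KineticParams",
    "Bond",
    "BondEvent",
    "formation_rate",
    "dissociation_rate",
    "slip_dissociation_rate",
    "slip_velocity",
    "bond_geometry",
    "sample_events",
]

#: cap on Bell exponents to avoid overflow; exp(50) ~ 5e21 1/s saturates
#: any per-step probability to 1 long before this matters physically.
_EXP_CAP = 50.0


@dataclass
class KineticParams:
    """Kinetic constants of the P-selectin/PSGL-1 pair.

    Defaults are the experimentally anchored values used throughout the
    simulations; lengths in um, rates in 1/s, forces in fN, energies in
    fN*um.
    """

    kf2D0: float = 10.0          # unstressed 2-D formation rate (1/s)
    sigma: float = 250_000.0     # bond spring constant (fN/um)
    lb: float = 0.08             # equilibrium bond length (um)
    gamma_f: float = 3.9e-5      # reactive compliance for formation (um)
    kN_off0: float = 9.0         # catch-pathway unstressed off-rate (1/s)
    kI_off0: float = 0.33        # slip-pathway unstressed off-rate (1/s)
    yI: float = 2.4e-4           # slip force compliance (um)
    phi0: float = 90.01          # unstressed [I]/[N] equilibrium constant
    gamma_prime: float = 8.16e-7 # force compliance ratio (um; 8.16e-4 nm)
    temperature: float = units.BODY_TEMPERATURE  # K
    slip_velocity_scale: float = 0.0  # um/s; 0 disables velocity attenuation

    def __post_init__(self) -> None:
        for name in ("kf2D0", "sigma", "lb", "gamma_f", "kN_off0", "kI_off0",
                     "yI", "phi0", "gamma_prime"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    @property
    def kBT(self) -> float:
        return units.thermal_energy(self.temperature)


@dataclass
class Bond:
    """A single receptor-wall tether.

    The wall anchor is fixed at formation (vertical projection of the
    receptor tip onto the wall steric surface, i.e. the minimal-length
    bond) and never moves.
    """

    receptor_index: int
    wall_anchor: np.ndarray       # (3,) on the wall steric surface
    xb: float                     # current tip-to-anchor distance (um)
    deviation: float              # |xb - lb| (um)
    force: float                  # sigma * deviation (fN)
    t_formed: float               # s

    def __post_init__(self) -> None:
        self.wall_anchor = np.asarray(self.wall_anchor, dtype=float)


@dataclass
class BondEvent:
    kind: str                     # "formation" | "breakage"
    bond: Bond
    time: float


def _bell_formation_exponent(deviation: np.ndarray, p: KineticParams) -> np.ndarray:
    return p.sigma * deviation * (p.gamma_f - 0.5 * deviation) / p.kBT


def formation_rate(deviation, slip_velocity=0.0, p: KineticParams | None = None):
    """Bond formation rate (1/s) at the given bond-length deviation.

    ``deviation`` is |xb - lb| in um.  The optional slip-velocity
    attenuation multiplies by exp(-v / slip_velocity_scale) when a scale is
    configured; the default leaves formation purely length-dependent.
    Scalar or array inputs are supported.
    """
    if p is None:
        p = KineticParams()
    deviation = np.asarray(deviation, dtype=float)
    if np.any(deviation < 0):
        raise ValueError("deviation must be >= 0")
    expo = np.clip(_bell_formation_exponent(deviation, p), -_EXP_CAP, _EXP_CAP)
    kf = p.kf2D0 * np.exp(expo)
    if p.slip_velocity_scale > 0:
        v = np.asarray(slip_velocity, dtype=float)
        kf = kf * np.exp(-np.clip(v / p.slip_velocity_scale, 0.0, _EXP_CAP))
    return kf if kf.ndim else float(kf)


def dissociation_rate(force, p: KineticParams | None = None):
    """Two-pathway (catch-slip) dissociation rate (1/s) at bond force fN."""
    if p is None:
        p = KineticParams()
    f = np.asarray(force, dtype=float)
    if np.any(f < 0):
        raise ValueError("force must be >= 0")
    phi = p.phi0 * np.exp(np.clip(p.gamma_prime * f / p.kBT, -_EXP_CAP, _EXP_CAP))
    kI = p.kI_off0 * np.exp(np.clip(p.yI * f / p.kBT, -_EXP_CAP, _EXP_CAP))
    kr = (p.kN_off0 + phi * kI) / (1.0 + phi)
    return kr if kr.ndim else float(kr)


def population_ratio(force, p: KineticParams | None = None):
    """Phi(f): force-dependent intermediate/native population ratio."""
    if p is None:
        p = KineticParams()
    f = np.asarray(force, dtype=float)
    phi = p.phi0 * np.exp(np.clip(p.gamma_prime * f / p.kBT, -_EXP_CAP, _EXP_CAP))
    return phi if phi.ndim else float(phi)


def slip_dissociation_rate(force, p: KineticParams | None = None):
    """Single-pathway Bell slip off-rate (legacy mode, testing only)."""
    if p is None:
        p = KineticParams()
    f = np.asarray(force, dtype=float)
    kr = p.kN_off0 * np.exp(np.clip(p.gamma_f * f / p.kBT, -_EXP_CAP, _EXP_CAP))
    return kr if kr.ndim else float(kr)


def slip_velocity(state, receptor_world_positions: np.ndarray) -> np.ndarray:
    """Wall-parallel speed of receptor sites carried by the rigid body."""
    v = state.point_velocity(np.atleast_2d(receptor_world_positions))
    return np.hypot(v[:, 0], v[:, 1])


def bond_geometry(receptor_tip: np.ndarray, wall_anchor: np.ndarray,
                  p: KineticParams):
    """Length, deviation and force vector of a bond.

    Returns ``(xb, deviation, force_vector)`` where the force vector acts
    on the cell at the receptor tip: tension (xb > lb) pulls the tip
    toward the anchor, compression pushes it away.
    """
    tip = np.asarray(receptor_tip, dtype=float)
    anchor = np.asarray(wall_anchor, dtype=float)
    d = anchor - tip
    xb = float(np.linalg.norm(d))
    deviation = abs(xb - p.lb)
    if xb == 0.0:
        return 0.0, p.lb, np.zeros(3)
    force_vec = p.sigma * (xb - p.lb) * d / xb
    return xb, deviation, force_vec


def sample_events(bound: Sequence[Bond],
                  candidates: Iterable[tuple[int, float, float]],
                  dt: float, p: KineticParams, rng: np.random.Generator,
                  time: float = 0.0,
                  candidate_tips: np.ndarray | None = None,
                  wall_steric_layer: float = 0.35) -> list[BondEvent]:
    """Draw formation and breakage events for one time step.

    Parameters
    ----------
    bound : existing bonds (their ``force`` must be current).
    candidates : iterable of (receptor_index, deviation, slip_velocity)
        for unbound receptors within reactive range.
    candidate_tips : optional (n, 3) world tips of the candidate receptors,
        used to place the wall anchor vertically beneath the tip on the
        wall steric surface.

    Breakage and formation draws are independent Bernoulli trials with
    P = 1 - exp(-k dt).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    events: list[BondEvent] = []

    cand = list(candidates)
    if cand:
        idx = np.array([c[0] for c in cand], dtype=np.intp)
        dev = np.array([c[1] for c in cand], dtype=float)
        vs = np.array([c[2] for c in cand], dtype=float)
        kf = np.asarray(formation_rate(dev, vs, p), dtype=float).reshape(-1)
        pf = -np.expm1(-kf * dt)
        hits = rng.random(len(cand)) < pf
        for j in np.flatnonzero(hits):
            if candidate_tips is not None:
                tip = candidate_tips[j]
                anchor = np.array([tip[0], tip[1], wall_steric_layer])
                xb = float(abs(tip[2] - wall_steric_layer))
            else:
                anchor = np.zeros(3)
                xb = p.lb + dev[j]
            bond = Bond(receptor_index=int(idx[j]), wall_anchor=anchor,
                        xb=xb, deviation=abs(xb - p.lb),
                        force=p.sigma * abs(xb - p.lb), t_formed=time)
            events.append(BondEvent("formation", bond, time))

    if bound:
        forces = np.array([b.force for b in bound], dtype=float)
        kr = np.asarray(dissociation_rate(forces, p), dtype=float).reshape(-1)
        pr = -np.expm1(-kr * dt)
        breaks = rng.random(len(bound)) < pr
        for j in np.flatnonzero(breaks):
            events.append(BondEvent("breakage", bound[j], time))
    return events
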