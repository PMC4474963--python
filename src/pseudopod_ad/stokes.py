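"""Rigid-body Stokes mobility of the cell above a plane no-slip wall.

The ambient flow is linear shear u = shear_rate * z * x_hat over the wall
z = 0.  At zero Reynolds number the instantaneous translational/angular
velocity (U, Omega) of the force- and torque-loaded rigid cell follows from
a quasi-static balance between hydrodynamic drag and the applied loads
(bond springs + steric repulsion).

The solver is a first-kind boundary-integral method: a single-layer density
on the cell surface, constant per QUAD9 element, collocated at element
centres, with the wall no-slip condition built into the kernel through the
classical image system for a point force above a plane wall (Stokeslet +
image Stokeslet + potential dipole + Stokeslet doublet).  The free-space
Stokeslet is regularised with a blob parameter tied to the local element
size, which keeps the self-element quadrature finite and the collocation
system well conditioned; the image-system terms are evaluated in
unregularised form since the image singularities lie below the wall.

Given the element densities q_e, the hydrodynamic force/torque on the body
are surface integrals of q; writing the rigid-body boundary condition for
the six unit rigid modes yields a 6x6 resistance matrix R and a shear
forcing vector s, and the mobility solve is

    [U, Omega] = R^{-1} ([F_ext, T_ext] + s).

With zero loads the motion is force- and torque-free (freestream advection
with wall retardation); far from the wall the translation tends to
shear_rate * z_c and the rotation to shear_rate / 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numba
import numpy as np
import scipy.linalg
from scipy.spatial.transform import Rotation

from .geometry import CellMesh

__all__ = [
    "FlowConfig",
    "RigidState",
    "LoadSet",
    "MobilitySolverError",
    "wall_greens_function",
    "blake_tensor",
    "MobilitySolver",
    "solve_mobility",
]


class MobilitySolverError(RuntimeError):
    """Collocation system could not be solved (e.g. mesh touching the wall)."""


@dataclass
class FlowConfig:
    """Ambient linear shear flow u = shear_rate * z * x_hat."""

    shear_rate: float = 1000.0   # 1/s
    viscosity: float = 1.0       # fN*s/um^2 (1.0 == 1 cP, plasma)

    def __post_init__(self) -> None:
        if self.shear_rate < 0:
            raise ValueError("shear_rate must be >= 0")
        if self.viscosity <= 0:
            raise ValueError("viscosity must be positive")

    def ambient(self, points: np.ndarray) -> np.ndarray:
        u = np.zeros_like(points)
        u[..., 0] = self.shear_rate * points[..., 2]
        return u


@dataclass
class RigidState:
    """Pose and velocity of the rigid cell.

    ``rotation`` maps body-frame coordinates to world-frame offsets from
    the centroid.
    """

    centroid: np.ndarray = field(default_factory=lambda: np.zeros(3))
    rotation: Rotation = field(default_factory=Rotation.identity)
    U: np.ndarray = field(default_factory=lambda: np.zeros(3))
    Omega: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.centroid = np.asarray(self.centroid, dtype=float)
        self.U = np.asarray(self.U, dtype=float)
        self.Omega = np.asarray(self.Omega, dtype=float)

    def to_world(self, body_points: np.ndarray) -> np.ndarray:
        return self.rotation.apply(body_points) + self.centroid

    def rotate_vectors(self, body_vectors: np.ndarray) -> np.ndarray:
        return self.rotation.apply(body_vectors)

    def point_velocity(self, world_points: np.ndarray) -> np.ndarray:
        """Material velocity U + Omega x (x - centroid) of surface points."""
        return self.U + np.cross(self.Omega, world_points - self.centroid)

    def advance(self, dt: float) -> "RigidState":
        """Explicit rigid-body update over dt (quaternion exponential map)."""
        rot = Rotation.from_rotvec(self.Omega * dt) * self.rotation
        return RigidState(
            centroid=self.centroid + self.U * dt,
            rotation=rot,
            U=self.U.copy(),
            Omega=self.Omega.copy(),
        )


@dataclass
class LoadSet:
    """External force/torque (about the centroid) applied to the cell."""

    total_force: np.ndarray = field(default_factory=lambda: np.zeros(3))
    total_torque: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __add__(self, other: "LoadSet") -> "LoadSet":
        return LoadSet(self.total_force + other.total_force,
                       self.total_torque + other.total_torque)


def _stokeslet(r: np.ndarray, eps: float | np.ndarray = 0.0) -> np.ndarray:
    """(Regularised) Oseen tensor, shape (..., 3, 3), without 1/(8 pi mu)."""
    r = np.asarray(r, dtype=float)
    r2 = np.einsum("...i,...i->...", r, r)
    e2 = np.broadcast_to(np.asarray(eps, dtype=float) ** 2, r2.shape)
    d2 = r2 + e2
    d = np.sqrt(d2)
    inv3 = 1.0 / (d2 * d)
    iso = (r2 + 2.0 * e2) * inv3
    out = np.einsum("...i,...j->...ij", r, r) * inv3[..., None, None]
    out[..., 0, 0] += iso
    out[..., 1, 1] += iso
    out[..., 2, 2] += iso
    return out


def blake_tensor(field_points: np.ndarray, source_points: np.ndarray,
                 eps: float | np.ndarray = 0.0) -> np.ndarray:
    """Green's function for a point force above the no-slip wall z = 0.

    Broadcasts over leading dimensions: for field x and source y (with
    source height h) the velocity at x due to a force F at y is
    G . F / (8 pi mu).  The image system (image Stokeslet, potential
    dipole, Stokeslet doublet) enforces u = 0 on z = 0 exactly when
    eps = 0.  ``eps`` regularises only the free-space Stokeslet.
    """
    x = np.asarray(field_points, dtype=float)
    y = np.asarray(source_points, dtype=float)
    h = y[..., 2]
    ystar = y.copy()
    ystar[..., 2] = -h

    r = x - y
    R = x - ystar
    G = _stokeslet(r, eps) - _stokeslet(R, eps)

    Rn = np.sqrt(np.einsum("...i,...i->...", R, R))
    inv3 = Rn**-3
    inv5 = Rn**-5
    R3 = R[..., 2]

    # D[i, l] = d phi_i / d R_l with
    # phi_i = h R_i / R^3 - delta_i3 / R - R_i R_3 / R^3
    eye = np.eye(3)
    RiRl = np.einsum("...i,...l->...il", R, R)
    D = h[..., None, None] * (eye * inv3[..., None, None] - 3.0 * RiRl * inv5[..., None, None])
    D[..., 2, :] += R * inv3[..., None]
    D -= eye * (R3 * inv3)[..., None, None]
    D -= np.einsum("...i,l->...il", R, eye[2]) * inv3[..., None, None]
    D += 3.0 * RiRl * (R3 * inv5)[..., None, None]

    sign = np.array([1.0, 1.0, -1.0])
    G += 2.0 * h[..., None, None] * D * sign[None, :]
    return G


def wall_greens_function(source: np.ndarray, fieldp: np.ndarray,
                         viscosity: float = 1.0) -> np.ndarray:
    """Velocity response tensor u_i = G_ij F_j for a point force at ``source``.

    Both points must lie strictly above the wall (field points exactly on
    z = 0 are allowed and return zero by the no-slip property; points below
    are rejected).
    """
    source = np.asarray(source, dtype=float)
    fieldp = np.asarray(fieldp, dtype=float)
    if np.any(source[..., 2] <= 0):
        raise ValueError("source point must lie strictly above the wall z=0")
    if np.any(fieldp[..., 2] < 0):
        raise ValueError("field point must not lie below the wall z=0")
    return blake_tensor(fieldp, source) / (8.0 * np.pi * viscosity)


@numba.njit(cache=True, fastmath=True)
def _assemble_kernel(colloc, qp, wj, eps, ne):  # pragma: no cover - jitted
    """Dense single-layer matrix: collocation x (element-summed quadrature).

    Same mathematics as :func:`blake_tensor` (regularised free-space pair,
    exact image system), written out scalar-wise for speed.
    """
    nc = colloc.shape[0]
    nq = qp.shape[0]
    per = nq // ne
    A = np.zeros((3 * nc, 3 * ne))
    Gxx = np.empty((3, 3))
    for i in range(nc):
        xi0, xi1, xi2 = colloc[i, 0], colloc[i, 1], colloc[i, 2]
        for q in range(nq):
            e = q // per
            w = wj[q]
            h = qp[q, 2]
            ep2 = eps[q] * eps[q]
            r0 = xi0 - qp[q, 0]
            r1 = xi1 - qp[q, 1]
            r2 = xi2 - h
            R2 = xi2 + h
            # regularised Stokeslet of the real point force
            rr = r0 * r0 + r1 * r1 + r2 * r2
            d2 = rr + ep2
            inv3 = 1.0 / (d2 * np.sqrt(d2))
            iso = (rr + 2.0 * ep2) * inv3
            G00 = iso + r0 * r0 * inv3
            G01 = r0 * r1 * inv3
            G02 = r0 * r2 * inv3
            G11 = iso + r1 * r1 * inv3
            G12 = r1 * r2 * inv3
            G22 = iso + r2 * r2 * inv3
            Gxx[0, 0] = G00; Gxx[0, 1] = G01; Gxx[0, 2] = G02
            Gxx[1, 0] = G01; Gxx[1, 1] = G11; Gxx[1, 2] = G12
            Gxx[2, 0] = G02; Gxx[2, 1] = G12; Gxx[2, 2] = G22
            # minus regularised image Stokeslet
            RR = r0 * r0 + r1 * r1 + R2 * R2
            d2i = RR + ep2
            inv3i = 1.0 / (d2i * np.sqrt(d2i))
            isoi = (RR + 2.0 * ep2) * inv3i
            Gxx[0, 0] -= isoi + r0 * r0 * inv3i
            Gxx[0, 1] -= r0 * r1 * inv3i
            Gxx[0, 2] -= r0 * R2 * inv3i
            Gxx[1, 0] -= r0 * r1 * inv3i
            Gxx[1, 1] -= isoi + r1 * r1 * inv3i
            Gxx[1, 2] -= r1 * R2 * inv3i
            Gxx[2, 0] -= r0 * R2 * inv3i
            Gxx[2, 1] -= r1 * R2 * inv3i
            Gxx[2, 2] -= isoi + R2 * R2 * inv3i
            # image dipole/doublet terms (exact): D[i,l] = d phi_i / d R_l
            Rn2 = RR
            Rn = np.sqrt(Rn2)
            i3 = 1.0 / (Rn2 * Rn)
            i5 = i3 / Rn2
            Rv0, Rv1, Rv2 = r0, r1, R2
            R3 = Rv2
            for a in range(3):
                Ra = Rv0 if a == 0 else (Rv1 if a == 1 else Rv2)
                for l in range(3):
                    Rl = Rv0 if l == 0 else (Rv1 if l == 1 else Rv2)
                    D = h * ((1.0 if a == l else 0.0) * i3 - 3.0 * Ra * Rl * i5)
                    if a == 2:
                        D += Rl * i3
                    if a == l:
                        D -= R3 * i3
                    if l == 2:
                        D -= Ra * i3
                    D += 3.0 * Ra * R3 * Rl * i5
                    sgn = -1.0 if l == 2 else 1.0
                    Gxx[a, l] += 2.0 * h * D * sgn
            for a in range(3):
                for b in range(3):
                    A[3 * i + a, 3 * e + b] += w * Gxx[a, b]
    return A


class MobilitySolver:
    """Single-layer collocation mobility solver for one cell mesh.

    Parameters
    ----------
    mesh : CellMesh
        Body-frame surface mesh (geometry module).
    regularization : float
        Blob size as a fraction of sqrt(element area).  The default was
        fixed by benchmarking the translational drag of the 384-element
        sphere against 6*pi*mu*a (sub-percent agreement) and is not meant
        to be tuned per run.
    """

    #: pose-change thresholds beyond which the collocation matrix is
    #: rebuilt: the operator is exactly invariant under wall-parallel
    #: translation, so only height changes and rotations invalidate it
    Z_TOL = 0.01      # um
    ANGLE_TOL = 0.002  # rad

    def __init__(self, mesh: CellMesh, regularization: float = 0.15,
                 reuse_operator: bool = True):
        self.mesh = mesh
        self.eps_per_element = regularization * np.sqrt(mesh.element_areas)
        self.reuse_operator = reuse_operator
        self._cache = None  # (z, quat, lu_factor of A, viscosity)

    def _assemble(self, state: RigidState, viscosity: float):
        mesh = self.mesh
        ne = mesh.n_elements
        rot = state.rotation.as_matrix()
        centres = mesh.element_centroids @ rot.T + state.centroid
        qp = mesh.quad_points.reshape(-1, 3) @ rot.T + state.centroid
        if qp[:, 2].min() <= 0.0 or centres[:, 2].min() <= 0.0:
            raise MobilitySolverError("mesh intersects the wall plane z=0")
        wj = mesh.quad_weights.reshape(-1)
        eps = np.repeat(self.eps_per_element, 9)
        A = _assemble_kernel(centres, qp, wj, eps, ne)
        A /= 8.0 * np.pi * viscosity
        return A, centres

    def solve(self, state: RigidState, flow: FlowConfig,
              loads: LoadSet | None = None):
        """Return (U, Omega) satisfying quasi-static force/torque balance."""
        if loads is None:
            loads = LoadSet()
        mesh = self.mesh
        ne = mesh.n_elements
        lu = None
        if self.reuse_operator and self._cache is not None:
            z0, quat0, lu0, visc0, centres0, c0 = self._cache
            quat = state.rotation.as_quat()
            # quaternion distance ~ half the rotation angle
            dq = min(np.abs(quat - quat0).max(), np.abs(quat + quat0).max())
            if (visc0 == flow.viscosity
                    and abs(state.centroid[2] - z0) < self.Z_TOL
                    and 2.0 * dq < self.ANGLE_TOL):
                lu = lu0
                # operator is translation-invariant along the wall
                centres = centres0 + (state.centroid - c0) * [1.0, 1.0, 0.0]
        if lu is None:
            A, centres = self._assemble(state, flow.viscosity)
            try:
                lu = scipy.linalg.lu_factor(A)
            except np.linalg.LinAlgError as exc:  # pragma: no cover
                raise MobilitySolverError(
                    f"singular collocation system: {exc}") from exc
            self._cache = (state.centroid[2], state.rotation.as_quat(), lu,
                           flow.viscosity, centres, state.centroid.copy())

        lever = centres - state.centroid
        rhs = np.zeros((3 * ne, 7))
        for k in range(3):
            rhs[k::3, k] = 1.0                       # unit translations
        for k in range(3):
            ek = np.zeros(3)
            ek[k] = 1.0
            rhs[:, 3 + k] = np.cross(ek, lever).ravel()  # unit rotations
        rhs[:, 6] = -flow.ambient(centres).ravel()

        Q = scipy.linalg.lu_solve(lu, rhs)

        areas = mesh.element_areas
        q = Q.reshape(ne, 3, 7)
        F = np.einsum("e,ekm->km", areas, q)                     # (3, 7)
        T = np.einsum("e,ekm->km", areas,
                      np.cross(lever[:, :, None], q, axis=1))    # (3, 7)
        FT = np.vstack([F, T])                                   # (6, 7)
        resistance = FT[:, :6]
        shear_forcing = -FT[:, 6]

        ext = np.concatenate([loads.total_force, loads.total_torque])
        try:
            sol = np.linalg.solve(resistance, ext + shear_forcing)
        except np.linalg.LinAlgError as exc:  # pragma: no cover
            raise MobilitySolverError(f"singular resistance matrix: {exc}") from exc
        return sol[:3], sol[3:]

    def grand_mobility(self, state: RigidState, flow: FlowConfig) -> np.ndarray:
        """6x6 mobility matrix mapping (F, T) -> (U, Omega) in quiescent fluid."""
        quiet = FlowConfig(shear_rate=0.0, viscosity=flow.viscosity)
        cols = []
        for k in range(6):
            load = LoadSet()
            vec = np.zeros(6)
            vec[k] = 1.0
            load.total_force = vec[:3]
            load.total_torque = vec[3:]
            U, W = self.solve(state, quiet, load)
            cols.append(np.concatenate([U, W]))
        return np.array(cols).T


def solve_mobility(mesh: CellMesh, state: RigidState, flow: FlowConfig,
                   loads: LoadSet | None = None, regularization: float = 0.15):
    """One-shot convenience wrapper around :class:`MobilitySolver`."""
    return MobilitySolver(mesh, regularization).solve(state, flow, loads)
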