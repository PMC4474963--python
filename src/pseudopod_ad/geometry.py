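"""Neutrophil surface geometry: sphere + Gaussian pseudopod.

The cell is a star-shaped surface given in spherical coordinates about the
pseudopod axis (+x in the body frame) by

    r(theta) = a_body * (1 + Lambda * exp(-theta**2 / (2 * w**2)))

where ``theta`` is the polar angle measured from the pseudopod axis,
``Lambda`` is the dimensionless pseudopod protrusion (tip height above the
spherical body surface in units of the body radius) and ``w`` the angular
width of the Gaussian bump.  ``a_body`` is rescaled after meshing so the
enclosed volume equals that of the equal-volume sphere (radius 4 um by
default), matching the convention that a pseudopod-bearing cell conserves
its cytoplasmic volume.

The surface is discretised into 9-node biquadratic quadrilateral (QUAD9)
elements on a cubed-sphere layout: 6 logical faces, n x n elements each, so
the default target of 384 elements is met exactly with n = 8.  Areas,
outward normals and the enclosed volume are evaluated with 3x3 Gauss
quadrature on the biquadratic patches; the volume uses the divergence
theorem, V = (1/3) * surface_integral(x . n dA).

PSGL-1 receptors are apportioned to elements proportionally to element area
(largest-remainder rounding so the configured total is hit exactly) and
placed at deterministic low-discrepancy (Halton) points inside each
element, so receptor geometry carries no Monte-Carlo seed dependence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats.qmc import Halton

__all__ = [
    "CellShapeParams",
    "CellMesh",
    "ReceptorSet",
    "build_cell_mesh",
    "allocate_receptors",
    "wall_gap",
    "largest_remainder",
    "write_vtk",
    "write_off",
]

# 3-point Gauss-Legendre rule on [-1, 1]
_GAUSS_X = np.array([-np.sqrt(3.0 / 5.0), 0.0, np.sqrt(3.0 / 5.0)])
_GAUSS_W = np.array([5.0 / 9.0, 8.0 / 9.0, 5.0 / 9.0])


@dataclass
class CellShapeParams:
    """Shape of the neutrophil body + pseudopod.

    Parameters
    ----------
    equivalent_radius : float
        Radius (um) of the sphere with the same enclosed volume.
    dimensionless_pseudopod_length : float
        Pseudopod tip protrusion divided by the spherical body radius.
        0 recovers a plain sphere.
    pseudopod_width : float
        Angular width ``w`` (radians) of the Gaussian bump.
    cell_steric_layer : float
        Thickness (um) of the exclusion shell on the cell (membrane
        roughness).
    mesh_resolution : int
        Target element count; rounded to the nearest cubed-sphere
        resolution 6*n**2.
    """

    equivalent_radius: float = 4.0
    dimensionless_pseudopod_length: float = 1.9
    pseudopod_width: float = 0.45
    cell_steric_layer: float = 0.175
    mesh_resolution: int = 384

    def __post_init__(self) -> None:
        if self.equivalent_radius <= 0:
            raise ValueError("equivalent_radius must be positive")
        if self.dimensionless_pseudopod_length < 0:
            raise ValueError("dimensionless_pseudopod_length must be >= 0")
        if self.pseudopod_width <= 0:
            raise ValueError("pseudopod_width must be positive")
        if self.mesh_resolution < 6:
            raise ValueError("mesh_resolution must be >= 6")


@dataclass
class CellMesh:
    """QUAD9 surface mesh of the cell in the body frame (lengths in um)."""

    nodes: np.ndarray            # (n_nodes, 3)
    elements: np.ndarray         # (n_elem, 9) int, tensor-product ordering
    element_areas: np.ndarray    # (n_elem,)
    element_normals: np.ndarray  # (n_elem, 3) outward unit normal at centre
    element_centroids: np.ndarray  # (n_elem, 3) area-weighted centroids
    quad_points: np.ndarray      # (n_elem, 9, 3) Gauss points on surface
    quad_weights: np.ndarray     # (n_elem, 9) includes |J|, sums to areas
    quad_normals: np.ndarray     # (n_elem, 9, 3) outward unit normals
    volume: float
    area: float
    shape: CellShapeParams
    receptors_per_element: np.ndarray | None = None

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def equal_volume_radius(self) -> float:
        """Radius of the sphere enclosing the same volume as the mesh."""
        return (3.0 * self.volume / (4.0 * np.pi)) ** (1.0 / 3.0)


@dataclass
class ReceptorSet:
    """Individual receptor sites on the mesh surface (body frame)."""

    positions: np.ndarray      # (n_receptors, 3)
    normals: np.ndarray        # (n_receptors, 3) outward unit normals
    element_index: np.ndarray  # (n_receptors,) int

    @property
    def n_receptors(self) -> int:
        return len(self.positions)


def _shape_functions(xi: np.ndarray, eta: np.ndarray):
    """Biquadratic Lagrange shape functions and derivatives.

    Local node ordering is tensor-product row-major: node k = 3*j + i sits
    at (xi_i, eta_j) with xi, eta in {-1, 0, 1}.

    Returns (N, dN_dxi, dN_deta), each of shape (npts, 9).
    """
    def lag(t):
        return np.stack([0.5 * t * (t - 1.0), 1.0 - t * t, 0.5 * t * (t + 1.0)], axis=-1)

    def dlag(t):
        return np.stack([t - 0.5, -2.0 * t, t + 0.5], axis=-1)

    lx, ly = lag(xi), lag(eta)
    dlx, dly = dlag(xi), dlag(eta)
    N = (ly[:, :, None] * lx[:, None, :]).reshape(len(xi), 9)
    dNdx = (ly[:, :, None] * dlx[:, None, :]).reshape(len(xi), 9)
    dNdy = (dly[:, :, None] * lx[:, None, :]).reshape(len(xi), 9)
    return N, dNdx, dNdy


# Gauss points of the 3x3 rule in the same row-major ordering
_QXI, _QETA = np.meshgrid(_GAUSS_X, _GAUSS_X, indexing="xy")
_QXI, _QETA = _QXI.ravel(), _QETA.ravel()
_QW = np.outer(_GAUSS_W, _GAUSS_W).ravel()
_QN, _QdNdXI, _QdNdETA = _shape_functions(_QXI, _QETA)
_CN, _CdNdXI, _CdNdETA = _shape_functions(np.array([0.0]), np.array([0.0]))


def _radial_profile(directions: np.ndarray, lam: float, width: float) -> np.ndarray:
    """r(theta)/a_body for unit direction vectors; pseudopod axis = +x."""
    cos_t = np.clip(directions[..., 0], -1.0, 1.0)
    theta = np.arccos(cos_t)
    return 1.0 + lam * np.exp(-(theta**2) / (2.0 * width**2))


def _cubed_sphere_grid(n: int):
    """Node grid directions and QUAD9 connectivity for a 6-face cubed sphere.

    Each face carries a (2n+1) x (2n+1) node grid; coincident nodes along
    shared cube edges are merged afterwards.
    """
    m = 2 * n + 1
    u = np.linspace(-1.0, 1.0, m)
    uu, vv = np.meshgrid(u, u, indexing="xy")
    faces = []
    one = np.ones_like(uu)
    # (x, y, z) of each cube face, oriented so u x v points outward
    faces.append(np.stack([one, uu, vv], axis=-1))      # +x
    faces.append(np.stack([-one, vv, uu], axis=-1))     # -x
    faces.append(np.stack([vv, one, uu], axis=-1))      # +y
    faces.append(np.stack([uu, -one, vv], axis=-1))     # -y
    faces.append(np.stack([uu, vv, one], axis=-1))      # +z
    faces.append(np.stack([vv, uu, -one], axis=-1))     # -z

    all_pts = []
    elems = []
    offset = 0
    for fpts in faces:
        pts = fpts.reshape(-1, 3)
        pts = pts / np.linalg.norm(pts, axis=1, keepdims=True)
        all_pts.append(pts)
        for ej in range(n):
            for ei in range(n):
                idx = []
                for lj in range(3):
                    for li in range(3):
                        gi = 2 * ei + li
                        gj = 2 * ej + lj
                        idx.append(offset + gj * m + gi)
                elems.append(idx)
        offset += m * m
    pts = np.concatenate(all_pts, axis=0)
    elems = np.asarray(elems, dtype=np.intp)

    # merge duplicated nodes along shared cube edges
    key = np.round(pts, 9)
    _, first, inverse = np.unique(key, axis=0, return_index=True, return_inverse=True)
    pts = pts[np.sort(first)]
    remap = np.empty(len(key), dtype=np.intp)
    order = np.argsort(first)
    rank = np.empty_like(order)
    rank[order] = np.arange(len(order))
    remap_unique = rank  # unique-row id -> position in sorted-first ordering
    remap = remap_unique[inverse]
    return pts, remap[elems]


def _evaluate_mesh(nodes: np.ndarray, elements: np.ndarray):
    """Quadrature geometry: areas, normals, centroids, volume."""
    xe = nodes[elements]                      # (ne, 9, 3)
    qpts = np.einsum("qk,eki->eqi", _QN, xe)  # (ne, 9, 3)
    t1 = np.einsum("qk,eki->eqi", _QdNdXI, xe)
    t2 = np.einsum("qk,eki->eqi", _QdNdETA, xe)
    nvec = np.cross(t1, t2)
    jac = np.linalg.norm(nvec, axis=-1)
    nhat = nvec / jac[..., None]
    wj = _QW[None, :] * jac                   # (ne, 9)
    areas = wj.sum(axis=1)
    centroids = np.einsum("eq,eqi->ei", wj, qpts) / areas[:, None]
    volume = np.einsum("eq,eqi,eqi->", wj, qpts, nhat) / 3.0
    # centre-point normals for per-element outward direction
    cpts = np.einsum("qk,eki->eqi", _CN, xe)[:, 0, :]
    ct1 = np.einsum("qk,eki->eqi", _CdNdXI, xe)[:, 0, :]
    ct2 = np.einsum("qk,eki->eqi", _CdNdETA, xe)[:, 0, :]
    cn = np.cross(ct1, ct2)
    cn /= np.linalg.norm(cn, axis=-1, keepdims=True)
    return qpts, wj, nhat, areas, centroids, volume, cpts, cn


def build_cell_mesh(shape: CellShapeParams) -> CellMesh:
    """Construct the QUAD9 surface mesh of the body + pseudopod.

    The mesh is built on the unit profile first, then uniformly rescaled so
    the quadrature-evaluated enclosed volume equals (4/3)*pi*R_eq^3 exactly
    (up to roundoff), so the equal-volume constraint holds by construction.
    """
    n = max(1, int(round(np.sqrt(shape.mesh_resolution / 6.0))))
    if shape.dimensionless_pseudopod_length > 0 and shape.pseudopod_width < 0.2 * (np.pi / 2) / n:
        raise ValueError(
            "pseudopod_width too small for mesh resolution; bump would be "
            "unresolved (self-intersecting interpolation)"
        )
    directions, elements = _cubed_sphere_grid(n)
    radii = _radial_profile(directions, shape.dimensionless_pseudopod_length,
                            shape.pseudopod_width)
    nodes = directions * radii[:, None]

    _, _, _, _, _, v_unit, _, _ = _evaluate_mesh(nodes, elements)
    if v_unit <= 0:
        raise ValueError("mesh volume non-positive; inconsistent element orientation")
    v_target = 4.0 / 3.0 * np.pi * shape.equivalent_radius**3
    a_body = (v_target / v_unit) ** (1.0 / 3.0)
    nodes = nodes * a_body

    qpts, wj, nhat, areas, centroids, volume, cpts, cnorm = _evaluate_mesh(nodes, elements)
    return CellMesh(
        nodes=nodes,
        elements=elements,
        element_areas=areas,
        element_normals=cnorm,
        element_centroids=centroids,
        quad_points=qpts,
        quad_weights=wj,
        quad_normals=nhat,
        volume=float(volume),
        area=float(areas.sum()),
        shape=shape,
    )


def largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Apportion ``total`` integer counts proportionally to ``weights``.

    Largest-remainder (Hamilton) rounding: floor the exact quotas, then
    hand the leftover units to the largest fractional remainders.  The
    result always sums to ``total`` exactly.
    """
    if total < 0:
        raise ValueError("total must be non-negative")
    weights = np.asarray(weights, dtype=float)
    if np.any(weights < 0) or weights.sum() <= 0:
        raise ValueError("weights must be non-negative with positive sum")
    quota = weights / weights.sum() * total
    counts = np.floor(quota).astype(np.int64)
    short = int(total - counts.sum())
    if short > 0:
        remainders = quota - counts
        # stable tie-break on index keeps the allocation deterministic
        top = np.argsort(-remainders, kind="stable")[:short]
        counts[top] += 1
    return counts


def allocate_receptors(mesh: CellMesh, total_count: int) -> ReceptorSet:
    """Distribute receptors over elements proportionally to element area.

    In-element placement uses the 2-D Halton sequence mapped through the
    element shape functions — deterministic, seed-free, and approximately
    uniform in the reference square.
    """
    if total_count < 0:
        raise ValueError("total_count must be non-negative")
    counts = largest_remainder(mesh.element_areas, total_count)
    mesh.receptors_per_element = counts
    if total_count == 0:
        return ReceptorSet(
            positions=np.zeros((0, 3)), normals=np.zeros((0, 3)),
            element_index=np.zeros(0, dtype=np.intp),
        )
    kmax = int(counts.max())
    halton = Halton(d=2, scramble=False).random(kmax + 1)[1:]  # drop the origin
    uv = 2.0 * halton - 1.0  # reference square [-1, 1]^2
    N, dNx, dNy = _shape_functions(uv[:, 0], uv[:, 1])

    positions = np.empty((total_count, 3))
    normals = np.empty((total_count, 3))
    element_index = np.empty(total_count, dtype=np.intp)
    out = 0
    xe = mesh.nodes[mesh.elements]
    for e, k in enumerate(counts):
        if k == 0:
            continue
        pos = N[:k] @ xe[e]
        t1 = dNx[:k] @ xe[e]
        t2 = dNy[:k] @ xe[e]
        nv = np.cross(t1, t2)
        nv /= np.linalg.norm(nv, axis=-1, keepdims=True)
        # align with the element's outward centre normal
        flip = (nv @ mesh.element_normals[e]) < 0
        nv[flip] *= -1.0
        positions[out:out + k] = pos
        normals[out:out + k] = nv
        element_index[out:out + k] = e
        out += k
    return ReceptorSet(positions=positions, normals=normals, element_index=element_index)


def wall_gap(mesh: CellMesh, state, wall_steric_layer: float = 0.35):
    """Steric gap between the cell surface and the wall's steric surface.

    The wall is the plane z = 0; its steric surface sits at
    ``z = wall_steric_layer`` and the cell's own steric shell adds
    ``shape.cell_steric_layer``.  Negative gaps signal steric overlap.

    Returns ``(min_gap, per_node_gap)`` in um.
    """
    world = state.to_world(mesh.nodes)
    per_node = world[:, 2] - wall_steric_layer - mesh.shape.cell_steric_layer
    return float(per_node.min()), per_node


def write_vtk(path, mesh: CellMesh, point_data: dict | None = None) -> None:
    """Write the mesh as a legacy-ASCII VTK file (biquadratic quads)."""
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\ncell surface mesh\nASCII\n")
        fh.write("DATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {mesh.n_nodes} double\n")
        for p in mesh.nodes:
            fh.write(f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}\n")
        ne = mesh.n_elements
        fh.write(f"CELLS {ne} {ne * 10}\n")
        # VTK_BIQUADRATIC_QUAD ordering: corners, edge mids, centre
        order = [0, 2, 8, 6, 1, 5, 7, 3, 4]
        for el in mesh.elements:
            fh.write("9 " + " ".join(str(el[k]) for k in order) + "\n")
        fh.write(f"CELL_TYPES {ne}\n")
        fh.write("28\n" * ne)
        if point_data:
            fh.write(f"POINT_DATA {mesh.n_nodes}\n")
            for name, values in point_data.items():
                fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                for v in np.asarray(values, dtype=float):
                    fh.write(f"{v:.9g}\n")


def write_off(path, mesh: CellMesh) -> None:
    """Write corner-node quads in OFF format (drops midside nodes)."""
    with open(path, "w") as fh:
        fh.write("OFF\n")
        fh.write(f"{mesh.n_nodes} {mesh.n_elements} 0\n")
        for p in mesh.nodes:
            fh.write(f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}\n")
        for el in mesh.elements:
            fh.write(f"4 {el[0]} {el[2]} {el[8]} {el[6]}\n")
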