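"""Voxel micro-finite-element linear elasticity.

One 8-node hexahedral element per bone voxel, trilinear shape functions,
2x2x2 Gauss quadrature, isotropic small-strain elasticity.  The system
K u = f is solved matrix-free by element-by-element preconditioned conjugate
gradients (Jacobi preconditioner): because all elements are geometrically
identical cubes sharing one global Poisson ratio, every element stiffness is
the unit-modulus reference matrix scaled by that element's Young's modulus,
and peak memory stays proportional to the node count.

Axial compression replicates the in vivo tibial loading configuration:
the distal end face is fixed and the applied load (negative = compression,
e.g. -3.5 / -5.2 / -7.0 N) is distributed over the proximal end-face nodes,
whose in-plane translation is left unconstrained.

Units: node coordinates mm, moduli MPa, forces N, displacements mm
(1 N / mm^2 = 1 MPa, so the unit system is consistent without scaling).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage
from scipy.sparse.linalg import LinearOperator, cg

from .volumes import BoneMask, VoxelVolume

__all__ = [
    "FEMesh",
    "MaterialMap",
    "LoadCase",
    "DisplacementField",
    "voxel_mesh",
    "assign_materials",
    "apply_axial_compression",
    "solve_linear_elasticity",
    "reaction_forces",
    "element_strains",
    "export_vtk",
]

# Local corner order (VTK hexahedron): offsets in (dx, dy, dz)
_CORNERS = np.array(
    [
        (0, 0, 0),
        (1, 0, 0),
        (1, 1, 0),
        (0, 1, 0),
        (0, 0, 1),
        (1, 0, 1),
        (1, 1, 1),
        (0, 1, 1),
    ],
    dtype=np.int64,
)

_GAUSS = 1.0 / np.sqrt(3.0)


def _shape_gradients(xi: float, eta: float, zeta: float) -> np.ndarray:
    """dN/d(xi,eta,zeta) for the 8 trilinear shape functions, shape (8, 3)."""
    signs = 2.0 * _CORNERS - 1.0  # corner positions in natural coords
    g = np.empty((8, 3))
    for i, (sx, sy, sz) in enumerate(signs):
        g[i, 0] = sx * (1 + sy * eta) * (1 + sz * zeta) / 8.0
        g[i, 1] = (1 + sx * xi) * sy * (1 + sz * zeta) / 8.0
        g[i, 2] = (1 + sx * xi) * (1 + sy * eta) * sz / 8.0
    return g


def _b_matrix(xi: float, eta: float, zeta: float, h: float) -> np.ndarray:
    """Strain-displacement matrix (6 x 24), Voigt order
    (exx, eyy, ezz, gxy, gyz, gxz) with engineering shears."""
    dN = _shape_gradients(xi, eta, zeta) * (2.0 / h)  # d/dx = d/dxi * 2/h
    B = np.zeros((6, 24))
    for i in range(8):
        bx, by, bz = dN[i]
        c = 3 * i
        B[0, c] = bx
        B[1, c + 1] = by
        B[2, c + 2] = bz
        B[3, c] = by
        B[3, c + 1] = bx
        B[4, c + 1] = bz
        B[4, c + 2] = by
        B[5, c] = bz
        B[5, c + 2] = bx
    return B


def _elastic_d(e: float, nu: float) -> np.ndarray:
    c = e / ((1 + nu) * (1 - 2 * nu))
    d = np.zeros((6, 6))
    d[:3, :3] = c * nu
    np.fill_diagonal(d[:3, :3], c * (1 - nu))
    d[3, 3] = d[4, 4] = d[5, 5] = c * (1 - 2 * nu) / 2.0
    return d


def hex_stiffness(e: float, nu: float, h: float) -> np.ndarray:
    """Element stiffness (24 x 24) of a cube of edge h (mm), E in MPa."""
    d = _elastic_d(e, nu)
    k = np.zeros((24, 24))
    detj = (h / 2.0) ** 3
    for sx in (-_GAUSS, _GAUSS):
        for sy in (-_GAUSS, _GAUSS):
            for sz in (-_GAUSS, _GAUSS):
                b = _b_matrix(sx, sy, sz, h)
                k += b.T @ d @ b * detj
    return k


@dataclass
class FEMesh:
    """Conforming voxel hex mesh.

    ``nodes``: (n_nodes, 3) coordinates in mm (x, y, z); ``elements``:
    (n_elem, 8) node indices in VTK corner order; ``voxel_index``: (n_elem, 3)
    source-voxel (iz, iy, ix); ``grid_shape`` the source mask shape.
    """

    nodes: np.ndarray
    elements: np.ndarray
    voxel_index: np.ndarray
    voxel_size: float  # um
    grid_shape: tuple[int, int, int]
    n_removed_voxels: int = 0

    @property
    def h(self) -> float:
        """Element edge length in mm."""
        return self.voxel_size / 1000.0

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    @property
    def dofmap(self) -> np.ndarray:
        """(n_elem, 24) global dof indices, cached."""
        if not hasattr(self, "_dofmap"):
            dm = (3 * self.elements[:, :, None] + np.arange(3)[None, None, :]).reshape(-1, 24)
            self._dofmap = np.ascontiguousarray(dm.astype(np.int64))
        return self._dofmap

    def element_lookup(self) -> np.ndarray:
        """Flat voxel-linear-index -> element id (-1 where unmeshed)."""
        lut = np.full(int(np.prod(self.grid_shape)), -1, dtype=np.int64)
        lin = np.ravel_multi_index(
            (self.voxel_index[:, 0], self.voxel_index[:, 1], self.voxel_index[:, 2]),
            self.grid_shape,
        )
        lut[lin] = np.arange(self.n_elements)
        return lut


@dataclass
class MaterialMap:
    """Per-element Young's modulus (MPa) and a global Poisson ratio."""

    e: np.ndarray
    nu: float
    n_clamped: int = 0

    def __post_init__(self) -> None:
        self.e = np.asarray(self.e, dtype=np.float64)
        if not np.all(self.e > 0):
            raise ValueError("all element moduli must be > 0")
        if not 0 <= self.nu < 0.5:
            raise ValueError("Poisson ratio must lie in [0, 0.5)")


@dataclass
class LoadCase:
    """Boundary conditions: prescribed dofs (values, usually 0) and nodal forces."""

    applied_load: float  # N, axial; negative = compression
    fixed_dofs: np.ndarray  # global dof indices with prescribed displacement
    fixed_values: np.ndarray  # prescribed displacement values (mm)
    forces: np.ndarray  # (3 * n_nodes,) external nodal forces, N
    fixed_nodes: np.ndarray = field(default_factory=lambda: np.array([], dtype=np.int64))
    loaded_nodes: np.ndarray = field(default_factory=lambda: np.array([], dtype=np.int64))


@dataclass
class DisplacementField:
    """Nodal displacements (mm) with solver diagnostics."""

    u: np.ndarray  # (n_nodes, 3)
    iterations: int
    residual: float  # relative residual ||K u - f|| / ||f|| on free dofs


def voxel_mesh(mask: BoneMask) -> FEMesh:
    """One hex element per voxel of the largest face-connected component.

    Node numbering is deterministic (lexicographic in z, y, x of the node
    lattice); voxels outside the largest component are removed and counted in
    ``n_removed_voxels``.
    """
    if not mask.values.any():
        raise ValueError("cannot mesh an empty mask")
    lab, n = ndimage.label(mask.values)
    if n > 1:
        counts = np.bincount(lab.ravel())
        counts[0] = 0
        keep = int(np.argmax(counts))
        solid = lab == keep
        removed = int(mask.values.sum() - solid.sum())
        warnings.warn(f"removed {removed} floating voxels disconnected from the main component",
                      stacklevel=2)
    else:
        solid = mask.values
        removed = 0

    occ = np.flatnonzero(solid.any(axis=(1, 2)))
    if occ[0] == occ[-1] and solid.ndim == 3 and solid.shape[0] > 1:
        pass  # single-slice structures are legal; face spanning checked at load time

    nz, ny, nx = solid.shape
    iz, iy, ix = np.nonzero(solid)
    voxel_index = np.stack([iz, iy, ix], axis=1).astype(np.int64)

    # lattice node ids: (nz+1, ny+1, nx+1), index = (z*(ny+1) + y)*(nx+1) + x
    nyx = (ny + 1) * (nx + 1)
    nxp = nx + 1

    def lattice(zi, yi, xi):
        return (zi * (ny + 1) + yi) * nxp + xi

    corner_ids = np.empty((len(iz), 8), dtype=np.int64)
    for k, (dx, dy, dz) in enumerate(_CORNERS):
        corner_ids[:, k] = lattice(iz + dz, iy + dy, ix + dx)

    used = np.unique(corner_ids)
    remap = {}
    # vectorized remap via searchsorted (used is sorted -> deterministic z,y,x order)
    elements = np.searchsorted(used, corner_ids).astype(np.int64)
    del remap

    h = mask.voxel_size / 1000.0
    zi = used // nyx
    rem = used % nyx
    yi = rem // nxp
    xi = rem % nxp
    nodes = np.stack([xi * h, yi * h, zi * h], axis=1).astype(np.float64)

    return FEMesh(
        nodes=nodes,
        elements=elements,
        voxel_index=voxel_index,
        voxel_size=mask.voxel_size,
        grid_shape=solid.shape,
        n_removed_voxels=removed,
    )


def assign_materials(
    vol: Optional[VoxelVolume],
    mesh: FEMesh,
    model: str = "homogeneous",
    e0: float = 17000.0,
    nu: float = 0.3,
    a: float = 15000.0,
    b: float = 2.0,
    e_min: float = 1.0,
) -> MaterialMap:
    """Per-element moduli.

    ``homogeneous``: E = e0 everywhere.  ``power_law``: E = a * rho^b from
    each element's source-voxel density (g HA/cm^3), floored at ``e_min``
    (non-positive densities are clamped and counted).
    """
    if model == "homogeneous":
        return MaterialMap(e=np.full(mesh.n_elements, float(e0)), nu=nu)
    if model == "power_law":
        if vol is None:
            raise ValueError("power_law material model requires the calibrated volume")
        rho = vol.values[
            mesh.voxel_index[:, 0], mesh.voxel_index[:, 1], mesh.voxel_index[:, 2]
        ].astype(np.float64)
        bad = rho <= 0
        e = np.where(bad, e_min, a * np.clip(rho, 0, None) ** b)
        e = np.maximum(e, e_min)
        return MaterialMap(e=e, nu=nu, n_clamped=int(bad.sum()))
    raise ValueError(f"unknown material model {model!r}")


def _face_nodes(mesh: FEMesh, which: str) -> np.ndarray:
    z = mesh.nodes[:, 2]
    zref = z.min() if which == "proximal" else z.max()
    return np.flatnonzero(np.abs(z - zref) < 1e-9 * max(1.0, abs(zref)) + 1e-12)


def apply_axial_compression(
    mesh: FEMesh,
    load: float,
    distal_constraint: str = "clamped",
    distribution: str = "uniform",
) -> LoadCase:
    """Axial load case: distal face constrained, proximal face loaded in z.

    ``distal_constraint``: ``clamped`` fixes all three dofs of distal-face
    nodes; ``roller`` fixes only z there plus a minimal 3-2-1 pin against
    rigid in-plane motion (useful for uniform-stress verification).
    ``distribution``: ``uniform`` splits the load equally over proximal-face
    nodes; ``consistent`` uses trilinear face-consistent weights (each loaded
    element face contributes a quarter of its share to each of its 4 nodes).
    """
    prox = _face_nodes(mesh, "proximal")
    dist = _face_nodes(mesh, "distal")
    if prox.size == 0 or dist.size == 0:
        raise ValueError("empty proximal or distal face node set")
    if np.intersect1d(prox, dist).size:
        raise ValueError("proximal and distal faces share nodes; structure too thin")

    # The load acts along the outward normal of the proximal face (-z), so a
    # negative (compressive) load pushes the face in +z, toward the fixed
    # distal end, and produces negative axial strains.
    forces = np.zeros(3 * mesh.n_nodes)
    if distribution == "uniform":
        forces[3 * prox + 2] = -load / prox.size
    elif distribution == "consistent":
        zmin_vox = mesh.voxel_index[:, 0].min()
        face_elems = np.flatnonzero(mesh.voxel_index[:, 0] == zmin_vox)
        # proximal face of each element: local corners with dz == 0
        loc = np.flatnonzero(_CORNERS[:, 2] == 0)
        face_nodes = mesh.elements[np.ix_(face_elems, loc)]
        w = np.zeros(mesh.n_nodes)
        np.add.at(w, face_nodes.ravel(), 0.25)
        w = w / w.sum()
        forces[2::3] = -load * w
    else:
        raise ValueError(f"unknown load distribution {distribution!r}")

    if distal_constraint == "clamped":
        fixed = (3 * dist[:, None] + np.arange(3)[None, :]).ravel()
    elif distal_constraint == "roller":
        fixed = [3 * dist + 2]
        # 3-2-1 pin: one node fixed in x and y, another in y only
        n0 = dist[0]
        xy = mesh.nodes[dist, :2]
        far = dist[int(np.argmax(np.abs(xy[:, 0] - mesh.nodes[n0, 0])))]
        fixed.append(np.array([3 * n0, 3 * n0 + 1, 3 * far + 1]))
        fixed = np.unique(np.concatenate(fixed))
    else:
        raise ValueError(f"unknown distal constraint {distal_constraint!r}")

    return LoadCase(
        applied_load=float(load),
        fixed_dofs=np.asarray(fixed, dtype=np.int64),
        fixed_values=np.zeros(len(fixed)),
        forces=forces,
        fixed_nodes=dist,
        loaded_nodes=prox,
    )


def _matvec_factory(mesh: FEMesh, materials: MaterialMap):
    """Element-by-element K @ u on the full dof vector."""
    k0 = hex_stiffness(1.0, materials.nu, mesh.h)
    dofmap = mesh.dofmap
    scale = materials.e
    ndof = 3 * mesh.n_nodes
    homogeneous = np.allclose(scale, scale[0])
    if homogeneous:
        k_h = k0 * scale[0]

        def matvec(u: np.ndarray) -> np.ndarray:
            ue = u[dofmap]
            fe = ue @ k_h.T
            return np.bincount(dofmap.ravel(), weights=fe.ravel(), minlength=ndof)

    else:

        def matvec(u: np.ndarray) -> np.ndarray:
            ue = u[dofmap]
            fe = (ue @ k0.T) * scale[:, None]
            return np.bincount(dofmap.ravel(), weights=fe.ravel(), minlength=ndof)

    diag = np.bincount(dofmap.ravel(),
                       weights=(np.diag(k0)[None, :] * scale[:, None]).ravel(),
                       minlength=ndof)
    return matvec, diag


def solve_linear_elasticity(
    mesh: FEMesh,
    materials: MaterialMap,
    loadcase: LoadCase,
    rel_tol: float = 1e-8,
    max_iter: int = 20000,
) -> DisplacementField:
    """Jacobi-preconditioned CG solve of K u = f with Dirichlet elimination.

    Deterministic for fixed inputs.  Raises on non-convergence, reporting the
    final relative residual.  The reaction at the constrained face balances
    the applied load to within the solver tolerance (checked by tests, not
    enforced here).
    """
    ndof = 3 * mesh.n_nodes
    matvec, diag = _matvec_factory(mesh, materials)

    fixed = loadcase.fixed_dofs
    free = np.setdiff1d(np.arange(ndof), fixed, assume_unique=False)
    if free.size == 0:
        raise ValueError("no free degrees of freedom")

    u_p = np.zeros(ndof)
    u_p[fixed] = loadcase.fixed_values
    b_full = loadcase.forces - (matvec(u_p) if np.any(loadcase.fixed_values) else 0.0)
    b = np.asarray(b_full)[free] if np.ndim(b_full) else loadcase.forces[free]

    def a_free(x: np.ndarray) -> np.ndarray:
        full = np.zeros(ndof)
        full[free] = x
        return matvec(full)[free]

    d_free = diag[free]
    d_free[d_free <= 0] = 1.0
    m_inv = 1.0 / d_free

    a_op = LinearOperator((free.size, free.size), matvec=a_free)
    m_op = LinearOperator((free.size, free.size), matvec=lambda x: m_inv * x)

    it_count = {"n": 0}

    def cb(_xk):
        it_count["n"] += 1

    bnorm = np.linalg.norm(b)
    if bnorm == 0:
        u = u_p.copy()
        return DisplacementField(u=u.reshape(-1, 3), iterations=0, residual=0.0)

    x, info = cg(a_op, b, rtol=rel_tol, atol=0.0, maxiter=max_iter, M=m_op, callback=cb)
    res = float(np.linalg.norm(a_free(x) - b) / bnorm)
    if info != 0:
        raise RuntimeError(
            f"CG failed to converge in {max_iter} iterations (relative residual {res:.3e})"
        )
    u = u_p.copy()
    u[free] = x
    return DisplacementField(u=u.reshape(-1, 3), iterations=it_count["n"], residual=res)


def reaction_forces(mesh: FEMesh, materials: MaterialMap, disp: DisplacementField) -> np.ndarray:
    """Nodal internal forces K u, shape (n_nodes, 3); at constrained nodes these
    are the reactions."""
    matvec, _ = _matvec_factory(mesh, materials)
    return matvec(disp.u.ravel()).reshape(-1, 3)


_B_CENTER = None


def element_strains(mesh: FEMesh, disp: DisplacementField) -> np.ndarray:
    """Per-element centroid strain tensors in Voigt order
    (exx, eyy, ezz, gxy, gyz, gxz), engineering shears, dimensionless."""
    b = _b_matrix(0.0, 0.0, 0.0, mesh.h)
    ue = disp.u.ravel()[mesh.dofmap]
    return ue @ b.T


def export_vtk(path, mesh: FEMesh, disp: Optional[DisplacementField] = None,
               cell_data: Optional[dict] = None) -> None:
    """Legacy ASCII VTK unstructured-grid export for visualization."""
    lines = ["# vtk DataFile Version 3.0", "osteoadapt voxel mesh", "ASCII",
             "DATASET UNSTRUCTURED_GRID", f"POINTS {mesh.n_nodes} double"]
    lines += [f"{x:.9g} {y:.9g} {z:.9g}" for x, y, z in mesh.nodes]
    ne = mesh.n_elements
    lines.append(f"CELLS {ne} {9 * ne}")
    lines += ["8 " + " ".join(map(str, e)) for e in mesh.elements]
    lines.append(f"CELL_TYPES {ne}")
    lines += ["12"] * ne
    if disp is not None:
        lines.append(f"POINT_DATA {mesh.n_nodes}")
        lines.append("VECTORS displacement double")
        lines += [f"{a:.9g} {b:.9g} {c:.9g}" for a, b, c in disp.u]
    if cell_data:
        lines.append(f"CELL_DATA {ne}")
        for name, arr in cell_data.items():
            lines.append(f"SCALARS {name} double 1")
            lines.append("LOOKUP_TABLE default")
            lines += [f"{v:.9g}" for v in np.asarray(arr)]
    from pathlib import Path

    Path(path).write_text("\n".join(lines) + "\n")
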