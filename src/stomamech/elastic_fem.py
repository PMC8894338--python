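"""Small-strain isotropic linear elasticity on P1 tetrahedra.

The wall tissue is modelled as linear elastic: stress is proportional to
the symmetric displacement gradient through the standard 3-D isotropic
Hooke law with Lame parameters ``lambda = E*nu/((1+nu)(1-2nu))`` and
``mu = E/(2(1+nu))``.  Each material region of the mesh carries its own
Young's modulus (MPa) and Poisson ratio; the built-in table holds the
abdominal-wall values (soft muscle layers EO/IO/RA/TR between 0.52 and
1.03 MPa, tendinous linea alba 72 MPa, all with nu = 0.3).

The load is a uniform pressure on a named facet group — the
intraabdominal pressure on the inner wall surface — applied as a dead
load on the reference-configuration normals, plus a homogeneous
Dirichlet condition on a named node set (the wall edges, where muscle
attaches to bone).  The analysis is geometrically linear: displacements
scale exactly with pressure, so a pressure sweep needs one solve per
geometry.  Voigt order is ``[xx, yy, zz, xy, yz, zx]`` with engineering
shear strains.

Stress post-processing is element-wise (P1 strain is element-constant):
strain, stress and the von Mises scalar
``sigma_v = sqrt(3/2 * dev(sigma) : dev(sigma))`` used as the
rupture-risk proxy; a volume-weighted nodal average is available for
visualization only.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .mesh_core import MeshError, TetMesh, facet_area_vectors

logger = logging.getLogger(__name__)

VOIGT = ("xx", "yy", "zz", "xy", "yz", "zx")


class SolverError(RuntimeError):
    """Singular or non-converged linear solve."""


# ---------------------------------------------------------------------------
# materials
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Material:
    """Isotropic elastic constants: E in MPa, nu dimensionless."""
    E: float
    nu: float

    def __post_init__(self) -> None:
        if not self.E > 0:
            raise ValueError(f"Young's modulus must be positive (got {self.E})")
        if not 0.0 < self.nu < 0.5:
            raise ValueError(f"Poisson ratio must lie in (0, 0.5) (got {self.nu})")


class MaterialTable:
    """Map region tag -> :class:`Material`."""

    def __init__(self, entries: dict[str, Material | tuple[float, float]]):
        self.entries: dict[str, Material] = {
            k: (v if isinstance(v, Material) else Material(*v))
            for k, v in entries.items()}

    def __getitem__(self, tag: str) -> Material:
        return self.entries[tag]

    def __contains__(self, tag: str) -> bool:
        return tag in self.entries

    def items(self):
        return self.entries.items()

    def check_covers(self, mesh: TetMesh) -> None:
        missing = sorted(set(mesh.region_names()) - set(self.entries))
        if missing:
            raise MeshError(f"no material for region tag(s): {', '.join(missing)}")

    @classmethod
    def abdominal_wall(cls) -> "MaterialTable":
        """Default abdominal-wall moduli (MPa), nu = 0.3 throughout."""
        nu = 0.3
        return cls({"EO": Material(1.0, nu), "IO": Material(0.65, nu),
                    "RA": Material(0.52, nu), "TR": Material(1.03, nu),
                    "LA": Material(72.0, nu)})

    def to_dict(self) -> dict[str, list[float]]:
        return {k: [m.E, m.nu] for k, m in self.entries.items()}


def hooke_isotropic(E: float, nu: float) -> np.ndarray:
    """6x6 isotropic elasticity matrix in Voigt notation (MPa).

    Normal block ``lambda + 2 mu`` on the diagonal / ``lambda`` off it,
    shear diagonal ``mu`` (engineering-strain convention).  Raises for
    the incompressible limit nu -> 0.5.
    """
    if abs(nu - 0.5) <= 1e-6:
        raise ValueError("incompressible limit unsupported (nu ~ 0.5)")
    if not (E > 0 and -1.0 < nu < 0.5):
        raise ValueError(f"invalid elastic constants E={E}, nu={nu}")
    lam = E * nu / ((1.0 + nu) * (1.0 - 2.0 * nu))
    mu = E / (2.0 * (1.0 + nu))
    C = np.zeros((6, 6))
    C[:3, :3] = lam
    C[np.arange(3), np.arange(3)] = lam + 2.0 * mu
    C[np.arange(3, 6), np.arange(3, 6)] = mu
    return C


# ---------------------------------------------------------------------------
# load case / fields
# ---------------------------------------------------------------------------

@dataclass
class LoadCase:
    """Uniform pressure (MPa) on a facet group plus zero-displacement sets.

    ``constraints`` adds component-wise roller conditions as
    ``(node_group, (fix_x, fix_y, fix_z))`` pairs; ``fixed_group`` may be
    ``None`` when rollers alone remove the rigid modes.
    """
    pressure: float
    pressure_group: str = "inner_surface"
    fixed_group: str | None = "fixed_edges"
    constraints: tuple[tuple[str, tuple[bool, bool, bool]], ...] = ()

    def validate(self, mesh: TetMesh) -> None:
        if self.pressure < 0:
            raise ValueError("pressure must be non-negative")
        if self.pressure_group not in mesh.facet_groups:
            raise MeshError(f"facet group '{self.pressure_group}' not in mesh "
                            f"(has {sorted(mesh.facet_groups)})")
        names = ([self.fixed_group] if self.fixed_group else []) + \
            [g for g, _ in self.constraints]
        for g in names:
            if g not in mesh.node_groups:
                raise MeshError(f"node group '{g}' not in mesh "
                                f"(has {sorted(mesh.node_groups)})")


@dataclass
class DisplacementField:
    """Per-node displacement vectors (mm)."""
    u: np.ndarray                      # (N, 3)

    def magnitudes(self) -> np.ndarray:
        return np.linalg.norm(self.u, axis=1)

    def max_magnitude(self) -> float:
        return float(self.magnitudes().max())


@dataclass
class StressState:
    """Element-constant strain/stress in Voigt order and von Mises scalar."""
    strain: np.ndarray                 # (M, 6), engineering shear
    stress: np.ndarray                 # (M, 6), MPa
    von_mises: np.ndarray              # (M,), MPa


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def _element_geometry(mesh: TetMesh) -> tuple[np.ndarray, np.ndarray]:
    """Shape-function gradients (M, 4, 3) and signed volumes (M,)."""
    x = mesh.nodes[mesh.tets]                       # (M, 4, 3)
    edges = x[:, 1:] - x[:, :1]                     # rows X_i - X_0
    vols = np.linalg.det(edges) / 6.0
    if (vols <= 0).any():
        raise MeshError(f"{int((vols <= 0).sum())} non-positive tets; "
                        "run validate_mesh / fix_tet_orientation first")
    inv = np.linalg.inv(edges)
    grads = np.empty((len(vols), 4, 3))
    grads[:, 1:] = np.transpose(inv, (0, 2, 1))     # grad lambda_i = col i of inv
    grads[:, 0] = -grads[:, 1:].sum(axis=1)
    return grads, vols


def _element_B(grads: np.ndarray) -> np.ndarray:
    """Strain-displacement matrices (M, 6, 12), Voigt engineering shear."""
    M = len(grads)
    B = np.zeros((M, 6, 12))
    for n in range(4):
        gx, gy, gz = grads[:, n, 0], grads[:, n, 1], grads[:, n, 2]
        c = 3 * n
        B[:, 0, c + 0] = gx
        B[:, 1, c + 1] = gy
        B[:, 2, c + 2] = gz
        B[:, 3, c + 0] = gy
        B[:, 3, c + 1] = gx
        B[:, 4, c + 1] = gz
        B[:, 4, c + 2] = gy
        B[:, 5, c + 0] = gz
        B[:, 5, c + 2] = gx
    return B


def assemble_stiffness(mesh: TetMesh, materials: MaterialTable) -> sp.csr_array:
    """Global stiffness operator on the 3N displacement unknowns (symmetric).

    Before constraints its kernel is spanned by the six rigid-body modes.
    Raises naming the tag if a region lacks a material.
    """
    materials.check_covers(mesh)
    grads, vols = _element_geometry(mesh)
    B = _element_B(grads)
    M = mesh.n_tets
    Ke = np.empty((M, 12, 12))
    for tag in mesh.region_names():
        sel = mesh.regions == tag
        mat = materials[tag]
        C = hooke_isotropic(mat.E, mat.nu)
        Ke[sel] = np.einsum("eki,kl,elj->eij", B[sel], C, B[sel],
                            optimize=True) * vols[sel, None, None]
    dofs = (3 * mesh.tets[:, :, None] + np.arange(3)).reshape(M, 12)
    rows = np.repeat(dofs, 12, axis=1).ravel()
    cols = np.tile(dofs, (1, 12)).ravel()
    n = 3 * mesh.n_nodes
    K = sp.coo_array((Ke.ravel(), (rows, cols)), shape=(n, n)).tocsr()
    return K


def assemble_pressure_load(mesh: TetMesh, group: str, pressure: float) -> np.ndarray:
    """Consistent P1 nodal forces (N) for a uniform pressure on a facet group.

    Facets are wound with outward normals; a pressure pushes along the
    inward normal, so each facet of area A contributes a total force of
    magnitude ``pressure * A`` split equally over its three nodes.
    Raises if the group's facets are inconsistently oriented.
    """
    if group not in mesh.facet_groups:
        raise MeshError(f"facet group '{group}' not in mesh")
    faces = mesh.facet_groups[group]
    _check_orientation(faces, group)
    av = facet_area_vectors(mesh.nodes, faces)      # outward area vectors
    f_face = -pressure * av                         # push into the solid
    f = np.zeros((mesh.n_nodes, 3))
    for corner in range(3):
        np.add.at(f, faces[:, corner], f_face / 3.0)
    return f.ravel()


def _check_orientation(faces: np.ndarray, group: str) -> None:
    edges = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    uniq = np.unique(edges, axis=0)
    if len(uniq) != len(edges):
        raise MeshError(f"facet group '{group}': inconsistent orientation "
                        "(a directed edge is traversed twice)")


def dirichlet_mask(mesh: TetMesh, load: LoadCase) -> np.ndarray:
    """Boolean mask over the 3N dofs that are constrained to zero."""
    mask = np.zeros(3 * mesh.n_nodes, dtype=bool)
    if load.fixed_group:
        idx = mesh.node_groups[load.fixed_group]
        mask[(3 * idx[:, None] + np.arange(3)).ravel()] = True
    for gname, comps in load.constraints:
        idx = mesh.node_groups[gname]
        for c, on in enumerate(comps):
            if on:
                mask[3 * idx + c] = True
    return mask


# ---------------------------------------------------------------------------
# solve
# ---------------------------------------------------------------------------

@dataclass
class SolveResult:
    displacement: DisplacementField
    stiffness: sp.csr_array
    load_vector: np.ndarray
    fixed_mask: np.ndarray
    residual: float

    def reactions(self) -> np.ndarray:
        """Constraint reactions (N): (K u - f) on the fixed dofs."""
        r = self.stiffness @ self.displacement.u.ravel() - self.load_vector
        out = np.zeros_like(r)
        out[self.fixed_mask] = r[self.fixed_mask]
        return out.reshape(-1, 3)


def solve_case(mesh: TetMesh, materials: MaterialTable, load: LoadCase,
               method: str = "direct", cg_tol: float = 1e-10,
               stiffness: sp.csr_array | None = None) -> SolveResult:
    """Assemble and solve one load case; returns displacement + operators.

    ``method='direct'`` uses a deterministic sparse LU factorization;
    ``method='cg'`` a Jacobi-preconditioned conjugate gradient for large
    meshes.  A precomputed stiffness matrix can be reused across load
    cases on the same mesh/material pair.
    """
    load.validate(mesh)
    K = assemble_stiffness(mesh, materials) if stiffness is None else stiffness
    f = assemble_pressure_load(mesh, load.pressure_group, load.pressure)
    mask = dirichlet_mask(mesh, load)
    if not mask.any():
        raise SolverError("insufficient constraints: empty Dirichlet set")
    free = ~mask
    Kff = K[free][:, free].tocsc()
    ff = f[free]

    if np.linalg.norm(ff) == 0.0:
        uf = np.zeros(len(ff))
        res = 0.0
    elif method == "direct":
        try:
            lu = spla.splu(Kff, permc_spec="COLAMD")
        except RuntimeError as exc:
            raise SolverError(f"insufficient constraints ({exc})") from exc
        uf = lu.solve(ff)
        res = _relative_residual(Kff, uf, ff)
        if not np.isfinite(res) or res > 1e-8:
            raise SolverError(f"insufficient constraints: direct solve residual "
                              f"{res:.2e}")
    elif method == "cg":
        Mpre = sp.diags_array(1.0 / Kff.diagonal())
        uf, info = spla.cg(Kff, ff, M=Mpre, rtol=cg_tol, maxiter=20000)
        res = _relative_residual(Kff, uf, ff)
        if info != 0 or res > 1e-8:
            raise SolverError(f"cg did not converge (info={info}, "
                              f"residual {res:.2e})")
    else:
        raise ValueError(f"unknown solver method '{method}'")

    u = np.zeros(3 * mesh.n_nodes)
    u[free] = uf
    logger.debug("solved %d free dofs, residual %.2e", int(free.sum()), res)
    return SolveResult(DisplacementField(u.reshape(-1, 3)), K, f, mask, res)


def _relative_residual(K, u, f) -> float:
    return float(np.linalg.norm(K @ u - f) / np.linalg.norm(f))


def rigid_body_modes(nodes: np.ndarray) -> np.ndarray:
    """Orthonormal basis (3N, 6) of the rigid translations and rotations."""
    n = len(nodes)
    c = nodes - nodes.mean(axis=0)
    modes = np.zeros((3 * n, 6))
    for i in range(3):
        modes[i::3, i] = 1.0
    modes[1::3, 3], modes[2::3, 3] = -c[:, 2], c[:, 1]
    modes[0::3, 4], modes[2::3, 4] = c[:, 2], -c[:, 0]
    modes[0::3, 5], modes[1::3, 5] = -c[:, 1], c[:, 0]
    q, _ = np.linalg.qr(modes)
    return q


def solve_free_floating(mesh: TetMesh, materials: MaterialTable,
                        pressure_group: str, pressure: float,
                        rtol: float = 1e-10,
                        maxiter: int = 40000) -> DisplacementField:
    """Solve a self-equilibrated pressure case with no Dirichlet set.

    Used for closed pressurized solids (the thick-walled-sphere oracle):
    the load on a closed surface has zero resultant, so the singular
    stiffness system is consistent; the six rigid-body modes are
    projected out and the reduced system solved by preconditioned CG.
    """
    K = assemble_stiffness(mesh, materials)
    f = assemble_pressure_load(mesh, pressure_group, pressure)
    R = rigid_body_modes(mesh.nodes)

    def project(x):
        return x - R @ (R.T @ x)

    fp = project(f)
    op = spla.LinearOperator(K.shape, matvec=lambda x: project(K @ project(x)))
    dinv = 1.0 / K.diagonal()
    pre = spla.LinearOperator(K.shape, matvec=lambda x: project(dinv * x))
    u, info = spla.cg(op, fp, M=pre, rtol=rtol, maxiter=maxiter)
    res = float(np.linalg.norm(project(K @ u - f)) / np.linalg.norm(fp))
    if info != 0 or res > 1e-8:
        raise SolverError(f"free-floating cg failed (info={info}, "
                          f"residual {res:.2e})")
    return DisplacementField(project(u).reshape(-1, 3))


def lame_radial_displacement(r: np.ndarray | float, a: float, b: float,
                             E: float, nu: float, p: float) -> np.ndarray | float:
    """Closed-form radial displacement of an internally pressurized
    thick-walled sphere (inner radius a, outer b, internal pressure p)."""
    r = np.asarray(r, dtype=float)
    out = (p * a ** 3 * r / (E * (b ** 3 - a ** 3))
           * ((1 - 2 * nu) + (1 + nu) * b ** 3 / (2 * r ** 3)))
    return float(out) if out.ndim == 0 else out


def solve_displacements(mesh: TetMesh, materials: MaterialTable,
                        load: LoadCase, **kwargs) -> DisplacementField:
    """Displacement field for one load case (zero exactly on fixed nodes)."""
    return solve_case(mesh, materials, load, **kwargs).displacement


# ---------------------------------------------------------------------------
# stress post-processing
# ---------------------------------------------------------------------------

def compute_strain_stress(mesh: TetMesh, materials: MaterialTable,
                          u: DisplacementField) -> StressState:
    """Element-constant strain, stress and von Mises from a P1 field."""
    materials.check_covers(mesh)
    grads, _ = _element_geometry(mesh)
    ue = u.u[mesh.tets]                              # (M, 4, 3)
    grad_u = np.einsum("mni,mnj->mij", ue, grads)    # du_i/dx_j
    eps_t = 0.5 * (grad_u + np.transpose(grad_u, (0, 2, 1)))
    strain = np.column_stack([eps_t[:, 0, 0], eps_t[:, 1, 1], eps_t[:, 2, 2],
                              2 * eps_t[:, 0, 1], 2 * eps_t[:, 1, 2],
                              2 * eps_t[:, 2, 0]])
    stress = np.empty_like(strain)
    for tag in mesh.region_names():
        sel = mesh.regions == tag
        mat = materials[tag]
        stress[sel] = strain[sel] @ hooke_isotropic(mat.E, mat.nu).T
    return StressState(strain, stress, von_mises_voigt(stress))


def von_mises_voigt(stress: np.ndarray) -> np.ndarray:
    """Von Mises scalar from Voigt stress rows [xx, yy, zz, xy, yz, zx]."""
    sxx, syy, szz, sxy, syz, szx = stress.T
    return np.sqrt(0.5 * ((sxx - syy) ** 2 + (syy - szz) ** 2 + (szz - sxx) ** 2)
                   + 3.0 * (sxy ** 2 + syz ** 2 + szx ** 2))


def von_mises(stress: np.ndarray) -> np.ndarray | float:
    """Von Mises stress of one (or a batch of) symmetric 3x3 tensor(s).

    Rotation-invariant; zero for hydrostatic states, ``sqrt(3)*tau`` for
    pure shear ``tau``.
    """
    t = np.asarray(stress, dtype=float)
    single = t.ndim == 2
    t = t.reshape(-1, 3, 3)
    if not np.allclose(t, np.transpose(t, (0, 2, 1)), atol=1e-9 * max(1.0, float(np.abs(t).max()))):
        raise ValueError("stress tensor must be symmetric")
    voigt = np.column_stack([t[:, 0, 0], t[:, 1, 1], t[:, 2, 2],
                             t[:, 0, 1], t[:, 1, 2], t[:, 2, 0]])
    sv = von_mises_voigt(voigt)
    return float(sv[0]) if single else sv


def nodal_von_mises(mesh: TetMesh, state: StressState) -> np.ndarray:
    """Volume-weighted nodal average of element von Mises (visualization)."""
    vols = mesh.tet_volumes()
    num = np.zeros(mesh.n_nodes)
    den = np.zeros(mesh.n_nodes)
    for corner in range(4):
        np.add.at(num, mesh.tets[:, corner], state.von_mises * vols)
        np.add.at(den, mesh.tets[:, corner], vols)
    return num / np.maximum(den, 1e-300)


def stress_summary(mesh: TetMesh, state: StressState) -> dict[str, float]:
    """Max element von Mises (MPa), globally and per region."""
    out = {"global": float(state.von_mises.max())}
    for tag in mesh.region_names():
        out[tag] = float(state.von_mises[mesh.regions == tag].max())
    return out
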