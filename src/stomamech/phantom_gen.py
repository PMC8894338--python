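"""Synthetic layered abdominal-wall phantom and analytic verification meshes.

The phantom is a deterministic stand-in for a patient-derived abdominal
wall: a curved slab of four stacked soft muscle strata (transverse
abdominis innermost, then rectus abdominis, internal oblique and
external oblique) joined by a stiff tendinous midline strip (the linea
alba analogue), clamped on all four lateral edges and pressurized on the
concave (inner) surface.  An optional circular through-hole — the stoma
trephine — can be cut at one of seventeen labelled grid positions
(``s0`` on the midline strip, ``s11``..``s16``, ``s21``..``s26``,
``s31``..``s34`` at increasing lateral offset and height on the left
half), mirroring the labelling scheme used for stoma-placement studies.

Geometry is built on a graded tensor-product grid in a developable
parameter plane (arc length ``s`` across the wall, height ``y``,
thickness ``t``), split into tetrahedra with a mirror-symmetric Kuhn
template, and bent onto a cylinder of the requested curvature radius.
Because the inner surface is developable, a circle drawn in the
parameter plane keeps its exact perimeter on the curved wall, so the
trephine boundary loop reproduces the analytic 2 cm-diameter baseline
(perimeter 6.28 cm, area 3.14 cm^2) to within the polygonal
discretization of the circle.  The hole is cut by snapping the nearest
ring of grid nodes exactly onto the circle and deleting the cells
inside, which makes the reference loop geometry exact rather than a
remeshing artefact.

Also provided: a hollow-sphere mesh (for the pressurized thick-walled
sphere closed form) and a unit cube (for uniform-strain patch tests).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .mesh_core import MeshError, TetMesh, boundary_faces_of, fix_tet_orientation

logger = logging.getLogger(__name__)

# region names, innermost first (TR is the innermost muscle layer)
LAYERS_INNER_TO_OUTER = ("TR", "RA", "IO", "EO")
STRIP_REGION = "LA"

POSITION_LABELS = ("s0",
                   "s11", "s12", "s13", "s14", "s15", "s16",
                   "s21", "s22", "s23", "s24", "s25", "s26",
                   "s31", "s32", "s33", "s34")


@dataclass(frozen=True)
class HoleSpec:
    """Circular trephine: labelled position and diameter in mm."""
    position: str = "s0"
    diameter: float = 20.0


@dataclass
class PhantomSpec:
    """Parameters of the synthetic layered wall.

    Lengths in mm.  ``layer_thicknesses`` is ordered outer to inner
    (EO, IO, RA, TR analogues).  ``curvature_radius`` is the radius of
    the inner surface; ``numpy.inf`` gives a flat slab.  ``resolution``
    is the target in-plane edge length away from the hole; around a hole
    the grid is graded down so the circle carries at least
    ``hole_segments`` nodes (set ``hole_segments=None`` to disable the
    local refinement and discretize the hole at ``resolution``).
    ``seed``/``jitter`` control an optional interior-node perturbation
    (off by default: ``jitter=0``).
    """
    width: float = 300.0
    height: float = 400.0
    layer_thicknesses: tuple[float, float, float, float] = (3.0, 3.0, 3.0, 3.0)
    strip_width: float = 20.0
    curvature_radius: float = 200.0
    hole: Optional[HoleSpec] = None
    resolution: float = 6.0
    hole_segments: Optional[int] = 64
    seed: int = 0
    jitter: float = 0.0

    @property
    def thickness(self) -> float:
        return float(sum(self.layer_thicknesses))

    def validate(self) -> None:
        pos = [self.width, self.height, self.strip_width, self.resolution,
               self.curvature_radius, *self.layer_thicknesses]
        if any(not v > 0 for v in pos):
            raise MeshError("all phantom lengths must be strictly positive")
        if self.hole is not None:
            if self.hole.position not in POSITION_LABELS:
                raise MeshError(f"unknown hole position '{self.hole.position}'; "
                                f"expected one of {POSITION_LABELS}")
            if not self.hole.diameter > 0:
                raise MeshError("hole diameter must be strictly positive")
            sc, yc = self.hole_center()
            d = self.hole.diameter
            edge_dist = min(self.width / 2 - abs(sc), yc, self.height - yc)
            if edge_dist <= d:
                raise MeshError(
                    f"hole at {self.hole.position} (center offset {sc:.1f}, "
                    f"{yc:.1f} mm) comes within one diameter of the fixed "
                    "boundary; refusing to build")

    # -- the labelled position grid ----------------------------------------

    def column_offsets(self) -> dict[int, float]:
        """Lateral offset (mm, toward the left half) of columns i=1..3."""
        step = self.width * (2.0 / 15.0)          # 40 mm on the default wall
        return {i: i * step for i in (1, 2, 3)}

    def row_heights(self) -> dict[int, float]:
        """Height (mm) of rows j=1..6."""
        base = self.height / 4.0                  # 100 mm default
        step = self.height / 10.0                 # 40 mm default
        return {j: base + (j - 1) * step for j in range(1, 7)}

    def hole_center(self) -> tuple[float, float]:
        """Parameter-plane (s, y) center of the configured hole."""
        if self.hole is None:
            raise MeshError("spec has no hole")
        label = self.hole.position
        if label == "s0":
            return 0.0, self.height / 2.0
        i, j = int(label[1]), int(label[2])
        return -self.column_offsets()[i], self.row_heights()[j]


def analytic_phantom_volume(spec: PhantomSpec) -> float:
    """Closed-form volume (mm^3) of the parameterized solid.

    The wall occupies radii [R, R+T] over an inner-surface arc of length
    ``width``; the hole removes a parameter-plane disc swept through the
    thickness with the same radial Jacobian.
    """
    T = spec.thickness
    R = spec.curvature_radius
    jac = 1.0 + (0.0 if np.isinf(R) else T / (2.0 * R))
    area = spec.width * spec.height
    if spec.hole is not None:
        area -= np.pi * (spec.hole.diameter / 2.0) ** 2
    return area * T * jac


# ---------------------------------------------------------------------------
# graded 1-D grids and the structured tet template
# ---------------------------------------------------------------------------

def _grade_1d(x0: float, x1: float, h_fun) -> np.ndarray:
    """Nodes on [x0, x1] following the sizing function h(x) (deterministic)."""
    xs = np.linspace(x0, x1, max(16, int((x1 - x0) * 8) + 2))
    dens = 1.0 / np.maximum(h_fun(xs), 1e-9)
    cum = np.concatenate([[0.0], np.cumsum(0.5 * (dens[1:] + dens[:-1])
                                           * np.diff(xs))])
    n = max(1, int(round(cum[-1])))
    nodes = np.interp(np.linspace(0.0, cum[-1], n + 1), cum, xs)
    nodes[0], nodes[-1] = x0, x1
    return nodes


def _graded_axis(breaks: list[float], h_fun) -> np.ndarray:
    parts = [_grade_1d(a, b, h_fun) for a, b in zip(breaks[:-1], breaks[1:])]
    return np.unique(np.concatenate(parts))


# Kuhn 6-tet split of a hex (positive volume on an axis-aligned box);
# corner code bits = (di, dj, dk); used for the uniform cube fixture
_KUHN = np.array([[0b000, 0b100, 0b110, 0b111],
                  [0b000, 0b110, 0b010, 0b111],
                  [0b000, 0b010, 0b011, 0b111],
                  [0b000, 0b011, 0b001, 0b111],
                  [0b000, 0b001, 0b101, 0b111],
                  [0b000, 0b101, 0b100, 0b111]])


def _hexes_to_tets(corner_ids: np.ndarray) -> np.ndarray:
    """corner_ids: (C, 8) node ids indexed by the 3-bit corner code."""
    out = np.empty((len(corner_ids), 6, 4), dtype=np.int64)
    for t in range(6):
        out[:, t] = corner_ids[:, _KUHN[t]]
    return out.reshape(-1, 4)


def _cross2(o, p, q):
    return ((p[..., 0] - o[..., 0]) * (q[..., 1] - o[..., 1])
            - (p[..., 1] - o[..., 1]) * (q[..., 0] - o[..., 0]))


def _triangulate_quads(pos: np.ndarray, keep2d: np.ndarray,
                       ny: int) -> tuple[np.ndarray, np.ndarray]:
    """Split kept grid quads into triangles, picking per quad the diagonal
    that maximizes the minimum signed triangle area (robust near the
    snapped hole boundary, where quads can be concave).

    Returns (triangles (2C, 3) of flat 2-D node ids, quad index (2C,)).
    """
    ci, cj = np.nonzero(keep2d)
    i00 = ci * ny + cj
    i10 = (ci + 1) * ny + cj
    i11 = (ci + 1) * ny + cj + 1
    i01 = ci * ny + cj + 1
    flat = pos.reshape(-1, 2)
    p00, p10, p11, p01 = flat[i00], flat[i10], flat[i11], flat[i01]
    main = np.minimum(_cross2(p00, p10, p11), _cross2(p00, p11, p01))
    anti = np.minimum(_cross2(p00, p10, p01), _cross2(p10, p11, p01))
    use_main = main >= anti
    tris = np.empty((len(ci), 2, 3), dtype=np.int64)
    tris[use_main, 0] = np.column_stack([i00, i10, i11])[use_main]
    tris[use_main, 1] = np.column_stack([i00, i11, i01])[use_main]
    tris[~use_main, 0] = np.column_stack([i00, i10, i01])[~use_main]
    tris[~use_main, 1] = np.column_stack([i10, i11, i01])[~use_main]
    quad_index = np.repeat(np.arange(len(ci)), 2)
    return tris.reshape(-1, 3), quad_index


def _split_prisms(bottom: np.ndarray, top: np.ndarray) -> np.ndarray:
    """Conforming 3-tet split of triangular prisms (vectorized).

    Quad-face diagonals run through each face's smallest global node id,
    so adjacent prisms always match; requires min(prism ids) in the
    bottom triangle (true for bottom-to-top extrusion numbering).
    """
    rot = np.argmin(bottom, axis=1)
    idx = (rot[:, None] + np.arange(3)) % 3
    rows = np.arange(len(bottom))[:, None]
    b = bottom[rows, idx]
    t = top[rows, idx]
    v0, v1, v2 = b.T
    v3, v4, v5 = t.T
    through_v1 = np.minimum(v1, v5) < np.minimum(v2, v4)
    tets = np.empty((len(bottom), 3, 4), dtype=np.int64)
    tets[through_v1] = np.stack([
        np.column_stack([v0, v1, v2, v5]),
        np.column_stack([v0, v1, v5, v4]),
        np.column_stack([v0, v4, v5, v3])], axis=1)[through_v1]
    tets[~through_v1] = np.stack([
        np.column_stack([v0, v1, v2, v4]),
        np.column_stack([v0, v4, v2, v5]),
        np.column_stack([v0, v4, v5, v3])], axis=1)[~through_v1]
    return tets.reshape(-1, 4)


# ---------------------------------------------------------------------------
# wall phantom
# ---------------------------------------------------------------------------

def build_wall_phantom(spec: PhantomSpec) -> TetMesh:
    """Build the layered wall phantom mesh for the given spec.

    Returns a :class:`TetMesh` with one region per muscle layer plus the
    ``"LA"`` strip, facet groups ``inner_surface`` (concave side) and
    ``outer_surface``, node group ``fixed_edges`` (all four lateral
    boundary edges through the thickness) and, when a hole is requested,
    the ``trephine_wall`` facet group and the ``trephine_inner_loop`` /
    ``trephine_outer_loop`` node cycles snapped exactly onto the circle
    of the requested diameter.  Generation is deterministic for a fixed
    spec (seed included).
    """
    spec.validate()
    W, H, T = spec.width, spec.height, spec.thickness
    R = spec.curvature_radius
    w2 = spec.strip_width / 2.0

    hole = spec.hole
    if hole is not None:
        sc, yc = spec.hole_center()
        a = hole.diameter / 2.0
        circ = np.pi * hole.diameter
        h_fine = spec.resolution if spec.hole_segments is None else \
            min(spec.resolution, circ / spec.hole_segments)

        def h_of(center):
            def h(x):
                dist = np.abs(x - center)
                return np.clip(h_fine + 0.3 * np.maximum(dist - (a + 2 * h_fine), 0.0),
                               h_fine, spec.resolution)
            return h

        h_s, h_y = h_of(sc), h_of(yc)
    else:
        h_s = h_y = lambda x: np.full_like(np.asarray(x, dtype=float),
                                           spec.resolution)

    s_nodes = _graded_axis([-W / 2, -w2, 0.0, w2, W / 2], h_s)
    y_nodes = _graded_axis([0.0, H], h_y)

    t_nodes = [0.0]
    layer_of_tcell: list[str] = []
    for name, th in zip(LAYERS_INNER_TO_OUTER, spec.layer_thicknesses[::-1]):
        m = max(1, int(round(th / spec.resolution)))
        for k in range(m):
            t_nodes.append(t_nodes[-1] + th / m)
            layer_of_tcell.append(name)
    t_nodes = np.asarray(t_nodes)

    ns, ny, nt = len(s_nodes), len(y_nodes), len(t_nodes)
    S, Y = np.meshgrid(s_nodes, y_nodes, indexing="ij")
    pos = np.stack([S, Y], axis=-1)            # (ns, ny, 2) parameter plane

    keep2d = np.ones((ns - 1, ny - 1), dtype=bool)
    if hole is not None:
        d2 = np.hypot(S - sc, Y - yc)
        interior = d2 < a * (1.0 - 1e-12)
        if not interior.any():
            raise MeshError("resolution too coarse: no grid node falls inside "
                            f"the hole; need resolution <= {a:.2f} mm")
        # delete every cell touching an interior node, so the hole boundary
        # nodes all start on or outside the circle ...
        cell_int = (interior[:-1, :-1] | interior[1:, :-1]
                    | interior[:-1, 1:] | interior[1:, 1:])
        keep2d = ~cell_int
        in_kept = _corner_scatter(keep2d, ns, ny)
        # hole-wall nodes: endpoints of grid edges shared by a kept and a
        # deleted cell (corner-only contact does not put a node on the wall)
        interface = np.zeros((ns, ny), dtype=bool)
        ii, jj = np.nonzero(keep2d[:-1, :] != keep2d[1:, :])
        interface[ii + 1, jj] = True
        interface[ii + 1, jj + 1] = True
        ii, jj = np.nonzero(keep2d[:, :-1] != keep2d[:, 1:])
        interface[ii, jj + 1] = True
        interface[ii + 1, jj + 1] = True
        n_ring = int(interface.sum())
        if n_ring < 16:
            raise MeshError(
                f"hole circumference carries only {n_ring} nodes (< 16); "
                f"need resolution <= {circ / 16:.2f} mm near the hole")
        # ... then pull them radially onto the circle and relax the annulus
        vec = pos[interface] - (sc, yc)
        pos[interface] = (sc, yc) + a * vec / np.linalg.norm(vec, axis=1,
                                                            keepdims=True)
        _relax_annulus(pos, d2, interface, interior, in_kept, a, h_fine,
                       (sc, yc))

    if spec.jitter > 0:
        rng = np.random.default_rng(spec.seed)
        inner = np.zeros((ns, ny), dtype=bool)
        inner[1:-1, 1:-1] = True
        if hole is not None:
            inner &= np.hypot(S - sc, Y - yc) > a + 3 * h_fine
        pert = rng.normal(scale=spec.jitter, size=(int(inner.sum()), 2))
        pos[inner] += pert

    # --- triangulate kept cells and extrude through the thickness ---------
    # node ids: flat 2-D grid id * nt + t-level
    tris, quad_of_tri = _triangulate_quads(pos, keep2d, ny)
    ci, cj = np.nonzero(keep2d)
    nlay = nt - 1
    bottoms = (tris[:, None, :] * nt
               + np.arange(nlay)[None, :, None]).reshape(-1, 3)
    tets = _split_prisms(bottoms, bottoms + 1)      # 3 tets per prism

    cell_center_s = 0.5 * (s_nodes[ci] + s_nodes[ci + 1])
    reg = np.empty((len(tris), nlay), dtype="<U4")
    reg[:, :] = np.asarray(layer_of_tcell)[None, :]
    reg[np.abs(cell_center_s)[quad_of_tri] < w2, :] = STRIP_REGION
    regions = np.repeat(reg.reshape(-1), 3)

    # --- node coordinates: bend the parameter plane onto the cylinder -----
    s_par = np.repeat(pos[:, :, 0].ravel(), nt)
    y_par = np.repeat(pos[:, :, 1].ravel(), nt)
    t_par = np.tile(t_nodes, ns * ny)
    if np.isinf(R):
        nodes = np.column_stack([s_par, y_par, t_par])
    else:
        r = R + t_par
        theta = s_par / R
        nodes = np.column_stack([r * np.sin(theta), y_par, r * np.cos(theta) - R])

    # --- compress node numbering to used nodes ----------------------------
    used = np.zeros(ns * ny * nt, dtype=bool)
    used[tets.ravel()] = True
    new_id = np.cumsum(used) - 1
    tets = new_id[tets]
    nodes = nodes[used]
    s_par, y_par, t_par = s_par[used], y_par[used], t_par[used]

    grid_i = np.repeat(np.repeat(np.arange(ns), ny), nt)[used]
    grid_j = np.repeat(np.tile(np.arange(ny), ns), nt)[used]

    tets, _ = fix_tet_orientation(nodes, tets)

    # --- groups -----------------------------------------------------------
    tol = 1e-9
    bnd = boundary_faces_of(tets)
    on_inner = np.abs(t_par) < tol
    on_outer = np.abs(t_par - T) < tol
    facet_groups = {
        "inner_surface": bnd[on_inner[bnd].all(axis=1)],
        "outer_surface": bnd[on_outer[bnd].all(axis=1)],
    }
    fixed = ((grid_i == 0) | (grid_i == ns - 1)
             | (grid_j == 0) | (grid_j == ny - 1))
    node_groups = {"fixed_edges": np.flatnonzero(fixed)}

    loops = {}
    if hole is not None:
        on_circle = np.abs(np.hypot(s_par - sc, y_par - yc) - a) < 1e-7
        facet_groups["trephine_wall"] = bnd[on_circle[bnd].all(axis=1)]
        for lname, level in (("trephine_inner_loop", 0.0),
                             ("trephine_outer_loop", T)):
            sel = np.flatnonzero(on_circle & (np.abs(t_par - level) < tol))
            ang = np.arctan2(y_par[sel] - yc, s_par[sel] - sc)
            loops[lname] = sel[np.argsort(ang)]

    mesh = TetMesh(nodes, tets, regions, facet_groups, node_groups, loops)
    vols = mesh.tet_volumes()
    if (vols <= 0).any():
        # snapping can fold a sliver in pathological spec combinations
        raise MeshError(f"phantom generation produced {(vols <= 0).sum()} "
                        "non-positive tets; refine the resolution")
    return mesh


def _corner_scatter(cells: np.ndarray, ns: int, ny: int) -> np.ndarray:
    """Mark every node that is a corner of a flagged (ns-1, ny-1) cell."""
    out = np.zeros((ns, ny), dtype=bool)
    for di in (0, 1):
        for dj in (0, 1):
            out[di:ns - 1 + di, dj:ny - 1 + dj] |= cells
    return out


def _relax_annulus(pos: np.ndarray, d2: np.ndarray, interface: np.ndarray,
                   interior: np.ndarray, in_kept: np.ndarray, a: float,
                   h: float, center: tuple[float, float],
                   sweeps: int = 30) -> None:
    """Constrained Laplace smoothing of the grid around the hole (in place).

    Projecting the interface nodes onto the circle distorts the adjacent
    cells by up to ~1.4 grid spacings.  Jacobi sweeps relax the
    surrounding annulus; interface nodes slide *along* the circle (they
    are re-projected after each averaging step), deleted-region nodes
    are ignored, and everything outside the annulus stays fixed.
    """
    free = in_kept & ~interface & (d2 > a) & (d2 < a + 4.0 * h)
    slide = interface.copy()
    for m in (free, slide):
        m[0, :] = m[-1, :] = False
        m[:, 0] = m[:, -1] = False
    w = (~interior).astype(float)
    cx, cy = center
    for _ in range(sweeps):
        pw = pos * w[:, :, None]
        num = np.zeros_like(pos)
        den = np.zeros_like(w)
        for src, dst in (((slice(1, None), slice(None)),
                          (slice(None, -1), slice(None))),
                         ((slice(None, -1), slice(None)),
                          (slice(1, None), slice(None))),
                         ((slice(None), slice(1, None)),
                          (slice(None), slice(None, -1))),
                         ((slice(None), slice(None, -1)),
                          (slice(None), slice(1, None)))):
            num[dst] += pw[src]
            den[dst] += w[src]
        avg = num / np.maximum(den, 1.0)[:, :, None]
        pos[free] = avg[free]
        vec = avg[slide] - (cx, cy)
        pos[slide] = (cx, cy) + a * vec / np.linalg.norm(vec, axis=1,
                                                        keepdims=True)


# ---------------------------------------------------------------------------
# verification fixtures
# ---------------------------------------------------------------------------

def build_hollow_sphere(inner_radius: float, outer_radius: float,
                        resolution: float) -> TetMesh:
    """Tet mesh of a full hollow sphere (single region ``"shell"``).

    Radial stacks of prisms over an icosphere triangulation, split into
    tetrahedra with the index-ordered diagonal rule so neighbouring
    prisms conform.  Facet groups ``inner_surface``/``outer_surface``
    are wound outward with respect to the solid (the inner surface
    normal points toward the center).
    """
    import trimesh

    if not 0 < inner_radius < outer_radius:
        raise MeshError("need 0 < inner_radius < outer_radius")
    edge0 = 1.0515 * outer_radius          # icosahedron edge at unit radius
    sub = int(np.clip(np.ceil(np.log2(max(edge0 / resolution, 1.0))), 1, 5))
    ico = trimesh.creation.icosphere(subdivisions=sub, radius=1.0)
    dirs = np.asarray(ico.vertices)
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    faces = np.asarray(ico.faces, dtype=np.int64)
    nv = len(dirs)

    # the pressurized-shell solution varies as 1/r^2 through the thickness,
    # so sample the radial direction twice as finely as the surface
    nr = max(2, int(np.ceil(2.0 * (outer_radius - inner_radius) / resolution)))
    radii = np.linspace(inner_radius, outer_radius, nr + 1)
    nodes = (radii[:, None, None] * dirs[None, :, :]).reshape(-1, 3)

    bottoms = (faces[:, None, :] + nv * np.arange(nr)[None, :, None])
    bottoms = bottoms.reshape(-1, 3)
    tets = _split_prisms(bottoms, bottoms + nv)
    tets, n_fixed = fix_tet_orientation(nodes, tets)
    if n_fixed:
        logger.debug("hollow sphere: oriented %d tets", n_fixed)

    inner = faces[:, ::-1]                      # outward of solid = inward
    outer = faces + nr * nv
    regions = np.full(len(tets), "shell")
    return TetMesh(nodes, tets, regions,
                   {"inner_surface": inner, "outer_surface": outer},
                   {}, {})


def build_unit_cube(resolution: float) -> TetMesh:
    """Unit cube patch-test fixture.

    Facet groups ``face_{x,y,z}{0,1}`` (one per face), node groups
    ``nodes_{x,y,z}{0,1}`` (all nodes of each face, for component-wise
    roller constraints), plus ``corners`` and ``edges``.
    """
    if resolution > 1.0:
        raise MeshError("resolution must be <= 1 mm for the unit cube")
    n = max(1, int(round(1.0 / resolution)))
    xs = np.linspace(0.0, 1.0, n + 1)
    I, J, K = np.meshgrid(np.arange(n + 1), np.arange(n + 1), np.arange(n + 1),
                          indexing="ij")
    nodes = np.column_stack([xs[I.ravel()], xs[J.ravel()], xs[K.ravel()]])

    def nid(i, j, k):
        return (i * (n + 1) + j) * (n + 1) + k

    ci, cj, ck = np.meshgrid(np.arange(n), np.arange(n), np.arange(n),
                             indexing="ij")
    ci, cj, ck = ci.ravel(), cj.ravel(), ck.ravel()
    corners = np.stack([nid(ci + ((c >> 2) & 1), cj + ((c >> 1) & 1),
                            ck + (c & 1)) for c in range(8)], axis=1)
    tets = _hexes_to_tets(corners)
    regions = np.full(len(tets), "cube")

    bnd = boundary_faces_of(tets)
    coords = nodes[bnd]
    facet_groups = {}
    node_groups = {}
    for axis, ax in enumerate("xyz"):
        for side, val in ((0, 0.0), (1, 1.0)):
            on = np.abs(coords[:, :, axis] - val).max(axis=1) < 1e-12
            facet_groups[f"face_{ax}{side}"] = bnd[on]
            node_groups[f"nodes_{ax}{side}"] = np.flatnonzero(
                np.abs(nodes[:, axis] - val) < 1e-12)

    on_face = np.stack([(np.abs(nodes[:, a] - v) < 1e-12)
                        for a in range(3) for v in (0.0, 1.0)])
    n_faces = on_face.sum(axis=0)
    node_groups["corners"] = np.flatnonzero(n_faces == 3)
    node_groups["edges"] = np.flatnonzero(n_faces >= 2)
    return TetMesh(nodes, tets, regions, facet_groups, node_groups, {})
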