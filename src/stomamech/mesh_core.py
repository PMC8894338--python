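"""Tetrahedral mesh data model, validation and file I/O.

The pipeline works on tagged linear-tetrahedron volume meshes: every
tetrahedron carries exactly one material-region tag (a name such as
``"RA"`` or ``"LA"``), oriented triangle groups mark boundary surfaces
(``"inner_surface"``, ``"trephine_wall"``, ...), node groups mark
Dirichlet sets (``"fixed_edges"``) and named closed node cycles mark the
trephine boundary loops used by the morphometry stage.

Conventions (fixed pipeline-wide):

* units: mm for lengths, MPa for stresses/moduli, N for forces
  (so an intraabdominal pressure of 20 kPa enters as 0.02 MPa);
* tetrahedra are stored with strictly positive signed volume; readers
  repair negative tets by swapping two nodes and log the count;
* surface triangles are stored with outward normals with respect to the
  solid; the sign convention of the pressure load lives in the solver;
* node/element indices are 0-based in memory; the 1-based indices of the
  ``.msh`` dialect are translated at the I/O boundary.

Supported formats: Gmsh ``.msh`` ASCII v4.1 (read/write) and v2.2
(read); VTU XML unstructured grid (write, with result fields); binary
STL (write, surface groups only, for quick inspection).  Only linear
(4-node) tetrahedra are accepted; higher-order elements raise.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

MM_PER_CM = 10.0


class MeshError(ValueError):
    """Invalid mesh content or an operation on an unsolvable mesh."""


class MeshFormatError(MeshError):
    """Unreadable or unsupported mesh file."""


# ---------------------------------------------------------------------------
# data model
# ---------------------------------------------------------------------------

@dataclass
class TetMesh:
    """Tagged tetrahedral volume mesh.

    Parameters
    ----------
    nodes:
        ``(N, 3)`` float array of node coordinates in mm.
    tets:
        ``(M, 4)`` int array of 0-based connectivity, positive signed
        volume under the ``det([b-a, c-a, d-a]) > 0`` convention.
    regions:
        ``(M,)`` array of region-tag names, one per tetrahedron.
    facet_groups:
        name -> ``(K, 3)`` int array of boundary triangles, wound so the
        right-hand normal points out of the solid.
    node_groups:
        name -> 1-D int array of node indices.
    loops:
        name -> 1-D int array of node indices forming an ordered closed
        cycle (the first node is *not* repeated at the end).
    """

    nodes: np.ndarray
    tets: np.ndarray
    regions: np.ndarray
    facet_groups: dict[str, np.ndarray] = field(default_factory=dict)
    node_groups: dict[str, np.ndarray] = field(default_factory=dict)
    loops: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.nodes = np.ascontiguousarray(self.nodes, dtype=np.float64)
        self.tets = np.ascontiguousarray(self.tets, dtype=np.int64)
        self.regions = np.asarray(self.regions)
        if self.nodes.ndim != 2 or self.nodes.shape[1] != 3:
            raise MeshError("nodes must be an (N, 3) array")
        if self.tets.ndim != 2 or self.tets.shape[1] != 4:
            raise MeshError("tets must be an (M, 4) array")
        if len(self.regions) != len(self.tets):
            raise MeshError("one region tag per tetrahedron required")
        self.facet_groups = {k: np.ascontiguousarray(v, dtype=np.int64).reshape(-1, 3)
                             for k, v in self.facet_groups.items()}
        self.node_groups = {k: np.ascontiguousarray(v, dtype=np.int64).ravel()
                            for k, v in self.node_groups.items()}
        self.loops = {k: np.ascontiguousarray(v, dtype=np.int64).ravel()
                      for k, v in self.loops.items()}

    # -- basic queries ------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_tets(self) -> int:
        return len(self.tets)

    def region_names(self) -> list[str]:
        """Region tags present, in order of first appearance."""
        _, first = np.unique(self.regions, return_index=True)
        return [str(self.regions[i]) for i in np.sort(first)]

    def tet_volumes(self) -> np.ndarray:
        """Signed volumes (mm^3), positive for well-oriented tets."""
        return tet_signed_volumes(self.nodes, self.tets)

    def total_volume(self) -> float:
        return float(self.tet_volumes().sum())

    def boundary_faces(self) -> np.ndarray:
        """Outward-oriented boundary triangles extracted from the tets."""
        return boundary_faces_of(self.tets)

    def copy(self) -> "TetMesh":
        return TetMesh(self.nodes.copy(), self.tets.copy(), self.regions.copy(),
                       {k: v.copy() for k, v in self.facet_groups.items()},
                       {k: v.copy() for k, v in self.node_groups.items()},
                       {k: v.copy() for k, v in self.loops.items()})


def tet_signed_volumes(nodes: np.ndarray, tets: np.ndarray) -> np.ndarray:
    a, b, c, d = (nodes[tets[:, i]] for i in range(4))
    return np.einsum("ij,ij->i", b - a, np.cross(c - a, d - a)) / 6.0


def fix_tet_orientation(nodes: np.ndarray, tets: np.ndarray) -> tuple[np.ndarray, int]:
    """Swap two nodes of every negative-volume tet; returns (tets, n_fixed)."""
    tets = np.array(tets, dtype=np.int64, copy=True)
    neg = tet_signed_volumes(nodes, tets) < 0
    n = int(neg.sum())
    if n:
        tets[neg, 0], tets[neg, 1] = tets[neg, 1].copy(), tets[neg, 0].copy()
    return tets, n


def _face_key(faces: np.ndarray) -> np.ndarray:
    return np.sort(faces, axis=1)


def boundary_faces_of(tets: np.ndarray) -> np.ndarray:
    """Faces used by exactly one tet, wound outward for positive tets."""
    # outward face set of a positive tet (a,b,c,d)
    faces = np.concatenate([tets[:, [0, 2, 1]], tets[:, [0, 1, 3]],
                            tets[:, [0, 3, 2]], tets[:, [1, 2, 3]]])
    key = _face_key(faces)
    _, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
    return faces[counts[inv] == 1]


def facet_area_vectors(nodes: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Per-triangle area vectors 0.5 * (b-a) x (c-a) (mm^2)."""
    a, b, c = nodes[faces[:, 0]], nodes[faces[:, 1]], nodes[faces[:, 2]]
    return 0.5 * np.cross(b - a, c - a)


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate_mesh(mesh: TetMesh) -> list[str]:
    """Check the TetMesh invariants; returns a list of violation messages.

    An empty report means the mesh is structurally solvable (materials
    coverage is checked separately by the solver, which knows the
    material table).  This function reports and never raises.
    """
    report: list[str] = []
    n = mesh.n_nodes
    if n == 0 or mesh.n_tets == 0:
        report.append("empty mesh: no nodes or no volume elements")
        return report
    if not np.isfinite(mesh.nodes).all():
        report.append("non-finite node coordinates")
    if mesh.tets.min() < 0 or mesh.tets.max() >= n:
        report.append("tet connectivity refers to a missing node")
        return report

    vols = mesh.tet_volumes()
    bad = np.flatnonzero(vols <= 0.0)
    for i in bad[:20]:
        report.append(f"tet {i}: non-positive volume ({vols[i]:.3e} mm^3)")
    if len(bad) > 20:
        report.append(f"... and {len(bad) - 20} more tets with non-positive volume")

    boundary = {tuple(f) for f in _face_key(mesh.boundary_faces())}
    for name, faces in mesh.facet_groups.items():
        if faces.size and (faces.min() < 0 or faces.max() >= n):
            report.append(f"facet group '{name}': refers to a missing node")
            continue
        for f in _face_key(faces):
            if tuple(f) not in boundary:
                report.append(f"facet group '{name}': facet {tuple(int(i) for i in f)} "
                              "not on the mesh boundary")
                break
    for name, idx in mesh.node_groups.items():
        if idx.size and (idx.min() < 0 or idx.max() >= n):
            report.append(f"node group '{name}': refers to a missing node")
    for name, loop in mesh.loops.items():
        report.extend(_check_loop(mesh.nodes, loop, name))
    return report


def _check_loop(nodes: np.ndarray, loop: np.ndarray, name: str) -> list[str]:
    out: list[str] = []
    if loop.size and (loop.min() < 0 or loop.max() >= len(nodes)):
        return [f"loop '{name}': refers to a missing node"]
    if len(loop) < 8:
        out.append(f"loop '{name}': fewer than 8 nodes")
        return out
    if len(np.unique(loop)) != len(loop):
        out.append(f"loop '{name}': non-simple loop (repeated node)")
        return out
    if not _loop_is_simple(nodes[loop]):
        out.append(f"loop '{name}': non-simple loop (self-intersecting)")
    return out


def _loop_is_simple(pts: np.ndarray) -> bool:
    """Project the cycle on its best-fit plane and test self-intersection."""
    from shapely.geometry import LinearRing

    centered = pts - pts.mean(axis=0)
    # two dominant right-singular vectors span the best-fit plane
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    uv = centered @ vt[:2].T
    try:
        ring = LinearRing(uv)
    except Exception:
        return False
    return bool(ring.is_simple) and ring.length > 0


# ---------------------------------------------------------------------------
# Gmsh .msh I/O
# ---------------------------------------------------------------------------
# Physical-group naming carries all semantics: dim-3 groups are material
# regions, dim-2 groups are facet groups, dim-1 groups are trephine loops
# (chains of 2-node line elements, written in cycle order) and dim-0
# groups are node groups (1-node point elements).

_TRI = 2
_LINE = 1
_TET = 4
_POINT = 15


def read_gmsh(path: str | Path) -> TetMesh:
    """Read a Gmsh ``.msh`` ASCII file (v4.1, or legacy v2.2) into a TetMesh.

    Named physical groups map 1:1 onto region tags / facet groups / node
    groups; loops are reconstructed from physical line groups when
    present.  Negative-volume tetrahedra are repaired by a node swap
    (logged).  Only linear tetrahedra are supported.
    """
    path = Path(path)
    sections = _split_msh_sections(path.read_text().splitlines())
    if "MeshFormat" not in sections:
        raise MeshFormatError(f"{path}: not a Gmsh .msh file")
    version = sections["MeshFormat"][0].split()[0]
    if version.startswith("4"):
        raw = _parse_msh4(sections)
    elif version.startswith("2"):
        raw = _parse_msh2(sections)
    else:
        raise MeshFormatError(f"{path}: unsupported msh dialect (version {version})")
    return _assemble_mesh(raw, path)


def _split_msh_sections(lines: list[str]) -> dict[str, list[str]]:
    sections: dict[str, list[str]] = {}
    name = None
    buf: list[str] = []
    for line in lines:
        s = line.strip()
        if not s:
            continue
        if s.startswith("$End"):
            if name is not None:
                sections[name] = buf
            name, buf = None, []
        elif s.startswith("$"):
            name, buf = s[1:], []
        elif name is not None:
            buf.append(s)
    return sections


def _parse_physical_names(lines: list[str]) -> dict[tuple[int, int], str]:
    names = {}
    for line in lines[1:]:
        parts = line.split(None, 2)
        dim, tag = int(parts[0]), int(parts[1])
        names[(dim, tag)] = parts[2].strip().strip('"')
    return names


class _RawMesh:
    def __init__(self) -> None:
        self.node_tags: list[int] = []
        self.coords: list[list[float]] = []
        # per element dim: list of (group_name, node-tag tuple)
        self.elements: dict[int, list[tuple[str | None, tuple[int, ...]]]] = {
            0: [], 1: [], 2: [], 3: []}


def _parse_msh4(sections: dict[str, list[str]]) -> _RawMesh:
    phys = _parse_physical_names(sections.get("PhysicalNames", ["0"]))
    # entity (dim, tag) -> physical name (first physical tag wins)
    ent_phys: dict[tuple[int, int], str | None] = {}
    if "Entities" in sections:
        toks = " ".join(sections["Entities"]).split()
        pos = 0

        def take(k: int) -> list[str]:
            nonlocal pos
            out = toks[pos:pos + k]
            pos += k
            return out

        np_, nc, ns, nv = (int(x) for x in take(4))
        for _ in range(np_):
            tag = int(take(1)[0])
            take(3)
            nph = int(take(1)[0])
            tags = [int(x) for x in take(nph)]
            ent_phys[(0, tag)] = phys.get((0, tags[0])) if tags else None
        for dim, count in ((1, nc), (2, ns), (3, nv)):
            for _ in range(count):
                tag = int(take(1)[0])
                take(6)
                nph = int(take(1)[0])
                tags = [int(x) for x in take(nph)]
                ent_phys[(dim, tag)] = phys.get((dim, tags[0])) if tags else None
                nb = int(take(1)[0])
                take(nb)

    raw = _RawMesh()
    lines = sections["Nodes"]
    n_blocks = int(lines[0].split()[0])
    i = 1
    for _ in range(n_blocks):
        _dim, _tag, _param, nb = (int(x) for x in lines[i].split())
        i += 1
        tags = [int(lines[i + k]) for k in range(nb)]
        i += nb
        for k in range(nb):
            raw.node_tags.append(tags[k])
            raw.coords.append([float(x) for x in lines[i + k].split()[:3]])
        i += nb

    lines = sections["Elements"]
    n_blocks = int(lines[0].split()[0])
    i = 1
    for _ in range(n_blocks):
        dim, tag, etype, nb = (int(x) for x in lines[i].split())
        i += 1
        gname = ent_phys.get((dim, tag))
        for k in range(nb):
            parts = lines[i + k].split()
            nodes = tuple(int(x) for x in parts[1:])
            _store_element(raw, etype, gname, nodes)
        i += nb
    return raw


def _parse_msh2(sections: dict[str, list[str]]) -> _RawMesh:
    phys = _parse_physical_names(sections.get("PhysicalNames", ["0"]))
    raw = _RawMesh()
    lines = sections["Nodes"]
    for line in lines[1:1 + int(lines[0])]:
        parts = line.split()
        raw.node_tags.append(int(parts[0]))
        raw.coords.append([float(x) for x in parts[1:4]])
    lines = sections["Elements"]
    for line in lines[1:1 + int(lines[0])]:
        parts = [int(x) for x in line.split()]
        etype, ntags = parts[1], parts[2]
        ptag = parts[3] if ntags >= 1 else None
        nodes = tuple(parts[3 + ntags:])
        dim = {_POINT: 0, _LINE: 1, _TRI: 2, _TET: 3}.get(etype)
        gname = phys.get((dim, ptag)) if (dim is not None and ptag is not None) else None
        _store_element(raw, etype, gname, nodes)
    return raw


def _store_element(raw: _RawMesh, etype: int, gname: str | None,
                   nodes: tuple[int, ...]) -> None:
    if etype == _TET:
        raw.elements[3].append((gname, nodes))
    elif etype == _TRI:
        raw.elements[2].append((gname, nodes))
    elif etype == _LINE:
        raw.elements[1].append((gname, nodes))
    elif etype == _POINT:
        raw.elements[0].append((gname, nodes))
    elif etype in (11, 9, 8):  # quadratic tet/tri/line
        raise MeshFormatError("unsupported msh dialect: quadratic elements "
                              "(only linear tetrahedra are supported)")
    # other element types (quads, hexes, ...) are rejected too
    elif etype in (3, 5, 6, 7):
        raise MeshFormatError(f"unsupported msh dialect: element type {etype}")


def _assemble_mesh(raw: _RawMesh, path: Path) -> TetMesh:
    if not raw.elements[3]:
        raise MeshFormatError(f"{path}: no volume elements")
    tag2idx = {t: i for i, t in enumerate(raw.node_tags)}
    nodes = np.asarray(raw.coords, dtype=np.float64)

    tets, regions = [], []
    for gname, conn in raw.elements[3]:
        if gname is None:
            raise MeshFormatError(f"{path}: untagged region (tetrahedron without a "
                                  "named physical group)")
        tets.append([tag2idx[t] for t in conn])
        regions.append(gname)
    tets_arr, n_fixed = fix_tet_orientation(nodes, np.asarray(tets, dtype=np.int64))
    if n_fixed:
        logger.info("read_gmsh: repaired orientation of %d tetrahedra", n_fixed)

    facet_groups: dict[str, list[list[int]]] = {}
    for gname, conn in raw.elements[2]:
        if gname is None:
            continue
        facet_groups.setdefault(gname, []).append([tag2idx[t] for t in conn])

    line_groups: dict[str, list[tuple[int, int]]] = {}
    for gname, conn in raw.elements[1]:
        if gname is None:
            continue
        line_groups.setdefault(gname, []).append((tag2idx[conn[0]], tag2idx[conn[1]]))

    node_groups: dict[str, list[int]] = {}
    for gname, conn in raw.elements[0]:
        if gname is None:
            continue
        node_groups.setdefault(gname, []).append(tag2idx[conn[0]])

    loops = {}
    for gname, segs in line_groups.items():
        cycle = _chain_segments(segs)
        if cycle is None:
            logger.warning("read_gmsh: line group '%s' is not a single closed "
                           "cycle; skipped", gname)
        else:
            loops[gname] = np.asarray(cycle, dtype=np.int64)

    return TetMesh(nodes, tets_arr, np.asarray(regions),
                   {k: np.asarray(v, dtype=np.int64) for k, v in facet_groups.items()},
                   {k: np.asarray(sorted(v), dtype=np.int64) for k, v in node_groups.items()},
                   loops)


def _chain_segments(segs: list[tuple[int, int]]) -> list[int] | None:
    succ = {}
    for a, b in segs:
        if a in succ:
            return None
        succ[a] = b
    start = segs[0][0]
    cycle = [start]
    cur = succ.get(start)
    while cur is not None and cur != start and len(cycle) <= len(segs):
        cycle.append(cur)
        cur = succ.get(cur)
    if cur != start or len(cycle) != len(segs):
        return None
    return cycle


def write_gmsh(mesh: TetMesh, path: str | Path) -> None:
    """Write a TetMesh as Gmsh ``.msh`` ASCII v4.1.

    Physical groups are named exactly as the mesh's groups; regions
    become volume groups, facet groups surface groups, loops physical
    line chains (in cycle order) and node groups physical point sets, so
    :func:`read_gmsh` inverts this writer.  Refuses to write a mesh that
    fails :func:`validate_mesh`; empty groups are omitted with a warning.
    """
    path = Path(path)
    report = validate_mesh(mesh)
    if report:
        raise MeshError("refusing to write invalid mesh: " + "; ".join(report[:3]))

    regions = mesh.region_names()
    facet_groups = {k: v for k, v in mesh.facet_groups.items() if len(v)}
    node_groups = {k: v for k, v in mesh.node_groups.items() if len(v)}
    loops = {k: v for k, v in mesh.loops.items() if len(v)}
    for name in set(mesh.facet_groups) - set(facet_groups):
        logger.warning("write_gmsh: empty facet group '%s' omitted", name)
    for name in set(mesh.node_groups) - set(node_groups):
        logger.warning("write_gmsh: empty node group '%s' omitted", name)
    for name in set(mesh.loops) - set(loops):
        logger.warning("write_gmsh: empty loop '%s' omitted", name)

    out: list[str] = []
    out.append("$MeshFormat\n4.1 0 8\n$EndMeshFormat")

    # one discrete entity per group, tags 1..k per dimension
    pt_names = list(node_groups)
    ln_names = list(loops)
    sf_names = list(facet_groups)
    vl_names = regions
    out.append("$PhysicalNames")
    out.append(str(len(pt_names) + len(ln_names) + len(sf_names) + len(vl_names)))
    for i, n in enumerate(pt_names, 1):
        out.append(f'0 {i} "{n}"')
    for i, n in enumerate(ln_names, 1):
        out.append(f'1 {i} "{n}"')
    for i, n in enumerate(sf_names, 1):
        out.append(f'2 {i} "{n}"')
    for i, n in enumerate(vl_names, 1):
        out.append(f'3 {i} "{n}"')
    out.append("$EndPhysicalNames")

    lo = mesh.nodes.min(axis=0)
    hi = mesh.nodes.max(axis=0)
    bbox = f"{lo[0]:.17g} {lo[1]:.17g} {lo[2]:.17g} {hi[0]:.17g} {hi[1]:.17g} {hi[2]:.17g}"
    out.append("$Entities")
    out.append(f"{len(pt_names)} {len(ln_names)} {len(sf_names)} {len(vl_names)}")
    for i in range(1, len(pt_names) + 1):
        out.append(f"{i} 0 0 0 1 {i}")
    for i in range(1, len(ln_names) + 1):
        out.append(f"{i} {bbox} 1 {i} 0")
    for i in range(1, len(sf_names) + 1):
        out.append(f"{i} {bbox} 1 {i} 0")
    for i in range(1, len(vl_names) + 1):
        out.append(f"{i} {bbox} 1 {i} 0")
    out.append("$EndEntities")

    n = mesh.n_nodes
    out.append("$Nodes")
    out.append(f"1 {n} 1 {n}")
    out.append(f"3 1 0 {n}")
    out.extend(str(i) for i in range(1, n + 1))
    out.extend(f"{p[0]:.17g} {p[1]:.17g} {p[2]:.17g}" for p in mesh.nodes)
    out.append("$EndNodes")

    blocks: list[tuple[int, int, int, list[tuple[int, ...]]]] = []
    for i, name in enumerate(pt_names, 1):
        blocks.append((0, i, _POINT, [(int(j),) for j in node_groups[name]]))
    for i, name in enumerate(ln_names, 1):
        loop = loops[name]
        segs = [(int(loop[k]), int(loop[(k + 1) % len(loop)])) for k in range(len(loop))]
        blocks.append((1, i, _LINE, segs))
    for i, name in enumerate(sf_names, 1):
        blocks.append((2, i, _TRI, [tuple(int(x) for x in f) for f in facet_groups[name]]))
    for i, name in enumerate(vl_names, 1):
        sel = mesh.tets[mesh.regions == name]
        blocks.append((3, i, _TET, [tuple(int(x) for x in t) for t in sel]))

    n_elem = sum(len(b[3]) for b in blocks)
    out.append("$Elements")
    out.append(f"{len(blocks)} {n_elem} 1 {n_elem}")
    etag = 1
    for dim, tag, etype, elems in blocks:
        out.append(f"{dim} {tag} {etype} {len(elems)}")
        for conn in elems:
            out.append(f"{etag} " + " ".join(str(c + 1) for c in conn))
            etag += 1
    out.append("$EndElements")
    path.write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# VTU / STL export
# ---------------------------------------------------------------------------

def write_vtk(mesh: TetMesh,
              node_fields: dict[str, np.ndarray] | None = None,
              cell_fields: dict[str, np.ndarray] | None = None,
              path: str | Path = "out.vtu") -> None:
    """Write the mesh and result fields as a VTU (XML unstructured grid).

    ``node_fields`` arrays must have length ``n_nodes`` (scalars or
    3-vectors, e.g. ``{"displacement": u}``); ``cell_fields`` length
    ``n_tets`` (e.g. ``{"von_mises": sv}``).  A mismatched length raises
    naming the offending field.
    """
    node_fields = node_fields or {}
    cell_fields = cell_fields or {}
    for name, arr in node_fields.items():
        if len(np.asarray(arr)) != mesh.n_nodes:
            raise MeshError(f"node field '{name}': length {len(arr)} != "
                            f"{mesh.n_nodes} nodes")
    for name, arr in cell_fields.items():
        if len(np.asarray(arr)) != mesh.n_tets:
            raise MeshError(f"cell field '{name}': length {len(arr)} != "
                            f"{mesh.n_tets} cells")

    def da(arr: np.ndarray, name: str) -> str:
        arr = np.asarray(arr, dtype=np.float64)
        ncomp = 1 if arr.ndim == 1 else arr.shape[1]
        body = "\n".join(" ".join(f"{x:.9g}" for x in np.atleast_1d(row))
                         for row in arr)
        return (f'<DataArray type="Float64" Name="{name}" '
                f'NumberOfComponents="{ncomp}" format="ascii">\n{body}\n</DataArray>')

    conn = " ".join(str(i) for i in mesh.tets.ravel())
    offs = " ".join(str(4 * (i + 1)) for i in range(mesh.n_tets))
    types = " ".join("10" for _ in range(mesh.n_tets))
    pdata = "\n".join(da(v, k) for k, v in node_fields.items())
    # region id written alongside user cell fields for inspection
    region_ids = np.searchsorted(np.sort(np.unique(mesh.regions)), mesh.regions)
    cdata = "\n".join([da(v, k) for k, v in cell_fields.items()] +
                      [da(region_ids.astype(float), "region_id")])
    xml = f"""<?xml version="1.0"?>
<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">
<UnstructuredGrid>
<Piece NumberOfPoints="{mesh.n_nodes}" NumberOfCells="{mesh.n_tets}">
<Points>
{da(mesh.nodes, "points")}
</Points>
<Cells>
<DataArray type="Int64" Name="connectivity" format="ascii">
{conn}
</DataArray>
<DataArray type="Int64" Name="offsets" format="ascii">
{offs}
</DataArray>
<DataArray type="UInt8" Name="types" format="ascii">
{types}
</DataArray>
</Cells>
<PointData>
{pdata}
</PointData>
<CellData>
{cdata}
</CellData>
</Piece>
</UnstructuredGrid>
</VTKFile>
"""
    Path(path).write_text(xml)


def write_stl(mesh: TetMesh, path: str | Path,
              groups: list[str] | None = None) -> None:
    """Export surface facet groups (default: all) as binary STL."""
    import trimesh

    names = groups if groups is not None else list(mesh.facet_groups)
    faces = np.concatenate([mesh.facet_groups[n] for n in names]) if names else \
        mesh.boundary_faces()
    trimesh.Trimesh(vertices=mesh.nodes, faces=faces, process=False).export(str(path))
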