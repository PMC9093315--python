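"""Layered head phantoms: five-shell tetrahedral meshes with scalp electrodes.

The phantom is a head-like convex solid -- a hemisphere of radius R sitting on
a short cylindrical base -- partitioned into five concentric tissue shells
(white matter innermost, then grey matter, CSF, skull, scalp).  Shells are
defined by the generalized radius rho(p) = |p| for z >= 0 and hypot(x, y)
below the equator, so tissue assignment of an element is simply the shell
containing its centroid.  Meshing is Delaunay tetrahedralization of a seeded,
jittered point cloud (the solid is convex, so the Delaunay hull fills it
exactly up to surface facet chords).

Units are SI throughout: metres, S/m, ohm.m^2.  The coordinate frame is
right-handed with +x toward the nose and +z up.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import Delaunay

from . import layouts

#: Tissue names, outermost first.
TISSUES = ("scalp", "skull", "csf", "grey", "white")

#: Nominal tissue conductivities, S/m.  Scalp and skull come from a global
#: fit of long-term measurement data to a head model; CSF, grey and white
#: matter are literature values.
DEFAULT_TISSUE_TABLE: dict[str, float] = {
    "scalp": 0.584,
    "skull": 0.0084,
    "csf": 1.802,
    "grey": 0.2849,
    "white": 0.2556,
}

#: Default contact impedance for low-impedance scalp electrodes, ohm.m^2.
DEFAULT_CONTACT_IMPEDANCE = 1.0e-3

#: Base (cylinder) depth as a fraction of the outer radius.
BASE_DEPTH_FRACTION = 0.35

TissueTable = dict
ConductivityField = np.ndarray


def simulation_tissue_table() -> dict[str, float]:
    """Reduced 3-value table used for inclusion simulations: grey matter and
    CSF are set to the white-matter conductivity."""
    t = dict(DEFAULT_TISSUE_TABLE)
    t["grey"] = t["white"]
    t["csf"] = t["white"]
    return t


@dataclass(frozen=True)
class HeadMesh:
    """Tetrahedral head mesh with tissue labels and electrode patches.

    ``tissue`` holds per-element indices into :data:`TISSUES`.
    ``electrode_faces`` holds, per electrode, an array of boundary faces
    (node index triples); ``contact_impedance`` is per electrode in ohm.m^2.
    """

    nodes: np.ndarray
    elements: np.ndarray
    tissue: np.ndarray
    electrode_faces: tuple[np.ndarray, ...] = ()
    contact_impedance: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    @property
    def electrode_count(self) -> int:
        return len(self.electrode_faces)

    def tissue_names(self) -> np.ndarray:
        return np.array(TISSUES)[self.tissue]

    def tissue_mask(self, name: str) -> np.ndarray:
        if name not in TISSUES:
            raise KeyError(f"unknown tissue {name!r}")
        return self.tissue == TISSUES.index(name)

    def element_volumes(self) -> np.ndarray:
        x = self.nodes[self.elements]
        return _tet_volumes(x)

    def element_centroids(self) -> np.ndarray:
        return self.nodes[self.elements].mean(axis=1)

    def boundary_faces(self) -> np.ndarray:
        return _boundary_faces(self.elements)

    def element_gradients(self) -> tuple[np.ndarray, np.ndarray]:
        """P1 shape-function gradients (m, 4, 3) and volumes (m,), cached."""
        cached = getattr(self, "_grad_cache", None)
        if cached is None:
            cached = _p1_gradients(self.nodes, self.elements)
            object.__setattr__(self, "_grad_cache", cached)
        return cached


def generalized_radius(points: np.ndarray) -> np.ndarray:
    """Shell coordinate: spherical radius above the equator, cylindrical
    radius below."""
    p = np.atleast_2d(points)
    r_sph = np.linalg.norm(p, axis=1)
    r_cyl = np.hypot(p[:, 0], p[:, 1])
    return np.where(p[:, 2] >= 0.0, r_sph, r_cyl)


def _tet_volumes(x: np.ndarray) -> np.ndarray:
    d = x[:, 1:] - x[:, :1]
    return np.linalg.det(d) / 6.0


def _p1_gradients(nodes, elements):
    x = nodes[elements]
    d = x[:, 1:] - x[:, :1]           # (m, 3, 3)
    vol = np.linalg.det(d) / 6.0
    dinv = np.linalg.inv(d)           # rows of dinv.T are grads of lam 1..3
    g = np.transpose(dinv, (0, 2, 1))
    grads = np.empty((len(elements), 4, 3))
    grads[:, 1:, :] = g
    grads[:, 0, :] = -g.sum(axis=1)
    return grads, vol


def _boundary_faces(elements: np.ndarray) -> np.ndarray:
    faces = np.concatenate([
        elements[:, [0, 1, 2]], elements[:, [0, 1, 3]],
        elements[:, [0, 2, 3]], elements[:, [1, 2, 3]],
    ])
    key = np.sort(faces, axis=1)
    _, idx, counts = np.unique(key, axis=0, return_index=True,
                               return_counts=True)
    return faces[idx[counts == 1]]


def _surface_points(R: float, depth: float, h: float) -> np.ndarray:
    pts = []
    # hemisphere: Fibonacci spiral on the upper half-sphere
    n_hemi = max(8, int(round(2.0 * np.pi * R * R / (h * h))))
    i = np.arange(n_hemi)
    z = (i + 0.5) / n_hemi                     # uniform in z on (0, 1)
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    rxy = np.sqrt(1.0 - z * z)
    pts.append(R * np.stack([rxy * np.cos(phi), rxy * np.sin(phi), z], axis=1))
    # cylinder side: rings between z = -depth and the equator (inclusive)
    n_lev = max(2, int(round(depth / h)) + 1)
    for j, zl in enumerate(np.linspace(-depth, 0.0, n_lev + 1)):
        n_ring = max(6, int(round(2.0 * np.pi * R / h)))
        th = 2.0 * np.pi * (np.arange(n_ring) + 0.5 * (j % 2)) / n_ring
        pts.append(np.stack([R * np.cos(th), R * np.sin(th),
                             np.full(n_ring, zl)], axis=1))
    # bottom disk: polar grid incl. rim
    n_rad = max(2, int(round(R / h)))
    for r in np.linspace(0.0, R, n_rad + 1):
        if r == 0.0:
            pts.append(np.array([[0.0, 0.0, -depth]]))
            continue
        n_ring = max(6, int(round(2.0 * np.pi * r / h)))
        th = 2.0 * np.pi * np.arange(n_ring) / n_ring
        pts.append(np.stack([r * np.cos(th), r * np.sin(th),
                             np.full(n_ring, -depth)], axis=1))
    return np.concatenate(pts)


def _mesh_once(R, depth, h, rng):
    surf = _surface_points(R, depth, h)
    # jittered interior grid, kept clear of the surface by a margin
    ax = np.arange(-R, R + h, h)
    az = np.arange(-depth, R + h, h)
    gx, gy, gz = np.meshgrid(ax, ax, az, indexing="ij")
    grid = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
    grid = grid + rng.uniform(-0.25 * h, 0.25 * h, grid.shape)
    rho = generalized_radius(grid)
    keep = (rho <= R - 0.45 * h) & (grid[:, 2] >= -depth + 0.45 * h)
    points = np.concatenate([surf, grid[keep]])
    tri = Delaunay(points)
    tets = tri.simplices.astype(np.int64)
    vols = _tet_volumes(points[tets])
    # fix orientation, drop surface slivers
    flip = vols < 0
    tets[flip] = tets[flip][:, [0, 1, 3, 2]]
    vols = np.abs(vols)
    tets = tets[vols > 1e-7 * h ** 3]
    # drop nodes orphaned by sliver removal and reindex
    used = np.unique(tets)
    remap = np.full(len(points), -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    return points[used], remap[tets]


def build_layered_head(radii: tuple[float, ...] = (0.060, 0.065, 0.070,
                                                   0.075, 0.080),
                       target_elements: int = 5000,
                       seed: int = 0) -> HeadMesh:
    """Generate a five-shell head phantom.

    Parameters
    ----------
    radii
        Outer radii of the five shells in metres, strictly increasing
        outward: white < grey < CSF < skull < scalp.
    target_elements
        Requested tetrahedron count (achieved within roughly +-30%).
    seed
        Seed for the point-cloud jitter; meshes are deterministic per seed.
    """
    radii = tuple(float(r) for r in radii)
    if len(radii) != 5 or any(b <= a for a, b in zip(radii, radii[1:])) \
            or radii[0] <= 0:
        raise ValueError("radii must be five strictly increasing positive "
                         "values (white < grey < CSF < skull < scalp)")
    if target_elements < 500:
        raise ValueError("target_elements must be at least 500")
    R = radii[-1]
    depth = BASE_DEPTH_FRACTION * R
    volume = 2.0 / 3.0 * np.pi * R ** 3 + np.pi * R ** 2 * depth
    h = (6.2 * volume / target_elements) ** (1.0 / 3.0)
    points = tets = None
    for attempt in range(4):
        rng = np.random.default_rng(seed)
        points, tets = _mesh_once(R, depth, h, rng)
        ratio = len(tets) / target_elements
        if 0.77 <= ratio <= 1.3:
            break
        h *= ratio ** (1.0 / 3.0)
    else:
        raise RuntimeError(
            f"meshing failed to reach target element count: got {len(tets)} "
            f"for target {target_elements}")
    centroids = points[tets].mean(axis=1)
    rho = generalized_radius(centroids)
    layer = np.searchsorted(np.asarray(radii), rho)   # 0 = white .. 4 = scalp
    layer = np.minimum(layer, 4)
    tissue = np.array([TISSUES.index(n) for n in
                       ("white", "grey", "csf", "skull", "scalp")],
                      dtype=np.int8)[layer]
    mesh = HeadMesh(points, tets, tissue)
    if np.any(mesh.element_volumes() <= 0):
        raise RuntimeError("meshing produced non-positive element volumes")
    return mesh


def place_electrodes(mesh: HeadMesh,
                     layout: np.ndarray | None = None,
                     patch_diameter: float = 0.010,
                     contact_impedance: float = DEFAULT_CONTACT_IMPEDANCE
                     ) -> HeadMesh:
    """Attach 32 disjoint electrode patches to the outer boundary.

    Each patch is the set of outer boundary faces whose centroid lies within
    ``patch_diameter / 2`` of the electrode centre, which is the intersection
    of the layout direction with the outer surface.
    """
    if layout is None:
        layout = layouts.ELECTRODE_DIRECTIONS
    layout = np.asarray(layout, dtype=float)
    if layout.shape != (32, 3):
        raise ValueError("layout must be 32 unit directions")
    u = layout / np.linalg.norm(layout, axis=1, keepdims=True)
    if np.unique(np.round(u, 9), axis=0).shape[0] != 32:
        raise ValueError("electrode directions must be distinct")

    R = float(generalized_radius(mesh.nodes).max())
    centers = np.empty_like(u)
    up = u[:, 2] >= 0
    centers[up] = R * u[up]
    s = np.hypot(u[~up, 0], u[~up, 1])
    centers[~up] = R * u[~up] / s[:, None]

    dmin = np.inf
    for i in range(32):
        d = np.linalg.norm(centers[i + 1:] - centers[i], axis=1)
        if len(d):
            dmin = min(dmin, d.min())
    if patch_diameter >= dmin:
        raise ValueError(f"patch diameter {patch_diameter} exceeds the "
                         f"minimum inter-electrode spacing {dmin:.4g}")

    bfaces = mesh.boundary_faces()
    fc = mesh.nodes[bfaces].mean(axis=1)
    e1 = mesh.nodes[bfaces[:, 1]] - mesh.nodes[bfaces[:, 0]]
    e2 = mesh.nodes[bfaces[:, 2]] - mesh.nodes[bfaces[:, 0]]
    areas = 0.5 * np.linalg.norm(np.cross(e1, e2), axis=1)
    edge = np.median(np.sqrt(2.0 * areas))
    outer = generalized_radius(fc) >= R - 0.9 * edge

    owner = np.full(len(bfaces), -1)
    patches = []
    target_area = np.pi * (patch_diameter / 2.0) ** 2
    for l in range(32):
        dist = np.linalg.norm(fc - centers[l], axis=1)
        vdist = np.linalg.norm(mesh.nodes[bfaces] - centers[l],
                               axis=2).min(axis=1)
        dist[~outer] = np.inf
        vdist[~outer] = np.inf
        # candidates: any vertex within the patch radius; accumulate faces
        # nearest-first until the patch area reaches pi (d/2)^2
        sel = np.where(vdist <= patch_diameter / 2.0)[0]
        if len(sel) == 0:
            # coarse mesh: the nearest unclaimed outer face stands in
            free = np.where(owner < 0, dist, np.inf)
            if not np.isfinite(free.min()):
                raise ValueError(f"electrode {l + 1}: no free boundary face")
            sel = np.array([int(np.argmin(free))])
        else:
            sel = sel[np.argsort(dist[sel])]
            cum = np.cumsum(areas[sel])
            keep = int(np.searchsorted(cum, target_area)) + 1
            sel = sel[:min(keep, len(sel))]
        clash = np.unique(owner[sel][owner[sel] >= 0])
        if len(clash):
            raise ValueError("overlapping electrode patches: "
                             f"{sorted(int(c) + 1 for c in clash)} and {l + 1}")
        owner[sel] = l
        patches.append(bfaces[sel].copy())
    return replace(mesh, electrode_faces=tuple(patches),
                   contact_impedance=np.full(32, float(contact_impedance)))


def assign_conductivities(mesh: HeadMesh, table: dict[str, float]
                          ) -> np.ndarray:
    """Per-element conductivity field (S/m) from a tissue table."""
    missing = [t for t in TISSUES if t not in table]
    if missing:
        raise KeyError(f"tissue table missing {missing}")
    values = np.array([float(table[t]) for t in TISSUES])
    if np.any(values <= 0):
        raise ValueError("tissue conductivities must be positive")
    return values[mesh.tissue]


def embed_sphere(field: np.ndarray, mesh: HeadMesh, center, diameter: float,
                 value: float) -> np.ndarray:
    """Set elements whose centroid lies inside the sphere to ``value``."""
    if value <= 0:
        raise ValueError("inclusion conductivity must be positive")
    if diameter < 0:
        raise ValueError("diameter must be non-negative")
    out = np.array(field, dtype=float, copy=True)
    if diameter == 0:
        return out
    center = np.asarray(center, dtype=float)
    d = np.linalg.norm(mesh.element_centroids() - center, axis=1)
    hit = d <= diameter / 2.0
    if not np.any(hit):
        nearest = np.linalg.norm(mesh.nodes - center, axis=1).min()
        if nearest > diameter / 2.0:
            raise ValueError("sphere lies entirely outside the mesh")
    out[hit] = value
    return out


# ---------------------------------------------------------------------------
# Gmsh ASCII 2.2 exchange with physical groups for tissues and electrodes.
# Contact impedances travel in a custom $ContactImpedance section (readers
# of the MSH format skip unknown sections).

def write_mesh(mesh: HeadMesh, path) -> None:
    lines = ["$MeshFormat", "2.2 0 8", "$EndMeshFormat", "$PhysicalNames",
             str(5 + mesh.electrode_count)]
    for i, t in enumerate(TISSUES):
        lines.append(f'3 {i + 1} "{t}"')
    for l in range(mesh.electrode_count):
        lines.append(f'2 {101 + l} "E{l + 1:02d}"')
    lines.append("$EndPhysicalNames")
    lines.append("$Nodes")
    lines.append(str(mesh.n_nodes))
    for i, p in enumerate(mesh.nodes):
        lines.append(f"{i + 1} {float(p[0])!r} {float(p[1])!r} "
                     f"{float(p[2])!r}")
    lines.append("$EndNodes")
    n_tri = sum(len(f) for f in mesh.electrode_faces)
    lines.append("$Elements")
    lines.append(str(n_tri + mesh.n_elements))
    eid = 1
    for l, faces in enumerate(mesh.electrode_faces):
        for f in faces:
            lines.append(f"{eid} 2 2 {101 + l} {101 + l} "
                         f"{f[0] + 1} {f[1] + 1} {f[2] + 1}")
            eid += 1
    for e, t in zip(mesh.elements, mesh.tissue):
        lines.append(f"{eid} 4 2 {t + 1} {t + 1} "
                     f"{e[0] + 1} {e[1] + 1} {e[2] + 1} {e[3] + 1}")
        eid += 1
    lines.append("$EndElements")
    if mesh.electrode_count:
        lines.append("$ContactImpedance")
        lines.append(str(mesh.electrode_count))
        for l, z in enumerate(mesh.contact_impedance):
            lines.append(f"E{l + 1:02d} {float(z)!r}")
        lines.append("$EndContactImpedance")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_mesh(path) -> HeadMesh:
    with open(path) as fh:
        text = fh.read().split("\n")
    sections: dict[str, list[str]] = {}
    i = 0
    while i < len(text):
        line = text[i].strip()
        if line.startswith("$") and not line.startswith("$End"):
            name = line[1:]
            j = i + 1
            body = []
            while j < len(text) and text[j].strip() != f"$End{name}":
                body.append(text[j])
                j += 1
            sections[name] = body
            i = j + 1
        else:
            i += 1

    tissue_ids: dict[int, int] = {}
    electrode_ids: dict[int, int] = {}
    for line in sections.get("PhysicalNames", [])[1:]:
        parts = line.split()
        if len(parts) < 3:
            continue
        dim, pid = int(parts[0]), int(parts[1])
        name = line.split('"')[1]
        if dim == 3:
            if name not in TISSUES:
                raise ValueError(f"unknown tissue set name {name!r}")
            tissue_ids[pid] = TISSUES.index(name)
        elif dim == 2 and name.startswith("E"):
            electrode_ids[pid] = int(name[1:]) - 1
    missing = [t for t in TISSUES
               if TISSUES.index(t) not in tissue_ids.values()]
    if missing:
        raise ValueError(f"mesh file missing tissue set(s): {missing}")

    body = sections["Nodes"]
    n_nodes = int(body[0])
    nodes = np.array([[float(v) for v in line.split()[1:4]]
                      for line in body[1:1 + n_nodes]])

    elements, tissue = [], []
    faces_per_electrode: dict[int, list] = {l: [] for l in
                                            electrode_ids.values()}
    body = sections["Elements"]
    n_elem = int(body[0])
    for line in body[1:1 + n_elem]:
        parts = [int(v) for v in line.split()]
        etype, ntags = parts[1], parts[2]
        phys = parts[3]
        conn = [v - 1 for v in parts[3 + ntags:]]
        if etype == 4:
            elements.append(conn)
            tissue.append(tissue_ids[phys])
        elif etype == 2:
            faces_per_electrode[electrode_ids[phys]].append(conn)

    contact = {}
    if "ContactImpedance" in sections:
        for line in sections["ContactImpedance"][1:]:
            parts = line.split()
            if len(parts) == 2:
                contact[int(parts[0][1:]) - 1] = float(parts[1])

    n_el = len(faces_per_electrode)
    patches = []
    for l in range(n_el):
        fl = faces_per_electrode.get(l, [])
        if not fl:
            raise ValueError(f"electrode E{l + 1:02d} has an empty face set")
        patches.append(np.array(fl, dtype=np.int64))
    z = np.array([contact.get(l, DEFAULT_CONTACT_IMPEDANCE)
                  for l in range(n_el)])
    return HeadMesh(nodes, np.array(elements, dtype=np.int64),
                    np.array(tissue, dtype=np.int8), tuple(patches), z)
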