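"""Study geometries as tagged tetrahedral meshes.

Three built-in cases:

``plate_single``
    Rectangular tissue block between two plate electrodes; the electrodes are
    not meshed, they enter as Dirichlet boundary tags on (sub-rectangles of)
    the two faces x = 0 and x = d.  Optionally layered along the
    inter-electrode axis (series slab stacks for solver validation).
``needle_single``
    Tissue block with two parallel cylindrical bores (needle tracks) entering
    from the top face; the bore walls down to the insertion depth are the
    electrode contacts.
``tumor_composite``
    Skin-fold model of a subcutaneous tumor pinched between two plates a
    distance d apart: from each plate inward along x a stratum-corneum+
    epidermis layer and a dermis+fat layer, then a tumor sphere embedded in
    muscle.  X is the muscle-fiber (longitudinal) direction.

Conventions: the inter-electrode axis is x; configs are in mm, mesh
coordinates in metres; anode at x = 0 (or first needle), cathode opposite.
Meshing is fully deterministic for a given config.

Block cases use a structured grid with each hex cell cut into 6 tetrahedra
(Kuhn subdivision, conforming across cells).  The needle case triangulates
the cross-section with nodes placed exactly on the bore circles (Delaunay)
and extrudes the triangles into prisms, each split into 3 tetrahedra with
the index-ordering rule of Dompierre et al. so shared faces conform.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial import Delaunay

from .units import MM

FACET_TAGS = ("insulated", "anode", "cathode")
INSULATED, ANODE, CATHODE = 0, 1, 2


class GeometryError(ValueError):
    """Invalid geometry configuration."""


@dataclass(frozen=True)
class GeometryConfig:
    """Parameters of a study geometry (lengths in mm).

    ``gap_mm`` is the inter-electrode distance d (plate and tumor cases);
    ``width_mm``/``height_mm`` span the plate cross-section (y, z); the
    needle case uses ``width_mm`` (x) x ``depth_mm`` (y) x ``height_mm`` (z).
    ``layers`` optionally stacks named tissue slabs along x in the plate
    case, as (tissue_name, thickness_mm) pairs summing to ``gap_mm``.
    """

    case: str = "plate_single"
    gap_mm: Optional[float] = None      # plate: 4, tumor: 5.2
    width_mm: Optional[float] = None    # plate: 20 (y), needle: 24 (x)
    depth_mm: Optional[float] = None    # needle: 16 (y), tumor fold: 6
    height_mm: Optional[float] = None   # plate: 10, needle: 10, tumor fold: 6
    contact_width_mm: Optional[float] = None
    contact_height_mm: Optional[float] = None
    resolution_mm: float = 1.0
    tissue: str = "liver"
    layers: Optional[Tuple[Tuple[str, float], ...]] = None
    # needle case
    needle_diameter_mm: float = 1.1
    needle_spacing_mm: float = 8.0
    insertion_depth_mm: float = 7.0
    # tumor case
    layer_se_mm: float = 0.25
    layer_df_mm: float = 0.8
    muscle_base_mm: float = 1.0
    tumor_diameter_mm: float = 2.5
    tumor_depth_mm: float = 0.5
    tumor_shape: str = "sphere"

    _CASE_DEFAULTS = {
        "plate_single": {"gap_mm": 4.0, "width_mm": 20.0, "depth_mm": 16.0,
                         "height_mm": 10.0},
        "needle_single": {"gap_mm": 4.0, "width_mm": 24.0, "depth_mm": 16.0,
                          "height_mm": 10.0},
        "tumor_composite": {"gap_mm": 5.2, "width_mm": 20.0, "depth_mm": 6.0,
                            "height_mm": 6.0, "contact_width_mm": 3.0,
                            "contact_height_mm": 3.0},
        "imported": {"gap_mm": 4.0, "width_mm": 20.0, "depth_mm": 16.0,
                     "height_mm": 10.0},
    }

    def __post_init__(self):
        if self.case not in self._CASE_DEFAULTS:
            raise GeometryError(f"unknown geometry case {self.case!r}")
        for name, val in self._CASE_DEFAULTS[self.case].items():
            if getattr(self, name) is None:
                object.__setattr__(self, name, val)
        for name in ("gap_mm", "width_mm", "depth_mm", "height_mm", "resolution_mm",
                     "needle_diameter_mm", "needle_spacing_mm", "insertion_depth_mm",
                     "layer_se_mm", "layer_df_mm", "tumor_diameter_mm"):
            if not getattr(self, name) > 0:
                raise GeometryError(f"{name} must be > 0")


@dataclass
class Mesh:
    """Tetrahedral mesh with per-element tissue labels and tagged boundary.

    ``points`` are node coordinates in metres; ``tets`` index into points;
    ``region_ids`` index ``region_names``; ``bfacets`` are boundary triangles
    with ``bfacet_tags`` indexing :data:`FACET_TAGS`.
    """

    points: np.ndarray
    tets: np.ndarray
    region_ids: np.ndarray
    region_names: List[str]
    bfacets: np.ndarray
    bfacet_tags: np.ndarray

    @property
    def n_nodes(self) -> int:
        return self.points.shape[0]

    @property
    def n_elements(self) -> int:
        return self.tets.shape[0]

    def regions(self) -> List[str]:
        return list(self.region_names)

    def element_regions(self) -> np.ndarray:
        """Per-element tissue name, as an object array."""
        return np.asarray(self.region_names, dtype=object)[self.region_ids]

    def region_mask(self, name: str) -> np.ndarray:
        if name not in self.region_names:
            raise GeometryError(f"unknown region {name!r}; known: {self.region_names}")
        return self.region_ids == self.region_names.index(name)

    def tet_volumes(self) -> np.ndarray:
        p = self.points[self.tets]
        v = np.einsum(
            "ij,ij->i",
            np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]),
            p[:, 3] - p[:, 0],
        ) / 6.0
        return v

    def region_volume(self, name: str) -> float:
        return float(self.tet_volumes()[self.region_mask(name)].sum())

    def facet_areas(self) -> np.ndarray:
        p = self.points[self.bfacets]
        return 0.5 * np.linalg.norm(
            np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), axis=1
        )

    def electrode_area(self, tag: str) -> float:
        tid = FACET_TAGS.index(tag)
        return float(self.facet_areas()[self.bfacet_tags == tid].sum())

    def electrode_nodes(self, tag: str) -> np.ndarray:
        """Sorted unique node indices on the facets carrying ``tag``."""
        tid = FACET_TAGS.index(tag)
        return np.unique(self.bfacets[self.bfacet_tags == tid])

    def swap_electrodes(self) -> "Mesh":
        tags = self.bfacet_tags.copy()
        a, c = tags == ANODE, tags == CATHODE
        tags[a], tags[c] = CATHODE, ANODE
        return replace_mesh(self, bfacet_tags=tags)

    def validate(self) -> None:
        vols = self.tet_volumes()
        if np.any(vols <= 0):
            bad = int(np.argmin(vols))
            raise GeometryError(f"inverted/degenerate tetrahedron {bad}")
        for tag in ("anode", "cathode"):
            if self.electrode_nodes(tag).size == 0:
                raise GeometryError(f"no facets tagged {tag!r}")
        if np.intersect1d(
            self.electrode_nodes("anode"), self.electrode_nodes("cathode")
        ).size:
            raise GeometryError("anode and cathode share nodes")


def replace_mesh(mesh: Mesh, **kw) -> Mesh:
    d = dict(
        points=mesh.points, tets=mesh.tets, region_ids=mesh.region_ids,
        region_names=mesh.region_names, bfacets=mesh.bfacets,
        bfacet_tags=mesh.bfacet_tags,
    )
    d.update(kw)
    return Mesh(**d)


# ---------------------------------------------------------------------------
# low-level helpers
# ---------------------------------------------------------------------------

_KUHN_PATHS = [(0, 1, 2), (0, 2, 1), (1, 0, 2), (1, 2, 0), (2, 0, 1), (2, 1, 0)]


def _split_segments(breaks: Sequence[float]) -> List[Tuple[float, float]]:
    """Adjacent (a, b) pairs from a sorted breakpoint list, dropping empties."""
    b = sorted(breaks)
    return [(a, c) for a, c in zip(b[:-1], b[1:]) if c - a > 1e-12]


def _segmented_axis(segments: Sequence[Tuple[float, float]], h: float,
                    min_div: int = 1) -> np.ndarray:
    """Concatenate per-segment linspaces so segment ends are exact nodes."""
    xs = [segments[0][0]]
    for a, b in segments:
        n = max(min_div, int(round((b - a) / h)))
        xs.extend(np.linspace(a, b, n + 1)[1:])
    return np.asarray(xs)


def _box_tets(xs: np.ndarray, ys: np.ndarray, zs: np.ndarray):
    """Structured box: nodes and Kuhn 6-tet subdivision of each hex cell."""
    nx, ny, nz = len(xs), len(ys), len(zs)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    points = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    def nid(i, j, k):
        return (i * ny + j) * nz + k

    i, j, k = np.meshgrid(
        np.arange(nx - 1), np.arange(ny - 1), np.arange(nz - 1), indexing="ij"
    )
    i, j, k = i.ravel(), j.ravel(), k.ravel()
    corner = np.stack([i, j, k], axis=1)  # (ncell, 3)
    tets = []
    steps = np.eye(3, dtype=int)
    for path in _KUHN_PATHS:
        v0 = corner
        v1 = v0 + steps[path[0]]
        v2 = v1 + steps[path[1]]
        v3 = v2 + steps[path[2]]
        tets.append(
            np.stack(
                [nid(*v0.T), nid(*v1.T), nid(*v2.T), nid(*v3.T)], axis=1
            )
        )
    tets = np.vstack(tets)
    return points, _fix_orientation(points, tets)


def _fix_orientation(points: np.ndarray, tets: np.ndarray) -> np.ndarray:
    p = points[tets]
    v = np.einsum(
        "ij,ij->i",
        np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]),
        p[:, 3] - p[:, 0],
    )
    flip = v < 0
    tets = tets.copy()
    tets[flip, 2], tets[flip, 3] = tets[flip, 3], tets[flip, 2].copy()
    return tets


def _compact_nodes(points: np.ndarray, tets: np.ndarray):
    """Drop nodes not referenced by any element; renumber tets."""
    used = np.unique(tets)
    remap = np.full(len(points), -1, dtype=int)
    remap[used] = np.arange(len(used))
    return points[used], remap[tets], remap


def _boundary_facets(tets: np.ndarray) -> np.ndarray:
    faces = np.vstack(
        [tets[:, idx] for idx in ((0, 1, 2), (0, 1, 3), (0, 2, 3), (1, 2, 3))]
    )
    faces_sorted = np.sort(faces, axis=1)
    uniq, counts = np.unique(faces_sorted, axis=0, return_counts=True)
    return uniq[counts == 1]


def _tag_plate_contacts(points, bfacets, gap_m, cw_m, ch_m, yc, zc):
    """Tag facets on x=0 (anode) / x=gap (cathode) within the contact window."""
    tags = np.full(len(bfacets), INSULATED, dtype=int)
    fp = points[bfacets]
    tol = 1e-12
    for xplane, tag in ((0.0, ANODE), (gap_m, CATHODE)):
        on_plane = np.all(np.abs(fp[:, :, 0] - xplane) < tol, axis=1)
        in_y = np.all(np.abs(fp[:, :, 1] - yc) <= cw_m / 2 + tol, axis=1)
        in_z = np.all(np.abs(fp[:, :, 2] - zc) <= ch_m / 2 + tol, axis=1)
        tags[on_plane & in_y & in_z] = tag
    return tags


# ---------------------------------------------------------------------------
# plate (optionally layered) block
# ---------------------------------------------------------------------------

def build_plate_model(cfg: GeometryConfig) -> Mesh:
    """Rectangular block with plate contacts on the faces x = 0 and x = d."""
    if cfg.case != "plate_single":
        raise GeometryError(f"build_plate_model requires case='plate_single', got {cfg.case!r}")
    d, w, hgt, h = cfg.gap_mm, cfg.width_mm, cfg.height_mm, cfg.resolution_mm
    cw = cfg.contact_width_mm if cfg.contact_width_mm is not None else w
    ch = cfg.contact_height_mm if cfg.contact_height_mm is not None else hgt
    if cw > w + 1e-12 or ch > hgt + 1e-12:
        raise GeometryError(
            f"contact window {cw}x{ch} mm exceeds face {w}x{hgt} mm"
        )
    if cfg.layers is not None:
        names = [n for n, _ in cfg.layers]
        th = [t for _, t in cfg.layers]
        if abs(sum(th) - d) > 1e-9:
            raise GeometryError(
                f"layer thicknesses sum to {sum(th)} mm, gap is {d} mm"
            )
        bounds = np.concatenate([[0.0], np.cumsum(th)])
        segs = list(zip(bounds[:-1], bounds[1:]))
    else:
        names = [cfg.tissue]
        segs = [(0.0, d)]
    xs = _segmented_axis(segs, h)
    # contact window must land on grid lines so tagged area is exact
    ys = _contact_axis(w, cw, h)
    zs = _contact_axis(hgt, ch, h)
    points, tets = _box_tets(xs * MM, ys * MM, zs * MM)

    cent = points[tets].mean(axis=1)
    region_names = list(dict.fromkeys(names))
    region_ids = np.zeros(len(tets), dtype=int)
    for (a, b), nm in zip(segs, names):
        mask = (cent[:, 0] >= a * MM) & (cent[:, 0] <= b * MM + 1e-15)
        region_ids[mask] = region_names.index(nm)

    bfacets = _boundary_facets(tets)
    tags = _tag_plate_contacts(
        points, bfacets, d * MM, cw * MM, ch * MM,
        yc=float(ys.mean() * MM), zc=float(zs.mean() * MM),
    )
    mesh = Mesh(points, tets, region_ids, region_names, bfacets, tags)
    mesh.validate()
    return mesh


def _contact_axis(total, contact, h):
    """Axis through [0, total] with nodes at the contact-window edges."""
    lo, hi = (total - contact) / 2.0, (total + contact) / 2.0
    segs = []
    if lo > 1e-12:
        segs.append((0.0, lo))
    segs.append((lo, hi))
    if hi < total - 1e-12:
        segs.append((hi, total))
    return _segmented_axis(segs, h)


# ---------------------------------------------------------------------------
# needle block
# ---------------------------------------------------------------------------

def _dompierre_split(prisms: np.ndarray) -> np.ndarray:
    """Split prisms (bottom v0 v1 v2, top v3 v4 v5) into 3 tets each,
    choosing quad diagonals from global node order so shared faces conform."""
    rotations = np.array(
        [
            (0, 1, 2, 3, 4, 5),
            (1, 2, 0, 4, 5, 3),
            (2, 0, 1, 5, 3, 4),
            (3, 5, 4, 0, 2, 1),
            (4, 3, 5, 1, 0, 2),
            (5, 4, 3, 2, 1, 0),
        ]
    )
    out = np.empty((len(prisms), 3, 4), dtype=prisms.dtype)
    for n, pr in enumerate(prisms):
        rot = rotations[int(np.argmin(pr))]
        w = pr[rot]
        if min(w[1], w[5]) < min(w[2], w[4]):
            t = ((w[0], w[1], w[2], w[5]), (w[0], w[1], w[5], w[4]),
                 (w[0], w[4], w[5], w[3]))
        else:
            t = ((w[0], w[1], w[2], w[4]), (w[0], w[4], w[2], w[5]),
                 (w[0], w[4], w[5], w[3]))
        out[n] = t
    return out.reshape(-1, 4)


def _needle_cross_section(cfg: GeometryConfig):
    """2D point set and triangulation of the block cross-section with the two
    needle circles; nodes are placed exactly on the circles."""
    w, dep, h = cfg.width_mm, cfg.depth_mm, cfg.resolution_mm
    r = cfg.needle_diameter_mm / 2.0
    s = cfg.needle_spacing_mm
    if s <= cfg.needle_diameter_mm:
        raise GeometryError("needle spacing must exceed needle diameter")
    centers = np.array([[-s / 2.0, 0.0], [s / 2.0, 0.0]])
    if np.any(np.abs(centers[:, 0]) + r >= w / 2.0) or r >= dep / 2.0:
        raise GeometryError("needles fall outside the tissue block")

    nx = max(2, int(round(w / h))) + 1
    ny = max(2, int(round(dep / h))) + 1
    gx, gy = np.meshgrid(
        np.linspace(-w / 2, w / 2, nx), np.linspace(-dep / 2, dep / 2, ny),
        indexing="ij",
    )
    grid = np.column_stack([gx.ravel(), gy.ravel()])
    hx = w / (nx - 1)
    keep = np.ones(len(grid), dtype=bool)
    for c in centers:
        keep &= np.linalg.norm(grid - c, axis=1) > r + 0.45 * hx
    pts = [grid[keep]]
    ring_nodes: List[np.ndarray] = []
    n_theta = max(16, int(np.ceil(2 * np.pi * r / min(h, r))))
    for c in centers:
        th = 2 * np.pi * np.arange(n_theta) / n_theta
        ring = c + r * np.column_stack([np.cos(th), np.sin(th)])
        start = sum(len(p) for p in pts)
        pts.append(ring)
        ring_nodes.append(np.arange(start, start + n_theta))
        pts.append(c[None, :])  # circle centre, fills the bore below the tip
    pts2d = np.vstack(pts)
    tri = Delaunay(pts2d)
    tris = tri.simplices.copy()
    # consistent CCW orientation
    p = pts2d[tris]
    area2 = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    flip = area2 < 0
    tris[flip, 1], tris[flip, 2] = tris[flip, 2], tris[flip, 1].copy()
    cent = pts2d[tris].mean(axis=1)
    hole_id = np.zeros(len(tris), dtype=int)
    for idx, c in enumerate(centers):
        hole_id[np.linalg.norm(cent - c, axis=1) < r - 1e-9] = idx + 1
    return pts2d, tris, hole_id, ring_nodes, centers, r


def build_needle_model(cfg: GeometryConfig) -> Mesh:
    """Tissue block with two parallel needle-track bores from the top face.

    The bore lateral walls (over the insertion depth) are the electrode
    contacts; the flat tip disc and all outer faces are insulated.
    """
    if cfg.case != "needle_single":
        raise GeometryError(f"build_needle_model requires case='needle_single', got {cfg.case!r}")
    if cfg.insertion_depth_mm >= cfg.height_mm:
        raise GeometryError("insertion depth must be smaller than block height")
    pts2d, tris, hole_id, ring_nodes, centers, r = _needle_cross_section(cfg)
    H, depth, h = cfg.height_mm, cfg.insertion_depth_mm, cfg.resolution_mm
    z_tip = H - depth
    zs = _segmented_axis([(0.0, z_tip), (z_tip, H)], h)
    n2d, nz = len(pts2d), len(zs)
    points = np.empty((n2d * nz, 3))
    for k, z in enumerate(zs):
        points[k * n2d:(k + 1) * n2d, :2] = pts2d
        points[k * n2d:(k + 1) * n2d, 2] = z
    points *= MM

    prisms = []
    for k in range(nz - 1):
        zmid = 0.5 * (zs[k] + zs[k + 1])
        active = tris if zmid < z_tip else tris[hole_id == 0]
        lo = active + k * n2d
        hi = active + (k + 1) * n2d
        prisms.append(np.hstack([lo, hi]))
    prisms = np.vstack(prisms)
    tets = _fix_orientation(points, _dompierre_split(prisms))
    # bore interiors above the tip reference no elements; drop those nodes
    points, tets, remap = _compact_nodes(points, tets)

    region_ids = np.zeros(len(tets), dtype=int)
    bfacets = _boundary_facets(tets)
    tags = np.full(len(bfacets), INSULATED, dtype=int)
    for which, (nodes2d, tag) in enumerate(
        zip(ring_nodes, (ANODE, CATHODE))
    ):
        ring_all = remap[
            (nodes2d[None, :] + n2d * np.arange(nz)[:, None]).ravel()
        ]
        ring_all = ring_all[ring_all >= 0]
        on_ring = np.isin(bfacets, ring_all).all(axis=1)
        deep = np.all(points[bfacets][:, :, 2] >= z_tip * MM - 1e-12, axis=1)
        # exclude degenerate horizontal facets (all three nodes at one z)
        zf = points[bfacets][:, :, 2]
        lateral = (zf.max(axis=1) - zf.min(axis=1)) > 1e-12
        tags[on_ring & deep & lateral] = tag
    mesh = Mesh(points, tets, region_ids, [cfg.tissue], bfacets, tags)
    mesh.validate()
    return mesh


# ---------------------------------------------------------------------------
# composite subcutaneous tumor
# ---------------------------------------------------------------------------

TUMOR_REGIONS = ("stratum_corneum_epidermis", "dermis_fat", "tumor", "muscle")


def _tet_vols(points, tets):
    p = points[tets]
    return np.einsum(
        "ij,ij->i",
        np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]),
        p[:, 3] - p[:, 0],
    ) / 6.0


def _snap_to_sphere(points, tets, center, radius, band,
                    min_vol_ratio: float = 0.2, max_rounds: int = 20):
    """Project nodes within ``band`` of the sphere onto it; revert any snap
    that shrinks an incident element below ``min_vol_ratio`` of its original
    volume (prevents slivers and inversions)."""
    orig = points
    vol0 = np.abs(_tet_vols(orig, tets))
    rel = orig - center
    rho = np.linalg.norm(rel, axis=1)
    snap = (np.abs(rho - radius) < band) & (rho > 1e-12)
    new = orig.copy()
    new[snap] = center + rel[snap] * (radius / rho[snap])[:, None]
    snapped = snap.copy()
    for _ in range(max_rounds):
        bad = np.abs(_tet_vols(new, tets)) < min_vol_ratio * vol0
        bad |= _tet_vols(new, tets) * np.sign(_tet_vols(orig, tets)) <= 0
        if not np.any(bad):
            break
        revert_nodes = np.unique(tets[bad])
        revert = np.zeros(len(points), dtype=bool)
        revert[revert_nodes] = True
        revert &= snapped
        if not np.any(revert):
            break
        new[revert] = orig[revert]
        snapped[revert] = False
    return new


def build_tumor_model(cfg: GeometryConfig, registry=None) -> Mesh:
    """Skin-fold subcutaneous-tumor model between plates d apart.

    The fold of tissue pinched between the plates is skinned on its two
    lateral faces (x = 0, x = d, where the electrodes make contact) and
    across its top: stratum corneum + epidermis outermost, the subcutis
    (dermis + fat) filling the fold interior.  The tumor sphere grows in
    the subcutis, its top ``tumor_depth_mm`` below the skin; a muscle slab
    of thickness ``muscle_base_mm`` forms the base of the fold (muscle
    fibers along x, the inter-electrode axis).  Region labels are assigned
    per element from the element centroid after the mesh has been made to
    conform to the tumor surface.  If ``registry`` is given, all four
    region labels must resolve in it.
    """
    if cfg.case != "tumor_composite":
        raise GeometryError(f"build_tumor_model requires case='tumor_composite', got {cfg.case!r}")
    d, dep, hgt = cfg.gap_mm, cfg.depth_mm, cfg.height_mm
    t_se, t_df, h = cfg.layer_se_mm, cfg.layer_df_mm, cfg.resolution_mm
    t_mus = cfg.muscle_base_mm
    r_t = cfg.tumor_diameter_mm / 2.0
    skin = t_se + t_df
    if 2 * skin >= d or skin + t_mus >= hgt:
        raise GeometryError("skin layers / muscle base thicker than the fold")
    cx, cy = d / 2.0, 0.0
    cz = hgt - skin - cfg.tumor_depth_mm - r_t
    if (r_t >= d / 2.0 - skin) or (r_t >= dep / 2.0) or (cz - r_t <= 0.0):
        raise GeometryError("tumor intersects a layer or the domain boundary")

    cw = cfg.contact_width_mm if cfg.contact_width_mm is not None else dep
    ch = cfg.contact_height_mm if cfg.contact_height_mm is not None else hgt
    if cw > dep + 1e-12 or ch > hgt + 1e-12:
        raise GeometryError("electrode contact window exceeds the fold face")

    segs = [
        (0.0, t_se), (t_se, skin), (skin, d - skin),
        (d - skin, d - t_se), (d - t_se, d),
    ]
    xs = _segmented_axis(segs, h)
    ys = _segmented_axis(_split_segments([-dep / 2, -cw / 2, cw / 2, dep / 2]), h)
    # contact window sits at the top of the fold (the plates pinch the
    # protruding part); its lower edge must land on a grid line
    z_breaks = sorted({0.0, t_mus, hgt - skin, hgt - t_se, hgt, hgt - ch})
    zs = _segmented_axis(_split_segments(z_breaks), h)
    points, tets = _box_tets(xs * MM, ys * MM, zs * MM)

    # make the mesh conform to the tumor surface: project nodes that lie
    # close to the sphere radially onto it, so no element straddles the
    # tissue interface (straddling elements average the field jump and
    # corrupt coverage statistics at the poles); snaps that flatten an
    # element are reverted
    center = np.array([cx, cy, cz]) * MM
    points = _snap_to_sphere(points, tets, center, r_t * MM, 0.45 * h * MM)

    cent = points[tets].mean(axis=1) / MM  # mm
    region_names = list(TUMOR_REGIONS)
    region_ids = np.full(len(tets), region_names.index("dermis_fat"), dtype=int)
    x, z = cent[:, 0], cent[:, 2]
    se = (x < t_se) | (x > d - t_se) | (z > hgt - t_se)
    mus = ~se & (z < t_mus)
    rr = np.linalg.norm(cent - [cx, cy, cz], axis=1)
    tum = rr < r_t
    if cfg.tumor_shape == "hemisphere":
        tum &= cent[:, 2] <= cz
    elif cfg.tumor_shape != "sphere":
        raise GeometryError(f"unknown tumor shape {cfg.tumor_shape!r}")
    # priority: skin > tumor > muscle > subcutis
    region_ids[mus] = region_names.index("muscle")
    region_ids[tum] = region_names.index("tumor")
    region_ids[se] = region_names.index("stratum_corneum_epidermis")

    if registry is not None:
        for nm in region_names:
            registry[nm]  # KeyError with a clear message if missing

    bfacets = _boundary_facets(tets)
    tags = _tag_plate_contacts(
        points, bfacets, d * MM, cw * MM, ch * MM,
        yc=0.0, zc=(hgt - ch / 2.0) * MM,
    )
    mesh = Mesh(points, tets, region_ids, region_names, bfacets, tags)
    mesh.validate()
    return mesh


def build_mesh(cfg: GeometryConfig, registry=None) -> Mesh:
    """Dispatch on ``cfg.case``."""
    if cfg.case == "plate_single":
        return build_plate_model(cfg)
    if cfg.case == "needle_single":
        return build_needle_model(cfg)
    if cfg.case == "tumor_composite":
        return build_tumor_model(cfg, registry)
    raise GeometryError(f"unknown geometry case {cfg.case!r}")


# ---------------------------------------------------------------------------
# mesh-convergence protocol
# ---------------------------------------------------------------------------

@dataclass
class ConvergenceReport:
    """Refinement sequence for a scalar model output.

    ``levels`` holds (element count, output value, relative change from the
    previous level); ``converged_level`` is the first level whose output
    differs from its predecessor by less than ``rtol`` (None if never)."""

    levels: List[Tuple[int, float, float]]
    converged_level: Optional[int]
    rtol: float

    @property
    def converged(self) -> bool:
        return self.converged_level is not None


def mesh_convergence_study(
    builder: Callable[[GeometryConfig], Mesh],
    cfg: GeometryConfig,
    output_fn: Callable[[Mesh], float],
    max_levels: int = 4,
    rtol: float = 0.005,
    refine: float = 2.0,
) -> ConvergenceReport:
    """Refine the mesh until ``output_fn`` changes by less than ``rtol``.

    Level L uses resolution ``cfg.resolution_mm / refine**L``.  Outputs are
    recorded at every level; non-convergence within ``max_levels`` is
    reported, not raised.
    """
    levels = []
    prev = None
    converged_level = None
    for lv in range(max_levels):
        c = replace(cfg, resolution_mm=cfg.resolution_mm / refine ** lv)
        mesh = builder(c)
        val = float(output_fn(mesh))
        rel = np.nan if prev is None else abs(val - prev) / max(abs(prev), 1e-300)
        levels.append((mesh.n_elements, val, float(rel)))
        if prev is not None and rel < rtol and converged_level is None:
            converged_level = lv
            break
        prev = val
    return ConvergenceReport(levels=levels, converged_level=converged_level, rtol=rtol)
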