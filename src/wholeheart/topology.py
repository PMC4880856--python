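"""Formal tissue-volume topology: patches, shells and hulls over a labeled mesh.

A cardiac (or thoracic) segmentation is described by a hierarchy of
topological elements:

* a **patch** is a set of facets forming an elementary surface part
  (e.g. the outer surface of the left atrium), linked to the segmentation
  by a unique integer color index;
* a **shell** is a set of patches forming a closed, orientable surface;
* a **hull** is a three-dimensional piece of tissue with uniform electrical
  properties, bounded by one outer shell and optionally by inner shells
  (holes — e.g. the heart wall as a closed volume with four cavities).

:func:`compile_topology` validates the whole hierarchy (closure, consistent
winding, nesting) and extracts per-hull boundary facet lists used by the
conduction and forward-modeling stages.  Point-in-volume queries use the
generalized winding number; boundary points within a small geometric
tolerance of a facet are classified as inside every hull whose boundary
they touch, so that mesh nodes lying exactly on an interface belong to the
tissues on both sides (the conduction pathway between tissues).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .errors import ConfigurationError, TopologyError

__all__ = [
    "TissueProperties",
    "TISSUE_PRESETS",
    "SurfaceMesh",
    "Patch",
    "Shell",
    "Hull",
    "TopologyDescription",
    "ValidationReport",
    "CompiledShell",
    "CompiledTopology",
    "validate_shell_closure",
    "compile_topology",
    "point_in_hull",
    "points_in_shell",
    "winding_number",
    "solid_angles",
    "shell_signed_volume",
    "point_triangle_distance",
]

#: Relative geometric tolerance: points within ``EPS_GEO_REL`` times the
#: bounding-box diagonal of a facet are treated as lying on that facet.
EPS_GEO_REL = 1e-9


# ---------------------------------------------------------------------------
# Tissue properties
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TissueProperties:
    """Uniform electrical properties of one tissue hull.

    Parameters
    ----------
    label:
        Tissue name (``"myocardium"``, ``"scar"``, ...).
    speed:
        Conduction velocity in mm/ms (numerically equal to m/s).
        ``speed == 0`` identifies non-conducting tissue.
    conductivity:
        Electrical conductivity in S/m, used by the volume-conductor model.
    """

    label: str
    speed: float
    conductivity: float

    def __post_init__(self):
        if self.speed < 0:
            raise ConfigurationError(f"tissue {self.label!r}: speed must be >= 0")
        if self.conductivity < 0:
            raise ConfigurationError(
                f"tissue {self.label!r}: conductivity must be >= 0"
            )

    @property
    def conducting(self) -> bool:
        return self.speed > 0


#: Literature-based presets.  Speeds in mm/ms, conductivities in S/m.
TISSUE_PRESETS: Dict[str, TissueProperties] = {
    "myocardium": TissueProperties("myocardium", speed=0.6, conductivity=0.2),
    "bundle_branch": TissueProperties("bundle_branch", speed=2.0, conductivity=0.2),
    "edema": TissueProperties("edema", speed=0.2, conductivity=0.0325),
    "scar": TissueProperties("scar", speed=0.0, conductivity=0.0),
    "lung": TissueProperties("lung", speed=0.0, conductivity=0.04),
    "thorax": TissueProperties("thorax", speed=0.0, conductivity=0.2),
    "valve_plane": TissueProperties("valve_plane", speed=0.0, conductivity=0.2),
}


# ---------------------------------------------------------------------------
# Surface mesh container
# ---------------------------------------------------------------------------

@dataclass
class SurfaceMesh:
    """Triangulated surface: vertices in mm, triangles as vertex index triples.

    ``labels`` holds the per-triangle patch color index (-1 = unlabeled).
    """

    vertices: np.ndarray
    triangles: np.ndarray
    labels: Optional[np.ndarray] = None

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.triangles = np.asarray(self.triangles, dtype=np.int64).reshape(-1, 3)
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int64).ravel()
            if self.labels.shape[0] != self.triangles.shape[0]:
                raise ConfigurationError("labels length != triangle count")
        if self.triangles.size and (
            self.triangles.min() < 0 or self.triangles.max() >= len(self.vertices)
        ):
            raise ConfigurationError("triangle indices out of range")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    def triangle_areas(self) -> np.ndarray:
        v = self.vertices
        t = self.triangles
        c = np.cross(v[t[:, 1]] - v[t[:, 0]], v[t[:, 2]] - v[t[:, 0]])
        return 0.5 * np.linalg.norm(c, axis=1)

    def bbox_diagonal(self) -> float:
        if not len(self.vertices):
            return 0.0
        return float(
            np.linalg.norm(self.vertices.max(axis=0) - self.vertices.min(axis=0))
        )


# ---------------------------------------------------------------------------
# Topological elements
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Patch:
    """Elementary surface part: a set of facet indices into the surface mesh."""

    id: str
    color_index: int
    facets: Tuple[int, ...]

    def __post_init__(self):
        object.__setattr__(self, "facets", tuple(sorted(set(int(f) for f in self.facets))))


@dataclass(frozen=True)
class Shell:
    """Closed surface assembled from patches.

    ``orientation`` records the outward-normal convention of the file the
    shell came from; compilation normalizes every shell to outward normals
    regardless of this flag.
    """

    id: str
    patches: Tuple[str, ...]
    orientation: str = "outward"

    def __post_init__(self):
        object.__setattr__(self, "patches", tuple(self.patches))


@dataclass(frozen=True)
class Hull:
    """Three-dimensional tissue volume with uniform properties.

    Bounded by ``outer`` (its outer shell) and by ``inner`` shells, the
    surfaces of holes in the volume.
    """

    id: str
    outer: str
    inner: Tuple[str, ...]
    tissue: TissueProperties

    def __post_init__(self):
        object.__setattr__(self, "inner", tuple(self.inner))


@dataclass
class TopologyDescription:
    """Complete formal description: mesh + patches + shells + hulls."""

    mesh: Optional[SurfaceMesh]
    patches: Dict[str, Patch] = field(default_factory=dict)
    shells: Dict[str, Shell] = field(default_factory=dict)
    hulls: Dict[str, Hull] = field(default_factory=dict)


@dataclass
class ValidationReport:
    """Outcome of a shell-closure check."""

    shell_id: str
    non_manifold_edges: List[Tuple[int, int]] = field(default_factory=list)
    orientation_conflicts: List[Tuple[int, int]] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.non_manifold_edges and not self.orientation_conflicts


# ---------------------------------------------------------------------------
# Low-level geometry
# ---------------------------------------------------------------------------

def solid_angles(points: np.ndarray, vertices: np.ndarray,
                 triangles: np.ndarray) -> np.ndarray:
    """Signed solid angles (sr) subtended by each triangle at each point.

    Uses the van Oosterom–Strackee formula.  Positive when the triangle's
    right-hand-winding normal faces away from the point, so that summing
    over a closed outward-oriented surface yields 4*pi for interior points
    and 0 for exterior points.

    Returns an array of shape ``(len(points), len(triangles))``.
    """
    p = np.asarray(points, dtype=float).reshape(-1, 3)
    r1 = vertices[triangles[:, 0]][None, :, :] - p[:, None, :]
    r2 = vertices[triangles[:, 1]][None, :, :] - p[:, None, :]
    r3 = vertices[triangles[:, 2]][None, :, :] - p[:, None, :]
    l1 = np.linalg.norm(r1, axis=2)
    l2 = np.linalg.norm(r2, axis=2)
    l3 = np.linalg.norm(r3, axis=2)
    triple = np.einsum("pti,pti->pt", r1, np.cross(r2, r3))
    denom = (
        l1 * l2 * l3
        + np.einsum("pti,pti->pt", r1, r2) * l3
        + np.einsum("pti,pti->pt", r1, r3) * l2
        + np.einsum("pti,pti->pt", r2, r3) * l1
    )
    out = 2.0 * np.arctan2(triple, denom)
    # a triangle coplanar with the point subtends exactly zero solid angle;
    # atan2(+-0, denom<0) would otherwise jitter between +-2 pi
    out[np.abs(triple) <= 1e-12 * l1 * l2 * l3] = 0.0
    return out


def winding_number(points: np.ndarray, vertices: np.ndarray,
                   triangles: np.ndarray, chunk: int = 4_000_000) -> np.ndarray:
    """Generalized winding number of each point w.r.t. an oriented surface.

    ~1 for points inside a closed outward-oriented surface, ~0 outside.
    """
    p = np.asarray(points, dtype=float).reshape(-1, 3)
    if not len(triangles):
        return np.zeros(len(p))
    out = np.empty(len(p))
    rows = max(1, chunk // max(1, len(triangles)))
    for s in range(0, len(p), rows):
        out[s:s + rows] = solid_angles(p[s:s + rows], vertices, triangles).sum(axis=1)
    return out / (4.0 * np.pi)


def shell_signed_volume(vertices: np.ndarray, triangles: np.ndarray) -> float:
    """Signed enclosed volume of an oriented closed triangulated surface.

    Positive for outward-facing normals (right-hand winding).
    """
    v0 = vertices[triangles[:, 0]]
    v1 = vertices[triangles[:, 1]]
    v2 = vertices[triangles[:, 2]]
    return float(np.einsum("ij,ij->i", v0, np.cross(v1, v2)).sum() / 6.0)


def point_triangle_distance(points: np.ndarray, v0: np.ndarray, v1: np.ndarray,
                            v2: np.ndarray) -> np.ndarray:
    """Min distance from each point to each triangle (broadcast P x T).

    The minimum over the three clamped edge-segment distances and, where the
    plane projection falls inside the triangle, the plane distance.
    ``points``: (P, 3); ``v0, v1, v2``: (T, 3).  Returns (P, T).
    """
    p = np.asarray(points, dtype=float).reshape(-1, 3)[:, None, :]

    def seg_dist(a, b):
        ab = b - a
        ab2 = np.einsum("ti,ti->t", ab, ab)[None, :]
        t = np.einsum("pti,ti->pt", p - a[None], ab) / np.where(ab2 == 0, 1.0, ab2)
        t = np.clip(t, 0.0, 1.0)
        cp = a[None] + t[..., None] * ab[None]
        return np.linalg.norm(p - cp, axis=2)

    d = np.minimum(seg_dist(v0, v1), np.minimum(seg_dist(v1, v2), seg_dist(v2, v0)))

    n = np.cross(v1 - v0, v2 - v0)
    n2 = np.einsum("ti,ti->t", n, n)
    ok = n2 > 0
    nhat = np.where(ok[:, None], n / np.sqrt(np.where(n2 == 0, 1.0, n2))[:, None], 0.0)
    h = np.einsum("pti,ti->pt", p - v0[None], nhat)
    proj = p - h[..., None] * nhat[None]
    # barycentric test of the projection
    e0 = v1 - v0
    e1 = v2 - v0
    w = proj - v0[None]
    d00 = np.einsum("ti,ti->t", e0, e0)[None]
    d01 = np.einsum("ti,ti->t", e0, e1)[None]
    d11 = np.einsum("ti,ti->t", e1, e1)[None]
    d20 = np.einsum("pti,ti->pt", w, e0)
    d21 = np.einsum("pti,ti->pt", w, e1)
    denom = d00 * d11 - d01 * d01
    denom = np.where(denom == 0, 1.0, denom)
    bv = (d11 * d20 - d01 * d21) / denom
    bw = (d00 * d21 - d01 * d20) / denom
    inside = ok[None] & (bv >= 0) & (bw >= 0) & (bv + bw <= 1)
    return np.where(inside, np.minimum(d, np.abs(h)), d)


# ---------------------------------------------------------------------------
# Shell validation
# ---------------------------------------------------------------------------

def _shell_facets(shell: Shell, patches: Mapping[str, Patch]) -> np.ndarray:
    facets: List[int] = []
    for pid in shell.patches:
        if pid not in patches:
            raise ConfigurationError(
                f"shell {shell.id!r} references unknown patch {pid!r}"
            )
        facets.extend(patches[pid].facets)
    return np.asarray(sorted(set(facets)), dtype=np.int64)


def validate_shell_closure(shell: Shell, mesh: SurfaceMesh,
                           patches: Mapping[str, Patch]) -> ValidationReport:
    """Check that a shell's facets form a closed, consistently wound surface.

    Every edge must be shared by exactly two facets (else it is reported as
    non-manifold — a single-facet edge is an open boundary) and the two
    facets must traverse it in opposite directions (else an orientation
    conflict is reported).
    """
    facets = _shell_facets(shell, patches)
    report = ValidationReport(shell_id=shell.id)
    if not len(facets):
        return report
    tris = mesh.triangles[facets]
    # directed edges of every triangle
    e = np.concatenate([tris[:, [0, 1]], tris[:, [1, 2]], tris[:, [2, 0]]])
    lo = np.minimum(e[:, 0], e[:, 1])
    hi = np.maximum(e[:, 0], e[:, 1])
    forward = (e[:, 0] < e[:, 1]).astype(np.int64)  # 1 if directed lo->hi
    key = lo * (mesh.n_vertices + 1) + hi
    order = np.argsort(key, kind="stable")
    key_s = key[order]
    uniq, start, count = np.unique(key_s, return_index=True, return_counts=True)
    fwd_sum = np.add.reduceat(forward[order], start)
    bad_count = count != 2
    # count==2 but both traversals in the same direction -> winding conflict
    bad_orient = (count == 2) & (fwd_sum != 1)
    for k in uniq[bad_count]:
        report.non_manifold_edges.append((int(k // (mesh.n_vertices + 1)),
                                          int(k % (mesh.n_vertices + 1))))
    for k in uniq[bad_orient]:
        report.orientation_conflicts.append((int(k // (mesh.n_vertices + 1)),
                                             int(k % (mesh.n_vertices + 1))))
    return report


# ---------------------------------------------------------------------------
# Compilation
# ---------------------------------------------------------------------------

@dataclass
class CompiledShell:
    """A validated shell with outward-normalized triangles."""

    id: str
    facets: np.ndarray          # facet indices into the surface mesh
    triangles: np.ndarray       # (m, 3) vertex indices, outward winding
    volume: float               # enclosed volume, positive
    flipped: bool               # True if the stored winding was inverted


@dataclass
class CompiledTopology:
    """Validated topology with per-hull boundary facet lists."""

    mesh: Optional[SurfaceMesh]
    description: TopologyDescription
    shells: Dict[str, CompiledShell]
    hull_boundary_facets: Dict[str, np.ndarray]
    hull_node_ids: Dict[str, np.ndarray]

    @property
    def hulls(self) -> Dict[str, Hull]:
        return self.description.hulls

    def hull_volume(self, hull_id: str) -> float:
        h = self.description.hulls[hull_id]
        v = self.shells[h.outer].volume
        for sid in h.inner:
            v -= self.shells[sid].volume
        return v

    def hull_boundary_triangles(self, hull_id: str) -> np.ndarray:
        """Outward-wound boundary triangles of a hull (outer + inner shells)."""
        h = self.description.hulls[hull_id]
        parts = [self.shells[h.outer].triangles]
        parts += [self.shells[sid].triangles for sid in h.inner]
        return np.concatenate(parts) if parts else np.empty((0, 3), np.int64)


def _interior_probe(comp_shell: CompiledShell, mesh: SurfaceMesh) -> np.ndarray:
    """A point strictly inside a closed shell (ray-midpoint construction)."""
    tris = comp_shell.triangles
    v = mesh.vertices
    centroid = v[np.unique(tris)].mean(axis=0)
    w = winding_number(centroid[None, :], v, tris)[0]
    if w > 0.5:
        return centroid
    # centroid outside (non-convex shell): shoot a ray from the first facet
    # centroid along the inward normal and bisect
    c0 = v[tris[0]].mean(axis=0)
    n = np.cross(v[tris[0, 1]] - v[tris[0, 0]], v[tris[0, 2]] - v[tris[0, 0]])
    n = n / np.linalg.norm(n)
    diag = mesh.bbox_diagonal() or 1.0
    for scale in (1e-3, 1e-2, 1e-1):
        p = c0 - n * scale * diag
        if winding_number(p[None, :], v, tris)[0] > 0.5:
            return p
    return centroid


def compile_topology(desc: TopologyDescription) -> CompiledTopology:
    """Validate a topology description and extract per-hull boundary data.

    Raises :class:`TopologyError` carrying the full violation list when any
    invariant fails: shell not closed or inconsistently wound, inner shell
    not strictly inside its outer shell, inner shells intersecting, facets
    missing from every patch, non-positive hull volume.
    """
    violations: List[str] = []
    mesh = desc.mesh
    if mesh is None or not desc.hulls:
        if desc.shells and mesh is None:
            raise TopologyError("shells declared without a mesh",
                                ["shells declared without a mesh"])
        return CompiledTopology(mesh, desc, {}, {}, {})

    # patch invariants
    seen_facets: Dict[int, str] = {}
    seen_colors: Dict[int, str] = {}
    for pid, patch in desc.patches.items():
        if patch.color_index in seen_colors:
            violations.append(
                f"patch {pid!r}: color index {patch.color_index} already used "
                f"by {seen_colors[patch.color_index]!r}")
        else:
            seen_colors[patch.color_index] = pid
        for f in patch.facets:
            if f < 0 or f >= mesh.n_triangles:
                violations.append(f"patch {pid!r}: facet {f} out of range")
            elif f in seen_facets:
                violations.append(
                    f"patch {pid!r}: facet {f} already in patch {seen_facets[f]!r}")
            else:
                seen_facets[f] = pid
    if len(seen_facets) < mesh.n_triangles:
        missing = mesh.n_triangles - len(seen_facets)
        violations.append(f"{missing} mesh facets belong to no patch")

    # shell closure + outward normalization
    compiled_shells: Dict[str, CompiledShell] = {}
    for sid, shell in desc.shells.items():
        report = validate_shell_closure(shell, mesh, desc.patches)
        if not report.ok:
            violations.append(
                f"shell {sid!r}: {len(report.non_manifold_edges)} non-manifold "
                f"edges, {len(report.orientation_conflicts)} orientation conflicts")
            continue
        facets = _shell_facets(shell, desc.patches)
        tris = mesh.triangles[facets].copy()
        vol = shell_signed_volume(mesh.vertices, tris)
        flipped = vol < 0
        if flipped:
            tris = tris[:, ::-1]
            vol = -vol
        if vol <= 0:
            violations.append(f"shell {sid!r}: zero enclosed volume")
        compiled_shells[sid] = CompiledShell(sid, facets, tris, vol, flipped)

    # hull nesting
    hull_boundary: Dict[str, np.ndarray] = {}
    hull_nodes: Dict[str, np.ndarray] = {}
    for hid, hull in desc.hulls.items():
        missing = [s for s in (hull.outer, *hull.inner) if s not in desc.shells]
        if missing:
            violations.append(f"hull {hid!r}: unknown shells {missing}")
            continue
        if any(s not in compiled_shells for s in (hull.outer, *hull.inner)):
            continue  # shell-level violation already recorded
        outer = compiled_shells[hull.outer]
        vol = outer.volume
        for sid in hull.inner:
            inner = compiled_shells[sid]
            vol -= inner.volume
            # every inner-shell vertex strictly inside the outer shell
            verts = mesh.vertices[np.unique(inner.triangles)]
            w = winding_number(verts, mesh.vertices, outer.triangles)
            if np.any(w < 0.5):
                violations.append(
                    f"hull {hid!r}: inner shell {sid!r} not inside outer "
                    f"shell {hull.outer!r}")
        # inner shells pairwise disjoint (probe-point containment test)
        for i, sa in enumerate(hull.inner):
            for sb in hull.inner[i + 1:]:
                pa = _interior_probe(compiled_shells[sa], mesh)
                pb = _interior_probe(compiled_shells[sb], mesh)
                inside_ab = winding_number(
                    pa[None], mesh.vertices, compiled_shells[sb].triangles)[0] > 0.5
                inside_ba = winding_number(
                    pb[None], mesh.vertices, compiled_shells[sa].triangles)[0] > 0.5
                if inside_ab or inside_ba:
                    violations.append(
                        f"hull {hid!r}: inner shells {sa!r} and {sb!r} intersect")
        if vol <= 0:
            violations.append(f"hull {hid!r}: non-positive volume {vol:.3g}")
        facets = np.concatenate(
            [compiled_shells[hull.outer].facets]
            + [compiled_shells[s].facets for s in hull.inner])
        hull_boundary[hid] = np.sort(facets)
        hull_nodes[hid] = np.unique(mesh.triangles[hull_boundary[hid]])

    if violations:
        raise TopologyError(
            f"topology has {len(violations)} violation(s): " + "; ".join(violations),
            violations)
    return CompiledTopology(mesh, desc, compiled_shells, hull_boundary, hull_nodes)


# ---------------------------------------------------------------------------
# Point location
# ---------------------------------------------------------------------------

def points_in_shell(points: np.ndarray, comp_shell: CompiledShell,
                    mesh: SurfaceMesh) -> np.ndarray:
    """Boolean inside-test for each point against a compiled closed shell."""
    w = winding_number(points, mesh.vertices, comp_shell.triangles)
    return w > 0.5


def point_in_hull(point: np.ndarray, hull, topo: CompiledTopology,
                  eps: Optional[float] = None) -> bool:
    """True iff ``point`` lies inside the hull's outer shell and outside all
    of its inner shells.

    Points within ``eps`` (default ``EPS_GEO_REL`` x mesh bounding-box
    diagonal) of any boundary facet of the hull are classified as inside:
    mesh nodes lie exactly on facets and must belong to their hull(s).
    """
    if topo.mesh is None:
        raise ConfigurationError("topology has no mesh")
    hull_id = hull if isinstance(hull, str) else hull.id
    if hull_id not in topo.description.hulls:
        raise ConfigurationError(f"unknown hull {hull_id!r}")
    if hull_id not in topo.hull_boundary_facets:
        raise ConfigurationError(f"hull {hull_id!r} was not validated")
    h = topo.description.hulls[hull_id]
    mesh = topo.mesh
    p = np.asarray(point, dtype=float).reshape(3)
    if eps is None:
        eps = EPS_GEO_REL * (mesh.bbox_diagonal() or 1.0)

    tris = topo.hull_boundary_triangles(hull_id)
    d = point_triangle_distance(p[None], mesh.vertices[tris[:, 0]],
                                mesh.vertices[tris[:, 1]],
                                mesh.vertices[tris[:, 2]])
    if d.min() <= eps:
        return True
    if not points_in_shell(p[None], topo.shells[h.outer], mesh)[0]:
        return False
    for sid in h.inner:
        if points_in_shell(p[None], topo.shells[sid], mesh)[0]:
            return False
    return True
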