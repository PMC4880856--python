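"""Synthetic desk-scale phantom geometries and mesh I/O.

In the clinical workflow the computational mesh comes from a topologically
correct segmentation of cardiac MRI.  This module replaces that step with
programmatically generated phantoms:

* :func:`make_slab_phantom` — a rectangular myocardial slab on a regular
  tetrahedral lattice (analytic distances; the conduction test bench);
* :func:`make_concentric_sphere_phantom` — nested icosphere surfaces
  (epicardium / optional lungs / body surface) for the volume-conductor
  model, with electrode candidate sites on the outermost surface;
* :func:`make_two_chamber_heart_phantom` — a drastically simplified
  two-chamber heart (atrial wall, ventricular wall, muscular septum,
  insulating valve plane) with a sinus-node source and a fast bundle
  branch;
* :func:`insert_lesion` — virtual edema or scar regions realized by
  re-labeling tetrahedra (no re-meshing, so total volume is conserved
  exactly and generation is instant, at the cost of stair-cased lesion
  boundaries).

Units are mm and ms throughout; conduction speeds quoted in m/s are used
unchanged as mm/ms (numerically equal).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import trimesh
import yaml

from .errors import (ConfigurationError, FormatError, LesionError, SizeError,
                     TopologyError)
from .topology import (CompiledTopology, Hull, Patch, Shell, SurfaceMesh,
                       TISSUE_PRESETS, TissueProperties, TopologyDescription,
                       compile_topology)

__all__ = [
    "VolumeMesh",
    "Bundle",
    "ConductionSystem",
    "PhantomModel",
    "BoxRegion",
    "SphereRegion",
    "LesionSpec",
    "LESION_PRESETS",
    "make_slab_phantom",
    "make_concentric_sphere_phantom",
    "make_two_chamber_heart_phantom",
    "insert_lesion",
    "emit_geometry_script",
    "write_model",
    "read_model",
    "derive_topology",
]

TOOL_VERSION = "0.1.0"
DEFAULT_NODE_CAP = 2000

# face index patterns giving outward-wound faces of a positively oriented tet
_TET_FACES = np.array([[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]])


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class VolumeMesh:
    """Labeled tetrahedral mesh: vertices (mm), tets, per-tet hull label index."""

    vertices: np.ndarray                 # (n, 3) float
    tets: np.ndarray                     # (m, 4) int, positive orientation
    tet_labels: np.ndarray               # (m,) int index into hull_ids
    hull_ids: Tuple[str, ...]            # label index -> hull id

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.tets = np.asarray(self.tets, dtype=np.int64).reshape(-1, 4)
        self.tet_labels = np.asarray(self.tet_labels, dtype=np.int64).ravel()
        self.hull_ids = tuple(self.hull_ids)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def tet_volumes(self) -> np.ndarray:
        v = self.vertices
        t = self.tets
        return np.einsum(
            "ij,ij->i",
            v[t[:, 1]] - v[t[:, 0]],
            np.cross(v[t[:, 2]] - v[t[:, 0]], v[t[:, 3]] - v[t[:, 0]]),
        ) / 6.0

    def tet_centroids(self) -> np.ndarray:
        return self.vertices[self.tets].mean(axis=1)

    def fix_orientation(self) -> None:
        """Swap vertices of negatively oriented tets in place."""
        neg = self.tet_volumes() < 0
        self.tets[neg] = self.tets[neg][:, [0, 1, 3, 2]]

    def hull_tets(self, label_index: int) -> np.ndarray:
        return np.nonzero(self.tet_labels == label_index)[0]

    def hull_nodes(self, label_index: int) -> np.ndarray:
        return np.unique(self.tets[self.tet_labels == label_index])

    def total_volume(self) -> float:
        return float(self.tet_volumes().sum())


@dataclass(frozen=True)
class Bundle:
    """A fast-conducting polyline (ordered mesh node ids)."""

    nodes: Tuple[int, ...]
    tissue: TissueProperties
    delay_ms: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "nodes", tuple(int(n) for n in self.nodes))
        if self.delay_ms < 0:
            raise ConfigurationError("bundle delay must be >= 0 ms")


@dataclass
class ConductionSystem:
    """Activation sources and bundle polylines."""

    sources: List[Tuple[int, float]] = field(default_factory=list)
    bundles: List[Bundle] = field(default_factory=list)

    def validate(self, n_vertices: int) -> None:
        for node, onset in self.sources:
            if not (0 <= node < n_vertices):
                raise ConfigurationError(f"source node {node} not in mesh")
            if onset < 0:
                raise ConfigurationError("source onset must be >= 0 ms")
        for b in self.bundles:
            for node in b.nodes:
                if not (0 <= node < n_vertices):
                    raise ConfigurationError(f"bundle node {node} not in mesh")


@dataclass
class PhantomModel:
    """A complete simulator input: mesh + compiled topology + conduction.

    ``hull_nodes`` maps hull id to ALL member node ids (interior tet nodes
    included); interface nodes belong to every adjacent hull.
    """

    mesh: Optional[VolumeMesh]
    surface: SurfaceMesh
    topology: CompiledTopology
    conduction: ConductionSystem
    hull_nodes: Dict[str, np.ndarray]
    provenance: Dict[str, object]
    electrode_candidates: Optional[np.ndarray] = None

    @property
    def vertices(self) -> np.ndarray:
        return self.surface.vertices

    @property
    def n_nodes(self) -> int:
        return len(self.vertices)

    def hull_tissue(self, hull_id: str) -> TissueProperties:
        return self.topology.hulls[hull_id].tissue

    def mean_edge_length(self) -> float:
        tris = self.surface.triangles
        v = self.surface.vertices
        e = np.concatenate([tris[:, [0, 1]], tris[:, [1, 2]], tris[:, [2, 0]]])
        return float(np.linalg.norm(v[e[:, 0]] - v[e[:, 1]], axis=1).mean())


# ---------------------------------------------------------------------------
# Lesions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BoxRegion:
    lo: Tuple[float, float, float]
    hi: Tuple[float, float, float]

    def contains(self, points: np.ndarray) -> np.ndarray:
        lo = np.asarray(self.lo, float)
        hi = np.asarray(self.hi, float)
        return np.all((points >= lo) & (points <= hi), axis=1)


@dataclass(frozen=True)
class SphereRegion:
    center: Tuple[float, float, float]
    radius: float

    def contains(self, points: np.ndarray) -> np.ndarray:
        c = np.asarray(self.center, float)
        return np.linalg.norm(points - c, axis=1) <= self.radius


@dataclass(frozen=True)
class LesionSpec:
    """A geometric region to be re-labeled with lesion tissue properties."""

    region: Union[BoxRegion, SphereRegion]
    tissue: TissueProperties
    id: str = ""


LESION_PRESETS = {
    "edema": TISSUE_PRESETS["edema"],
    "scar": TISSUE_PRESETS["scar"],
}


# ---------------------------------------------------------------------------
# Topology derivation from a labeled tetrahedral mesh
# ---------------------------------------------------------------------------

def _boundary_faces(tets: np.ndarray, tet_sel: np.ndarray) -> np.ndarray:
    """Outward-wound boundary triangles of the selected tet subset."""
    sub = tets[tet_sel]
    faces = sub[:, _TET_FACES].reshape(-1, 3)
    key = np.sort(faces, axis=1)
    order = np.lexsort((key[:, 2], key[:, 1], key[:, 0]))
    key_s = key[order]
    same_prev = np.zeros(len(key_s), dtype=bool)
    if len(key_s) > 1:
        same_prev[1:] = np.all(key_s[1:] == key_s[:-1], axis=1)
    same_next = np.zeros_like(same_prev)
    same_next[:-1] = same_prev[1:]
    unique_mask = ~(same_prev | same_next)
    return faces[order[unique_mask]]


def derive_topology(mesh: VolumeMesh,
                    tissues: Dict[str, TissueProperties]) -> Tuple[
                        TopologyDescription, Dict[str, np.ndarray]]:
    """Build a formal topology description from a labeled tet mesh.

    Each hull's boundary facets are extracted from the tetrahedra and split
    into edge-connected closed components (one shell per component; the
    largest-volume component is the outer shell, any others are holes).
    Interface facets shared by two hulls appear once per hull, wound outward
    with respect to that hull, so every shell is uniformly oriented.

    Returns the description plus a map hull id -> member node ids (all tet
    vertices of the hull).
    """
    import scipy.sparse as sp
    from scipy.sparse.csgraph import connected_components

    from .topology import shell_signed_volume

    all_tris: List[np.ndarray] = []
    patches: Dict[str, Patch] = {}
    shells: Dict[str, Shell] = {}
    hulls: Dict[str, Hull] = {}
    hull_nodes: Dict[str, np.ndarray] = {}
    color = 0
    offset = 0
    for li, hid in enumerate(mesh.hull_ids):
        sel = mesh.tet_labels == li
        if not sel.any():
            continue
        tris = _boundary_faces(mesh.tets, np.nonzero(sel)[0])
        # split boundary into edge-connected components
        e = np.concatenate([tris[:, [0, 1]], tris[:, [1, 2]], tris[:, [2, 0]]])
        ekey = (np.minimum(e[:, 0], e[:, 1]) * (mesh.n_vertices + 1)
                + np.maximum(e[:, 0], e[:, 1]))
        tri_of_edge = np.tile(np.arange(len(tris)), 3)
        order = np.argsort(ekey, kind="stable")
        ekey_s, tri_s = ekey[order], tri_of_edge[order]
        pair = np.nonzero(ekey_s[1:] == ekey_s[:-1])[0]
        rows, cols = tri_s[pair], tri_s[pair + 1]
        adj = sp.coo_matrix((np.ones(len(rows)), (rows, cols)),
                            shape=(len(tris), len(tris)))
        n_comp, comp = connected_components(adj, directed=False)
        comp_ids = []
        for ci in range(n_comp):
            ctris = tris[comp == ci]
            vol = shell_signed_volume(mesh.vertices, ctris)
            comp_ids.append((ci, vol, ctris))
        # outer shell = largest absolute enclosed volume
        comp_ids.sort(key=lambda t: -abs(t[1]))
        shell_names = []
        for rank, (ci, vol, ctris) in enumerate(comp_ids):
            pname = f"patches.{hid}_{rank}"
            sname = f"shells.{hid}_{rank}"
            facet_idx = tuple(range(offset, offset + len(ctris)))
            all_tris.append(ctris)
            offset += len(ctris)
            patches[pname] = Patch(pname, color, facet_idx)
            color += 1
            shells[sname] = Shell(sname, (pname,))
            shell_names.append(sname)
        hulls[f"hulls.{hid}"] = Hull(
            f"hulls.{hid}", shell_names[0], tuple(shell_names[1:]),
            tissues[hid])
        hull_nodes[f"hulls.{hid}"] = mesh.hull_nodes(li)

    labels = np.concatenate(
        [np.full(len(t), i) for i, t in enumerate(all_tris)]
    ) if all_tris else None
    surf = SurfaceMesh(
        mesh.vertices,
        np.concatenate(all_tris) if all_tris else np.empty((0, 3), np.int64),
        labels,
    )
    desc = TopologyDescription(surf, patches, shells, hulls)
    return desc, hull_nodes


def _assemble(mesh: VolumeMesh, tissues: Dict[str, TissueProperties],
              conduction: ConductionSystem,
              provenance: Dict[str, object],
              electrode_candidates: Optional[np.ndarray] = None) -> PhantomModel:
    mesh.fix_orientation()
    desc, hull_nodes = derive_topology(mesh, tissues)
    topo = compile_topology(desc)
    conduction.validate(mesh.n_vertices)
    return PhantomModel(mesh, desc.mesh, topo, conduction, hull_nodes,
                        provenance, electrode_candidates)


# ---------------------------------------------------------------------------
# Structured lattice helpers
# ---------------------------------------------------------------------------

#: Kuhn subdivision of the unit cube into six conforming tetrahedra: each
#: tet follows one axis-permutation path from corner (0,0,0) to (1,1,1).
_KUHN_PATHS = [
    (0, 1, 2), (0, 2, 1), (1, 0, 2), (1, 2, 0), (2, 0, 1), (2, 1, 0),
]


def _lattice(shape: Tuple[int, int, int], spacing: float,
             origin=(0.0, 0.0, 0.0)) -> Tuple[np.ndarray, np.ndarray]:
    """Regular grid vertices + Kuhn tetrahedra over ``shape`` nodes per axis."""
    nx, ny, nz = shape
    xs = origin[0] + spacing * np.arange(nx)
    ys = origin[1] + spacing * np.arange(ny)
    zs = origin[2] + spacing * np.arange(nz)
    gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
    verts = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)

    def nid(i, j, k):
        return (i * ny + j) * nz + k

    ci, cj, ck = np.meshgrid(np.arange(nx - 1), np.arange(ny - 1),
                             np.arange(nz - 1), indexing="ij")
    ci, cj, ck = ci.ravel(), cj.ravel(), ck.ravel()
    corner = [ci, cj, ck]
    tets = []
    for path in _KUHN_PATHS:
        idx = [nid(*corner)]
        cur = [c.copy() for c in corner]
        for axis in path:
            cur[axis] = cur[axis] + 1
            idx.append(nid(*cur))
        tets.append(np.stack(idx, axis=1))
    tets = np.concatenate(tets)
    return verts, tets


def _grid_shape(dimensions, spacing) -> Tuple[int, int, int]:
    shape = []
    for d in dimensions:
        n = d / spacing
        if abs(n - round(n)) > 1e-9:
            raise ConfigurationError(
                f"spacing {spacing} does not evenly divide dimension {d}")
        shape.append(int(round(n)) + 1)
    return tuple(shape)


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def make_slab_phantom(dimensions=(60.0, 10.0, 10.0), spacing=5.0,
                      tissue: Optional[TissueProperties] = None,
                      node_cap: int = DEFAULT_NODE_CAP,
                      seed: int = 0) -> PhantomModel:
    """Rectangular single-hull slab with a corner source at onset 0 ms.

    The default tissue is working myocardium at 0.6 mm/ms.  Node spacing
    must divide every dimension evenly; the resulting node count must stay
    below ``node_cap`` (a :class:`SizeError` suggests a coarser spacing
    otherwise).
    """
    if spacing <= 0:
        raise ConfigurationError("spacing must be > 0")
    tissue = tissue or TISSUE_PRESETS["myocardium"]
    shape = _grid_shape(dimensions, spacing)
    n_nodes = shape[0] * shape[1] * shape[2]
    if n_nodes > node_cap:
        factor = (n_nodes / node_cap) ** (1 / 3)
        raise SizeError(
            f"{n_nodes} nodes exceeds cap {node_cap}; try spacing >= "
            f"{spacing * factor:.2f} mm")
    verts, tets = _lattice(shape, spacing)
    mesh = VolumeMesh(verts, tets, np.zeros(len(tets), np.int64), ("slab",))
    conduction = ConductionSystem(sources=[(0, 0.0)])
    prov = {
        "tool": "wholeheart", "version": TOOL_VERSION,
        "generator": "make_slab_phantom",
        "parameters": {"dimensions": list(map(float, dimensions)),
                       "spacing": float(spacing), "tissue": tissue.label},
        "seed": int(seed),
    }
    return _assemble(mesh, {"slab": tissue}, conduction, prov)


def make_concentric_sphere_phantom(radii: Sequence[float],
                                   conductivities: Sequence[Optional[float]],
                                   level: int = 2,
                                   seed: int = 0) -> PhantomModel:
    """Nested icosphere surfaces: epicardium, optional lungs, body surface.

    ``radii`` are strictly increasing (mm, inner to outer);
    ``conductivities[k]`` is the conductivity (S/m) of the region directly
    inside surface ``k`` (entry 0, the heart interior, is ignored and may be
    ``None``).  Each icosphere at subdivision ``level`` has ``20 * 4**level``
    triangles.  Vertex ids of the outermost sphere are exposed as electrode
    candidate sites.
    """
    radii = [float(r) for r in radii]
    if len(radii) < 2:
        raise ConfigurationError("need at least two surfaces (heart, thorax)")
    if any(b <= a for a, b in zip(radii, radii[1:])):
        raise ConfigurationError("radii must be strictly increasing")
    if len(conductivities) != len(radii):
        raise ConfigurationError("one conductivity per surface required")

    tissue_names = {0.04: "lung", 0.2: "thorax"}
    all_v: List[np.ndarray] = []
    all_t: List[np.ndarray] = []
    patches: Dict[str, Patch] = {}
    shells: Dict[str, Shell] = {}
    voff = 0
    foff = 0
    shell_order = []
    for k, r in enumerate(radii):
        ico = trimesh.creation.icosphere(subdivisions=level, radius=r)
        v = np.asarray(ico.vertices, float)
        f = np.asarray(ico.faces, np.int64) + voff
        all_v.append(v)
        all_t.append(f)
        pname = f"patches.surface_{k}"
        sname = f"shells.surface_{k}"
        patches[pname] = Patch(pname, k, tuple(range(foff, foff + len(f))))
        shells[sname] = Shell(sname, (pname,))
        shell_order.append(sname)
        voff += len(v)
        foff += len(f)

    hulls: Dict[str, Hull] = {}
    tissues_used = {}
    for k in range(1, len(radii)):
        sigma = conductivities[k]
        if sigma is None:
            raise ConfigurationError(f"conductivity for surface {k} missing")
        label = tissue_names.get(float(sigma), f"region_{k}")
        tis = TissueProperties(label, speed=0.0, conductivity=float(sigma))
        hid = f"hulls.{label}" if f"hulls.{label}" not in hulls else f"hulls.{label}_{k}"
        hulls[hid] = Hull(hid, shell_order[k], (shell_order[k - 1],), tis)
        tissues_used[hid] = tis

    surf = SurfaceMesh(np.concatenate(all_v), np.concatenate(all_t),
                       np.concatenate([np.full(len(t), i)
                                       for i, t in enumerate(all_t)]))
    desc = TopologyDescription(surf, patches, shells, hulls)
    topo = compile_topology(desc)
    hull_nodes = {hid: np.unique(topo.hull_boundary_triangles(hid))
                  for hid in hulls}
    n_outer = len(all_v[-1])
    electrode_candidates = np.arange(voff - n_outer, voff)
    prov = {
        "tool": "wholeheart", "version": TOOL_VERSION,
        "generator": "make_concentric_sphere_phantom",
        "parameters": {"radii": radii,
                       "conductivities": [None if c is None else float(c)
                                          for c in conductivities],
                       "level": int(level)},
        "seed": int(seed),
    }
    return PhantomModel(None, surf, topo, ConductionSystem(), hull_nodes,
                        prov, electrode_candidates)


def _repair_pinch_edges(tets: np.ndarray, labels: np.ndarray,
                        max_iter: int = 40) -> Tuple[np.ndarray, bool]:
    """Relabel tets so every label's boundary surface is 2-manifold.

    Stair-cased voxelization of curved regions can leave "pinch" edges
    where a label's boundary touches itself (an edge shared by 4+ boundary
    faces).  Each pinch is resolved by assigning the whole tet fan around
    the edge to the fan's majority label (-1 = outside).  Iterates to a
    fixed point; returns (labels, converged).
    """
    labels = labels.copy()
    # vertex -> incident tets
    nv = int(tets.max()) + 1
    order = np.argsort(tets.ravel(), kind="stable")
    tet_of = order // 4
    starts = np.searchsorted(tets.ravel()[order], np.arange(nv + 1))

    def tets_at(v):
        return tet_of[starts[v]:starts[v + 1]]

    for _ in range(max_iter):
        changed = False
        for lab in np.unique(labels[labels >= 0]):
            sel = np.nonzero(labels == lab)[0]
            if not len(sel):
                continue
            tris = tets[sel][:, _TET_FACES].reshape(-1, 3)
            e = np.concatenate([tris[:, [0, 1]], tris[:, [1, 2]], tris[:, [2, 0]]])
            key = (np.minimum(e[:, 0], e[:, 1]).astype(np.int64) * (nv + 1)
                   + np.maximum(e[:, 0], e[:, 1]))
            # keep only boundary-face edges: faces not shared by two tets of lab
            fkey = np.sort(tris, axis=1)
            forder = np.lexsort((fkey[:, 2], fkey[:, 1], fkey[:, 0]))
            fk = fkey[forder]
            dup = np.zeros(len(fk), bool)
            if len(fk) > 1:
                dup[1:] = np.all(fk[1:] == fk[:-1], axis=1)
            dup[:-1] |= dup[1:].copy()
            bnd_face = np.ones(len(tris), bool)
            bnd_face[forder[dup]] = False
            bkey = key[np.tile(bnd_face, 3)]
            uniq, counts = np.unique(bkey, return_counts=True)
            bad = uniq[counts > 2]
            for k in bad:
                a, b = int(k // (nv + 1)), int(k % (nv + 1))
                cyc = np.intersect1d(tets_at(a), tets_at(b))
                votes = labels[cyc]
                vals, cnts = np.unique(votes, return_counts=True)
                win = int(vals[np.argmax(cnts)])
                if not np.all(votes == win):
                    labels[cyc] = win
                    changed = True
        if not changed:
            return labels, True
    return labels, False


def _repair_labels_and_envelope(verts: np.ndarray, tets: np.ndarray,
                                label: np.ndarray,
                                max_rounds: int = 10
                                ) -> Tuple[np.ndarray, bool]:
    """Joint pinch repair of every hull boundary AND the outer envelope.

    The envelope (boundary of the union of all kept tets) must itself be a
    2-manifold for the volume-conductor model.  Tets added to the union by
    the envelope repair receive the label of the nearest labeled tet.
    """
    label = label.copy()
    cents = verts[tets].mean(axis=1)
    for _ in range(max_rounds):
        label, conv1 = _repair_pinch_edges(tets, label)
        binary = np.where(label >= 0, 0, -1)
        repaired, conv2 = _repair_pinch_edges(tets, binary)
        delta = repaired != binary
        if not delta.any():
            if conv1 and conv2:
                return label, True
            continue
        dropped = (repaired == -1) & (label >= 0)
        added = (repaired == 0) & (label == -1)
        label[dropped] = -1
        if added.any():
            from scipy.spatial import cKDTree
            keep = label >= 0
            tree = cKDTree(cents[keep])
            src = np.nonzero(keep)[0]
            _, nearest = tree.query(cents[added])
            label[added] = label[src[nearest]]
    return label, False


def make_two_chamber_heart_phantom(atrial_radius: float = 12.0,
                                   ventricular_radius: float = 16.0,
                                   wall_thickness: float = 4.0,
                                   spacing: float = 3.0,
                                   valve_thickness: float = 2.0,
                                   bundle_speed: float = 2.0,
                                   seed: int = 0) -> PhantomModel:
    """Simplified two-chamber heart: two adjoined spherical chambers.

    Four hulls: atrial wall and ventricular wall (myocardium, 0.6 mm/ms), a
    muscular septal rim connecting them, and an insulating valve-plane disc
    separating the cavities.  A sinus-node source sits at the supero-lateral
    atrial wall (the superior-vena-cava border analog) and one bundle-branch
    polyline runs from the septal base down the inner ventricular wall at
    ``bundle_speed`` (default 2 mm/ms).
    """
    if wall_thickness <= spacing / 2:
        raise ConfigurationError("wall thickness must exceed spacing/2")
    ra, rv, wt = float(atrial_radius), float(ventricular_radius), float(wall_thickness)
    d = 0.8 * (ra + rv)                     # atrial center height
    z0 = (d * d + rv * rv - ra * ra) / (2 * d)   # chamber junction plane
    h = float(valve_thickness)

    lo = np.array([-rv, -rv, -rv])
    hi = np.array([rv, rv, d + ra])
    shape = tuple(int(np.ceil((hi[i] - lo[i]) / spacing)) + 1 for i in range(3))
    verts, tets = _lattice(shape, spacing, origin=lo)

    cen = verts[tets].mean(axis=1)
    ca = np.array([0.0, 0.0, d])
    r_a = np.linalg.norm(cen - ca, axis=1)
    r_v = np.linalg.norm(cen, axis=1)
    in_outer = (r_a <= ra) | (r_v <= rv)
    in_inner = (r_a <= ra - wt) | (r_v <= rv - wt)
    # the valve/septum band is snapped to whole lattice cell layers so its
    # interfaces are flat; at least one layer regardless of valve_thickness
    layer = np.floor((cen[:, 2] - lo[2]) / spacing).astype(np.int64)
    k0 = int(np.floor((z0 - lo[2]) / spacing))
    n_layers = max(1, int(round(h / spacing)))
    band_lo, band_hi = k0, k0 + n_layers - 1
    in_band = (layer >= band_lo) & (layer <= band_hi)
    in_a_cav = (r_a <= ra - wt) & (layer > band_hi)
    in_v_cav = (r_v <= rv - wt) & (layer < band_lo)

    # valve disc: the central part of the band (the fibrous plane between
    # the cavities); septum: the muscular rim of the band around it.
    # The disc radius is set to 60% of the band's outer radius so the
    # septal rim is at least a cell wide.
    z_mid = lo[2] + (band_lo + band_hi + 1) / 2 * spacing
    r_band = np.sqrt(max(rv * rv - z_mid * z_mid,
                         ra * ra - (z_mid - d) ** 2, 0.0))
    r_valve = 0.6 * r_band
    lateral = np.hypot(cen[:, 0], cen[:, 1])

    label = np.full(len(tets), -1, np.int64)
    hull_ids = ("atrial_wall", "ventricular_wall", "septum", "valve_plane")
    keep = in_outer & ~in_a_cav & ~in_v_cav
    label[keep & in_band & (lateral <= r_valve)] = 3          # valve plane
    label[keep & in_band & (lateral > r_valve)] = 2           # septal rim
    label[keep & ~in_band & (layer > band_hi)] = 0            # atrial wall
    label[keep & ~in_band & (layer < band_lo)] = 1            # ventricular wall

    label, converged = _repair_labels_and_envelope(verts, tets, label)
    if not converged:
        raise TopologyError(
            "two-chamber generation: non-manifold junction could not be "
            "repaired; try a finer spacing",
            ["unrepairable pinch edges"])

    kept = label >= 0
    tets = tets[kept]
    label = label[kept]
    # drop unreferenced vertices
    used, inv = np.unique(tets, return_inverse=True)
    verts = verts[used]
    tets = inv.reshape(-1, 4)

    mesh = VolumeMesh(verts, tets, label, hull_ids)
    tissues = {
        "atrial_wall": TISSUE_PRESETS["myocardium"],
        "ventricular_wall": TISSUE_PRESETS["myocardium"],
        "septum": TISSUE_PRESETS["myocardium"],
        "valve_plane": TISSUE_PRESETS["valve_plane"],
    }

    # sinus-node source: supero-lateral atrial wall node
    a_nodes = mesh.hull_nodes(0)
    target = ca + (ra - wt / 2) * np.array([np.sin(np.pi / 4), 0.0,
                                            np.cos(np.pi / 4)])
    src = int(a_nodes[np.argmin(np.linalg.norm(verts[a_nodes] - target, axis=1))])

    # bundle branch: from the septal base down the inner ventricular wall
    s_nodes = mesh.hull_nodes(2)
    v_nodes = mesh.hull_nodes(1)
    r_mid = rv - wt / 2
    phis = np.linspace(np.deg2rad(75), np.deg2rad(178), 10)
    waypoints = np.stack([r_mid * np.sin(phis), np.zeros_like(phis),
                          r_mid * np.cos(phis)], axis=1)
    start = int(s_nodes[np.argmin(
        np.linalg.norm(verts[s_nodes] - np.array([r_mid, 0.0, z0]), axis=1))])
    path = [start]
    for w in waypoints:
        nxt = int(v_nodes[np.argmin(np.linalg.norm(verts[v_nodes] - w, axis=1))])
        if nxt != path[-1]:
            path.append(nxt)
    bundle = Bundle(tuple(path),
                    TissueProperties("bundle_branch", speed=float(bundle_speed),
                                     conductivity=0.2))
    conduction = ConductionSystem(sources=[(src, 0.0)], bundles=[bundle])
    prov = {
        "tool": "wholeheart", "version": TOOL_VERSION,
        "generator": "make_two_chamber_heart_phantom",
        "parameters": {"atrial_radius": ra, "ventricular_radius": rv,
                       "wall_thickness": wt, "spacing": float(spacing),
                       "valve_thickness": h, "bundle_speed": float(bundle_speed)},
        "seed": int(seed),
    }
    try:
        return _assemble(mesh, tissues, conduction, prov)
    except TopologyError as exc:
        raise TopologyError(
            f"two-chamber generation produced an invalid junction: {exc}",
            exc.violations) from exc


# ---------------------------------------------------------------------------
# Lesion insertion
# ---------------------------------------------------------------------------

def insert_lesion(model: PhantomModel, lesion: LesionSpec) -> PhantomModel:
    """Re-label tetrahedra whose centroid falls inside the lesion region.

    Pure function: the input model is unchanged.  A conducting hull split
    into disconnected pieces by the lesion becomes several hulls (named
    ``<id>``, ``<id>_2``, ... in order of first tetrahedron).  Total mesh
    volume is conserved exactly since no re-meshing occurs.
    """
    import scipy.sparse as sp
    from scipy.sparse.csgraph import connected_components

    if model.mesh is None:
        raise LesionError("lesion insertion requires a volume mesh")
    mesh = model.mesh
    cen = mesh.tet_centroids()
    hit = lesion.region.contains(cen)
    if not hit.any():
        raise LesionError("lesion region does not intersect the mesh")
    conducting = np.array([model.hull_tissue(f"hulls.{mesh.hull_ids[l]}").conducting
                           for l in range(len(mesh.hull_ids))])
    if not conducting[mesh.tet_labels[hit]].any():
        raise LesionError("lesion region intersects no conducting hull")

    lesion_id = lesion.id or lesion.tissue.label
    old_ids = list(mesh.hull_ids)
    if lesion_id in old_ids:
        raise ConfigurationError(f"hull id {lesion_id!r} already in use")

    new_labels = mesh.tet_labels.copy()
    new_labels[hit] = len(old_ids)
    ids = old_ids + [lesion_id]

    # split each label into face-connected components
    faces = mesh.tets[:, _TET_FACES].reshape(-1, 3)
    fkey = np.sort(faces, axis=1)
    order = np.lexsort((fkey[:, 2], fkey[:, 1], fkey[:, 0]))
    tet_of_face = np.repeat(np.arange(len(mesh.tets)), 4)
    fkey_s = fkey[order]
    tet_s = tet_of_face[order]
    pair = np.nonzero(np.all(fkey_s[1:] == fkey_s[:-1], axis=1))[0]
    ta, tb = tet_s[pair], tet_s[pair + 1]
    same = new_labels[ta] == new_labels[tb]
    adj = sp.coo_matrix((np.ones(same.sum()), (ta[same], tb[same])),
                        shape=(len(mesh.tets),) * 2)
    n_comp, comp = connected_components(adj, directed=False)

    final_ids: List[str] = []
    final_labels = np.empty(len(mesh.tets), np.int64)
    comp_seen: Dict[int, int] = {}
    per_base_count: Dict[str, int] = {}
    for t in range(len(mesh.tets)):
        c = comp[t]
        if c not in comp_seen:
            base = ids[new_labels[t]]
            per_base_count[base] = per_base_count.get(base, 0) + 1
            name = base if per_base_count[base] == 1 else f"{base}_{per_base_count[base]}"
            comp_seen[c] = len(final_ids)
            final_ids.append(name)
        final_labels[t] = comp_seen[c]

    new_mesh = VolumeMesh(mesh.vertices.copy(), mesh.tets.copy(),
                          final_labels, tuple(final_ids))
    tissues: Dict[str, TissueProperties] = {}
    for name in final_ids:
        base = name.rsplit("_", 1)[0] if name.rsplit("_", 1)[-1].isdigit() else name
        if base == lesion_id or name == lesion_id:
            tissues[name] = lesion.tissue
        else:
            tissues[name] = model.hull_tissue(f"hulls.{base}")
    conduction = ConductionSystem(sources=list(model.conduction.sources),
                                  bundles=list(model.conduction.bundles))
    prov = dict(model.provenance)
    prov.setdefault("lesions", [])
    prov["lesions"] = list(prov["lesions"]) + [{
        "id": lesion_id, "tissue": lesion.tissue.label,
        "region": dataclass_to_dict(lesion.region),
    }]
    return _assemble(new_mesh, tissues, conduction, prov,
                     model.electrode_candidates)


def dataclass_to_dict(obj) -> Dict[str, object]:
    import dataclasses
    d = {k: (list(v) if isinstance(v, tuple) else v)
         for k, v in dataclasses.asdict(obj).items()}
    d["kind"] = type(obj).__name__
    return d


# ---------------------------------------------------------------------------
# GEO script emission
# ---------------------------------------------------------------------------

def emit_geometry_script(topo: CompiledTopology, lc: float = 5.0) -> str:
    """Emit the compiled topology as a Gmsh GEO geometry script.

    Points, per-facet plane surfaces, one surface loop per shell and one
    volume + physical volume per hull, so that meshing the script
    reproduces the hull labeling.
    """
    mesh = topo.mesh
    lines: List[str] = ["// wholeheart geometry script",
                        f"// tool wholeheart {TOOL_VERSION}",
                        f"lc = {lc};"]
    if mesh is None:
        return "\n".join(lines) + "\n"
    used = np.unique(np.concatenate(
        [s.triangles for s in topo.shells.values()])) if topo.shells else []
    for vid in used:
        x, y, z = mesh.vertices[vid]
        lines.append(f"Point({vid + 1}) = {{{x:.17g}, {y:.17g}, {z:.17g}, lc}};")
    line_ids: Dict[Tuple[int, int], int] = {}
    next_line = 1
    surf_id = 0
    shell_surfaces: Dict[str, List[int]] = {}
    for sid, cs in topo.shells.items():
        ids = []
        for tri in cs.triangles:
            loop = []
            for a, b in ((tri[0], tri[1]), (tri[1], tri[2]), (tri[2], tri[0])):
                key = (int(a), int(b))
                rkey = (int(b), int(a))
                if rkey in line_ids:
                    loop.append(-line_ids[rkey])
                else:
                    if key not in line_ids:
                        line_ids[key] = next_line
                        lines.append(f"Line({next_line}) = {{{a + 1}, {b + 1}}};")
                        next_line += 1
                    loop.append(line_ids[key])
            surf_id += 1
            lines.append(f"Line Loop({surf_id}) = {{{', '.join(map(str, loop))}}};")
            lines.append(f"Plane Surface({surf_id}) = {{{surf_id}}};")
            ids.append(surf_id)
        shell_surfaces[sid] = ids
    loop_id = 0
    vol_id = 0
    for hid, hull in topo.hulls.items():
        loops = []
        for sid in (hull.outer, *hull.inner):
            loop_id += 1
            ids = shell_surfaces[sid]
            lines.append(
                f"Surface Loop({loop_id}) = {{{', '.join(map(str, ids))}}};")
            loops.append(loop_id)
        vol_id += 1
        lines.append(f"Volume({vol_id}) = {{{', '.join(map(str, loops))}}};")
        lines.append(f'Physical Volume("{hid}") = {{{vol_id}}};')
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Model I/O (VTK legacy ASCII, Gmsh MSH 4.1 ASCII + YAML sidecar)
# ---------------------------------------------------------------------------

def _sidecar_path(path: str) -> str:
    return str(path) + ".topo.yaml"


def _tissue_to_dict(t: TissueProperties) -> Dict[str, object]:
    return {"label": t.label, "speed": float(t.speed),
            "conductivity": float(t.conductivity)}


def _write_vtk(path: str, model: PhantomModel, point_data=None) -> None:
    title = f"wholeheart {model.provenance.get('generator', 'model')} " \
            f"seed={model.provenance.get('seed', 0)}"
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\n")
        f.write(title[:255] + "\n")
        f.write("ASCII\nDATASET UNSTRUCTURED_GRID\n")
        if model.mesh is not None:
            verts, cells = model.mesh.vertices, model.mesh.tets
            labels = model.mesh.tet_labels
            ctype = 10  # VTK_TETRA
        else:
            verts = model.surface.vertices
            cells = model.surface.triangles
            labels = model.surface.labels
            ctype = 5   # VTK_TRIANGLE
        f.write(f"POINTS {len(verts)} double\n")
        for x, y, z in verts:
            f.write(f"{x:.17g} {y:.17g} {z:.17g}\n")
        k = cells.shape[1]
        f.write(f"CELLS {len(cells)} {len(cells) * (k + 1)}\n")
        for c in cells:
            f.write(f"{k} " + " ".join(map(str, c)) + "\n")
        f.write(f"CELL_TYPES {len(cells)}\n")
        f.write("\n".join([str(ctype)] * len(cells)) + "\n")
        f.write(f"CELL_DATA {len(cells)}\n")
        f.write("SCALARS hull_label int 1\nLOOKUP_TABLE default\n")
        f.write("\n".join(map(str, labels)) + "\n")
        if point_data:
            f.write(f"POINT_DATA {len(verts)}\n")
            for name, (kind, values) in point_data.items():
                f.write(f"SCALARS {name} {kind} 1\nLOOKUP_TABLE default\n")
                if kind == "int":
                    f.write("\n".join(str(int(v)) for v in values) + "\n")
                else:
                    f.write("\n".join(f"{float(v):.17g}" for v in values) + "\n")


def _read_vtk(path: str):
    with open(path) as f:
        lines = f.read().splitlines()
    verts = cells = labels = ctypes = None
    i = 0
    n = len(lines)
    while i < n:
        parts = lines[i].split()
        if not parts:
            i += 1
            continue
        kw = parts[0].upper()
        if kw == "POINTS":
            cnt = int(parts[1])
            vals: List[float] = []
            i += 1
            while len(vals) < cnt * 3:
                vals.extend(map(float, lines[i].split()))
                i += 1
            verts = np.array(vals).reshape(cnt, 3)
        elif kw == "CELLS":
            cnt = int(parts[1])
            total = int(parts[2])
            vals = []
            i += 1
            while len(vals) < total:
                vals.extend(map(int, lines[i].split()))
                i += 1
            cells_raw = vals
            cells = []
            j = 0
            for _ in range(cnt):
                k = cells_raw[j]
                cells.append(cells_raw[j + 1: j + 1 + k])
                j += k + 1
            cells = np.array(cells, dtype=np.int64)
        elif kw == "CELL_TYPES":
            cnt = int(parts[1])
            vals = []
            i += 1
            while len(vals) < cnt:
                vals.extend(map(int, lines[i].split()))
                i += 1
            ctypes = np.array(vals)
        elif kw == "SCALARS" and parts[1] == "hull_label":
            i += 2  # skip LOOKUP_TABLE
            vals = []
            while len(vals) < len(cells):
                vals.extend(map(int, lines[i].split()))
                i += 1
            labels = np.array(vals, dtype=np.int64)
        else:
            i += 1
    if verts is None or cells is None:
        raise FormatError(f"{path}: not a VTK unstructured grid")
    if labels is None:
        raise FormatError(f"{path}: cells carry no hull_label data "
                          f"(all {len(cells)} cells unlabeled)")
    return verts, cells, labels, ctypes


def _write_msh(path: str, model: PhantomModel) -> None:
    if model.mesh is None:
        raise FormatError("MSH output requires a volume mesh")
    mesh = model.mesh
    n_hulls = len(mesh.hull_ids)
    with open(path, "w") as f:
        f.write("$MeshFormat\n4.1 0 8\n$EndMeshFormat\n")
        f.write("$PhysicalNames\n")
        f.write(f"{n_hulls}\n")
        for i, hid in enumerate(mesh.hull_ids):
            f.write(f'3 {i + 1} "{hid}"\n')
        f.write("$EndPhysicalNames\n")
        f.write("$Entities\n")
        f.write(f"0 0 0 {n_hulls}\n")
        lo = mesh.vertices.min(axis=0)
        hi = mesh.vertices.max(axis=0)
        bbox = f"{lo[0]:.17g} {lo[1]:.17g} {lo[2]:.17g} " \
               f"{hi[0]:.17g} {hi[1]:.17g} {hi[2]:.17g}"
        for i in range(n_hulls):
            f.write(f"{i + 1} {bbox} 1 {i + 1} 0\n")
        f.write("$EndEntities\n")
        f.write("$Nodes\n")
        f.write(f"1 {mesh.n_vertices} 1 {mesh.n_vertices}\n")
        f.write(f"3 1 0 {mesh.n_vertices}\n")
        for i in range(mesh.n_vertices):
            f.write(f"{i + 1}\n")
        for x, y, z in mesh.vertices:
            f.write(f"{x:.17g} {y:.17g} {z:.17g}\n")
        f.write("$EndNodes\n")
        f.write("$Elements\n")
        blocks = [(li, np.nonzero(mesh.tet_labels == li)[0])
                  for li in range(n_hulls)]
        blocks = [(li, sel) for li, sel in blocks if len(sel)]
        f.write(f"{len(blocks)} {len(mesh.tets)} 1 {len(mesh.tets)}\n")
        eid = 1
        for li, sel in blocks:
            f.write(f"3 {li + 1} 4 {len(sel)}\n")
            for t in mesh.tets[sel]:
                f.write(f"{eid} " + " ".join(str(v + 1) for v in t) + "\n")
                eid += 1
        f.write("$EndElements\n")


def _read_msh(path: str):
    with open(path) as f:
        lines = f.read().splitlines()
    sec: Dict[str, List[str]] = {}
    cur = None
    for ln in lines:
        if ln.startswith("$End"):
            cur = None
        elif ln.startswith("$"):
            cur = ln[1:]
            sec[cur] = []
        elif cur is not None:
            sec[cur].append(ln)
    if "Nodes" not in sec or "Elements" not in sec:
        raise FormatError(f"{path}: missing $Nodes/$Elements sections")
    phys_names: Dict[int, str] = {}
    for ln in sec.get("PhysicalNames", [])[1:]:
        parts = ln.split(None, 2)
        if len(parts) == 3 and parts[0] == "3":
            phys_names[int(parts[1])] = parts[2].strip().strip('"')
    # entity -> physical tag
    ent_phys: Dict[int, int] = {}
    if "Entities" in sec:
        counts = list(map(int, sec["Entities"][0].split()))
        idx = 1
        for dim, cnt in enumerate(counts):
            for _ in range(cnt):
                parts = sec["Entities"][idx].split()
                idx += 1
                if dim == 3:
                    tag = int(parts[0])
                    n_phys = int(parts[7])
                    if n_phys >= 1:
                        ent_phys[tag] = int(parts[8])
    node_lines = sec["Nodes"]
    nblocks = int(node_lines[0].split()[0])
    idx = 1
    coords: Dict[int, Tuple[float, float, float]] = {}
    for _ in range(nblocks):
        _, _, _, cnt = map(int, node_lines[idx].split())
        idx += 1
        tags = [int(node_lines[idx + i]) for i in range(cnt)]
        idx += cnt
        for i in range(cnt):
            x, y, z = map(float, node_lines[idx + i].split())
            coords[tags[i]] = (x, y, z)
        idx += cnt
    tag_sorted = sorted(coords)
    remap = {t: i for i, t in enumerate(tag_sorted)}
    verts = np.array([coords[t] for t in tag_sorted])

    el_lines = sec["Elements"]
    nblocks = int(el_lines[0].split()[0])
    idx = 1
    tets: List[List[int]] = []
    labels: List[int] = []
    unlabeled: List[int] = []
    for _ in range(nblocks):
        ent_dim, ent_tag, el_type, cnt = map(int, el_lines[idx].split())
        idx += 1
        for i in range(cnt):
            parts = list(map(int, el_lines[idx + i].split()))
            if el_type == 4:
                tets.append([remap[t] for t in parts[1:5]])
                ptag = ent_phys.get(ent_tag)
                if ptag is None:
                    unlabeled.append(parts[0])
                else:
                    labels.append(ptag)
        idx += cnt
    if unlabeled:
        raise FormatError(
            f"{path}: {len(unlabeled)} unlabeled cells "
            f"(element ids {unlabeled[:10]}{'...' if len(unlabeled) > 10 else ''})")
    ptags = sorted(set(labels))
    label_idx = {p: i for i, p in enumerate(ptags)}
    hull_ids = tuple(phys_names.get(p, f"hull_{p}") for p in ptags)
    return (verts, np.array(tets, np.int64),
            np.array([label_idx[p] for p in labels], np.int64), hull_ids)


def write_model(model: PhantomModel, path: str, fmt: str = "vtk") -> None:
    """Write a phantom to ``path`` plus a ``<path>.topo.yaml`` sidecar.

    Formats: ``vtk`` (legacy ASCII unstructured grid) or ``msh`` (Gmsh 4.1
    ASCII, volume meshes only).  Hull labels travel as integer cell data /
    physical groups; tissue properties, conduction system and provenance
    travel in the sidecar.
    """
    fmt = fmt.lower()
    if fmt == "vtk":
        _write_vtk(path, model)
    elif fmt == "msh":
        _write_msh(path, model)
    else:
        raise FormatError(f"unsupported format {fmt!r} (use 'vtk' or 'msh')")
    side = {
        "format_version": 1,
        "mesh_format": fmt,
        "kind": "volume" if model.mesh is not None else "surfaces",
        "provenance": model.provenance,
        "hulls": {},
        "conduction": {
            "sources": [[int(n), float(t)] for n, t in model.conduction.sources],
            "bundles": [{"nodes": list(b.nodes),
                         "tissue": _tissue_to_dict(b.tissue),
                         "delay_ms": float(b.delay_ms)}
                        for b in model.conduction.bundles],
        },
    }
    if model.mesh is not None:
        side["hull_order"] = list(model.mesh.hull_ids)
        for hid in model.mesh.hull_ids:
            side["hulls"][hid] = _tissue_to_dict(
                model.hull_tissue(f"hulls.{hid}"))
    else:
        side["surface_phantom"] = {
            "hulls": {hid: _tissue_to_dict(h.tissue)
                      for hid, h in model.topology.hulls.items()},
            "parameters": model.provenance.get("parameters", {}),
        }
    if model.electrode_candidates is not None:
        side["electrode_candidates"] = [int(i) for i in model.electrode_candidates]
    with open(_sidecar_path(path), "w") as f:
        yaml.safe_dump(side, f, sort_keys=True)


def read_model(path: str, fmt: str = "vtk") -> PhantomModel:
    """Read a phantom written by :func:`write_model` (mesh + sidecar)."""
    fmt = fmt.lower()
    try:
        with open(_sidecar_path(path)) as f:
            side = yaml.safe_load(f)
    except FileNotFoundError as exc:
        raise FormatError(f"missing sidecar {_sidecar_path(path)}") from exc

    def tissue_from(d) -> TissueProperties:
        return TissueProperties(d["label"], d["speed"], d["conductivity"])

    conduction = ConductionSystem(
        sources=[(int(n), float(t))
                 for n, t in side.get("conduction", {}).get("sources", [])],
        bundles=[Bundle(tuple(b["nodes"]), tissue_from(b["tissue"]),
                        b.get("delay_ms", 0.0))
                 for b in side.get("conduction", {}).get("bundles", [])],
    )
    prov = side.get("provenance", {})
    if side.get("kind") == "surfaces":
        params = side.get("surface_phantom", {}).get("parameters", {})
        model = make_concentric_sphere_phantom(
            params["radii"], params["conductivities"], params["level"],
            seed=prov.get("seed", 0))
        return model

    if fmt == "vtk":
        verts, cells, labels, ctypes = _read_vtk(path)
        if cells.shape[1] != 4:
            raise FormatError(f"{path}: expected tetrahedral cells")
        order = side.get("hull_order")
        hull_ids = tuple(order) if order else tuple(side["hulls"].keys())
        mesh = VolumeMesh(verts, cells, labels, hull_ids)
    elif fmt == "msh":
        verts, cells, labels, hull_ids = _read_msh(path)
        mesh = VolumeMesh(verts, cells, labels, hull_ids)
    else:
        raise FormatError(f"unsupported format {fmt!r}")
    tissues = {hid: tissue_from(side["hulls"][hid]) for hid in mesh.hull_ids}
    ec = side.get("electrode_candidates")
    return _assemble(mesh, tissues, conduction, prov,
                     None if ec is None else np.asarray(ec, np.int64))
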