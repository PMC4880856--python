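"""Fastest-route cardiac activation simulation.

The activation model is a fixed-conduction-velocity, fastest-route model:

1. every pair of mesh nodes belonging to the same conducting tissue hull is
   connected iff the straight segment between them stays inside that hull
   (tested with the Möller–Trumbore ray/triangle algorithm against the
   hull's boundary facets), with travel time = Euclidean distance divided
   by the hull's conduction speed;
2. bundle-branch polylines add fast edges between consecutive nodes;
3. activation times are shortest-path times from the source nodes
   (Floyd–Warshall reference solver; single-source Dijkstra mode for large
   graphs), combined over sources by the first-come-first-serve rule.

Cross-tissue propagation happens only through interface nodes, which belong
to both adjacent hulls; edges never straddle a hull boundary, so every
edge's speed is well defined.  Nodes interior to zero-speed tissue (scar)
receive no edges at all and are reported as *blocked* (activation time
+inf), never as a large finite time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import dijkstra as _dijkstra

from .errors import (ConfigurationError, InsufficiencyError, SizeError)
from .phantom import PhantomModel
from .topology import TISSUE_PRESETS

__all__ = [
    "VisibilityGraph",
    "ActivationMap",
    "ray_triangle_intersect",
    "segment_admissible",
    "build_visibility_graph",
    "floyd_warshall",
    "all_pairs_activation",
    "simulate_activation",
    "recover_front_velocity",
    "write_activation_csv",
    "write_activation_vtk",
    "BLOCKED",
]

#: Sentinel activation time of unreachable (blocked) nodes.
BLOCKED = np.inf

#: Relative segment shrink applied at both endpoints before intersection
#: testing: endpoints lie exactly on boundary facets and would otherwise
#: self-intersect.
EPS_SEGMENT = 1e-6

DEFAULT_NODE_CAP = 2000


# ---------------------------------------------------------------------------
# Ray-triangle intersection (Möller–Trumbore)
# ---------------------------------------------------------------------------

def ray_triangle_intersect(origin, direction, tri, eps: float = 1e-9):
    """Möller–Trumbore ray/triangle intersection.

    Returns ``(t, u, v)`` — the parametric distance along ``direction`` and
    the barycentric coordinates — when the ray hits the triangle, or
    ``None``.  Hits require ``t >= -eps``, ``u >= -eps``, ``v >= -eps`` and
    ``u + v <= 1 + eps``; a determinant with ``|det| <= eps`` (ray parallel
    to the triangle plane) is a miss.
    """
    origin = np.asarray(origin, float).reshape(3)
    direction = np.asarray(direction, float).reshape(3)
    if not np.any(direction):
        raise ConfigurationError("ray direction must be non-zero")
    v0, v1, v2 = (np.asarray(v, float).reshape(3) for v in tri)
    e1 = v1 - v0
    e2 = v2 - v0
    pvec = np.cross(direction, e2)
    det = float(e1 @ pvec)
    if abs(det) <= eps:
        return None
    inv = 1.0 / det
    tvec = origin - v0
    u = float(tvec @ pvec) * inv
    if u < -eps or u > 1 + eps:
        return None
    qvec = np.cross(tvec, e1)
    v = float(direction @ qvec) * inv
    if v < -eps or u + v > 1 + eps:
        return None
    t = float(e2 @ qvec) * inv
    if t < -eps:
        return None
    return t, u, v


try:
    from numba import njit as _njit

    @_njit(cache=False)
    def _mt_blocked_kernel(P, Q, V0, E1, E2, S, eps_seg):  # pragma: no cover
        n = P.shape[0]
        m = V0.shape[0]
        out = np.zeros(n, np.bool_)
        tol = 1e-9
        for i in range(n):
            dx = Q[i, 0] - P[i, 0]
            dy = Q[i, 1] - P[i, 1]
            dz = Q[i, 2] - P[i, 2]
            for f in range(m):
                e2x, e2y, e2z = E2[f, 0], E2[f, 1], E2[f, 2]
                px = dy * e2z - dz * e2y
                py = dz * e2x - dx * e2z
                pz = dx * e2y - dy * e2x
                det = E1[f, 0] * px + E1[f, 1] * py + E1[f, 2] * pz
                if abs(det) <= 1e-12 * S[f]:
                    continue
                inv = 1.0 / det
                tx = P[i, 0] - V0[f, 0]
                ty = P[i, 1] - V0[f, 1]
                tz = P[i, 2] - V0[f, 2]
                u = (tx * px + ty * py + tz * pz) * inv
                if u < -tol or u > 1.0 + tol:
                    continue
                qx = ty * E1[f, 2] - tz * E1[f, 1]
                qy = tz * E1[f, 0] - tx * E1[f, 2]
                qz = tx * E1[f, 1] - ty * E1[f, 0]
                v = (dx * qx + dy * qy + dz * qz) * inv
                if v < -tol or u + v > 1.0 + tol:
                    continue
                t = (e2x * qx + e2y * qy + e2z * qz) * inv
                if eps_seg < t < 1.0 - eps_seg:
                    out[i] = True
                    break
        return out

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


def _segments_blocked(p: np.ndarray, q: np.ndarray, tri_xyz: np.ndarray,
                      eps_seg: float = EPS_SEGMENT,
                      chunk: int = 2_000_000) -> np.ndarray:
    """True for each segment p[i]-q[i] that crosses any of the triangles.

    Intersections are only counted for parameters ``t`` strictly inside
    ``(eps_seg, 1 - eps_seg)``: the segment is shrunk at both endpoints,
    which lie exactly on boundary facets.  ``tri_xyz``: (M, 3, 3).
    """
    p = np.asarray(p, float).reshape(-1, 3)
    q = np.asarray(q, float).reshape(-1, 3)
    n = len(p)
    blocked = np.zeros(n, bool)
    if not len(tri_xyz) or n == 0:
        return blocked
    v0 = tri_xyz[:, 0]
    e1 = tri_xyz[:, 1] - v0
    e2 = tri_xyz[:, 2] - v0
    scale = np.linalg.norm(e1, axis=1) * np.linalg.norm(e2, axis=1)
    if _HAVE_NUMBA:
        return _mt_blocked_kernel(
            np.ascontiguousarray(p), np.ascontiguousarray(q),
            np.ascontiguousarray(v0), np.ascontiguousarray(e1),
            np.ascontiguousarray(e2), np.ascontiguousarray(scale),
            float(eps_seg))
    d_all = q - p
    alive = np.nonzero(np.einsum("ij,ij->i", d_all, d_all) > 0)[0]
    m = len(tri_xyz)
    fchunk = max(1, chunk // max(1, len(alive) or 1))
    for f0 in range(0, m, fchunk):
        if not len(alive):
            break
        V0 = v0[f0:f0 + fchunk]
        E1 = e1[f0:f0 + fchunk]
        E2 = e2[f0:f0 + fchunk]
        S = scale[f0:f0 + fchunk]
        d = d_all[alive]
        # cross products, broadcast (N, M, 3)
        pvec = np.cross(d[:, None, :], E2[None, :, :])
        det = np.einsum("mi,nmi->nm", E1, pvec)
        parallel = np.abs(det) <= 1e-12 * S[None, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            inv = np.where(parallel, 0.0, 1.0 / np.where(det == 0, 1.0, det))
        tvec = p[alive][:, None, :] - V0[None, :, :]
        u = np.einsum("nmi,nmi->nm", tvec, pvec) * inv
        qvec = np.cross(tvec, E1[None, :, :])
        v = np.einsum("ni,nmi->nm", d, qvec) * inv
        t = np.einsum("mi,nmi->nm", E2, qvec) * inv
        tol = 1e-9
        hit = (~parallel & (u >= -tol) & (v >= -tol) & (u + v <= 1 + tol)
               & (t > eps_seg) & (t < 1 - eps_seg))
        newly = hit.any(axis=1)
        blocked[alive[newly]] = True
        alive = alive[~newly]
    return blocked


def segment_admissible(p_idx: int, q_idx: int, vertices: np.ndarray,
                       boundary_tris: np.ndarray,
                       eps: float = EPS_SEGMENT) -> bool:
    """True iff the open segment between two hull nodes stays inside the hull.

    The segment is shrunk by ``eps`` (relative) at both endpoints, then
    tested against every boundary facet; any crossing makes it
    inadmissible.  ``p_idx == q_idx`` is inadmissible (no self edges).
    """
    if p_idx == q_idx:
        return False
    tri_xyz = vertices[boundary_tris]
    return not _segments_blocked(vertices[p_idx][None], vertices[q_idx][None],
                                 tri_xyz, eps)[0]


# ---------------------------------------------------------------------------
# Visibility graph
# ---------------------------------------------------------------------------

@dataclass
class VisibilityGraph:
    """Undirected line-of-sight connection graph with travel-time weights."""

    n_nodes: int
    edge_i: np.ndarray          # (E,)
    edge_j: np.ndarray          # (E,)
    weights: np.ndarray         # (E,) travel time ms, > 0
    hull_labels: List[str]      # per-edge originating hull / bundle

    @property
    def n_edges(self) -> int:
        return len(self.weights)

    def _deduped(self):
        """Canonical (i, j, w) arrays with parallel edges reduced to min."""
        if not len(self.weights):
            return self.edge_i, self.edge_j, self.weights
        lo = np.minimum(self.edge_i, self.edge_j)
        hi = np.maximum(self.edge_i, self.edge_j)
        key = lo.astype(np.int64) * self.n_nodes + hi
        order = np.lexsort((self.weights, key))
        first = np.ones(len(key), bool)
        first[1:] = key[order][1:] != key[order][:-1]
        sel = order[first]
        return lo[sel], hi[sel], self.weights[sel]

    def to_csr(self) -> sp.csr_matrix:
        i, j, w = self._deduped()
        return sp.coo_matrix(
            (np.concatenate([w, w]),
             (np.concatenate([i, j]), np.concatenate([j, i]))),
            shape=(self.n_nodes, self.n_nodes)).tocsr()

    def to_dense(self) -> np.ndarray:
        i, j, w = self._deduped()
        d = np.full((self.n_nodes, self.n_nodes), np.inf)
        np.fill_diagonal(d, 0.0)
        d[i, j] = w
        d[j, i] = w
        return d


def build_visibility_graph(model: PhantomModel,
                           node_cap: int = DEFAULT_NODE_CAP,
                           eps: float = EPS_SEGMENT) -> VisibilityGraph:
    """Compute direct line-of-sight connections between all mesh nodes.

    For every conducting hull and every node pair within it, an edge with
    weight distance/speed is added iff the segment is admissible.  Bundle
    polylines contribute consecutive edges at bundle speed.  Zero-speed
    hulls contribute no edges.  Duplicate pairs (e.g. interface node pairs
    admissible in two hulls) keep the fastest edge.
    """
    n = model.n_nodes
    if n > node_cap:
        raise SizeError(f"{n} nodes exceeds visibility cap {node_cap}")
    verts = model.vertices
    ei: List[np.ndarray] = []
    ej: List[np.ndarray] = []
    ws: List[np.ndarray] = []
    labels: List[str] = []

    for hid, hull in model.topology.hulls.items():
        speed = hull.tissue.speed
        if speed <= 0:
            continue
        nodes = np.asarray(model.hull_nodes[hid], np.int64)
        if len(nodes) < 2:
            continue
        tri_xyz = verts[model.topology.hull_boundary_triangles(hid)]
        ii, jj = np.triu_indices(len(nodes), k=1)
        pi, pj = nodes[ii], nodes[jj]
        blocked = _segments_blocked(verts[pi], verts[pj], tri_xyz, eps)
        keep = ~blocked
        pi, pj = pi[keep], pj[keep]
        dist = np.linalg.norm(verts[pi] - verts[pj], axis=1)
        pos = dist > 0
        pi, pj, dist = pi[pos], pj[pos], dist[pos]
        ei.append(pi)
        ej.append(pj)
        ws.append(dist / speed)
        labels.extend([hid] * len(pi))

    for bi, bundle in enumerate(model.conduction.bundles):
        nodes = np.asarray(bundle.nodes, np.int64)
        if len(nodes) < 2 or bundle.tissue.speed <= 0:
            continue
        a, b = nodes[:-1], nodes[1:]
        dist = np.linalg.norm(verts[a] - verts[b], axis=1)
        pos = dist > 0
        ei.append(a[pos])
        ej.append(b[pos])
        ws.append(dist[pos] / bundle.tissue.speed)
        labels.extend([f"bundle:{bi}"] * int(pos.sum()))

    if ei:
        i = np.concatenate(ei)
        j = np.concatenate(ej)
        w = np.concatenate(ws)
        lab = np.array(labels, dtype=object)
        lo = np.minimum(i, j)
        hi = np.maximum(i, j)
        key = lo * n + hi
        order = np.lexsort((w, key))
        key_s = key[order]
        first = np.ones(len(key_s), bool)
        first[1:] = key_s[1:] != key_s[:-1]
        sel = order[first]
        i, j, w, lab = lo[sel], hi[sel], w[sel], lab[sel]
    else:
        i = j = np.empty(0, np.int64)
        w = np.empty(0, float)
        lab = np.empty(0, object)
    return VisibilityGraph(n, i, j, w, list(lab))


# ---------------------------------------------------------------------------
# Shortest paths
# ---------------------------------------------------------------------------

def floyd_warshall(dist: np.ndarray) -> np.ndarray:
    """All-pairs shortest paths by the Floyd–Warshall recurrence.

    ``dist`` is a dense (n, n) matrix of direct travel times (+inf where no
    edge, 0 diagonal); returns the shortest-time matrix.
    """
    d = np.array(dist, dtype=float, copy=True)
    n = d.shape[0]
    for k in range(n):
        np.minimum(d, d[:, k, None] + d[None, k, :], out=d)
    return d


def all_pairs_activation(graph: VisibilityGraph,
                         node_cap: int = DEFAULT_NODE_CAP) -> np.ndarray:
    """Shortest travel-time matrix between all node pairs (Floyd–Warshall).

    Unreachable pairs are +inf; the diagonal is 0; the result is symmetric.
    """
    if graph.n_nodes > node_cap:
        raise SizeError(
            f"{graph.n_nodes} nodes exceeds all-pairs cap {node_cap}; "
            "use simulate_activation's single-source mode")
    return floyd_warshall(graph.to_dense())


# ---------------------------------------------------------------------------
# Activation simulation
# ---------------------------------------------------------------------------

@dataclass
class ActivationMap:
    """Per-node activation time (ms); +inf marks blocked/unreachable nodes."""

    times: np.ndarray                  # (n,) ms, +inf when blocked
    activating_source: np.ndarray      # (n,) source index, -1 when blocked
    sources: List[Tuple[int, float]]   # (node id, onset ms)

    @property
    def blocked(self) -> np.ndarray:
        return ~np.isfinite(self.times)

    @property
    def n_nodes(self) -> int:
        return len(self.times)

    def finite_max(self) -> float:
        finite = self.times[np.isfinite(self.times)]
        return float(finite.max()) if len(finite) else 0.0


def simulate_activation(model: PhantomModel,
                        graph: Optional[VisibilityGraph] = None,
                        method: str = "auto",
                        node_cap: int = DEFAULT_NODE_CAP) -> ActivationMap:
    """First-come-first-serve activation times from all sources.

    ``t(node) = min over sources s of (onset(s) + shortest time s -> node)``;
    nodes unreachable from every source are flagged blocked.  Bundle onset
    delays shift the bundle's entry cost.  ``method``: ``"floyd-warshall"``
    (dense reference solver), ``"dijkstra"`` (single-source mode), or
    ``"auto"`` (Floyd–Warshall up to ``node_cap`` nodes).

    Ties between sources resolve to the lowest source index (metadata only).
    """
    sources = model.conduction.sources
    if not sources:
        raise ConfigurationError("conduction system has no sources")
    if graph is None:
        graph = build_visibility_graph(model, node_cap=node_cap)
    src_nodes = np.array([s[0] for s in sources], np.int64)
    onsets = np.array([s[1] for s in sources], float)

    if method == "auto":
        method = "floyd-warshall" if graph.n_nodes <= node_cap else "dijkstra"
    if method == "floyd-warshall":
        tmat = floyd_warshall(graph.to_dense())
        per_source = tmat[src_nodes]
    elif method == "dijkstra":
        per_source = _dijkstra(graph.to_csr(), directed=False,
                               indices=src_nodes)
    else:
        raise ConfigurationError(f"unknown method {method!r}")

    total = per_source + onsets[:, None]
    times = total.min(axis=0)
    who = np.where(np.isfinite(times), total.argmin(axis=0), -1)
    return ActivationMap(times, who, list(sources))


# ---------------------------------------------------------------------------
# Effective-velocity recovery
# ---------------------------------------------------------------------------

def recover_front_velocity(amap: ActivationMap, region_nodes: Sequence[int],
                           vertices: np.ndarray,
                           source: Union[int, Sequence[float]],
                           axis: Optional[Sequence[float]] = None,
                           reference: str = "source",
                           min_nodes: int = 10) -> float:
    """Effective conduction speed (mm/ms) by distance-vs-time regression.

    Least-squares slope of distance from the reference point against
    activation time over the non-blocked nodes of ``region_nodes``.  With
    ``axis`` given, distance is the projection onto that axis.  With
    ``reference="first_activated"`` the first-activated region node serves
    as the spatial and temporal origin (useful inside a lesion where the
    wavefront enters through interface nodes).

    Returns 0.0 when every region node is blocked; raises
    :class:`InsufficiencyError` when 1 <= usable nodes < ``min_nodes``.
    """
    region_nodes = np.asarray(region_nodes, np.int64)
    times = amap.times[region_nodes]
    usable = np.isfinite(times)
    if not usable.any():
        return 0.0
    if usable.sum() < min_nodes:
        raise InsufficiencyError(
            f"only {int(usable.sum())} non-blocked nodes in region "
            f"(need >= {min_nodes})")
    nodes = region_nodes[usable]
    t = amap.times[nodes]

    if reference == "first_activated":
        ref_node = nodes[np.argmin(t)]
        origin = vertices[ref_node]
        t = t - amap.times[ref_node]
    elif isinstance(source, (int, np.integer)):
        origin = vertices[int(source)]
    else:
        origin = np.asarray(source, float).reshape(3)

    delta = vertices[nodes] - origin
    if axis is not None:
        a = np.asarray(axis, float).reshape(3)
        a = a / np.linalg.norm(a)
        dist = delta @ a
    else:
        dist = np.linalg.norm(delta, axis=1)
    if np.ptp(t) == 0:
        return 0.0
    slope = np.polyfit(t, dist, 1)[0]
    return float(slope)


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def write_activation_csv(model: PhantomModel, amap: ActivationMap,
                         path: str) -> None:
    """CSV export: node id, x, y, z, activation time (blank when blocked)."""
    import pandas as pd

    v = model.vertices
    df = pd.DataFrame({
        "node": np.arange(len(v)),
        "x_mm": v[:, 0], "y_mm": v[:, 1], "z_mm": v[:, 2],
        "activation_time_ms": np.where(amap.blocked, np.nan, amap.times),
        "blocked": amap.blocked.astype(int),
    })
    df.to_csv(path, index=False)


def write_activation_vtk(model: PhantomModel, amap: ActivationMap,
                         path: str) -> None:
    """VTK export with point data ``activation_time_ms`` and ``blocked``.

    Blocked nodes carry -1 in the time array (the ``blocked`` byte array is
    authoritative); +inf does not survive many VTK readers.
    """
    from .phantom import _write_vtk

    times = np.where(amap.blocked, -1.0, amap.times)
    _write_vtk(path, model, point_data={
        "activation_time_ms": ("float", times),
        "blocked": ("int", amap.blocked.astype(int)),
    })
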