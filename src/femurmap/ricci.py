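"""Discrete Ricci flow to a flat metric, and planar embedding of the result.

The conformal structure is discrete vertex scaling: each vertex carries a
log factor ``u`` and edge lengths deform as

    l_ij(u) = l_ij(0) * exp((u_i + u_j) / 2).

The flat metric is found by Newton's method on ``u`` driving the discrete
Gaussian curvature ``K`` (angle deficits) to a prescribed target ``Kbar``;
the Jacobian ``dK/du`` is the half-cotangent-weight Laplacian of the
*current* metric, which is symmetric positive semi-definite, so each step
is a sparse SPD solve.  A step-halving line search guards both against
residual increase and against triangle-inequality violations.

Two boundary conditions are supported:

``disk_free_boundary``
    for chi = 1 surfaces: target ``K = 0`` at interior vertices, boundary
    ``u`` held at 0 (the boundary metric is left unchanged).
``annulus_zero``
    for chi = 0, two-boundary surfaces: target ``K = 0`` at *every* vertex
    including the boundaries, which makes both boundary loops geodesic and
    the flat surface a right cylinder.  One vertex is pinned to remove the
    global scale gauge.

The flat metric is realised in the plane by developing the boundary
polygon (integrating metric lengths and turning angles along the loop),
solving the metric's cotangent-Laplace Dirichlet problem for the interior
-- which the exact development satisfies identically -- and polishing with
a few Gauss-Newton passes on the relative edge-length residuals
(:func:`embed_flat`).  The module also provides the surgery needed to
move between topologies: shortest cut graphs, mesh slitting along edge
paths or straight planar segments, strip normalisation and the exponential
map to the annulus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.sparse.csgraph import dijkstra

from .errors import (
    ArgumentError,
    ConvergenceError,
    GeometryError,
    LayoutError,
    TopologyError,
)
from .mesh import TriMesh, corner_angles, discrete_gaussian_curvature, euler_characteristic

__all__ = [
    "RicciMetric",
    "PlanarEmbedding",
    "ricci_flow_metric",
    "embed_disk",
    "embed_flat",
    "transfer_metric",
    "cut_graph",
    "slit_mesh",
    "normalise_strip",
    "exponential_map",
]


@dataclass
class RicciMetric:
    """A conformally deformed metric on a fixed mesh."""

    u: np.ndarray  # per-vertex log conformal factor
    edge_lengths: np.ndarray  # per-unique-edge lengths under the metric (mm)
    target_curvature: np.ndarray  # Kbar, radians (nan where unconstrained)
    achieved_curvature: np.ndarray  # K, radians
    converged: bool
    residual: float  # max |K - Kbar| over constrained vertices
    mode: str
    history: list = field(default_factory=list)  # residual per Newton step


@dataclass
class PlanarEmbedding:
    """A planar (complex) realisation of a mesh with provenance.

    ``z`` holds the complex coordinate of each vertex of ``mesh``;
    ``source_vertex`` maps each vertex back to the original input surface
    (-1 for vertices synthesised by face splits).
    """

    z: np.ndarray  # complex per-vertex coordinates
    domain: Literal["disk", "plane", "strip", "annulus"]
    conformal_factor: np.ndarray  # per-vertex, peaks at protruding features
    mesh: TriMesh  # the (possibly slit) surface being embedded
    source_vertex: np.ndarray  # provenance to the original surface

    @property
    def coords(self) -> np.ndarray:
        return np.column_stack([self.z.real, self.z.imag])

    def signed_areas(self) -> np.ndarray:
        f = self.mesh.faces
        za, zb, zc = self.z[f[:, 0]], self.z[f[:, 1]], self.z[f[:, 2]]
        return 0.5 * np.imag(np.conj(zb - za) * (zc - za))

    def replace(self, **kw) -> "PlanarEmbedding":
        import dataclasses

        return dataclasses.replace(self, **kw)


# ----------------------------------------------------------------------
# the flow
# ----------------------------------------------------------------------

def _lengths(l0: np.ndarray, edges: np.ndarray, u: np.ndarray) -> np.ndarray:
    return l0 * np.exp(0.5 * (u[edges[:, 0]] + u[edges[:, 1]]))


def _triangle_ok(mesh: TriMesh, lengths: np.ndarray) -> bool:
    L = lengths[mesh.face_edges]
    a, b, c = L[:, 0], L[:, 1], L[:, 2]
    return bool(((a + b > c) & (b + c > a) & (c + a > b)).all())


def _cot_laplacian(mesh: TriMesh, lengths: np.ndarray) -> sp.csr_matrix:
    """Half-cotangent-weight Laplacian of the metric: the Jacobian dK/du."""
    angles = corner_angles(mesh, lengths)
    cots = 0.5 / np.tan(angles)  # half-weight per face corner
    n = mesh.n_vertices
    f = mesh.faces
    # corner c contributes cot(angle_c)/2 to the weight of the opposite edge
    rows, cols, vals = [], [], []
    for c in range(3):
        i = f[:, (c + 1) % 3]
        j = f[:, (c + 2) % 3]
        w = cots[:, c]
        rows.extend([i, j, i, j])
        cols.extend([j, i, i, j])
        vals.extend([-w, -w, w, w])
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    vals = np.concatenate(vals)
    return sp.csr_matrix((vals, (rows, cols)), shape=(n, n))


def ricci_flow_metric(
    mesh: TriMesh,
    mode: Literal["disk_free_boundary", "annulus_zero"],
    tolerance: float = 1e-8,
    max_iter: int = 50,
) -> RicciMetric:
    """Flow the mesh metric to the flat target for the given topology.

    Raises :class:`TopologyError` if the mesh has the wrong topology for
    the mode and :class:`ConvergenceError` (carrying the residual history)
    if ``max_iter`` Newton steps do not reach ``tolerance``.
    """
    topo = euler_characteristic(mesh)
    if mode == "disk_free_boundary":
        if topo.chi != 1:
            raise TopologyError(f"disk mode needs chi=1, got {topo}")
    elif mode == "annulus_zero":
        if not (topo.chi == 0 and topo.n_boundaries == 2):
            raise TopologyError(f"annulus mode needs chi=0, b=2, got {topo}")
    else:
        raise ArgumentError(f"unknown mode {mode!r}")

    boundary = mesh.boundary_vertex_mask
    n = mesh.n_vertices
    if mode == "disk_free_boundary":
        free = ~boundary  # boundary u fixed at 0
        constrained = ~boundary  # residual measured at interior only
    else:
        free = np.ones(n, dtype=bool)
        free[0] = False  # pin the scale gauge; K is unaffected by constants
        constrained = np.ones(n, dtype=bool)

    Kbar = np.zeros(n)
    edges = mesh.edges
    l0 = mesh.edge_lengths()
    u = np.zeros(n)
    lengths = l0.copy()
    K = discrete_gaussian_curvature(mesh, lengths)
    residual = float(np.abs((K - Kbar)[constrained]).max())
    history = [residual]
    free_idx = np.flatnonzero(free)

    for _ in range(max_iter):
        if residual <= tolerance:
            break
        H = _cot_laplacian(mesh, lengths)
        Hff = H[free_idx][:, free_idx].tocsc()
        rhs = (Kbar - K)[free_idx]
        try:
            delta = spla.spsolve(Hff, rhs)
        except RuntimeError as exc:  # singular factorisation
            raise ConvergenceError(
                f"Newton system singular: {exc}", history
            ) from exc
        step = 1.0
        du = np.zeros(n)
        du[free_idx] = delta
        for _halving in range(40):
            u_try = u + step * du
            l_try = _lengths(l0, edges, u_try)
            if _triangle_ok(mesh, l_try):
                K_try = discrete_gaussian_curvature(mesh, l_try)
                r_try = float(np.abs((K_try - Kbar)[constrained]).max())
                if r_try < residual:
                    break
            step *= 0.5
        else:
            raise ConvergenceError(
                "line search failed to reduce curvature residual", history
            )
        u, lengths, K, residual = u_try, l_try, K_try, r_try
        history.append(residual)

    converged = residual <= tolerance
    if not converged:
        raise ConvergenceError(
            f"Ricci flow did not reach tolerance {tolerance:g} in "
            f"{max_iter} iterations (residual {residual:g})",
            history,
        )
    target = np.where(constrained, Kbar, np.nan)
    return RicciMetric(
        u=u,
        edge_lengths=lengths,
        target_curvature=target,
        achieved_curvature=K,
        converged=converged,
        residual=residual,
        mode=mode,
        history=history,
    )


# ----------------------------------------------------------------------
# planar layout
# ----------------------------------------------------------------------

def embed_flat(
    mesh: TriMesh,
    metric: RicciMetric,
    domain: str = "plane",
    source_vertex: np.ndarray | None = None,
    check_tol: float = 1e-6,
) -> PlanarEmbedding:
    """Lay out a flat single-boundary metric in the plane.

    The boundary polygon is developed first by integrating the metric's
    boundary edge lengths and turning angles (a short chain, so roundoff
    cannot compound); interior vertices then solve the Dirichlet problem
    for the metric's cotangent Laplacian, which the exact development
    satisfies identically; a few Gauss-Newton passes on relative
    edge-length residuals polish the result to near machine precision.
    Raises :class:`LayoutError` if any face comes out flipped or an edge
    deviates from its metric length by more than ``check_tol`` (relative).
    """
    if not metric.converged:
        raise ArgumentError("metric has not converged; refusing to lay out")
    loops = mesh.boundary_loops()
    if len(loops) != 1:
        raise LayoutError(
            f"planar layout needs exactly one boundary loop, found {len(loops)}"
        )
    loop = loops[0]
    n = mesh.n_vertices
    f = mesh.faces

    # interior angle at every vertex under the metric
    angles = corner_angles(mesh, metric.edge_lengths)
    angle_sum = np.zeros(n)
    np.add.at(angle_sum, f.ravel(), angles.ravel())

    # metric length of each boundary edge, in loop order
    edge_index = {tuple(e): i for i, e in enumerate(mesh.edges.tolist())}
    blen = np.array(
        [
            metric.edge_lengths[
                edge_index[
                    (min(loop[i], loop[(i + 1) % len(loop)]),
                     max(loop[i], loop[(i + 1) % len(loop)]))
                ]
            ]
            for i in range(len(loop))
        ]
    )
    # develop the boundary: walk CCW (interior on the left), turning left
    # by the exterior angle pi - theta at each vertex
    z = np.zeros(n, dtype=complex)
    heading = 1.0 + 0.0j
    pos = 0.0 + 0.0j
    for i in range(len(loop)):
        z[loop[i]] = pos
        pos = pos + heading * blen[i]
        v_next = loop[(i + 1) % len(loop)]
        heading = heading * np.exp(1j * (np.pi - angle_sum[v_next]))

    # interior: Dirichlet solve of the metric cotan Laplacian
    boundary_mask = np.zeros(n, dtype=bool)
    boundary_mask[loop] = True
    interior = np.flatnonzero(~boundary_mask)
    if len(interior):
        Lap = _cot_laplacian(mesh, metric.edge_lengths)
        A_ii = Lap[interior][:, interior].tocsc()
        rhs = -Lap[interior][:, loop] @ z[loop]
        try:
            z[interior] = spla.spsolve(A_ii, rhs)
        except RuntimeError as exc:
            raise LayoutError(f"interior layout solve failed: {exc}") from exc

    z = _polish_layout(mesh, metric.edge_lengths, z, (int(loop[0]), int(loop[1])))

    emb = PlanarEmbedding(
        z=z,
        domain=domain,
        conformal_factor=-metric.u,
        mesh=mesh,
        source_vertex=(
            source_vertex
            if source_vertex is not None
            else np.arange(mesh.n_vertices)
        ),
    )
    areas = emb.signed_areas()
    if (areas <= 0).any():
        bad = int(np.argmin(areas))
        raise LayoutError(f"flipped face in layout (e.g. face {bad})")
    e = mesh.edges
    lv = np.abs(z[e[:, 0]] - z[e[:, 1]])
    rel = np.abs(lv - metric.edge_lengths) / metric.edge_lengths
    if rel.max() > check_tol:
        raise LayoutError(
            f"layout edge-length error {rel.max():.2e} exceeds {check_tol:g}"
        )
    return emb


def _polish_layout(mesh, lengths, z, gauge, n_iter=3):
    """Gauss-Newton on relative edge-length residuals; the gauge pins one
    vertex and the direction of the seed edge."""
    e = mesh.edges
    n = mesh.n_vertices
    E = len(e)
    va, vb = gauge
    best = z.copy()
    best_err = np.inf
    for _ in range(n_iter):
        d = z[e[:, 0]] - z[e[:, 1]]
        dl = np.abs(d)
        g = (dl - lengths) / lengths
        err = np.abs(g).max()
        if err < best_err:
            best, best_err = z.copy(), err
        if err < 1e-12:
            break
        ux = (d.real / dl) / lengths
        uy = (d.imag / dl) / lengths
        rows = np.concatenate([np.arange(E)] * 4)
        cols = np.concatenate(
            [2 * e[:, 0], 2 * e[:, 0] + 1, 2 * e[:, 1], 2 * e[:, 1] + 1]
        )
        vals = np.concatenate([ux, uy, -ux, -uy])
        J = sp.csr_matrix((vals, (rows, cols)), shape=(E, 2 * n))
        pin = [2 * va, 2 * va + 1, 2 * vb + 1]
        mask = np.ones(2 * n, dtype=bool)
        mask[pin] = False
        Jf = J[:, mask].tocsc()
        cn = np.sqrt(np.asarray(Jf.multiply(Jf).sum(axis=0)).ravel())
        cn[cn == 0] = 1.0
        D = sp.diags(1.0 / cn)
        Js = (Jf @ D).tocsc()
        JtJ = (Js.T @ Js + 1e-14 * sp.eye(Js.shape[1])).tocsc()
        try:
            lu = spla.splu(JtJ)
        except RuntimeError:
            break
        dy = lu.solve(Js.T @ (-g))
        delta = np.zeros(2 * n)
        delta[mask] = D @ dy
        z = z + delta[0::2] + 1j * delta[1::2]
    d = z[e[:, 0]] - z[e[:, 1]]
    final = np.abs((np.abs(d) - lengths) / lengths).max()
    return z if final <= best_err else best


def transfer_metric(
    metric: RicciMetric, dst: TriMesh, provenance: np.ndarray
) -> RicciMetric:
    """Carry a converged metric across a mesh slit.

    ``provenance`` maps each vertex of ``dst`` to the mesh the metric was
    computed on; duplicated vertices inherit the original conformal factor,
    so every face of ``dst`` keeps exactly the edge lengths it had before
    the cut.
    """
    if (provenance < 0).any():
        raise ArgumentError("destination mesh has vertices without provenance")
    u = metric.u[provenance]
    e = dst.edges
    lengths = dst.edge_lengths() * np.exp(0.5 * (u[e[:, 0]] + u[e[:, 1]]))
    K = discrete_gaussian_curvature(dst, lengths)
    return RicciMetric(
        u=u,
        edge_lengths=lengths,
        target_curvature=np.zeros(dst.n_vertices),
        achieved_curvature=K,
        converged=metric.converged,
        residual=metric.residual,
        mode=metric.mode,
        history=list(metric.history),
    )


def embed_disk(mesh: TriMesh, metric: RicciMetric, **kw) -> PlanarEmbedding:
    """Planar layout of a disk-topology flat metric (free boundary)."""
    if metric.mode != "disk_free_boundary":
        raise ArgumentError("embed_disk expects a disk_free_boundary metric")
    return embed_flat(mesh, metric, domain="disk", **kw)


# ----------------------------------------------------------------------
# cut graph
# ----------------------------------------------------------------------

def cut_graph(
    mesh: TriMesh,
    from_vertex: int,
    to_boundary: int = 0,
    avoid_other_boundaries: bool = False,
) -> np.ndarray:
    """Shortest edge path (3D lengths, Dijkstra) from a vertex to a boundary.

    ``to_boundary`` is the index of the target loop in
    ``mesh.boundary_loops()``.  Returns the path as an array of vertex ids,
    starting at ``from_vertex`` and ending on the boundary.  With
    ``avoid_other_boundaries`` the path interior is kept strictly interior
    (so the path can later be slit), except for its two endpoints.
    """
    loops = mesh.boundary_loops()
    if to_boundary >= len(loops):
        raise ArgumentError(f"mesh has {len(loops)} boundary loops")
    target = loops[to_boundary]
    if from_vertex in set(target.tolist()):
        raise ArgumentError("from_vertex already lies on the target boundary")
    e = mesh.edges
    w = mesh.edge_lengths()
    n = mesh.n_vertices
    if avoid_other_boundaries:
        allowed = ~mesh.boundary_vertex_mask
        allowed[target] = True
        allowed[from_vertex] = True
        keep = allowed[e[:, 0]] & allowed[e[:, 1]]
        e, w = e[keep], w[keep]
    G = sp.csr_matrix(
        (np.concatenate([w, w]), (np.concatenate([e[:, 0], e[:, 1]]),
                                  np.concatenate([e[:, 1], e[:, 0]]))),
        shape=(n, n),
    )
    dist, pred = dijkstra(
        G, indices=from_vertex, return_predecessors=True, directed=False
    )
    if not np.isfinite(dist[target]).any():
        raise TopologyError("no path to the target boundary (disconnected?)")
    end = int(target[np.argmin(dist[target])])
    path = [end]
    while path[-1] != from_vertex:
        path.append(int(pred[path[-1]]))
    return np.asarray(path[::-1], dtype=np.int64)


# ----------------------------------------------------------------------
# slitting
# ----------------------------------------------------------------------

def slit_mesh(
    mesh: TriMesh,
    path,
    mode: Literal["edge_path", "planar_line"] = "edge_path",
    embedding: PlanarEmbedding | None = None,
):
    """Open the mesh along a path, inserting a new boundary.

    ``edge_path`` mode: ``path`` is a simple vertex path along existing
    edges.  Path-interior vertices are duplicated; an endpoint is also
    duplicated when it lies on an existing boundary (the cut then merges
    into that boundary), while interior endpoints become slit tips.

    ``planar_line`` mode: ``path`` is a pair of vertex ids whose straight
    segment in ``embedding`` defines the slit; crossed edges are first
    split (new vertices interpolate 3D coordinates and fields linearly
    along the crossed edge), then the resulting edge path is slit.

    Returns ``(slit_mesh, provenance, new_path)`` where ``provenance`` maps
    new vertex ids to ids in the input mesh (-1 for synthesised split
    points) and ``new_path`` gives the slit path in new-mesh indices (one
    side of the cut).
    """
    if mode == "planar_line":
        if embedding is None:
            raise ArgumentError("planar_line mode needs the disk embedding")
        refined, prov0, epath = _insert_segment(mesh, embedding, path)
        out, prov1, newpath = _slit_edge_path(refined, epath)
        prov = np.where(prov1 >= 0, prov0[prov1], -1)
        # fix: synthesised vertices (prov0 == -1) must stay -1
        synth = prov1 >= 0
        prov = np.full(len(prov1), -1, dtype=np.int64)
        prov[synth] = prov0[prov1[synth]]
        return out, prov, newpath
    if mode != "edge_path":
        raise ArgumentError(f"unknown slit mode {mode!r}")
    return _slit_edge_path(mesh, np.asarray(path, dtype=np.int64))


def _slit_edge_path(mesh: TriMesh, path: np.ndarray):
    path = np.asarray(path, dtype=np.int64)
    if len(path) < 2:
        raise ArgumentError("slit path needs at least two vertices")
    if len(np.unique(path)) != len(path):
        raise ArgumentError("slit path must be simple")
    eset = {tuple(e) for e in mesh.edges.tolist()}
    for u, v in zip(path[:-1], path[1:]):
        if (min(u, v), max(u, v)) not in eset:
            raise ArgumentError(f"path step ({u}, {v}) is not a mesh edge")
    boundary = mesh.boundary_vertex_mask
    binterior = boundary[path[1:-1]]
    if binterior.any():
        raise GeometryError(
            "slit path touches an existing boundary at an interior position"
        )
    path_edges = {
        (min(u, v), max(u, v)) for u, v in zip(path[:-1], path[1:])
    }
    # vertices to duplicate: path interior + boundary endpoints
    dup = list(path[1:-1])
    for end in (path[0], path[-1]):
        if boundary[end]:
            dup.append(int(end))
    dup_set = set(int(v) for v in dup)

    faces = mesh.faces.copy()
    n = mesh.n_vertices
    new_vertices = [mesh.vertices]
    provenance = list(range(n))
    new_fields = {k: [v] for k, v in mesh.fields.items()}
    dup_of: dict[int, int] = {}

    # incidence: vertex -> faces
    vert_faces: dict[int, list[int]] = {}
    for fi, fv in enumerate(mesh.faces):
        for v in fv:
            vert_faces.setdefault(int(v), []).append(fi)

    for v in dup:
        v = int(v)
        inc = vert_faces[v]
        # union-find over incident faces: join faces sharing a non-cut edge at v
        parent = {fi: fi for fi in inc}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        edge_map: dict[tuple[int, int], list[int]] = {}
        for fi in inc:
            for w in mesh.faces[fi]:
                w = int(w)
                if w == v:
                    continue
                edge_map.setdefault((min(v, w), max(v, w)), []).append(fi)
        for e_key, fl in edge_map.items():
            if e_key in path_edges or len(fl) < 2:
                continue
            r = find(fl[0])
            for other in fl[1:]:
                parent[find(other)] = r
        comps: dict[int, list[int]] = {}
        for fi in inc:
            comps.setdefault(find(fi), []).append(fi)
        if len(comps) != 2:
            raise GeometryError(
                f"slit at vertex {v} does not separate its star "
                f"({len(comps)} components)"
            )
        # keep v in the first component (deterministic: smallest face id),
        # re-point the second to a duplicate
        keys = sorted(comps, key=lambda k: min(comps[k]))
        new_id = n + len(dup_of)
        dup_of[v] = new_id
        provenance.append(v)
        new_vertices.append(mesh.vertices[v][None])
        for k in new_fields:
            new_fields[k].append(np.atleast_1d(mesh.fields[k][v]))
        for fi in comps[keys[1]]:
            faces[fi] = np.where(mesh.faces[fi] == v, new_id, faces[fi])

    out = TriMesh(
        np.vstack(new_vertices),
        faces,
        {k: np.concatenate(v) for k, v in new_fields.items()},
    )
    out.validate()
    return out, np.asarray(provenance, dtype=np.int64), path.copy()


def _insert_segment(mesh: TriMesh, emb: PlanarEmbedding, endpoints):
    """Split faces crossed by the straight planar segment between two
    vertices; returns (refined mesh, provenance, edge path of the segment).
    """
    p_id, q_id = int(endpoints[0]), int(endpoints[1])
    boundary = mesh.boundary_vertex_mask
    if boundary[p_id] or boundary[q_id]:
        raise GeometryError("segment endpoints must be interior vertices")
    zp, zq = emb.z[p_id], emb.z[q_id]
    seg = zq - zp
    seglen = abs(seg)
    if seglen == 0:
        raise ArgumentError("degenerate segment")
    snap = 1e-9 * seglen

    e = mesh.edges
    za, zb = emb.z[e[:, 0]], emb.z[e[:, 1]]
    # solve zp + s*seg = za + t*(zb - za) for s, t
    d = zb - za
    denom = np.imag(np.conj(seg) * d)
    # edges nearly collinear with the segment have an ill-conditioned
    # intersection (garbage s, t); their endpoints, if on the segment, are
    # picked up as vertex events through the transversal edges instead
    ok = np.abs(denom) > 1e-9 * seglen * np.abs(d)
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.where(ok, np.imag(np.conj(d) * (za - zp)) / -denom, np.nan)
        t = np.where(ok, np.imag(np.conj(seg) * (za - zp)) / -denom, np.nan)
    eps = 1e-12
    crossing = (
        np.isfinite(s) & (s > eps) & (s < 1 - eps) & (t > -eps) & (t < 1 + eps)
    )

    events: list[tuple[float, str, int, float]] = [(0.0, "v", p_id, 0.0)]
    used_vertices = {p_id, q_id}
    for ei in np.flatnonzero(crossing):
        ti = float(np.clip(t[ei], 0.0, 1.0))
        point = za[ei] + ti * d[ei]
        # snap to an endpoint vertex of the edge if essentially through it
        if abs(point - za[ei]) < snap:
            vid = int(e[ei, 0])
            if vid not in used_vertices:
                events.append((float(s[ei]), "v", vid, 0.0))
                used_vertices.add(vid)
            continue
        if abs(point - zb[ei]) < snap:
            vid = int(e[ei, 1])
            if vid not in used_vertices:
                events.append((float(s[ei]), "v", vid, 0.0))
                used_vertices.add(vid)
            continue
        events.append((float(s[ei]), "e", int(ei), ti))
    events.append((1.0, "v", q_id, 0.0))
    events.sort(key=lambda x: x[0])

    if boundary[[v for _, kind, v, _ in events if kind == "v"]].any():
        raise GeometryError("segment leaves the interior of the domain")
    crossed_edges = [ev for ev in events if ev[1] == "e"]
    for _, _, ei, _ in crossed_edges:
        if mesh.edge_face_count[ei] == 1:
            raise GeometryError("segment crosses a boundary edge")

    # new vertices for edge events
    n = mesh.n_vertices
    new_pts_3d, new_z, new_field_vals = [], [], {k: [] for k in mesh.fields}
    edge_point_id: dict[int, int] = {}
    for s_i, kind, ei, ti in crossed_edges:
        vid = n + len(new_pts_3d)
        edge_point_id[ei] = vid
        va, vb = e[ei]
        new_pts_3d.append((1 - ti) * mesh.vertices[va] + ti * mesh.vertices[vb])
        new_z.append((1 - ti) * emb.z[va] + ti * emb.z[vb])
        for k in mesh.fields:
            new_field_vals[k].append(
                (1 - ti) * mesh.fields[k][va] + ti * mesh.fields[k][vb]
            )

    # rebuild faces with splits
    out_faces = []
    for fi, fv in enumerate(mesh.faces):
        pts = []  # (corner edge slot, edge id)
        for c in range(3):
            ei = int(mesh.face_edges[fi][c])  # edge opposite corner c
            if ei in edge_point_id:
                pts.append((c, ei))
        if not pts:
            out_faces.append(tuple(fv))
        elif len(pts) == 1:
            c, ei = pts[0]
            a, b = fv[(c + 1) % 3], fv[(c + 2) % 3]
            p = edge_point_id[ei]
            cc = fv[c]
            out_faces.append((a, p, cc))
            out_faces.append((p, b, cc))
        else:  # two split edges
            (c1, e1), (c2, e2) = pts
            p1, p2 = edge_point_id[e1], edge_point_id[e2]
            # shared vertex of the two edges is the corner not in {c1, c2}
            shared = fv[3 - c1 - c2]
            # relabel: triangle (A, B, C) with B = shared, p on AB? work in
            # cyclic order: find corners a, b such that edge1 = (x, shared),
            # edge2 = (shared, y)
            others = [fv[c1], fv[c2]]  # corners opposite the split edges
            # edge opposite c1 joins the other two corners
            # quad split keeping orientation: walk the original cycle
            cyc = [int(fv[0]), int(fv[1]), int(fv[2])]
            si = cyc.index(int(shared))
            prev_v = cyc[(si + 2) % 3]
            next_v = cyc[(si + 1) % 3]
            # edge (shared, next_v) is opposite corner prev; which split
            # point lies on it?
            ei_next = int(mesh.face_edges[fi][cyc.index(prev_v)])
            ei_prev = int(mesh.face_edges[fi][cyc.index(next_v)])
            pn = edge_point_id.get(ei_next)
            pp = edge_point_id.get(ei_prev)
            if pn is None or pp is None:
                raise GeometryError("inconsistent face split")
            # original cycle: prev_v -> shared -> next_v; points: pp on
            # (prev_v, shared), pn on (shared, next_v)
            out_faces.append((pp, int(shared), pn))
            out_faces.append((int(prev_v), pp, pn))
            out_faces.append((int(prev_v), pn, int(next_v)))

    vertices = (
        np.vstack([mesh.vertices] + [np.asarray(p)[None] for p in new_pts_3d])
        if new_pts_3d
        else mesh.vertices.copy()
    )
    fields = {
        k: np.concatenate([mesh.fields[k], np.asarray(new_field_vals[k])])
        if new_pts_3d
        else mesh.fields[k].copy()
        for k in mesh.fields
    }
    refined = TriMesh(vertices, np.asarray(out_faces, dtype=np.int64), fields)
    refined.validate()
    provenance = np.concatenate(
        [np.arange(n), np.full(len(new_pts_3d), -1)]
    ).astype(np.int64)

    epath = []
    for s_i, kind, idx, ti in events:
        epath.append(idx if kind == "v" else edge_point_id[idx])
    # sanity: consecutive points must share an edge in the refined mesh
    eset = {tuple(x) for x in refined.edges.tolist()}
    for u_, v_ in zip(epath[:-1], epath[1:]):
        if (min(u_, v_), max(u_, v_)) not in eset:
            raise GeometryError("segment insertion produced a broken path")
    return refined, provenance, np.asarray(epath, dtype=np.int64)


# ----------------------------------------------------------------------
# strip normalisation and exponential map
# ----------------------------------------------------------------------

def normalise_strip(
    embedding: PlanarEmbedding,
    slit_vertices: np.ndarray,
    distal_vertices: np.ndarray | None = None,
    tol: float = 1e-6,
) -> PlanarEmbedding:
    """Similarity transform placing the slit boundary on the imaginary axis
    spanning exactly [0, 2*pi], with the domain at non-positive real parts.

    ``slit_vertices`` must be ordered along the slit (first and last entries
    are its endpoints).  Raises :class:`GeometryError` if the slit is not
    straight, or the distal boundary not parallel to it, within ``tol``
    (relative to the slit length).
    """
    slit_vertices = np.asarray(slit_vertices, dtype=np.int64)
    z = embedding.z
    a, b = z[slit_vertices[0]], z[slit_vertices[-1]]
    length = abs(b - a)
    if length == 0:
        raise GeometryError("slit endpoints coincide")
    # collinearity of the slit
    rel = np.imag((z[slit_vertices] - a) / (b - a))
    if np.abs(rel).max() > tol:
        raise GeometryError(
            f"slit boundary is not straight (deviation {np.abs(rel).max():.2e})"
        )
    w = 2j * np.pi * (z - a) / (b - a)
    # domain must lie at real <= 0; otherwise map from the other endpoint
    interior = ~embedding.mesh.boundary_vertex_mask
    ref = w[interior] if interior.any() else w
    if np.median(ref.real) > 0:
        w = 2j * np.pi * (z - b) / (a - b)
    if distal_vertices is not None:
        dv = np.asarray(distal_vertices, dtype=np.int64)
        spread = np.ptp(w[dv].real)
        if spread > tol * 2 * np.pi:
            raise GeometryError(
                f"distal boundary not parallel to the slit (spread {spread:.2e})"
            )
    out = embedding.replace(z=w, domain="strip")
    if (out.signed_areas() <= 0).any():
        raise LayoutError("strip normalisation flipped a face")
    return out


def exponential_map(strip: PlanarEmbedding) -> PlanarEmbedding:
    """Map the normalised strip to the annulus via ``z -> exp(z)``.

    The slit boundary (real part 0) maps onto the unit circle; the distal
    boundary maps to an inner circle of radius ``exp(min real part)``.
    """
    if strip.domain != "strip":
        raise ArgumentError("exponential_map expects a normalised strip")
    return strip.replace(z=np.exp(strip.z), domain="annulus")
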