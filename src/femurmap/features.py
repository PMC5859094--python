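"""Feature detection on conformal-factor fields.

Protruding processes of the femur (femoral head FH, greater trochanter GT,
lesser trochanter LT) concentrate surface area, so the conformal factor of
a flattening map peaks over them.  Peaks are found as 1-ring local maxima
of the per-vertex conformal factor and ranked by topographic prominence
computed by watershed flooding (descending sweep with union-find); the two
most prominent interior peaks of the disk parametrisation are FH and GT,
and the most prominent remaining peak of the annulus parametrisation is
LT.  Each feature's footprint is summarised by an anisotropic 2D Gaussian
fitted over the peak's watershed basin; its 1-sigma Mahalanobis ellipse
defines the support node set used by the correspondence stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .errors import ArgumentError, DetectionError, FitError
from .ricci import PlanarEmbedding

__all__ = [
    "FeaturePoint",
    "FeatureRegion",
    "peak_prominences",
    "detect_disk_features",
    "detect_lt",
    "fit_feature_region",
    "inter_feature_segment",
]


@dataclass
class FeaturePoint:
    vertex: int  # id on the embedding's mesh
    source: int  # id on the original surface (-1 if synthesised)
    z: complex  # planar position
    label: str  # "FH" | "GT" | "LT"
    value: float  # conformal factor at the peak


@dataclass
class FeatureRegion:
    point: FeaturePoint
    centre: np.ndarray  # (2,) fitted Gaussian centre
    cov: np.ndarray  # (2, 2) fitted covariance
    amplitude: float
    offset: float
    support: np.ndarray  # vertex ids with Mahalanobis distance <= 1
    basin: np.ndarray | None = None  # the peak's full watershed catchment

    @property
    def support_area(self) -> float:
        """Area of the 1-sigma ellipse (pi * sqrt(det cov))."""
        return float(np.pi * np.sqrt(max(np.linalg.det(self.cov), 0.0)))


def peak_prominences(mesh, height: np.ndarray):
    """Local maxima of a vertex field with watershed prominence.

    Vertices are swept in descending field order; each starts or joins a
    component (union-find).  When a vertex bridges two components the lower
    peak's prominence is fixed as its height above the bridging saddle.
    Returns ``(peaks, prominence, basin)`` where ``basin[v]`` is the peak
    whose catchment first claimed vertex ``v``.  Deterministic: ties break
    on vertex index.
    """
    n = mesh.n_vertices
    neigh = mesh.vertex_neighbors()
    order = np.lexsort((np.arange(n), -height))
    parent = np.full(n, -1, dtype=np.int64)
    comp_peak = {}
    prominence: dict[int, float] = {}
    basin = np.full(n, -1, dtype=np.int64)

    def find(x):
        root = x
        while parent[root] != root:
            root = parent[root]
        while parent[x] != root:
            parent[x], x = root, parent[x]
        return root

    processed = np.zeros(n, dtype=bool)
    for v in order:
        roots = []
        for w in neigh[v]:
            if processed[w]:
                r = find(w)
                if r not in roots:
                    roots.append(r)
        if not roots:
            parent[v] = v
            comp_peak[v] = v
            basin[v] = v
        else:
            # join the component with the highest peak; deterministic ties
            roots.sort(key=lambda r: (-height[comp_peak[r]], comp_peak[r]))
            main = roots[0]
            parent[v] = main
            basin[v] = comp_peak[main]
            for r in roots[1:]:
                pk = comp_peak[r]
                prominence[pk] = float(height[pk] - height[v])
                parent[r] = main
        processed[v] = True
    # the global maximum never merges: full relief
    top = int(order[0])
    prominence.setdefault(top, float(height[top] - height.min()))
    peaks = np.asarray(sorted(prominence, key=lambda p: (-prominence[p], p)))
    return peaks, prominence, basin


def detect_disk_features(
    disk: PlanarEmbedding, min_prominence: float = 0.25
) -> tuple[FeaturePoint, FeaturePoint]:
    """Detect FH and GT as the two most prominent interior conformal-factor
    peaks of the disk parametrisation.

    FH is the peak with the higher conformal factor (the femoral head is
    the dominant process and concentrates the most area).  Raises
    :class:`DetectionError` when fewer than two sufficiently prominent
    interior peaks exist.
    """
    cf = disk.conformal_factor
    boundary = disk.mesh.boundary_vertex_mask
    peaks, prom, _basin = peak_prominences(disk.mesh, cf)
    good = [
        int(p) for p in peaks if not boundary[p] and prom[int(p)] >= min_prominence
    ]
    if len(good) < 2:
        raise DetectionError(
            f"expected two prominent interior peaks, found {len(good)} "
            f"(prominences: { {int(p): round(prom[int(p)], 3) for p in peaks[:5]} })"
        )
    a, b = good[0], good[1]
    # FH: dominant (higher) conformal-factor peak
    fh_v, gt_v = (a, b) if cf[a] >= cf[b] else (b, a)
    src = disk.source_vertex
    fh = FeaturePoint(fh_v, int(src[fh_v]), complex(disk.z[fh_v]), "FH", float(cf[fh_v]))
    gt = FeaturePoint(gt_v, int(src[gt_v]), complex(disk.z[gt_v]), "GT", float(cf[gt_v]))
    return fh, gt


def detect_lt(
    annulus: PlanarEmbedding,
    exclusion: list[FeatureRegion] | tuple[FeatureRegion, ...] = (),
    min_prominence: float = 0.1,
    boundary_collar: float = 1.25,
) -> FeaturePoint:
    """Detect LT on the annulus parametrisation.

    Two exclusion zones remove the FH/GT processes: (a) the 1-sigma
    supports of the given disk-frame feature regions (plus one ring), and
    (b) the *conformal collar* of the slit boundary -- vertices with
    ``log|z| > -boundary_collar``.  On the annulus, ``log|z|`` measures
    conformal depth below the FH-GT slit in circumference-normalised
    units (the slit is scaled to 2*pi), so the head and trochanter, which
    hug the slit however much 3D area they carry, always land in a collar
    of order-one depth, while the lesser trochanter sits several units
    deeper.  Returns the most prominent remaining interior peak; raises
    :class:`DetectionError` if none remains.
    """
    cf = annulus.conformal_factor
    mesh = annulus.mesh
    boundary = mesh.boundary_vertex_mask
    excluded_src: set[int] = set()
    for region in exclusion:
        excluded_src.update(int(s) for s in np.asarray(region.support))
        excluded_src.add(int(region.point.source))
    src = annulus.source_vertex
    excluded = np.array(
        [int(s) in excluded_src for s in src], dtype=bool
    )
    with np.errstate(divide="ignore"):
        depth = -np.log(np.maximum(np.abs(annulus.z), 1e-300))
    excluded |= depth < boundary_collar
    # grow by one ring so ridge vertices adjacent to a region are excluded
    neigh = mesh.vertex_neighbors()
    grown = excluded.copy()
    for v in np.flatnonzero(excluded):
        grown[neigh[v]] = True
    peaks, prom, _ = peak_prominences(mesh, cf)
    for p in peaks:
        p = int(p)
        if boundary[p] or grown[p] or prom[p] < min_prominence:
            continue
        return FeaturePoint(
            p, int(src[p]), complex(annulus.z[p]), "LT", float(cf[p])
        )
    raise DetectionError(
        "no prominent conformal-factor peak outside the FH/GT regions"
    )


def fit_feature_region(
    embedding: PlanarEmbedding,
    peak: FeaturePoint,
    field: np.ndarray | None = None,
    min_basin: int = 12,
) -> FeatureRegion:
    """Least-squares fit of an anisotropic 2D Gaussian around a peak.

    The model is ``offset + A * exp(-(p - mu)^T P (p - mu) / 2)`` fitted
    over the peak's watershed basin (grown to at least ``min_basin``
    vertices), with the precision matrix ``P`` parameterised by its
    Cholesky factor so the fit stays positive definite.  The support set
    is every vertex within Mahalanobis distance 1 of the fitted centre.
    """
    h = embedding.conformal_factor if field is None else np.asarray(field)
    mesh = embedding.mesh
    _, _, basin = peak_prominences(mesh, h)
    sel = np.flatnonzero(basin == peak.vertex)
    if len(sel) == 0:
        raise FitError(f"vertex {peak.vertex} is not a watershed peak")
    neigh = mesh.vertex_neighbors()
    grow_guard = 0
    while len(sel) < min_basin and grow_guard < 5:
        grown = set(sel.tolist())
        for v in sel:
            grown.update(int(w) for w in neigh[v])
        sel = np.asarray(sorted(grown), dtype=np.int64)
        grow_guard += 1

    pts = embedding.coords[sel]
    vals = h[sel]
    offset0 = float(vals.min())
    amp0 = float(h[peak.vertex] - offset0)
    if amp0 <= 0:
        raise FitError("degenerate fit: peak has zero amplitude")
    w = np.maximum(vals - offset0, 0.0)
    wsum = w.sum()
    mu0 = (
        (w[:, None] * pts).sum(axis=0) / wsum
        if wsum > 0
        else np.array([peak.z.real, peak.z.imag])
    )
    d = pts - mu0
    cov0 = (w[:, None, None] * (d[:, :, None] * d[:, None, :])).sum(axis=0)
    cov0 = cov0 / max(wsum, 1e-300) + 1e-12 * np.eye(2) * max(
        np.abs(pts).max() ** 2, 1e-12
    )
    try:
        P0 = np.linalg.inv(cov0)
        Lc = np.linalg.cholesky(P0)
    except np.linalg.LinAlgError as exc:
        raise FitError(f"singular covariance in region fit: {exc}") from exc

    def model(p):
        mux, muy, l11, l21, l22, amp, off = p
        dx = pts[:, 0] - mux
        dy = pts[:, 1] - muy
        # q = |L^T d|^2 with L lower-triangular Cholesky of the precision
        q = (l11 * dx + l21 * dy) ** 2 + (l22 * dy) ** 2
        return off + amp * np.exp(-0.5 * q)

    p0 = np.array([mu0[0], mu0[1], Lc[0, 0], Lc[1, 0], Lc[1, 1], amp0, offset0])
    res = least_squares(lambda p: model(p) - vals, p0, method="lm", xtol=1e-14)
    mux, muy, l11, l21, l22, amp, off = res.x
    if abs(amp) < 1e-12 or abs(l11) < 1e-12 or abs(l22) < 1e-12:
        raise FitError("degenerate Gaussian fit (vanishing amplitude/width)")
    Lfit = np.array([[l11, 0.0], [l21, l22]])
    P = Lfit @ Lfit.T
    cov = np.linalg.inv(P)
    centre = np.array([mux, muy])
    allpts = embedding.coords - centre
    maha2 = (
        P[0, 0] * allpts[:, 0] ** 2
        + 2 * P[0, 1] * allpts[:, 0] * allpts[:, 1]
        + P[1, 1] * allpts[:, 1] ** 2
    )
    support = np.flatnonzero(maha2 <= 1.0)
    return FeatureRegion(
        point=peak,
        centre=centre,
        cov=cov,
        amplitude=float(amp),
        offset=float(off),
        support=support,
        basin=np.flatnonzero(basin == peak.vertex),
    )


def inter_feature_segment(
    disk: PlanarEmbedding, fh: FeaturePoint, gt: FeaturePoint
) -> tuple[int, int]:
    """The straight slit segment between the FH and GT feature vertices,
    as the vertex pair consumed by ``slit_mesh(..., mode="planar_line")``."""
    boundary = disk.mesh.boundary_vertex_mask
    if boundary[fh.vertex] or boundary[gt.vertex]:
        raise ArgumentError("feature points must be interior to the disk")
    return (fh.vertex, gt.vertex)
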