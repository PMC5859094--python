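"""Template matching in the parametric plane and dense resampling.

All subjects are parametrised into a common normalised strip frame, where
conformal invariance has already absorbed rigid motion, scale and
isometric bending.  Residual (anisometric) misalignment is corrected
locally: the template's FH and LT feature regions are deformed onto the
target's regions (translation plus anisotropic scaling along the
template's principal axes; the strip frame fixes orientation, so no
rotation) and the displacements are interpolated smoothly with
compactly-supported Wendland C2 radial basis functions.  Template nodes
then receive a *natural representation* on the target mesh — containing
face plus barycentric weights — from which 3D coordinates and per-node
scalar fields are resampled, producing an isotopological surface set
(one shared connectivity, per-subject geometry and features).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import matplotlib.tri as mtri
import numpy as np

from .errors import ArgumentError, GeometryError, SolverError
from .features import FeatureRegion
from .ricci import PlanarEmbedding

__all__ = [
    "Template2D",
    "CorrespondenceMap",
    "RBFDeformation",
    "IsotopologicalSet",
    "build_template",
    "build_rbf",
    "natural_representation",
    "resample",
    "build_isotopological_set",
]


@dataclass
class Template2D:
    """Canonical 2D template: a cropped strip-frame mesh with feature regions."""

    coords: np.ndarray  # (N_t, 2) strip coordinates
    faces: np.ndarray  # (M_t, 3)
    fh_region: FeatureRegion
    lt_region: FeatureRegion
    distal_limit: float  # most negative real coordinate retained


@dataclass
class CorrespondenceMap:
    face_id: np.ndarray  # (N_t,) containing face on the target
    bary: np.ndarray  # (N_t, 3) barycentric weights, >= 0, rows sum to 1
    clamped: np.ndarray  # (N_t,) flag: node fell outside the target domain


@dataclass
class RBFDeformation:
    """Wendland-C2 interpolant of 2D control displacements.

    The kernel ``phi(r) = (1 - r/rho)^4 (4 r/rho + 1)`` vanishes with two
    continuous derivatives at ``r = rho``; with no polynomial term the
    deformation is identically zero beyond distance ``rho`` from every
    control point.
    """

    centres: np.ndarray  # (K, 2)
    displacements: np.ndarray  # (K, 2)
    rho: float
    coeffs: np.ndarray = field(init=False)

    def __post_init__(self):
        K = _wendland(_pairwise(self.centres, self.centres), self.rho)
        try:
            self.coeffs = np.linalg.solve(K, self.displacements)
        except np.linalg.LinAlgError as exc:
            raise SolverError(
                f"RBF kernel matrix is singular; try a larger support "
                f"radius than rho={self.rho:g}"
            ) from exc
        cond = np.linalg.cond(K)
        if cond > 1e12:
            raise SolverError(
                f"RBF kernel matrix ill-conditioned (cond={cond:.1e}); "
                f"try a larger support radius than rho={self.rho:g}"
            )

    def __call__(self, points: np.ndarray) -> np.ndarray:
        """Displacement at each query point (zero beyond the support)."""
        points = np.atleast_2d(points)
        return _wendland(_pairwise(points, self.centres), self.rho) @ self.coeffs


@dataclass
class IsotopologicalSet:
    """Surfaces sharing the template connectivity."""

    faces: np.ndarray  # (M_t, 3) template connectivity
    coords: np.ndarray  # (S, N_t, 3) per-subject resampled coordinates (mm)
    fields: dict[str, np.ndarray]  # name -> (S, N_t)
    subject_ids: list[str]
    clamped: np.ndarray  # (S, N_t) bool
    template: Template2D | None = None

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_nodes(self) -> int:
        return self.coords.shape[1]

    def valid_nodes(self) -> np.ndarray:
        """Nodes never clamped in any subject (default analysis set)."""
        return ~self.clamped.any(axis=0)


def _pairwise(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return np.linalg.norm(a[:, None, :] - b[None, :, :], axis=2)


def _wendland(r: np.ndarray, rho: float) -> np.ndarray:
    q = np.clip(r / rho, 0.0, 1.0)
    return (1.0 - q) ** 4 * (4.0 * q + 1.0)


# ----------------------------------------------------------------------
# template construction
# ----------------------------------------------------------------------

def build_template(
    strip: PlanarEmbedding,
    fh_region: FeatureRegion,
    lt_region: FeatureRegion,
    distal_limit: float | None = None,
) -> Template2D:
    """Crop a reference subject's strip mesh into the canonical template.

    Faces whose vertices all satisfy ``Re(z) >= distal_limit`` are kept
    (default: 95% of the reference's own distal extent), then vertices are
    re-indexed compactly.  The feature regions must be fitted in the strip
    frame of the same embedding.
    """
    z = strip.z
    if distal_limit is None:
        distal_limit = 0.95 * float(z.real.min())
    keep_face = (z.real[strip.mesh.faces] >= distal_limit).all(axis=1)
    faces = strip.mesh.faces[keep_face]
    used = np.unique(faces)
    remap = -np.ones(len(z), dtype=np.int64)
    remap[used] = np.arange(len(used))
    coords = np.column_stack([z.real[used], z.imag[used]])

    def remap_region(region: FeatureRegion) -> FeatureRegion:
        supp = remap[np.asarray(region.support, dtype=np.int64)]
        return FeatureRegion(
            point=region.point,
            centre=region.centre.copy(),
            cov=region.cov.copy(),
            amplitude=region.amplitude,
            offset=region.offset,
            support=supp[supp >= 0],
        )

    return Template2D(
        coords=coords,
        faces=remap[faces],
        fh_region=remap_region(fh_region),
        lt_region=remap_region(lt_region),
        distal_limit=float(distal_limit),
    )


# ----------------------------------------------------------------------
# RBF feature-region matching
# ----------------------------------------------------------------------

def _region_control_points(src: FeatureRegion, dst: FeatureRegion, n_ring: int = 8):
    """Controls mapping the source centre/1-sigma ellipse onto the target's.

    The map is ``x -> mu_dst + A (x - mu_src)`` with ``A`` symmetric
    positive definite: anisotropic scaling along the source region's
    principal axes (no rotation — the strip frame already fixes
    orientation).
    """
    evals, evecs = np.linalg.eigh(src.cov)
    if (evals <= 0).any():
        raise ArgumentError("degenerate source region covariance")
    # variance of the target along the source's principal axes
    tvar = np.einsum("ij,jk,ik->i", evecs.T, dst.cov, evecs.T)
    scale = np.sqrt(np.maximum(tvar, 1e-300) / evals)
    A = evecs @ np.diag(scale) @ evecs.T
    theta = 2 * np.pi * np.arange(n_ring) / n_ring
    ring = (evecs @ np.diag(np.sqrt(evals)) @ np.vstack([np.cos(theta), np.sin(theta)])).T
    pts = np.vstack([[0.0, 0.0], ring]) + src.centre
    dsts = (pts - src.centre) @ A.T + dst.centre
    return pts, dsts - pts


def build_rbf(
    template_regions: tuple[FeatureRegion, FeatureRegion],
    target_regions: tuple[FeatureRegion, FeatureRegion],
    rho: float | None = None,
) -> RBFDeformation:
    """Wendland deformation driven by the FH and LT region matches.

    ``rho`` defaults to twice the largest 1-sigma radius among the fitted
    regions.
    """
    centres, disps = [], []
    sigmas = []
    for src, dst in zip(template_regions, target_regions):
        pts, d = _region_control_points(src, dst)
        centres.append(pts)
        disps.append(d)
        sigmas.append(np.sqrt(np.linalg.eigvalsh(src.cov).max()))
        sigmas.append(np.sqrt(np.linalg.eigvalsh(dst.cov).max()))
    if rho is None:
        rho = 2.0 * float(max(sigmas))
    return RBFDeformation(
        centres=np.vstack(centres), displacements=np.vstack(disps), rho=float(rho)
    )


# ----------------------------------------------------------------------
# natural representation and resampling
# ----------------------------------------------------------------------

def _bary_batch(p: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Barycentric coordinates of points in their 2D triangles.

    ``p`` is (K, 2); ``tri`` is (K, 3, 2).  Degenerate triangles give nan.
    """
    v0 = tri[:, 1] - tri[:, 0]
    v1 = tri[:, 2] - tri[:, 0]
    d = p - tri[:, 0]
    det = v0[:, 0] * v1[:, 1] - v0[:, 1] * v1[:, 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        l1 = (d[:, 0] * v1[:, 1] - d[:, 1] * v1[:, 0]) / det
        l2 = (v0[:, 0] * d[:, 1] - v0[:, 1] * d[:, 0]) / det
    return np.column_stack([1.0 - l1 - l2, l1, l2])


def natural_representation(
    points: np.ndarray,
    target: PlanarEmbedding,
) -> CorrespondenceMap:
    """Locate 2D points on the target's planar triangulation.

    Containing faces are found with a trapezoid-map point locator; a point
    landing on a shared edge or vertex is assigned to the lowest-index
    containing face.  Points outside the domain are clamped to the nearest
    boundary point of the nearest face and flagged.
    """
    areas = target.signed_areas()
    if (areas <= 0).any():
        raise GeometryError("target embedding has flipped faces")
    pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
    tx, ty = target.z.real, target.z.imag
    faces = target.mesh.faces
    tri = mtri.Triangulation(tx, ty, triangles=faces)
    finder = tri.get_trifinder()
    fid = np.asarray(finder(pts[:, 0], pts[:, 1]), dtype=np.int64)

    n = len(pts)
    bary = np.zeros((n, 3))
    clamped = np.zeros(n, dtype=bool)
    coords2 = np.column_stack([tx, ty])

    inside = fid >= 0
    if inside.any():
        w = _bary_batch(pts[inside], coords2[faces[fid[inside]]])
        bad = ~np.isfinite(w).all(axis=1)
        w = np.clip(w, 0.0, None)
        w = w / w.sum(axis=1, keepdims=True)
        bary[inside] = w
        ii = np.flatnonzero(inside)
        fid[ii[bad]] = -1

    # lowest-index containing face for points on shared edges/vertices
    eps = 1e-12
    on_edge = inside.copy()
    on_edge[inside] = (bary[inside] <= eps).any(axis=1)
    if on_edge.any():
        vert_faces: dict[int, list[int]] = {}
        for k, fv in enumerate(faces):
            for v in fv:
                vert_faces.setdefault(int(v), []).append(k)
        for i in np.flatnonzero(on_edge):
            cands = set()
            for c in range(3):
                if bary[i, c] > eps:
                    cands.update(vert_faces[int(faces[fid[i], c])])
            for k in sorted(cands):
                wk = _bary_batch(pts[i][None], coords2[faces[k]][None])[0]
                if np.isfinite(wk).all() and (wk >= -1e-9).all():
                    fid[i] = k
                    wk = np.clip(wk, 0.0, None)
                    bary[i] = wk / wk.sum()
                    break

    outside = np.flatnonzero(fid < 0)
    if len(outside):
        # clamp to the nearest point of the nearest face (exact, vectorised
        # over all faces via the 3D point-triangle kernel with z = 0)
        from .mesh import _closest_point_on_triangles

        p3 = np.column_stack([pts[outside], np.zeros(len(outside))])
        a3 = np.column_stack([coords2[faces[:, 0]], np.zeros(len(faces))])
        b3 = np.column_stack([coords2[faces[:, 1]], np.zeros(len(faces))])
        c3 = np.column_stack([coords2[faces[:, 2]], np.zeros(len(faces))])
        # points within roundoff of the domain boundary are hull hits the
        # point locator missed, not genuine out-of-domain nodes
        diag = np.hypot(np.ptp(tx), np.ptp(ty))
        tol = 1e-9 * max(diag, 1e-300)
        for s in range(0, len(outside), 128):
            blk = slice(s, min(s + 128, len(outside)))
            d2, wb = _closest_point_on_triangles(
                p3[blk], a3, b3, c3, return_bary=True
            )
            k = np.argmin(d2, axis=1)
            rows = np.arange(len(k))
            idx = outside[blk]
            fid[idx] = k
            w = np.clip(wb[rows, k], 0.0, None)
            bary[idx] = w / w.sum(axis=1, keepdims=True)
            clamped[idx] = np.sqrt(d2[rows, k]) > tol
    return CorrespondenceMap(face_id=fid, bary=bary, clamped=clamped)


def resample(
    cmap: CorrespondenceMap,
    target: PlanarEmbedding,
    field_names: tuple[str, ...] | None = None,
):
    """Barycentric resampling of 3D coordinates and per-node fields.

    Exactly reproduces any field that is affine in the strip coordinates
    (linear precision of barycentric interpolation).
    """
    mesh = target.mesh
    fv = mesh.faces[cmap.face_id]  # (N_t, 3)
    w = cmap.bary[:, :, None]
    coords = (mesh.vertices[fv] * w).sum(axis=1)
    names = (
        tuple(mesh.fields.keys()) if field_names is None else field_names
    )
    fields = {
        name: (mesh.fields[name][fv] * cmap.bary).sum(axis=1) for name in names
    }
    return coords, fields


def build_isotopological_set(
    template: Template2D,
    targets: dict,
    rho: float | None = None,
    field_names: tuple[str, ...] | None = None,
) -> IsotopologicalSet:
    """Register the template to every parametrised target.

    ``targets`` maps subject id -> an object with ``strip`` (the normalised
    strip :class:`PlanarEmbedding`) and strip-frame ``fh_region_strip`` /
    ``lt_region_strip`` attributes (a
    :class:`~femurmap.pipeline.Parametrisation` or any namespace shaped
    like one).  Per-subject failures are collected; successful subjects
    are kept.  Raises :class:`GeometryError` carrying the error report if
    every subject failed.
    """
    coords_all, fields_all, ids, clamp_all = [], [], [], []
    errors: dict[str, str] = {}
    for sid, tgt in targets.items():
        try:
            rbf = build_rbf(
                (template.fh_region, template.lt_region),
                (tgt.fh_region_strip, tgt.lt_region_strip),
                rho=rho,
            )
            warped = template.coords + rbf(template.coords)
            cmap = natural_representation(warped, tgt.strip)
            coords, flds = resample(cmap, tgt.strip, field_names=field_names)
        except Exception as exc:  # noqa: BLE001 - per-subject isolation
            errors[str(sid)] = f"{type(exc).__name__}: {exc}"
            continue
        coords_all.append(coords)
        fields_all.append(flds)
        ids.append(str(sid))
        clamp_all.append(cmap.clamped)
    if not ids:
        raise GeometryError(f"all registrations failed: {errors}")
    names = fields_all[0].keys()
    out = IsotopologicalSet(
        faces=template.faces.copy(),
        coords=np.stack(coords_all),
        fields={k: np.stack([f[k] for f in fields_all]) for k in names},
        subject_ids=ids,
        clamped=np.stack(clamp_all),
        template=template,
    )
    out.errors = errors  # type: ignore[attr-defined]
    return out
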