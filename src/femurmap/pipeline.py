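"""End-to-end parametrisation of one proximal-femur-like surface.

Fully automatic chain, mirroring the two-step construction:

1. free-boundary Ricci flow of the chi=1 surface and disk layout;
2. FH/GT detection from the conformal-factor peaks, Gaussian region fits;
3. slit along the straight FH-GT segment in the disk (chi=0, b=2);
4. zero-curvature Ricci flow of the slit surface (flat cylinder);
5. shortest cut graph from GT to the distal boundary, edge slit (chi=1);
6. planar layout of the fundamental domain, similarity normalisation
   placing the FH-GT boundary on the imaginary axis over [0, 2*pi];
7. exponential map to the annulus and LT detection.

The result carries every intermediate product plus provenance back to the
input surface, so per-vertex fields attached to the input (thickness,
strains) travel to the strip/annulus meshes automatically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import GeometryError
from .features import (
    FeaturePoint,
    FeatureRegion,
    detect_disk_features,
    detect_lt,
    fit_feature_region,
    inter_feature_segment,
)
from .mesh import TriMesh, euler_characteristic
from .ricci import (
    PlanarEmbedding,
    RicciMetric,
    cut_graph,
    embed_disk,
    embed_flat,
    exponential_map,
    normalise_strip,
    ricci_flow_metric,
    slit_mesh,
    transfer_metric,
)

__all__ = ["Parametrisation", "parametrise"]


@dataclass
class Parametrisation:
    """Everything produced by the automatic parametrisation chain."""

    surface: TriMesh
    disk: PlanarEmbedding
    fh: FeaturePoint
    gt: FeaturePoint
    fh_region: FeatureRegion
    gt_region: FeatureRegion
    strip: PlanarEmbedding  # normalised fundamental domain
    annulus: PlanarEmbedding
    lt: FeaturePoint
    lt_region: FeatureRegion
    fh_region_strip: FeatureRegion  # FH refitted in the strip frame
    gt_region_strip: FeatureRegion  # GT refitted in the strip frame
    lt_region_strip: FeatureRegion  # LT refitted in the strip frame
    slit_chain: np.ndarray  # ordered FH-GT boundary on the strip mesh
    fh_strip_imag: float  # checked output: FH's imaginary coordinate
    annulus_metric: RicciMetric
    disk_metric: RicciMetric
    log: dict = field(default_factory=dict)


def _uphill(embedding, v: int) -> int:
    """Walk uphill on the conformal factor to the nearest local maximum."""
    cf = embedding.conformal_factor
    neigh = embedding.mesh.vertex_neighbors()
    for _ in range(embedding.mesh.n_vertices):
        nb = neigh[v]
        best = int(nb[np.argmax(cf[nb])])
        if cf[best] <= cf[v]:
            return v
        v = best
    return v


def _ordered_boundary_run(mesh: TriMesh, member: np.ndarray) -> np.ndarray:
    """Contiguous run of ``member`` vertices along the single boundary loop
    of ``mesh``, in loop order."""
    loops = mesh.boundary_loops()
    if len(loops) != 1:
        raise GeometryError(f"expected one boundary loop, found {len(loops)}")
    loop = loops[0]
    flags = member[loop]
    if flags.all():
        return loop
    starts = np.flatnonzero(flags & ~np.roll(flags, 1))
    if len(starts) != 1:
        raise GeometryError("boundary subset is not contiguous on the loop")
    start = int(starts[0])
    rot_loop = np.roll(loop, -start)
    rot_flags = np.roll(flags, -start)
    nrun = int(rot_flags.sum())
    if not (rot_flags[:nrun].all() and not rot_flags[nrun:].any()):
        raise GeometryError("boundary subset is not contiguous on the loop")
    return rot_loop[:nrun]


def parametrise(
    surface: TriMesh,
    tolerance: float = 1e-8,
    max_iter: int = 50,
    min_prominence: float = 0.25,
) -> Parametrisation:
    """Run the full disk -> slit -> annulus parametrisation chain."""
    topo = euler_characteristic(surface)
    log: dict = {"input_topology": tuple(topo)}

    disk_metric = ricci_flow_metric(
        surface, "disk_free_boundary", tolerance=tolerance, max_iter=max_iter
    )
    log["disk_flow_iters"] = len(disk_metric.history) - 1
    log["disk_flow_residual"] = disk_metric.residual
    disk = embed_disk(surface, disk_metric)

    fh, gt = detect_disk_features(disk, min_prominence=min_prominence)
    fh_region = fit_feature_region(disk, fh)
    gt_region = fit_feature_region(disk, gt)

    segment = inter_feature_segment(disk, fh, gt)
    slit1, prov1, _ = slit_mesh(surface, segment, mode="planar_line", embedding=disk)
    log["slit_topology"] = tuple(euler_characteristic(slit1))

    annulus_metric = ricci_flow_metric(
        slit1, "annulus_zero", tolerance=tolerance, max_iter=max_iter
    )
    log["annulus_flow_iters"] = len(annulus_metric.history) - 1
    log["annulus_flow_residual"] = annulus_metric.residual

    # boundary bookkeeping: the distal loop is the one inherited from the
    # input surface; the other is the FH-GT slit
    loops1 = slit1.boundary_loops()
    orig_boundary = set(surface.boundary_loops()[0].tolist())
    distal_ids = [
        i
        for i, lp in enumerate(loops1)
        if all(prov1[v] in orig_boundary for v in lp if prov1[v] >= 0)
    ]
    if len(distal_ids) != 1:
        raise GeometryError("could not identify the distal boundary after slit")
    distal_loop_idx = distal_ids[0]
    slit_loop_idx = 1 - distal_loop_idx
    slit_loop = set(loops1[slit_loop_idx].tolist())

    # GT survives the slit as a tip with its original index
    gt_in_slit1 = gt.vertex
    cut = cut_graph(
        slit1, gt_in_slit1, to_boundary=distal_loop_idx, avoid_other_boundaries=True
    )
    log["cut_length"] = len(cut)
    fundamental, prov2, _ = slit_mesh(slit1, cut, mode="edge_path")
    log["fundamental_topology"] = tuple(euler_characteristic(fundamental))

    flat_metric = transfer_metric(annulus_metric, fundamental, prov2)
    # provenance to the original surface (-1 for synthesised split points)
    src = np.where(prov2 >= 0, prov1[prov2], -1)

    member = np.array([int(v) in slit_loop for v in prov2], dtype=bool)
    plane = embed_flat(fundamental, flat_metric, domain="plane", source_vertex=src)

    slit_chain = _ordered_boundary_run(fundamental, member)
    distal_member = np.array(
        [prov2[v] >= 0 and int(prov2[v]) in set(loops1[distal_loop_idx].tolist())
         for v in range(fundamental.n_vertices)],
        dtype=bool,
    )
    distal_chain = np.flatnonzero(distal_member)
    strip = normalise_strip(plane, slit_chain, distal_vertices=distal_chain)

    fh_copies = np.flatnonzero(src == fh.source)
    fh_strip_imag = float(np.mean(strip.z[fh_copies].imag)) if len(fh_copies) else np.nan
    log["fh_strip_imag"] = fh_strip_imag

    annulus = exponential_map(strip)

    # FH/GT regions refitted in the strip frame, where the head and
    # trochanter are magnified rather than compressed; their supports
    # (mapped to source vertices, which covers both slit copies) define
    # the exclusion zone for LT detection
    if not len(fh_copies):
        raise GeometryError("FH vertex lost during surgery")
    fh_v_strip = _uphill(strip, int(fh_copies[0]))
    fh_strip = FeaturePoint(
        fh_v_strip, int(src[fh_v_strip]), complex(strip.z[fh_v_strip]), "FH",
        float(strip.conformal_factor[fh_v_strip]),
    )
    fh_region_strip = fit_feature_region(strip, fh_strip)
    gt_copies = np.flatnonzero(src == gt.source)
    if not len(gt_copies):
        raise GeometryError("GT vertex lost during surgery")
    gt_v_strip = _uphill(strip, int(gt_copies[0]))
    gt_strip = FeaturePoint(
        gt_v_strip, int(src[gt_v_strip]), complex(strip.z[gt_v_strip]), "GT",
        float(strip.conformal_factor[gt_v_strip]),
    )
    gt_region_strip = fit_feature_region(strip, gt_strip)

    # the conformal collar around the slit excludes the FH/GT processes;
    # fitted 1-sigma supports are not passed: a shallow peak's Gaussian can
    # be near-flat and its support ellipse arbitrarily wide
    lt = detect_lt(annulus)
    lt_region = fit_feature_region(annulus, lt)
    lt_strip = FeaturePoint(
        lt.vertex, lt.source, complex(strip.z[lt.vertex]), "LT",
        float(strip.conformal_factor[lt.vertex]),
    )
    lt_region_strip = fit_feature_region(strip, lt_strip)

    return Parametrisation(
        surface=surface,
        disk=disk,
        fh=fh,
        gt=gt,
        fh_region=fh_region,
        gt_region=gt_region,
        strip=strip,
        annulus=annulus,
        lt=lt,
        lt_region=lt_region,
        fh_region_strip=fh_region_strip,
        gt_region_strip=gt_region_strip,
        lt_region_strip=lt_region_strip,
        slit_chain=slit_chain,
        fh_strip_imag=fh_strip_imag,
        annulus_metric=annulus_metric,
        disk_metric=disk_metric,
        log=log,
    )
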