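"""Seeded generator of proximal-femur-like surfaces and cohorts.

The outer surface is a surface of revolution (an open shaft capped by a
bulbous "head" through a narrowed "neck") with Gaussian protrusions added
along the vertex normals for the greater trochanter (GT) and lesser
trochanter (LT), plus optional extra shaping of the femoral head (FH).
The distal end is left open, so the surface is genus 0 with exactly one
boundary loop (chi = 1).  An inner (endosteal) surface with the same
connectivity is produced by offsetting inward along vertex normals by a
prescribed shell-thickness field.

Everything is a pure function of the spec and its seed: the same spec
generates bit-identical meshes.

Cohorts are collections of per-subject specs with planted shape variation
(shaft length, neck length, global size), covariates (body weight, impact
force) and planted group effects on the thickness / strain fields, plus a
fast field-level cohort generator used to exercise the node-wise statistics
at scale without re-running the parametrisation chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ArgumentError, GenerationError
from .mesh import TriMesh

__all__ = [
    "BumpSpec",
    "FemurSpec",
    "EffectSpec",
    "CohortSpec",
    "FemurGroundTruth",
    "make_femur",
    "make_cohort",
    "make_field_cohort",
]


@dataclass(frozen=True)
class BumpSpec:
    """A Gaussian protrusion along the surface normal.

    ``depth_mm`` is the position along the generating curve measured from
    the proximal apex (so trochanter anatomy stays put when the distal
    shaft extent varies across subjects), ``theta`` the azimuth (radians),
    ``amplitude_mm`` the peak normal displacement and ``sigma_mm`` the
    isotropic 1-sigma footprint on the surface.
    """

    depth_mm: float
    theta: float
    amplitude_mm: float
    sigma_mm: float


@dataclass(frozen=True)
class FemurSpec:
    """Parameters of one synthetic proximal femur.

    Defaults give a shape roughly the size of an adult proximal femur:
    a 55 mm open shaft of radius 15 mm, a 12 mm neck narrowing to 10 mm,
    an 18 mm-radius head, a lateral greater trochanter and a smaller,
    more distal lesser trochanter, with a 3 mm cortical shell.
    """

    shaft_length: float = 55.0
    shaft_radius: float = 15.0
    neck_length: float = 12.0
    neck_radius: float = 10.0
    head_radius: float = 18.0
    gt: BumpSpec = field(
        default_factory=lambda: BumpSpec(
            depth_mm=62.0, theta=np.pi, amplitude_mm=14.0, sigma_mm=6.0
        )
    )
    lt: BumpSpec = field(
        default_factory=lambda: BumpSpec(
            depth_mm=82.0, theta=0.0, amplitude_mm=4.5, sigma_mm=6.0
        )
    )
    fh: BumpSpec | None = None  # optional extra shaping of the head
    thickness_mm: float = 3.0
    # list of (t_lo, t_hi, theta_lo, theta_hi, multiplier) thickness patches
    thickness_patches: tuple = ()
    n_vertices: int = 2000
    size_scale: float = 1.0
    shape_jitter: float = 0.0  # amplitude (mm) of smooth random perturbation
    seed: int = 0


@dataclass
class FemurGroundTruth:
    """What the generator knows about the mesh it produced."""

    apex_fh: int
    apex_gt: int
    apex_lt: int
    thickness: np.ndarray  # prescribed shell thickness per outer vertex (mm)
    t_param: np.ndarray  # generating-curve coordinate per vertex (mm)
    depth: np.ndarray  # arclength from the proximal apex per vertex (mm)
    theta: np.ndarray  # azimuth per vertex (radians)


def _generating_curve(spec: FemurSpec, n: int = 2048):
    """Sample the profile (z, R) of the surface of revolution by arclength."""
    H, Ln = spec.shaft_length, spec.neck_length
    rs, rn, rh = spec.shaft_radius, spec.neck_radius, spec.head_radius
    if not (0 < rn <= rh):
        raise GenerationError("need 0 < neck_radius <= head_radius")
    zc = H + Ln + np.sqrt(rh**2 - rn**2)  # head-sphere centre on the axis
    z_apex = zc + rh
    z = np.linspace(0.0, z_apex, n)
    R = np.empty_like(z)
    shaft = z <= H
    neck = (z > H) & (z <= H + Ln)
    head = z > H + Ln
    R[shaft] = rs
    # cosine blend shaft radius -> neck radius
    u = (z[neck] - H) / Ln
    R[neck] = rs + (rn - rs) * (1 - np.cos(np.pi * u)) / 2
    R[head] = np.sqrt(np.maximum(rh**2 - (z[head] - zc) ** 2, 0.0))
    # arclength parameter
    ds = np.hypot(np.diff(z), np.diff(R))
    t = np.concatenate([[0.0], np.cumsum(ds)])
    return z, R, t


def _smooth_perturbation(t, theta, t_total, rng, amplitude):
    """Low-frequency random normal displacement field (smooth over surface)."""
    out = np.zeros_like(t)
    if amplitude <= 0:
        return out
    for k in range(1, 4):
        a = rng.normal(0.0, amplitude / k)
        phase = rng.uniform(0, 2 * np.pi)
        centre = rng.uniform(0.2, 0.8) * t_total
        width = rng.uniform(0.15, 0.35) * t_total
        out += a * np.cos(k * theta + phase) * np.exp(
            -0.5 * ((t - centre) / width) ** 2
        )
    return out


def _vertex_normals(vertices, faces):
    fn = np.cross(
        vertices[faces[:, 1]] - vertices[faces[:, 0]],
        vertices[faces[:, 2]] - vertices[faces[:, 0]],
    )
    vn = np.zeros_like(vertices)
    for c in range(3):
        np.add.at(vn, faces[:, c], fn)
    norm = np.linalg.norm(vn, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    return vn / norm


def make_femur(spec: FemurSpec) -> tuple[TriMesh, TriMesh, FemurGroundTruth]:
    """Generate an (outer, inner) surface pair with ground truth.

    The outer surface has genus 0 and exactly one (distal) boundary loop.
    The inner surface shares its connectivity and lies ``thickness`` mm
    inside along the vertex normals.
    """
    rng = np.random.default_rng(spec.seed)
    z_prof, R_prof, t_prof = _generating_curve(spec)
    t_total = t_prof[-1]

    # grid resolution: roughly isotropic spacing
    mean_R = float(np.trapezoid(R_prof, t_prof) / t_total)
    n_theta = max(16, int(round(np.sqrt(spec.n_vertices * 2 * np.pi * mean_R / t_total))))
    n_theta += n_theta % 2  # even: keeps theta = pi on the grid (mirror symmetry)
    n_rings = max(8, int(round(spec.n_vertices / n_theta)))
    dt = t_total / n_rings
    t_rings = np.arange(n_rings) * dt
    R_rings = np.interp(t_rings, t_prof, R_prof)
    z_rings = np.interp(t_rings, t_prof, z_prof)
    # stop ringing before the apex once rings get too thin for good aspect
    r_min = 0.35 * dt * n_theta / (2 * np.pi)
    keep = R_rings >= max(r_min, 1e-6)
    t_rings, R_rings, z_rings = t_rings[keep], R_rings[keep], z_rings[keep]
    n_rings = len(t_rings)
    if n_rings < 8:
        raise GenerationError("resolution too low for the requested shape")

    theta = 2 * np.pi * np.arange(n_theta) / n_theta
    tt = np.repeat(t_rings, n_theta)
    th = np.tile(theta, n_rings)
    rr = np.repeat(R_rings, n_theta)
    zz = np.repeat(z_rings, n_theta)
    verts = np.column_stack([rr * np.cos(th), rr * np.sin(th), zz])
    apex = np.array([[0.0, 0.0, z_prof[-1]]])
    vertices = np.vstack([verts, apex])
    apex_id = len(vertices) - 1
    tt = np.append(tt, t_total)
    th = np.append(th, 0.0)

    faces = []
    # quad diagonals flip direction across the theta = 0 / pi plane so the
    # triangulation is exactly mirror-symmetric (j <-> n_theta - j)
    for i in range(n_rings - 1):
        for j in range(n_theta):
            a = i * n_theta + j
            b = i * n_theta + (j + 1) % n_theta
            c = (i + 1) * n_theta + j
            d = (i + 1) * n_theta + (j + 1) % n_theta
            if j < n_theta // 2:
                faces.append((a, b, c))
                faces.append((b, d, c))
            else:
                faces.append((a, b, d))
                faces.append((a, d, c))
    top = (n_rings - 1) * n_theta
    for j in range(n_theta):
        faces.append((top + j, top + (j + 1) % n_theta, apex_id))
    faces = np.asarray(faces, dtype=np.int64)

    depth = t_total - tt  # arclength from the proximal apex

    # normal displacement field: bumps + seeded smooth jitter
    def bump_field(b: BumpSpec):
        if b is None or b.amplitude_mm == 0:
            return 0.0
        dth = np.angle(np.exp(1j * (th - b.theta)))
        arc = spec.shaft_radius * dth
        d2 = ((depth - b.depth_mm) / b.sigma_mm) ** 2 + (arc / b.sigma_mm) ** 2
        return b.amplitude_mm * np.exp(-0.5 * d2)

    disp = bump_field(spec.gt) + bump_field(spec.lt)
    if spec.fh is not None:
        disp = disp + bump_field(spec.fh)
    disp = disp + _smooth_perturbation(tt, th, t_total, rng, spec.shape_jitter)

    normals = _vertex_normals(vertices, faces)
    vertices = vertices + disp[:, None] * normals
    vertices *= spec.size_scale

    # shell thickness field with planted patches
    thickness = np.full(len(vertices), spec.thickness_mm)
    for d_lo, d_hi, th_lo, th_hi, mult in spec.thickness_patches:
        m = _region_mask(depth, th, d_lo, d_hi, th_lo, th_hi)
        thickness[m] *= mult
    # curvature-limited inward step: never offset more than a safe fraction
    # of the smallest cross-section radius
    limit = 0.45 * spec.neck_radius * spec.size_scale
    thickness = np.minimum(thickness, limit)

    normals = _vertex_normals(vertices, faces)
    inner_vertices = vertices - thickness[:, None] * normals

    outer = TriMesh(vertices, faces)
    outer.validate()
    inner = TriMesh(inner_vertices, faces.copy())

    def nearest_vertex(b: BumpSpec):
        dth = np.angle(np.exp(1j * (th - b.theta)))
        d2 = (depth - b.depth_mm) ** 2 + (spec.shaft_radius * dth) ** 2
        return int(np.argmin(d2))

    gt_truth = FemurGroundTruth(
        apex_fh=apex_id if spec.fh is None else nearest_vertex(spec.fh),
        apex_gt=nearest_vertex(spec.gt),
        apex_lt=nearest_vertex(spec.lt),
        thickness=thickness,
        t_param=tt,
        depth=depth,
        theta=th,
    )
    outer.fields["thickness_true"] = thickness.copy()
    return outer, inner, gt_truth


def _region_mask(depth, th, d_lo, d_hi, th_lo, th_hi):
    """Vertices inside a (depth-from-apex, theta) window; theta may wrap."""
    m_t = (depth >= d_lo) & (depth <= d_hi)
    lo = np.mod(th_lo, 2 * np.pi)
    hi = np.mod(th_hi, 2 * np.pi)
    a = np.mod(th, 2 * np.pi)
    m_th = (a >= lo) & (a <= hi) if lo <= hi else (a >= lo) | (a <= hi)
    return m_t & m_th


# ----------------------------------------------------------------------
# cohorts
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class EffectSpec:
    """A planted group effect on a per-node field.

    ``region`` is a (depth_lo, depth_hi, theta_lo, theta_hi) window in
    generator coordinates (depth measured from the proximal apex, mm);
    ``percent`` the multiplicative change (+30 means x1.3)
    applied to ``field_name`` ("thickness", "strain_max" or "strain_min")
    for members of ``group``.
    """

    group: str
    field_name: str
    region: tuple[float, float, float, float]
    percent: float


@dataclass(frozen=True)
class CohortSpec:
    """A synthetic study cohort.

    Shape variation across subjects: shaft length (isometric-ish), neck
    length and global size multiplier, plus small smooth jitter.  Covariate
    distributions follow an adult female athlete cohort: body weight
    ~ N(65, 8) kg and sideways-fall impact force ~ N(2600, 350) N.
    """

    groups: tuple[tuple[str, int], ...] = (("control", 10), ("loaded", 10))
    effects: tuple[EffectSpec, ...] = ()
    noise_sigma: float = 0.10  # multiplicative per-node field noise (smooth)
    shaft_length_sd: float = 4.0
    neck_length_sd: float = 1.5
    size_sd: float = 0.05
    shape_jitter: float = 0.8
    base: FemurSpec = field(default_factory=FemurSpec)
    seed: int = 0


@dataclass
class Subject:
    subject_id: str
    group: str
    spec: FemurSpec
    outer: TriMesh
    inner: TriMesh
    truth: FemurGroundTruth
    weight_kg: float
    impact_force_N: float


def make_cohort(spec: CohortSpec):
    """Generate subject meshes, a cohort table and ground-truth effect masks.

    Returns ``(subjects, table, effect_masks)`` where ``effect_masks`` maps
    each :class:`EffectSpec` index to the per-subject boolean vertex masks of
    its planted region.  Thickness effects are realised geometrically (the
    inner shell is offset further/less), strain effects are applied to the
    per-node strain fields attached to each outer mesh.
    """
    for _, n in spec.groups:
        if n < 2:
            raise ArgumentError("need at least 2 subjects per group")
    rng = np.random.default_rng(spec.seed)
    subjects: list[Subject] = []
    rows = []
    effect_masks: dict[int, list[np.ndarray]] = {i: [] for i in range(len(spec.effects))}
    for group, n in spec.groups:
        for k in range(n):
            sid = f"{group}_{k:02d}"
            sub_seed = int(rng.integers(0, 2**31 - 1))
            sub_rng = np.random.default_rng(sub_seed)
            thickness_patches = []
            for eff in spec.effects:
                if eff.group == group and eff.field_name == "thickness":
                    d_lo, d_hi, th_lo, th_hi = eff.region
                    thickness_patches.append(
                        (d_lo, d_hi, th_lo, th_hi, 1.0 + eff.percent / 100.0)
                    )
            fspec = replace(
                spec.base,
                shaft_length=spec.base.shaft_length
                + sub_rng.normal(0, spec.shaft_length_sd),
                neck_length=max(
                    4.0,
                    spec.base.neck_length + sub_rng.normal(0, spec.neck_length_sd),
                ),
                size_scale=spec.base.size_scale
                * float(np.exp(sub_rng.normal(0, spec.size_sd))),
                shape_jitter=spec.shape_jitter,
                thickness_patches=tuple(thickness_patches),
                seed=sub_seed,
            )
            outer, inner, truth = make_femur(fspec)
            # smooth multiplicative noise on thickness via the inner offset
            if spec.noise_sigma > 0:
                noise = _smooth_field_noise(outer, spec.noise_sigma, sub_rng)
                thick = truth.thickness * (1.0 + noise)
                thick = np.maximum(thick, 0.2)
                from .synth import _vertex_normals as _vn  # local alias

                normals = _vn(outer.vertices, outer.faces)
                inner = TriMesh(outer.vertices - thick[:, None] * normals,
                                outer.faces.copy())
                truth.thickness = thick
                outer.fields["thickness_true"] = thick.copy()
            strain_max, strain_min = _strain_fields(outer, truth, sub_rng,
                                                   spec.noise_sigma)
            for i, eff in enumerate(spec.effects):
                mask = _region_mask(truth.depth, truth.theta, *eff.region)
                effect_masks[i].append(mask)
                if eff.group != group:
                    continue
                if eff.field_name == "strain_max":
                    strain_max[mask] *= 1.0 + eff.percent / 100.0
                elif eff.field_name == "strain_min":
                    strain_min[mask] *= 1.0 + eff.percent / 100.0
            outer.fields["strain_max"] = strain_max
            outer.fields["strain_min"] = strain_min
            weight = float(sub_rng.normal(65.0, 8.0))
            force = float(sub_rng.normal(2600.0, 350.0))
            subjects.append(
                Subject(sid, group, fspec, outer, inner, truth, weight, force)
            )
            rows.append(
                dict(subject_id=sid, group=group, weight_kg=weight,
                     impact_force_N=force, seed=sub_seed)
            )
    table = pd.DataFrame(rows)
    return subjects, table, effect_masks


def _smooth_field_noise(mesh: TriMesh, sigma: float, rng, sweeps: int = 4):
    """Zero-mean smooth per-vertex noise with (approximate) sd ``sigma``."""
    x = rng.standard_normal(mesh.n_vertices)
    neigh = mesh.vertex_neighbors()
    for _ in range(sweeps):
        acc = np.array([x[nb].mean() if len(nb) else 0.0 for nb in neigh])
        x = 0.5 * x + 0.5 * acc
    sd = x.std()
    return x * (sigma / sd) if sd > 0 else x


def _strain_fields(mesh: TriMesh, truth: FemurGroundTruth, rng, noise_sigma):
    """Sideways-fall-like per-node principal strain patterns.

    Maximum (tensile) principal strain peaks on the superior neck; minimum
    (compressive) strain mirrors it inferiorly with negative sign.  These
    emulate externally supplied finite-element results and carry no
    mechanical fidelity beyond a plausible spatial pattern.
    """
    d, th = truth.depth, truth.theta
    d_neck = 50.0  # depth of the neck region below the apex
    sup = np.exp(-0.5 * (((d - d_neck) / 12.0) ** 2 + ((np.angle(np.exp(1j * (th - np.pi / 2)))) / 0.9) ** 2))
    inf = np.exp(-0.5 * (((d - d_neck) / 12.0) ** 2 + ((np.angle(np.exp(1j * (th + np.pi / 2)))) / 0.9) ** 2))
    smax = 0.004 + 0.010 * sup
    smin = -(0.005 + 0.012 * inf)
    if noise_sigma > 0:
        smax = smax * (1.0 + _smooth_field_noise(mesh, noise_sigma, rng))
        smin = smin * (1.0 + _smooth_field_noise(mesh, noise_sigma, rng))
    return smax, smin


def make_field_cohort(
    template: TriMesh,
    n_control: int,
    n_loaded: int,
    effect_mask: np.ndarray | None,
    effect_percent: float,
    noise_sigma: float,
    rng,
    base: float = 3.0,
    covariates: bool = True,
):
    """Per-node feature arrays on a fixed template for statistics testing.

    Generates smooth multiplicative noise around a constant baseline field
    and multiplies the effect region by ``1 + effect_percent/100`` for the
    loaded group.  Returns ``(features (n_subj, n_nodes), table)`` with the
    control group first.  This exercises the node-wise models and cluster
    inference at scale without re-running the geometric pipeline.
    """
    n = n_control + n_loaded
    # smooth noise: white noise diffused over the template graph
    neigh = template.vertex_neighbors()
    import scipy.sparse as sp

    rows, cols = [], []
    for i, nb in enumerate(neigh):
        rows.extend([i] * len(nb))
        cols.extend(nb.tolist())
    deg = np.array([max(len(nb), 1) for nb in neigh], dtype=float)
    A = sp.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(template.n_vertices,) * 2
    )
    X = rng.standard_normal((n, template.n_vertices))
    for _ in range(4):
        X = 0.5 * X + 0.5 * (X @ A.T) / deg
    X = X / X.std(axis=1, keepdims=True) * noise_sigma
    feats = base * (1.0 + X)
    if effect_mask is not None and effect_percent != 0:
        feats[n_control:, effect_mask] *= 1.0 + effect_percent / 100.0
    group = np.array(["control"] * n_control + ["loaded"] * n_loaded)
    table = pd.DataFrame(
        {
            "subject_id": [f"s{i:03d}" for i in range(n)],
            "group": group,
            "weight_kg": rng.normal(65, 8, n) if covariates else 65.0,
            "impact_force_N": rng.normal(2600, 350, n) if covariates else 2600.0,
        }
    )
    return feats, table
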