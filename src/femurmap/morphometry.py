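"""Per-node morphometric features, Procrustes alignment and shape modes.

Cortical thickness at an outer (periosteal) node is its shortest distance
to the inner (endosteal) surface.  Across a registered cohort, shapes are
superimposed by generalised Procrustes analysis (GPA: iterated removal of
translation, rotation and optionally scale about the evolving mean), and
shape variability is summarised by the principal components of the
mean-centred aligned coordinate vectors ("shape modes").  Rotations are
proper (no reflections): anatomy is chiral.

Scale factors are Procrustes scales of the mean-to-subject transform, so
with scale normalisation on, subject size lives entirely in the scale
factor and mode 1 does not encode isotropic size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ArgumentError
from .mesh import TriMesh, point_to_surface_distance

__all__ = [
    "ShapeModel",
    "cortical_thickness",
    "generalized_procrustes",
    "shape_modes",
    "align_point_sets",
    "save_shape_model",
]


@dataclass
class ShapeModel:
    mean_shape: np.ndarray  # (N, 3) mm
    aligned: np.ndarray  # (S, N, 3)
    scale_factors: np.ndarray  # (S,) relative to the mean shape
    scale_normalised: bool
    modes: np.ndarray | None = None  # (n_modes, 3N) orthonormal loadings
    scores: np.ndarray | None = None  # (S, n_modes)
    explained_variance: np.ndarray | None = None  # fractions, non-increasing
    objective_history: list = field(default_factory=list)


def cortical_thickness(outer: TriMesh, inner: TriMesh) -> np.ndarray:
    """Shortest distance (mm) from each outer vertex to the inner surface."""
    return point_to_surface_distance(outer.vertices, inner)


def _orthogonal_align(X: np.ndarray, Y: np.ndarray, allow_scale: bool):
    """Best proper rotation (and scale) mapping centred X onto centred Y."""
    H = X.T @ Y
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, 1.0, d]) if H.shape[0] == 3 else np.diag([1.0, d])
    R = U @ D @ Vt
    if allow_scale:
        num = (S * np.diag(D)).sum()
        s = num / (X**2).sum()
    else:
        s = 1.0
    return R, s


def generalized_procrustes(
    shapes: np.ndarray,
    scale_normalise: bool = True,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> ShapeModel:
    """Generalised Procrustes alignment of an isotopological coordinate stack.

    ``shapes`` is (S, N, 3) with identical node count across subjects.
    Iterates: align every subject to the current mean (translation +
    proper rotation + optional scale), recompute the mean, until the mean
    moves by less than ``tol`` (RMS).  The per-subject scale factor is the
    Procrustes scale of the mean-to-subject transform (subject size
    relative to the mean shape).
    """
    shapes = np.asarray(shapes, dtype=np.float64)
    if shapes.ndim != 3 or shapes.shape[2] != 3:
        raise ArgumentError("shapes must be (S, N, 3)")
    S, N, _ = shapes.shape
    if S < 2:
        raise ArgumentError("need at least two subjects")
    centred = shapes - shapes.mean(axis=1, keepdims=True)
    norms = np.sqrt((centred**2).sum(axis=(1, 2)))
    if (norms == 0).any():
        raise ArgumentError("degenerate (all-coincident) shape in cohort")
    aligned = centred.copy()
    if scale_normalise:
        aligned = aligned / norms[:, None, None]
    mean = aligned[0].copy()
    history = []
    for _ in range(max_iter):
        for k in range(S):
            R, s = _orthogonal_align(aligned[k], mean, allow_scale=scale_normalise)
            aligned[k] = s * aligned[k] @ R
        new_mean = aligned.mean(axis=0)
        if scale_normalise:
            new_mean = new_mean / np.sqrt((new_mean**2).sum())
        obj = float(((aligned - new_mean) ** 2).sum())
        history.append(obj)
        shift = np.sqrt(((new_mean - mean) ** 2).mean())
        mean = new_mean
        if shift < tol:
            break
    # subject size relative to the mean: Procrustes scale of mean -> subject,
    # normalised so the cohort's geometric-mean scale is 1
    scale_factors = np.empty(S)
    for k in range(S):
        _, s = _orthogonal_align(mean, centred[k], allow_scale=True)
        scale_factors[k] = s
    scale_factors /= np.exp(np.log(scale_factors).mean())
    return ShapeModel(
        mean_shape=mean,
        aligned=aligned,
        scale_factors=scale_factors,
        scale_normalised=scale_normalise,
        objective_history=history,
    )


def shape_modes(model: ShapeModel, n_modes: int = 5) -> ShapeModel:
    """Principal components of the aligned, mean-centred vertex coordinates.

    Loadings are orthonormal rows of length 3N; scores are per-subject
    projections; explained-variance fractions are non-increasing.
    """
    S = model.aligned.shape[0]
    if n_modes > S - 1:
        raise ArgumentError(
            f"n_modes={n_modes} exceeds the cohort's rank ({S - 1})"
        )
    X = model.aligned.reshape(S, -1) - model.mean_shape.reshape(1, -1)
    X = X - X.mean(axis=0, keepdims=True)
    U, sv, Vt = np.linalg.svd(X, full_matrices=False)
    var = sv**2
    total = var.sum()
    model.modes = Vt[:n_modes]
    model.scores = U[:, :n_modes] * sv[:n_modes]
    model.explained_variance = var[:n_modes] / total if total > 0 else var[:n_modes]
    return model


def align_point_sets(
    point_sets: list[np.ndarray],
    scale_normalise: bool = False,
    tol: float = 1e-10,
    max_iter: int = 100,
):
    """GPA utility for sparse landmark (annotation) sets.

    All sets must share the same landmark count K >= 3.  Returns
    ``(aligned sets (S, K, 3), mean (K, 3))``.  Reflections are never
    used; a mirrored set keeps a nonzero residual.
    """
    arr = np.asarray(point_sets, dtype=np.float64)
    if arr.ndim != 3:
        raise ArgumentError("point sets must share a common landmark count")
    if arr.shape[1] < 3:
        raise ArgumentError("need at least 3 landmarks per set")
    model = generalized_procrustes(
        arr, scale_normalise=scale_normalise, tol=tol, max_iter=max_iter
    )
    return model.aligned, model.mean_shape


def save_shape_model(model: ShapeModel, outdir, subject_ids=None) -> None:
    """Serialise a shape model as plain tables: mean shape, per-subject
    scores + scale factors, explained-variance fractions."""
    import pandas as pd
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(model.mean_shape, columns=["x", "y", "z"]).to_csv(
        outdir / "mean_shape.csv", index_label="node"
    )
    S = len(model.aligned)
    ids = subject_ids if subject_ids is not None else [f"s{i}" for i in range(S)]
    df = pd.DataFrame({"subject_id": ids, "scale_factor": model.scale_factors})
    if model.scores is not None:
        for m_i in range(model.scores.shape[1]):
            df[f"mode{m_i + 1}"] = model.scores[:, m_i]
    df.to_csv(outdir / "shape_scores.csv", index=False)
    if model.explained_variance is not None:
        pd.DataFrame(
            {"mode": np.arange(1, len(model.explained_variance) + 1),
             "variance_fraction": model.explained_variance}
        ).to_csv(outdir / "variance_fractions.csv", index=False)
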