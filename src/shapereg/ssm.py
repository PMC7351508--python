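"""Statistical shape model: PCA over registered correspondences.

Each registered subject is a deformed copy of the reference cloud with
identical point count and ordering, so it flattens to a 3n-vector in a
common shape space.  The mean shape is the coordinate-wise average; the
eigenmodes come from the sample covariance (divisor N−1) of the
flattened shapes.  PCA runs on raw millimetre coordinates — no
Procrustes size normalization — so the first mode is free to capture
overall size, which in bone populations dominates the variation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .geometry_io import ParameterError, PointCloud, TriMesh
from .registration import RegisteredSet

__all__ = ["ShapeModel", "build_model", "synthesize", "variance_explained",
           "triangulate_correspondence"]


class CorrespondenceError(ParameterError):
    """Point sets are not in one-to-one correspondence."""


@dataclass
class ShapeModel:
    """PCA shape model over corresponded point sets.

    mean_shape : (n, 3) mm; eigenvectors : (r, 3n), unit rows, mutually
    orthogonal; eigenvalues : variances (mm²) descending;
    variance_fraction sums to 1; training_scores : (N, r) per-subject
    mode scores (mm-weighted projections, not σ-units).
    """

    mean_shape: np.ndarray
    eigenvectors: np.ndarray
    eigenvalues: np.ndarray
    variance_fraction: np.ndarray
    n_subjects: int
    cohort_label: str = ""
    training_scores: np.ndarray | None = None

    @property
    def n_points(self) -> int:
        return len(self.mean_shape)

    @property
    def n_modes(self) -> int:
        return len(self.eigenvalues)


def build_model(registered: RegisteredSet, cohort_label: str = "") -> ShapeModel:
    """PCA of the registered set (≥ 2 subjects, shared point ordering).

    Uses the thin SVD of the centred (N × 3n) data matrix, which is the
    Gram-trick eigendecomposition when 3n ≫ N.  Eigenvector signs are
    fixed so each row's largest-magnitude entry is positive.
    """
    shapes = [np.asarray(p, float) for p in registered.registered_points]
    if len(shapes) < 2:
        raise ParameterError("PCA needs at least 2 subjects")
    n = shapes[0].shape[0]
    if any(s.shape != (n, 3) for s in shapes):
        raise CorrespondenceError("subjects have mismatched point counts")
    data = np.stack([s.reshape(-1) for s in shapes])  # (N, 3n)
    mean = data.mean(axis=0)
    centred = data - mean
    u, s, vt = np.linalg.svd(centred, full_matrices=False)
    n_sub = len(shapes)
    r = min(n_sub - 1, vt.shape[0])
    s, vt, u = s[:r], vt[:r], u[:, :r]
    # deterministic sign: largest-|.| component of each mode positive
    flips = np.where(vt[np.arange(r), np.abs(vt).argmax(axis=1)] < 0, -1.0, 1.0)
    vt = vt * flips[:, None]
    eigenvalues = s ** 2 / (n_sub - 1)
    total = eigenvalues.sum()
    fractions = eigenvalues / total if total > 0 else np.zeros_like(eigenvalues)
    scores = centred @ vt.T
    return ShapeModel(mean.reshape(-1, 3), vt, eigenvalues, fractions,
                      n_subjects=n_sub, cohort_label=cohort_label,
                      training_scores=scores)


def synthesize(model: ShapeModel, scores) -> PointCloud:
    """Shape at the given mode scores, in σ-units per mode:

    shape = mean + Σ_k scores_k · √eigenvalue_k · eigenvector_k.
    """
    scores = np.asarray(scores, float).reshape(-1)
    if len(scores) > model.n_modes:
        raise ParameterError(f"{len(scores)} scores but model has {model.n_modes} modes")
    flat = model.mean_shape.reshape(-1).copy()
    for k, c in enumerate(scores):
        flat += c * np.sqrt(model.eigenvalues[k]) * model.eigenvectors[k]
    return PointCloud(flat.reshape(-1, 3), source_id=f"{model.cohort_label}:synth")


def variance_explained(model: ShapeModel, k: int) -> float:
    """Cumulative fraction of total variance in the first k modes."""
    if not 1 <= k <= model.n_modes:
        raise ParameterError(f"k must be in [1, {model.n_modes}]")
    return float(model.variance_fraction[:k].sum())


def triangulate_correspondence(cloud, reference_mesh: TriMesh,
                               reference_cloud: PointCloud) -> TriMesh:
    """Transfer the reference mesh connectivity onto a corresponded cloud.

    ``cloud`` must be in one-to-one correspondence (same order) with
    ``reference_cloud``, and ``reference_cloud`` must be a reordering of
    the reference mesh's vertices; the vertex permutation is recovered
    by exact nearest-neighbour matching and applied to the faces.
    """
    pts = cloud.points if isinstance(cloud, PointCloud) else np.asarray(cloud, float).reshape(-1, 3)
    ref = reference_cloud.points
    if len(pts) != len(ref):
        raise CorrespondenceError(
            f"cloud has {len(pts)} points, reference cloud has {len(ref)}")
    if len(ref) != reference_mesh.n_vertices:
        raise CorrespondenceError(
            "reference cloud does not cover the reference mesh vertices "
            f"({len(ref)} vs {reference_mesh.n_vertices})")
    d, perm = cKDTree(ref).query(reference_mesh.vertices)
    if d.max() > 1e-8 or len(np.unique(perm)) != len(perm):
        raise CorrespondenceError("reference cloud is not a permutation of the mesh vertices")
    # mesh vertex v sits at reference_cloud[perm[v]], hence at pts[perm[v]]
    return TriMesh(pts[perm], reference_mesh.faces.copy(), name=reference_mesh.name)
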