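"""Thin-plate-spline deformation model.

The deformation maps a point set T through T' = T + φ θ, where φ is the
radial-basis matrix with entries φ(m, n) = ‖T_m − c_n‖₂ over control
points c_n (the 3D fundamental-solution kernel U(r) = r) and θ is the
(n_ctrl × 3) coefficient matrix.  There is no affine block by default;
gross pose is handled by rigid pre-alignment upstream.  The bending
(stress) energy tr(θᵀ φᵀ φ θ) = ‖φθ‖²_F penalizes non-smooth warps and
has gradient 2 φᵀφ θ.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist

from .geometry_io import ParameterError, PointCloud

__all__ = ["TPSTransform", "basis_matrix", "apply", "stress_energy", "stress_gradient"]


@dataclass
class TPSTransform:
    """Control points (n_ctrl, 3) mm and coefficients theta (n_ctrl, 3)."""

    control_points: np.ndarray
    theta: np.ndarray

    def __post_init__(self) -> None:
        self.control_points = np.asarray(self.control_points, float).reshape(-1, 3)
        self.theta = np.asarray(self.theta, float).reshape(-1, 3)
        if len(self.control_points) < 4:
            raise ParameterError("a TPS needs at least 4 control points")
        if self.theta.shape != self.control_points.shape:
            raise ParameterError("theta must be (n_ctrl, 3)")
        if not np.isfinite(self.theta).all():
            raise ParameterError("theta must be finite")

    @classmethod
    def identity(cls, control_points) -> "TPSTransform":
        cp = np.asarray(control_points, float).reshape(-1, 3)
        return cls(cp, np.zeros_like(cp))

    # -- plain-text serialization (control-point block, then theta block) --

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# tps n_control={len(self.control_points)}\n")
            fh.write("# control_points\n")
            np.savetxt(fh, self.control_points)
            fh.write("# theta\n")
            np.savetxt(fh, self.theta)

    @classmethod
    def load(cls, path) -> "TPSTransform":
        rows = np.loadtxt(Path(path), comments="#")
        if rows.shape[0] % 2 != 0:
            raise ParameterError(f"{path}: malformed TPS file")
        n = rows.shape[0] // 2
        return cls(rows[:n], rows[n:])


def basis_matrix(points, control_points) -> np.ndarray:
    """Radial basis matrix: entry (m, n) = ‖point_m − control_n‖₂."""
    pts = points.points if isinstance(points, PointCloud) else np.asarray(points, float)
    cps = (control_points.points if isinstance(control_points, PointCloud)
           else np.asarray(control_points, float))
    if len(pts) == 0 or len(cps) == 0:
        raise ParameterError("basis_matrix needs non-empty point sets")
    return cdist(pts.reshape(-1, 3), cps.reshape(-1, 3))


def apply(t: TPSTransform, points) -> PointCloud:
    """Deform ``points`` by T' = T + φ θ (φ built against t.control_points)."""
    pts = points.points if isinstance(points, PointCloud) else np.asarray(points, float).reshape(-1, 3)
    phi = basis_matrix(pts, t.control_points)
    moved = pts + phi @ t.theta
    source = points.source_id if isinstance(points, PointCloud) else ""
    return PointCloud(moved, source_id=source)


def stress_energy(t: TPSTransform, basis: np.ndarray) -> float:
    """Bending energy tr(θᵀ φᵀ φ θ) = ‖φ θ‖²_F ≥ 0."""
    basis = np.asarray(basis, float)
    if basis.shape[1] != t.theta.shape[0]:
        raise ParameterError("basis columns must match control-point count")
    d = basis @ t.theta
    return float(np.einsum("ij,ij->", d, d))


def stress_gradient(t: TPSTransform, basis: np.ndarray) -> np.ndarray:
    """Gradient of the bending energy: 2 φᵀ φ θ (n_ctrl × 3)."""
    basis = np.asarray(basis, float)
    if basis.shape[1] != t.theta.shape[0]:
        raise ParameterError("basis columns must match control-point count")
    return 2.0 * basis.T @ (basis @ t.theta)
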