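"""Gaussian-mixture representation of point clouds and the closed-form
L2 divergence between two mixtures.

Each cloud T with n points p_j is modelled as the equal-weight mixture

    D(x) = (1/n) sum_j G(x | p_j, sigma)

with a shared kernel covariance sigma.  The L2 divergence between two
clouds is the integrated squared density difference

    f_L2(Ti, Tj) = ∫ (Di − Dj)² dx
                 = ∫ Di² dx − 2 ∫ Di Dj dx + ∫ Dj² dx,

and every term reduces to sums of Gaussian product integrals

    ∫ G(x|u1, s1) G(x|u2, s2) dx = G(0 | u1 − u2, s1 + s2),

so the divergence and its gradient with respect to the point positions
are available in closed form.  Because distant kernel pairs contribute
negligibly, an optional k-nearest-neighbour truncation keeps only each
point's k closest partners (in the other cloud for the cross term, in
its own cloud for the squared terms) while retaining the full double-sum
1/(n_i n_j) weighting, so the truncated value approximates the full sum.

Two kernel normalisations are supported.  ``standard`` (default) uses
the properly normalised multivariate normal, for which the closed form
above is exact.  ``printed`` reproduces a legacy kernel with constant
1/((2π)^{3/2}|σ|) and exponent −rᵀσ⁻¹r, which equals a normalised
Gaussian of covariance σ/2 scaled by α = |σ/2|^{1/2}/|σ|; internally it
is handled exactly through that equivalence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .geometry_io import EmptyMeshError, ParameterError, PointCloud

__all__ = [
    "KernelConfig",
    "TruncationPairs",
    "gaussian_density",
    "mixture_density",
    "gauss_product_integral",
    "l2_divergence",
    "l2_gradient",
    "build_pairs",
    "l2_value_and_point_grad",
]


@dataclass
class KernelConfig:
    """Kernel covariance, neighbour truncation, and normalisation mode.

    sigma : (3, 3) symmetric positive-definite covariance in mm².
    knn : neighbours kept per point in truncated mode; ``None`` disables
        truncation (exact double sums).
    normalization : ``"standard"`` or ``"printed"`` (see module docstring).
    """

    sigma: np.ndarray = field(default_factory=lambda: np.eye(3))
    knn: int | None = 6
    normalization: str = "standard"

    def __post_init__(self) -> None:
        self.sigma = np.asarray(self.sigma, float).reshape(3, 3)
        if not np.allclose(self.sigma, self.sigma.T):
            raise ParameterError("sigma must be symmetric")
        if np.linalg.eigvalsh(self.sigma).min() <= 0:
            raise ParameterError("sigma must be positive-definite")
        if self.knn is not None and self.knn < 1:
            raise ParameterError("knn must be >= 1 (or None for no truncation)")
        if self.normalization not in ("standard", "printed"):
            raise ParameterError("normalization must be 'standard' or 'printed'")

    @property
    def effective_sigma(self) -> np.ndarray:
        """Covariance of the equivalent normalised Gaussian kernel."""
        return self.sigma if self.normalization == "standard" else self.sigma / 2.0

    @property
    def amplitude(self) -> float:
        """Scalar multiplying the equivalent normalised kernel."""
        if self.normalization == "standard":
            return 1.0
        return float(np.sqrt(np.linalg.det(self.sigma / 2.0)) / np.linalg.det(self.sigma))


def gaussian_density(x, u, sigma) -> float:
    """Normalised multivariate normal density G(x | u, sigma)."""
    x = np.asarray(x, float).reshape(3)
    u = np.asarray(u, float).reshape(3)
    sigma = np.asarray(sigma, float).reshape(3, 3)
    det = np.linalg.det(sigma)
    if det <= 0:
        raise ParameterError("sigma must be positive-definite")
    d = x - u
    expo = -0.5 * d @ np.linalg.solve(sigma, d)
    return float(np.exp(expo) / np.sqrt((2.0 * np.pi) ** 3 * det))


def gauss_product_integral(u1, u2, s1, s2) -> float:
    """∫ G(x|u1,s1) G(x|u2,s2) dx = G(0 | u1 − u2, s1 + s2)."""
    s = np.asarray(s1, float) + np.asarray(s2, float)
    return gaussian_density(np.zeros(3), np.asarray(u1, float) - np.asarray(u2, float), s)


def mixture_density(x, cloud: PointCloud, cfg: KernelConfig) -> float:
    """Mixture density of ``cloud`` at ``x`` (1/n-weighted kernel average)."""
    if len(cloud) == 0:
        raise EmptyMeshError("mixture density of an empty cloud is undefined")
    x = np.asarray(x, float).reshape(3)
    sig = cfg.effective_sigma
    inv = np.linalg.inv(sig)
    norm = cfg.amplitude / np.sqrt((2.0 * np.pi) ** 3 * np.linalg.det(sig))
    d = cloud.points - x
    expo = -0.5 * np.einsum("ij,jk,ik->i", d, inv, d)
    return float(norm * np.exp(expo).mean())


# ---------------------------------------------------------------------------
# pairwise machinery
#
# All pair terms share the covariance S = 2 * effective_sigma and the
# amplitude alpha².  Points are whitened by the Cholesky factor of S once,
# after which every Gaussian product integral is
#   q(a, b) = alpha² * c0 * exp(−½ |wa − wb|²),   c0 = (2π)^{−3/2} |S|^{−1/2}.
# ---------------------------------------------------------------------------


def _whitener(cfg: KernelConfig):
    s = 2.0 * cfg.effective_sigma
    chol = np.linalg.cholesky(s)
    c0 = cfg.amplitude ** 2 / np.sqrt((2.0 * np.pi) ** 3 * np.linalg.det(s))
    sinv = np.linalg.inv(s)
    return chol, c0, sinv


def _pair_sum(x: np.ndarray, y: np.ndarray, pairs: np.ndarray | None, cfg: KernelConfig) -> float:
    """Sum of Gaussian product integrals over point pairs.

    ``pairs`` is an (K, 2) index array into (x, y); ``None`` means all pairs.
    """
    chol, c0, _ = _whitener(cfg)
    wx = np.linalg.solve(chol, x.T).T
    wy = np.linalg.solve(chol, y.T).T
    if pairs is None:
        d2 = ((wx[:, None, :] - wy[None, :, :]) ** 2).sum(axis=2)
        return float(c0 * np.exp(-0.5 * d2).sum())
    d2 = ((wx[pairs[:, 0]] - wy[pairs[:, 1]]) ** 2).sum(axis=1)
    return float(c0 * np.exp(-0.5 * d2).sum())


def _sym_unique(pairs: np.ndarray) -> np.ndarray:
    both = np.vstack([pairs, pairs[:, ::-1]])
    return np.unique(both, axis=0)


@dataclass
class TruncationPairs:
    """Fixed neighbour-pair lists for one (deformed-reference, target) pair.

    Freezing the pairs keeps the truncated objective smooth within one
    optimizer run; callers rebuild them between outer iterations.
    ``None`` entries denote exact (all-pairs) evaluation.
    """

    cross: np.ndarray | None  # (K, 2) indices (ref, target)
    self_ref: np.ndarray | None  # (K, 2) symmetric ordered pairs within ref
    self_tgt: np.ndarray | None  # same within target
    const_tgt_sum: float | None = None  # cached Σq over self_tgt (θ-independent)


def build_pairs(x: np.ndarray, y: np.ndarray, cfg: KernelConfig,
                active: np.ndarray | None = None) -> TruncationPairs:
    """k-nearest-neighbour pair lists between current reference positions
    ``x`` and target positions ``y``.

    ``active`` optionally restricts the reference side to an index subset
    (refinement of high-deviation points): cross pairs keep only active
    reference points and the reference self term runs over active points.
    """
    if cfg.knn is None:
        if active is None:
            return TruncationPairs(None, None, None)
        nx, ny = len(x), len(y)
        cross = np.stack(np.meshgrid(active, np.arange(ny), indexing="ij"), axis=-1).reshape(-1, 2)
        sr = np.stack(np.meshgrid(active, active, indexing="ij"), axis=-1).reshape(-1, 2)
        return TruncationPairs(cross, sr, None)
    k = cfg.knn
    tx = cKDTree(x)
    ty = cKDTree(y)
    kx = min(k, len(y))
    ky = min(k, len(x))
    # cross: each x-point's k nearest in y, plus each y-point's k nearest in x
    ix = tx.query(y, k=ky)[1].reshape(len(y), -1)
    iy = ty.query(x, k=kx)[1].reshape(len(x), -1)
    cross_a = np.column_stack([np.repeat(np.arange(len(x)), kx), iy.ravel()])
    cross_b = np.column_stack([ix.ravel(), np.repeat(np.arange(len(y)), ky)])
    cross = np.unique(np.vstack([cross_a, cross_b]), axis=0)
    # self terms: k nearest within own cloud (self included at distance 0)
    ks = min(k, len(x))
    sr = tx.query(x, k=ks)[1].reshape(len(x), -1)
    self_ref = _sym_unique(np.column_stack([np.repeat(np.arange(len(x)), ks), sr.ravel()]))
    kt = min(k, len(y))
    st = ty.query(y, k=kt)[1].reshape(len(y), -1)
    self_tgt = _sym_unique(np.column_stack([np.repeat(np.arange(len(y)), kt), st.ravel()]))
    if active is not None:
        mask = np.zeros(len(x), bool)
        mask[active] = True
        cross = cross[mask[cross[:, 0]]]
        self_ref = self_ref[mask[self_ref[:, 0]] & mask[self_ref[:, 1]]]
    return TruncationPairs(cross, self_ref, self_tgt)


def l2_value_and_point_grad(x: np.ndarray, y: np.ndarray, cfg: KernelConfig,
                            pairs: TruncationPairs | None = None,
                            need_grad: bool = True):
    """L2 divergence between mixtures on ``x`` (movable) and ``y`` (fixed),
    and its gradient with respect to each x-point.

    Returns ``(value, grad)`` with ``grad`` of shape (len(x), 3) or ``None``.
    The Dj² (target-only) term is included in the value and is constant in
    ``x``, so it never contributes to the gradient.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    nx, ny = len(x), len(y)
    if nx == 0 or ny == 0:
        raise EmptyMeshError("L2 divergence needs two non-empty clouds")
    if pairs is None:
        pairs = build_pairs(x, y, cfg)
    chol, c0, sinv = _whitener(cfg)
    wx = np.linalg.solve(chol, x.T).T
    wy = np.linalg.solve(chol, y.T).T

    def term(wa, wb, pr, a_pts, b_pts, with_grad):
        """Sum of q(a,b) over pairs and the slot-0 scatter of ∇₁q.

        ∇₁q(a,b) = −q · S⁻¹ (a − b).  For a pair set symmetric in its two
        slots (all-pairs, or the symmetrized kNN self list), the full
        derivative d/d a_k of the pair sum is exactly twice this scatter.
        """
        if pr is None:
            d2 = ((wa[:, None, :] - wb[None, :, :]) ** 2).sum(axis=2)
            q = c0 * np.exp(-0.5 * d2)
            if with_grad:
                diff = a_pts[:, None, :] - b_pts[None, :, :]
                g = -(q[..., None] * (diff @ sinv.T)).sum(axis=1)
                return float(q.sum()), g
            return float(q.sum()), None
        d2 = ((wa[pr[:, 0]] - wb[pr[:, 1]]) ** 2).sum(axis=1)
        q = c0 * np.exp(-0.5 * d2)
        if with_grad:
            gi = -(q[:, None] * ((a_pts[pr[:, 0]] - b_pts[pr[:, 1]]) @ sinv.T))
            g = np.column_stack([np.bincount(pr[:, 0], weights=gi[:, c], minlength=len(a_pts))
                                 for c in range(3)])
            return float(q.sum()), g
        return float(q.sum()), None

    s_xx, g_xx = term(wx, wx, pairs.self_ref, x, x, need_grad)
    s_xy, g_xy = term(wx, wy, pairs.cross, x, y, need_grad)
    if pairs.const_tgt_sum is not None:
        s_yy = pairs.const_tgt_sum
    else:
        s_yy, _ = term(wy, wy, pairs.self_tgt, y, y, False)
        pairs.const_tgt_sum = s_yy
    value = s_xx / nx ** 2 - 2.0 * s_xy / (nx * ny) + s_yy / ny ** 2
    grad = None
    if need_grad:
        grad = 2.0 * g_xx / nx ** 2 - 2.0 * g_xy / (nx * ny)
    return value, grad


# ---------------------------------------------------------------------------
# spec-surface wrappers
# ---------------------------------------------------------------------------


def l2_divergence(ti: PointCloud, tj: PointCloud, cfg: KernelConfig) -> float:
    """L2 divergence between the Gaussian mixtures of two clouds.

    Non-negative; zero iff the two mixtures coincide.  With ``cfg.knn``
    set, cross and squared terms are truncated to nearest neighbours.
    """
    value, _ = l2_value_and_point_grad(ti.points, tj.points, cfg, need_grad=False)
    return value


def l2_gradient(ti_deformed: PointCloud, tj: PointCloud, basis: np.ndarray,
                cfg: KernelConfig, pairs: TruncationPairs | None = None) -> np.ndarray:
    """Gradient of the L2 divergence with respect to the TPS coefficients.

    ``ti_deformed`` holds the current deformed reference positions
    x = ref + basis @ theta; the chain rule gives d/dθ = basisᵀ (d/dx).
    """
    basis = np.asarray(basis, float)
    if basis.shape[0] != len(ti_deformed):
        raise ParameterError("basis rows must match the deformed reference point count")
    _, g = l2_value_and_point_grad(ti_deformed.points, tj.points, cfg, pairs=pairs)
    return basis.T @ g
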