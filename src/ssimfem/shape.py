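"""Shape pipeline: alignment, kernel deformations and the shape matrix.

Each subject's anatomy is expressed relative to a template through a set of
moment vectors ``beta`` attached to a shared control-point grid: a point
``x`` is carried to

    x + sum_k exp(-||x - c_k||^2 / w^2) * beta_k

with ``c_k`` the control points and ``w`` the kernel width (mm).  This is a
single-step Gaussian-kernel small-deformation model: it keeps the data
structure of a moment-based non-parametric shape representation (moments on
a control grid, no landmarking) while replacing geodesic large-deformation
flows by their linearisation.  The departure matters for large deformations
only; the statistical pipeline downstream is unchanged.

Alignment is two-step: a pose initialisation from anatomical annotations
(femoral-head centre + neck axis, roll about the neck axis resolved by the
shaft axis), then point-to-point ICP.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

__all__ = [
    "ControlGrid",
    "MomentField",
    "ShapeMatrix",
    "AnatomicalFrame",
    "RigidTransform",
    "make_control_grid",
    "kernel_matrix",
    "deform",
    "initial_align",
    "kabsch",
    "icp_align",
    "fit_moments",
    "build_shape_matrix",
]


@dataclass
class ControlGrid:
    """Shared control-point grid: ``points`` (q, 3) in mm, Gaussian
    ``kernel_width`` in mm."""

    points: np.ndarray
    kernel_width: float

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.shape[1] != 3 or self.points.shape[0] < 1:
            raise ValueError("grid points must be (q, 3) with q >= 1")
        if len(np.unique(self.points, axis=0)) != len(self.points):
            raise ValueError("grid points must be distinct")
        if not self.kernel_width > 0:
            raise ValueError("kernel_width must be > 0")

    @property
    def q(self) -> int:
        return len(self.points)

    def same_as(self, other: "ControlGrid") -> bool:
        return (self.points.shape == other.points.shape
                and np.array_equal(self.points, other.points)
                and self.kernel_width == other.kernel_width)


def make_control_grid(bounds_min, bounds_max, q: int,
                      kernel_width: Optional[float] = None) -> ControlGrid:
    """Regular lattice of ``q`` control points covering an axis-aligned box.

    When ``q`` is a perfect cube the grid is the full k x k x k lattice
    (e.g. q=64 on the unit box gives exactly the 4x4x4 lattice corners);
    otherwise the lattice is the smallest cube covering ``q`` and the first
    ``q`` points in lexicographic (x-fastest) order are kept.

    ``kernel_width`` defaults to twice the largest lattice spacing, giving
    smooth deformations with full spatial coverage.
    """
    lo = np.asarray(bounds_min, dtype=float)
    hi = np.asarray(bounds_max, dtype=float)
    if q < 1:
        raise ValueError("q must be >= 1")
    k = int(round(q ** (1.0 / 3.0)))
    while k ** 3 < q:
        k += 1
    axes = [np.linspace(lo[d], hi[d], k) if k > 1 else
            np.array([(lo[d] + hi[d]) / 2.0]) for d in range(3)]
    zz, yy, xx = np.meshgrid(axes[2], axes[1], axes[0], indexing="ij")
    pts = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])[:q]
    if kernel_width is None:
        spacing = (hi - lo) / max(k - 1, 1)
        kernel_width = 2.0 * float(np.max(spacing))
        if kernel_width <= 0:
            kernel_width = 1.0
    return ControlGrid(pts, kernel_width)


@dataclass
class MomentField:
    """Per-subject moment vectors ``beta`` (q, 3) on a control grid.

    Flattening to length 3q is row-major per control point:
    ``(bx1, by1, bz1, ..., bxq, byq, bzq)``.
    """

    beta: np.ndarray
    grid: Optional[ControlGrid] = None

    def __post_init__(self):
        self.beta = np.atleast_2d(np.asarray(self.beta, dtype=float))
        if self.beta.shape[1] != 3:
            raise ValueError("beta must be (q, 3)")
        if not np.all(np.isfinite(self.beta)):
            raise ValueError("beta entries must be finite")
        if self.grid is not None and self.grid.q != len(self.beta):
            raise ValueError("beta row count does not match grid size")

    @property
    def flat(self) -> np.ndarray:
        return self.beta.reshape(-1)

    @classmethod
    def from_flat(cls, flat: np.ndarray,
                  grid: Optional[ControlGrid] = None) -> "MomentField":
        flat = np.asarray(flat, dtype=float).ravel()
        if flat.size % 3:
            raise ValueError("flat moment vector length must be 3q")
        return cls(flat.reshape(-1, 3), grid)


@dataclass
class ShapeMatrix:
    """N x 3q matrix with subject i's flattened moments in row i."""

    X_beta: np.ndarray
    subject_ids: List[str]
    grid: Optional[ControlGrid] = None


@dataclass
class AnatomicalFrame:
    """Annotations used for pose initialisation: femoral-head centre (mm),
    neck-shaft axis direction and shaft axis direction (unit-normalised on
    construction)."""

    head_centre: np.ndarray
    neck_axis: np.ndarray
    shaft_axis: np.ndarray

    def __post_init__(self):
        self.head_centre = np.asarray(self.head_centre, dtype=float).ravel()
        for name in ("neck_axis", "shaft_axis"):
            v = np.asarray(getattr(self, name), dtype=float).ravel()
            n = np.linalg.norm(v)
            if n == 0:
                raise ValueError(f"{name} must be a nonzero vector")
            setattr(self, name, v / n)


@dataclass
class RigidTransform:
    """x -> R @ x + t"""

    rotation: np.ndarray
    translation: np.ndarray

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.rotation.T + \
            self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other: (self o other)(x) = R_s (R_o x + t_o) + t_s."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation
                              + self.translation)

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T,
                              -self.rotation.T @ self.translation)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))


def _frame_basis(frame: AnatomicalFrame) -> np.ndarray:
    """Right-handed orthonormal basis (neck axis, orthogonalised shaft
    axis, their cross product) as columns."""
    e1 = frame.neck_axis
    s = frame.shaft_axis - (frame.shaft_axis @ e1) * e1
    n = np.linalg.norm(s)
    if n < 1e-12:
        raise ValueError("shaft axis is parallel to the neck axis; the roll "
                         "about the neck axis cannot be resolved")
    e2 = s / n
    e3 = np.cross(e1, e2)
    return np.column_stack([e1, e2, e3])


def initial_align(subject: AnatomicalFrame,
                  reference: AnatomicalFrame) -> RigidTransform:
    """Rigid pose initialisation from anatomical annotations.

    The rotation maps the subject's neck axis exactly onto the reference's
    (to round-off) and resolves the residual roll about the neck axis by
    aligning the (orthogonalised) shaft axes; the translation then
    superposes the femoral-head centres exactly.  Works for anti-parallel
    axes too: the frame construction picks the rotation of pi about the
    axis bisecting the two shaft directions.
    """
    if subject is None or reference is None:
        raise ValueError("both surfaces must carry anatomical annotations "
                         "(head centre, neck axis, shaft axis)")
    R = _frame_basis(reference) @ _frame_basis(subject).T
    t = reference.head_centre - R @ subject.head_centre
    return RigidTransform(R, t)


def kabsch(source: np.ndarray, target: np.ndarray) -> RigidTransform:
    """Least-squares rigid transform mapping ``source`` onto ``target``
    under fixed one-to-one correspondence (SVD of the cross-covariance,
    determinant-corrected to a proper rotation)."""
    P = np.asarray(source, dtype=float)
    Q = np.asarray(target, dtype=float)
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    H = (P - cp).T @ (Q - cq)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    return RigidTransform(R, cq - R @ cp)


def icp_align(source_points: np.ndarray, target_points: np.ndarray,
              max_iter: int = 50, tol: float = 1e-10,
              init: Optional[RigidTransform] = None):
    """Point-to-point ICP.

    Closest-point correspondence (KD-tree), least-squares rigid update by
    :func:`kabsch`, iterated until the mean-squared-distance improvement
    drops below ``tol`` or ``max_iter`` is reached.  Non-convergence is not
    an error: the best transform so far is returned with ``converged=False``.

    Returns ``(RigidTransform, rmsd, converged)``.
    """
    src = np.asarray(source_points, dtype=float)
    tgt = np.asarray(target_points, dtype=float)
    if len(src) < 4 or len(tgt) < 4:
        raise ValueError("ICP needs at least 4 points on each side")
    transform = init if init is not None else RigidTransform.identity()
    tree = cKDTree(tgt)
    cur = transform.apply(src)
    prev_msd = np.inf
    converged = False
    for _ in range(max_iter):
        dists, idx = tree.query(cur)
        msd = float(np.mean(dists ** 2))
        if prev_msd - msd < tol:
            converged = True
            break
        step = kabsch(cur, tgt[idx])
        transform = step.compose(transform)
        cur = step.apply(cur)
        prev_msd = msd
    dists, _ = tree.query(cur)
    rmsd = float(np.sqrt(np.mean(dists ** 2)))
    if not converged:
        warnings.warn(f"ICP did not converge in {max_iter} iterations "
                      f"(RMSD {rmsd:.3g}); returning best transform so far")
    return transform, rmsd, converged


def kernel_matrix(points: np.ndarray, grid: ControlGrid) -> np.ndarray:
    """Gaussian kernel matrix K[i, k] = exp(-||x_i - c_k||^2 / w^2)."""
    d2 = cdist(np.atleast_2d(points), grid.points, "sqeuclidean")
    return np.exp(-d2 / grid.kernel_width ** 2)


def deform(template_points: np.ndarray, grid: ControlGrid,
           beta) -> np.ndarray:
    """Apply the kernel deformation to points; exactly linear in ``beta``.

    Applying the same moments to surface vertices and tet-mesh nodes yields
    corresponding (iso-topological) meshes.
    """
    if isinstance(beta, MomentField):
        B = beta.beta
    else:
        B = np.asarray(beta, dtype=float)
        if B.ndim == 1:
            B = B.reshape(-1, 3)
    if B.shape != (grid.q, 3):
        raise ValueError(f"beta shape {B.shape} incompatible with grid of "
                         f"{grid.q} control points")
    pts = np.atleast_2d(np.asarray(template_points, dtype=float))
    return pts + kernel_matrix(pts, grid) @ B


def fit_moments(template_points: np.ndarray, subject_points: np.ndarray,
                grid: ControlGrid, max_iter: int = 25, tol: float = 1e-8,
                reg_lambda: Optional[float] = None) -> MomentField:
    """Estimate the moment field carrying the template onto a subject.

    Alternates (a) closest-point correspondence from the currently deformed
    template vertices to the subject vertices (vertex-to-vertex) with
    (b) a ridge-regularised linear least-squares solve for ``beta``
    minimising ``sum ||deform(v) - corresp(v)||^2 + reg_lambda ||beta||^2``.
    Stops when the maximum vertex displacement update falls below ``tol``
    (mm) or after ``max_iter`` rounds.  Deterministic.

    ``reg_lambda`` defaults to ``1e-6 * trace(K^T K)``, a scale-free
    conditioning floor.  At ``reg_lambda=0`` a singular normal system
    raises with the advice to increase the regularisation.
    """
    tmpl = np.atleast_2d(np.asarray(template_points, dtype=float))
    subj = np.atleast_2d(np.asarray(subject_points, dtype=float))
    K = kernel_matrix(tmpl, grid)
    G = K.T @ K
    if reg_lambda is None:
        reg_lambda = 1e-6 * float(np.trace(G))
    A = G + reg_lambda * np.eye(grid.q)
    if reg_lambda == 0 and np.linalg.matrix_rank(G) < grid.q:
        raise np.linalg.LinAlgError(
            "singular normal system while fitting moments (fewer "
            "independent surface constraints than control points); raise "
            "reg_lambda above 0")
    tree = cKDTree(subj)
    B = np.zeros((grid.q, 3))
    prev = tmpl.copy()
    for _ in range(max_iter):
        cur = tmpl + K @ B
        _, idx = tree.query(cur)
        D = subj[idx] - tmpl
        try:
            B_new = np.linalg.solve(A, K.T @ D)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                "singular normal system while fitting moments; raise "
                "reg_lambda above 0") from exc
        new = tmpl + K @ B_new
        update = float(np.max(np.linalg.norm(new - prev, axis=1)))
        B = B_new
        prev = new
        if update < tol:
            break
    return MomentField(B, grid)


def build_shape_matrix(moment_fields: Sequence[MomentField],
                       subject_ids: Optional[Sequence[str]] = None
                       ) -> ShapeMatrix:
    """Stack flattened moment fields into the N x 3q shape matrix,
    preserving subject order.  All fields must share one grid."""
    if not moment_fields:
        raise ValueError("no moment fields given")
    grid = moment_fields[0].grid
    for i, f in enumerate(moment_fields):
        same = (f.grid is None and grid is None) or \
            (f.grid is not None and grid is not None and f.grid.same_as(grid))
        if not same:
            raise ValueError(f"moment field {i} uses a different control "
                             "grid; all subjects must share one grid")
        if f.beta.shape != moment_fields[0].beta.shape:
            raise ValueError(f"moment field {i} has {len(f.beta)} control "
                             "points, expected "
                             f"{len(moment_fields[0].beta)}")
    X = np.vstack([f.flat for f in moment_fields])
    if subject_ids is None:
        subject_ids = [f"subject_{i:03d}" for i in range(len(moment_fields))]
    return ShapeMatrix(X, list(subject_ids), grid)
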