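"""Partial-least-squares (NIPALS PLS1) mode extraction.

The statistical shape model (SSM), statistical intensity model (SIM) and the
two-level shape-and-intensity model (SSIM) all rest on the same primitive:
given a data matrix ``X`` (one subject per row — moment vectors for shape,
element-wise density for intensity, or concatenated component matrices for
the fused model) and a binary fracture-status array ``y``, extract the
directions ("modes") of maximal covariance between ``X`` and ``y``.

Every subject is then represented, to ``m`` modes, as

    x_i = x_bar + sum_j t_ij * p_j

where ``x_bar`` is the column mean, ``p_j`` the j-th mode (X-loading) and
``t_ij`` the subject's j-th component (score).  Columns are centered but not
variance-scaled by default: within each block (shape, intensity) the units
are homogeneous, so scaling would only reweight noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "PLSModel",
    "fit_pls",
    "reconstruct",
    "project",
    "predict_y",
    "fit_ssim",
    "modes_to_explain",
    "ModeCount",
    "mode_vector",
    "export_shape_mode",
    "export_intensity_mode",
    "export_ssim_mode",
]


@dataclass
class PLSModel:
    """Fitted PLS1 model.

    Attributes
    ----------
    mean : (p,) column means of the training matrix.
    y_mean : scalar mean of the (0/1) response.
    weights : (p, m) NIPALS weight vectors w_j (unit norm).
    modes : (p, m) X-loadings p_j, the PLS modes.
    components : (N, m) training scores t_j^i.
    y_loadings : (m,) regression loadings q_j of the deflated response.
    mode_variance : (m,) variance of each score column (ddof=1); the
        "mode variance" sigma^2 used for +/-sigma mode rendering.
    varexp_x, varexp_y : (m,) cumulative fractions of the centered X / y
        sum of squares captured by the first j modes.
    stopped_early : True when extraction halted because the residual
        cross-covariance vanished before the requested mode count.
    scaled : whether columns were variance-scaled before fitting.
    block_sizes : for two-level (SSIM) models, the number of input columns
        contributed by each block, e.g. (m_shape, m_int); None otherwise.
    """

    mean: np.ndarray
    y_mean: float
    weights: np.ndarray
    modes: np.ndarray
    components: np.ndarray
    y_loadings: np.ndarray
    mode_variance: np.ndarray
    varexp_x: np.ndarray
    varexp_y: np.ndarray
    stopped_early: bool = False
    scaled: bool = False
    scale_: Optional[np.ndarray] = None
    block_sizes: Optional[tuple] = None

    @property
    def n_modes(self) -> int:
        return self.weights.shape[1]


def fit_pls(
    X: np.ndarray,
    y: np.ndarray,
    m: Optional[int] = None,
    *,
    varexp_target: Optional[float] = None,
    scale: bool = False,
) -> PLSModel:
    """Fit a PLS1 model of ``X`` against a binary response ``y`` by NIPALS.

    Per mode j (on the column-centered, deflated matrices ``X_j``, ``y_j``):

    - weight        ``w_j = X_j^T y_j / ||X_j^T y_j||``
    - score         ``t_j = X_j w_j``
    - X-loading     ``p_j = X_j^T t_j / (t_j^T t_j)``
    - y-loading     ``q_j = y_j^T t_j / (t_j^T t_j)``
    - deflation     ``X_{j+1} = X_j - t_j p_j^T``,  ``y_{j+1} = y_j - q_j t_j``

    Each ``w_j`` is sign-fixed so that its largest-magnitude entry is
    positive (scores and loadings flipped consistently), making mode signs
    reproducible.

    Parameters
    ----------
    m : number of modes to extract; defaults to ``min(N - 1, p)`` when
        ``varexp_target`` is not given.
    varexp_target : when set, stop as soon as the cumulative X-variance
        explained reaches this fraction (capped at ``min(N - 1, p)``).
    scale : variance-scale columns before fitting (default off).

    Raises
    ------
    ValueError : on single-class ``y`` or invalid shapes.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2:
        raise ValueError("X must be 2-D (subjects x variables)")
    N, p = X.shape
    if y.shape[0] != N:
        raise ValueError(f"y length {y.shape[0]} != number of rows {N}")
    if N < 2:
        raise ValueError("need at least 2 subjects")
    if np.unique(y).size < 2:
        raise ValueError("y contains a single class; PLS1 against a constant "
                         "response is undefined")
    m_max = min(N - 1, p)
    if m is None:
        m = m_max
    if not 1 <= m <= m_max:
        raise ValueError(f"m must be in [1, {m_max}], got {m}")

    mean = X.mean(axis=0)
    Xc = X - mean
    scale_ = None
    if scale:
        scale_ = Xc.std(axis=0, ddof=1)
        scale_[scale_ == 0] = 1.0
        Xc = Xc / scale_
    y_mean = float(y.mean())
    yc = y - y_mean

    ssx_total = float(np.sum(Xc * Xc))
    ssy_total = float(np.sum(yc * yc))

    W, P, T, Q = [], [], [], []
    ssx_cum, ssy_cum = [], []
    ssx_acc = 0.0
    ssy_acc = 0.0
    stopped = False
    # absolute floor scaled to the problem, guards the w normalisation
    tol = 1e-12 * max(1.0, np.sqrt(ssx_total * ssy_total))
    for _ in range(m):
        c = Xc.T @ yc
        cnorm = float(np.linalg.norm(c))
        if cnorm <= tol:
            stopped = True
            break
        w = c / cnorm
        k = int(np.argmax(np.abs(w)))
        if w[k] < 0:
            w = -w
        t = Xc @ w
        tt = float(t @ t)
        if tt <= tol:
            stopped = True
            break
        p_vec = (Xc.T @ t) / tt
        q = float(yc @ t) / tt
        Xc = Xc - np.outer(t, p_vec)
        yc = yc - q * t
        W.append(w)
        P.append(p_vec)
        T.append(t)
        Q.append(q)
        ssx_acc += tt * float(p_vec @ p_vec)
        ssy_acc += q * q * tt
        ssx_cum.append(ssx_acc / ssx_total if ssx_total > 0 else 1.0)
        ssy_cum.append(ssy_acc / ssy_total if ssy_total > 0 else 1.0)
        if varexp_target is not None and ssx_cum[-1] >= varexp_target:
            break

    if not W:
        raise ValueError("zero cross-covariance between X and y at mode 1; "
                         "no modes extractable")

    Tm = np.column_stack(T)
    return PLSModel(
        mean=mean,
        y_mean=y_mean,
        weights=np.column_stack(W),
        modes=np.column_stack(P),
        components=Tm,
        y_loadings=np.asarray(Q),
        mode_variance=Tm.var(axis=0, ddof=1),
        varexp_x=np.asarray(ssx_cum),
        varexp_y=np.asarray(ssy_cum),
        stopped_early=stopped,
        scaled=scale,
        scale_=scale_,
    )


def reconstruct(model: PLSModel, components_row: np.ndarray,
                m: Optional[int] = None) -> np.ndarray:
    """Decode a component row back to data space: ``x_bar + sum t_j p_j``."""
    t = np.atleast_1d(np.asarray(components_row, dtype=float))
    if m is None:
        m = t.shape[-1]
    if m > model.n_modes:
        raise ValueError(f"requested {m} modes, model has {model.n_modes}")
    x = t[..., :m] @ model.modes[:, :m].T
    if model.scaled:
        x = x * model.scale_
    return model.mean + x


def project(model: PLSModel, x_new: np.ndarray,
            m: Optional[int] = None) -> np.ndarray:
    """Project new observations onto the model's modes.

    Sequential NIPALS projection with deflation: ``t_j = r^T w_j`` then
    ``r -= t_j p_j``.  Projecting a training row reproduces its stored
    component row.
    """
    if m is None:
        m = model.n_modes
    if m > model.n_modes:
        raise ValueError(f"requested {m} modes, model has {model.n_modes}")
    x = np.atleast_2d(np.asarray(x_new, dtype=float))
    r = x - model.mean
    if model.scaled:
        r = r / model.scale_
    T = np.empty((r.shape[0], m))
    for j in range(m):
        t = r @ model.weights[:, j]
        T[:, j] = t
        r = r - np.outer(t, model.modes[:, j])
    if np.asarray(x_new).ndim == 1:
        return T[0]
    return T


def predict_y(model: PLSModel, x_new: np.ndarray,
              m: Optional[int] = None) -> np.ndarray:
    """PLS-regression response prediction ``y_bar + sum q_j t_j``."""
    T = np.atleast_2d(project(model, x_new, m=m))
    m_eff = T.shape[1]
    out = model.y_mean + T @ model.y_loadings[:m_eff]
    if np.asarray(x_new).ndim == 1:
        return float(out[0])
    return out


def fit_ssim(
    ssm: PLSModel,
    sim: PLSModel,
    y: np.ndarray,
    m_shape: Optional[int] = None,
    m_int: Optional[int] = None,
    m: Optional[int] = None,
) -> PLSModel:
    """Two-level fusion: PLS on concatenated shape and intensity components.

    The first ``m_shape`` SSM score columns and the first ``m_int`` SIM
    score columns are concatenated into an ``N x (m_shape + m_int)`` matrix,
    and a fresh PLS1 model is fitted against the fracture status.  Block
    provenance is retained in ``block_sizes`` so fused modes can be decoded
    back to a shape part and an intensity part.
    """
    if m_shape is None:
        m_shape = ssm.n_modes
    if m_int is None:
        m_int = sim.n_modes
    if m_shape < 1 or m_int < 1:
        raise ValueError("both blocks must contribute at least one component "
                         f"(got m_shape={m_shape}, m_int={m_int})")
    if m_shape > ssm.n_modes or m_int > sim.n_modes:
        raise ValueError("requested more component columns than extracted")
    if ssm.components.shape[0] != sim.components.shape[0]:
        raise ValueError("SSM and SIM were fitted on different subject sets "
                         f"({ssm.components.shape[0]} vs "
                         f"{sim.components.shape[0]} rows)")
    Z = np.hstack([ssm.components[:, :m_shape], sim.components[:, :m_int]])
    model = fit_pls(Z, y, m=m)
    model.block_sizes = (m_shape, m_int)
    return model


@dataclass
class ModeCount:
    n_modes: int
    reached: bool


def modes_to_explain(model: PLSModel, target_fraction: float,
                     basis: str = "x") -> ModeCount:
    """Smallest mode count whose cumulative variance explained reaches
    ``target_fraction`` (``basis='x'`` for the data block, ``'y'`` for the
    fracture-status variance).  When unreachable with the extracted modes,
    returns the full mode count with ``reached=False``.
    """
    if not 0.0 < target_fraction < 1.0:
        raise ValueError("target_fraction must lie strictly in (0, 1)")
    profile = model.varexp_x if basis == "x" else model.varexp_y
    hit = np.nonzero(profile >= target_fraction)[0]
    if hit.size == 0:
        return ModeCount(int(profile.size), False)
    return ModeCount(int(hit[0]) + 1, True)


# --- +/- sigma mode exports ---------------------------------------------
#
# A mode j is rendered as the decoded data vector x_bar + s * sigma_j * p_j
# with s in {-1, 0, +1}: the template deformed along the mode by one score
# standard deviation (shape), the element density field perturbed likewise
# (intensity), or both for the fused model.

def mode_vector(model: PLSModel, j: int, scale: float) -> np.ndarray:
    """Data-space vector for mode ``j`` (0-based) at ``scale`` score
    standard deviations."""
    if not 0 <= j < model.n_modes:
        raise IndexError(f"mode {j} out of range (model has "
                         f"{model.n_modes})")
    sigma = float(np.sqrt(model.mode_variance[j]))
    t = np.zeros(model.n_modes)
    t[j] = scale * sigma
    return reconstruct(model, t)


def export_shape_mode(model: PLSModel, surface, grid, j: int, scale: float,
                      path) -> None:
    """Write the template surface deformed along shape mode ``j`` at
    ``scale`` sigma (ASCII PLY/STL via trimesh)."""
    import trimesh

    from .shape import MomentField, deform

    beta = MomentField.from_flat(mode_vector(model, j, scale), grid)
    verts = deform(surface.vertices, grid, beta)
    out = trimesh.Trimesh(vertices=verts, faces=surface.faces,
                          process=False)
    out.export(str(path), encoding="ascii")


def export_intensity_mode(model: PLSModel, tet_mesh, j: int, scale: float,
                          path) -> None:
    """Write the template tet mesh with the mode-``j`` density field at
    ``scale`` sigma as an element scalar field (legacy VTK)."""
    from .meshes import write_vtk

    field = mode_vector(model, j, scale)
    write_vtk(path, tet_mesh, cell_data={"bmd": field},
              title=f"intensity mode {j + 1} at {scale:+g} sigma")


def export_ssim_mode(ssim: PLSModel, ssm: PLSModel, sim: PLSModel,
                     surface, grid, tet_mesh, j: int, scale: float,
                     surface_path, field_path) -> None:
    """Decode fused mode ``j`` through its shape and intensity blocks.

    The fused mode lives in concatenated component space; its shape block
    is decoded through the SSM (to a deformed surface) and its intensity
    block through the SIM (to an element field on the template mesh).
    """
    import trimesh

    from .meshes import write_vtk
    from .shape import MomentField, deform

    if ssim.block_sizes is None:
        raise ValueError("model carries no block provenance; fit it with "
                         "fit_ssim")
    m_s, m_i = ssim.block_sizes
    z = mode_vector(ssim, j, scale)          # concatenated component space
    beta_flat = reconstruct(ssm, z[:m_s], m=m_s)
    field = reconstruct(sim, z[m_s:m_s + m_i], m=m_i)
    beta = MomentField.from_flat(beta_flat, grid)
    verts = deform(surface.vertices, grid, beta)
    trimesh.Trimesh(vertices=verts, faces=surface.faces,
                    process=False).export(str(surface_path),
                                          encoding="ascii")
    write_vtk(field_path, tet_mesh, cell_data={"bmd": field},
              title=f"fused mode {j + 1} at {scale:+g} sigma")
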