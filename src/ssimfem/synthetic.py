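"""Seeded synthetic cohorts with the statistical structure the analysis
assumes.

The generator stands in for a CT-derived study cohort (~100 post-menopausal
women, near-balanced fracture / non-fracture classes).  It emulates:

- a weak class-conditional *shape* effect: a mean shift of size ``d_s``
  along one fixed unit direction in moment space,
- a strong class-conditional *density* effect: a shift of size ``d_i``
  along a fixed, predominantly positive direction in element-density space
  (global bone-mass loss in the fractured class, so the areal-projection
  aBMD analog inherits part of the signal),
- a shape x intensity *interaction*: an extra density offset of size
  ``d_si`` along a second direction, switched on only when a subject's
  shape latent AND intensity latent scores are both low — joint information
  that a fused shape-and-intensity model can exploit beyond either block
  alone,
- shared nuisance latents loading on both moments and densities (benign
  anatomical covariation), plus i.i.d. Gaussian measurement noise.

With all effect sizes at zero the two classes are exchangeable.  All draws
come from a single ``numpy`` Generator seeded by ``config.seed``, consumed
in the documented order (template jitter, status, effect directions,
nuisance directions, latent scores, noise), so a cohort is bitwise
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, Optional

import numpy as np
import trimesh
from scipy.spatial import Delaunay
from shapely.geometry import Polygon
from shapely.ops import unary_union
from skimage.measure import marching_cubes

from .cohort import Cohort
from .meshes import TetMesh
from .shape import AnatomicalFrame, ControlGrid, MomentField, deform, \
    kernel_matrix, make_control_grid

__all__ = [
    "GeneratorConfig",
    "Template",
    "SyntheticCohort",
    "make_template",
    "sample_cohort",
    "areal_projection",
    "projected_area",
]


@dataclass
class GeneratorConfig:
    """Synthetic-cohort parameters.

    Effect sizes are unitless shifts of the class means along unit latent
    directions; ``noise_sd`` is the i.i.d. Gaussian noise per coordinate /
    element.  Defaults give ~100 subjects in near-balanced classes with a
    weak shape effect, a strong density effect and an interaction —
    the regime in which density dominates shape as a fracture
    discriminator and their fusion does best.
    """

    n_subjects: int = 100
    class_balance: float = 0.5
    n_control_points: int = 64
    n_elements: int = 400
    shape_effect: float = 0.3
    intensity_effect: float = 1.0
    interaction_effect: float = 1.0
    noise_sd: float = 0.3
    n_latents: int = 8
    nuisance_amplitude: float = 8.0
    nuisance_decay: float = 0.7
    seed: int = 0

    def validate(self) -> "GeneratorConfig":
        if self.n_subjects < 4:
            raise ValueError("n_subjects must be >= 4")
        if not 0.0 <= self.class_balance <= 1.0:
            raise ValueError("class_balance must lie in [0, 1]")
        n1 = int(round(self.class_balance * self.n_subjects))
        if n1 == 0 or n1 == self.n_subjects:
            raise ValueError("class_balance leaves one class empty after "
                             "rounding")
        for name in ("shape_effect", "intensity_effect",
                     "interaction_effect"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0")
        if not self.noise_sd > 0:
            raise ValueError("noise_sd must be > 0")
        if self.n_control_points < 1 or self.n_elements < 1:
            raise ValueError("counts must be >= 1")
        if self.n_latents < 0:
            raise ValueError("n_latents must be >= 0")
        if self.nuisance_amplitude < 0 or not 0 < self.nuisance_decay <= 1:
            raise ValueError("nuisance_amplitude must be >= 0 and "
                             "nuisance_decay in (0, 1]")
        return self

    def nuisance_amplitudes(self) -> np.ndarray:
        """Geometrically decaying nuisance-latent amplitudes: dominant
        anatomical variation concentrates in a few leading directions, so
        variance-explained profiles decay as they do in real cohorts."""
        return self.nuisance_amplitude * \
            self.nuisance_decay ** np.arange(self.n_latents)


# --- stylized proximal-femur template ----------------------------------

# Dimensions (mm) of the stylized geometry: a capped vertical shaft tube
# plus an offset, angled head sphere.  The pipeline is geometry-agnostic;
# these values only set a plausible proximal-femur scale.
_SHAFT_RADIUS = 13.0
_SHAFT_LENGTH = 70.0
_HEAD_CENTRE = np.array([24.0, 0.0, 62.0])
_HEAD_RADIUS = 17.0
_NECK_BASE = np.array([0.0, 0.0, 52.0])


def _implicit(points: np.ndarray) -> np.ndarray:
    """Negative inside the solid (union of capped tube and head sphere)."""
    p = np.atleast_2d(points)
    r = np.sqrt(p[:, 0] ** 2 + p[:, 1] ** 2)
    f_tube = np.maximum.reduce([r - _SHAFT_RADIUS,
                                p[:, 2] - _SHAFT_LENGTH,
                                -p[:, 2]])
    f_head = np.linalg.norm(p - _HEAD_CENTRE, axis=1) - _HEAD_RADIUS
    return np.minimum(f_tube, f_head)


def _template_frame() -> AnatomicalFrame:
    return AnatomicalFrame(
        head_centre=_HEAD_CENTRE,
        neck_axis=_HEAD_CENTRE - _NECK_BASE,
        shaft_axis=np.array([0.0, 0.0, 1.0]),
    )


@dataclass
class Template:
    """Template geometry bundle: surface, tet mesh, control grid and the
    anatomical annotations used for pose initialisation."""

    surface: trimesh.Trimesh
    tet_mesh: TetMesh
    grid: ControlGrid
    frame: AnatomicalFrame
    implicit = staticmethod(_implicit)


def _template_surface(resolution: int = 40) -> trimesh.Trimesh:
    pad = 4.0
    lo = np.array([-_SHAFT_RADIUS, -_SHAFT_RADIUS, 0.0]) - pad
    hi = np.array([_HEAD_CENTRE[0] + _HEAD_RADIUS,
                   max(_SHAFT_RADIUS, _HEAD_RADIUS),
                   max(_SHAFT_LENGTH, _HEAD_CENTRE[2] + _HEAD_RADIUS)]) + pad
    axes = [np.linspace(lo[d], hi[d], resolution) for d in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    vol = _implicit(np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()]))
    vol = vol.reshape(gx.shape)
    spacing = tuple((hi - lo) / (resolution - 1))
    verts, faces, _, _ = marching_cubes(vol, level=0.0, spacing=spacing)
    verts = verts + lo
    return trimesh.Trimesh(vertices=verts, faces=faces, process=False)


def _tet_fill(rng: np.random.Generator, n_target: int) -> TetMesh:
    """Tet-mesh the template interior: jittered lattice points inside the
    implicit solid, Delaunay, keep tets whose centroid is interior."""
    lo = np.array([-_SHAFT_RADIUS - 1, -_SHAFT_RADIUS - 1, -1.0])
    hi = np.array([_HEAD_CENTRE[0] + _HEAD_RADIUS + 1,
                   max(_SHAFT_RADIUS, _HEAD_RADIUS) + 1,
                   _HEAD_CENTRE[2] + _HEAD_RADIUS + 1])
    box_vol = float(np.prod(hi - lo))
    # ~6 tets per interior lattice cell; solve for spacing, then refine
    # until the element count clears 0.8 * target
    solid_frac = 0.35
    h = (6.0 * solid_frac * box_vol / max(n_target, 1)) ** (1.0 / 3.0)
    for _ in range(12):
        axes = [np.arange(lo[d], hi[d] + h, h) for d in range(3)]
        gx, gy, gz = np.meshgrid(*axes, indexing="ij")
        pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
        pts = pts + rng.uniform(-0.05 * h, 0.05 * h, size=pts.shape)
        inside = _implicit(pts) < 0.35 * h
        pts = pts[inside]
        if len(pts) < 10:
            h *= 0.8
            continue
        tri = Delaunay(pts)
        cells = tri.simplices
        mesh = TetMesh(pts, cells).orient_positive()
        vols = mesh.signed_volumes()
        keep = (vols > 1e-9 * h ** 3) & \
            (_implicit(mesh.centroids()) < 0.0)
        mesh = TetMesh(pts, mesh.cells[keep])
        if mesh.n_elements >= 0.8 * n_target:
            if np.any(mesh.signed_volumes() <= 0):
                raise RuntimeError("degenerate tetrahedra survived "
                                   f"meshing at spacing h={h:.3g}")
            return mesh
        h *= 0.85
    raise RuntimeError(f"could not reach {n_target} elements; geometry or "
                       "n_elements parameters are inconsistent")


def make_template(config: GeneratorConfig,
                  rng: Optional[np.random.Generator] = None) -> Template:
    """Build the template surface, tet mesh and control grid.

    Deterministic given ``config.seed`` (a fresh seeded Generator is used
    when ``rng`` is not supplied; :func:`sample_cohort` passes its own
    stream so template jitter is part of the documented draw order).
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    surface = _template_surface()
    tet = _tet_fill(rng, config.n_elements)
    lo, hi = surface.bounds
    grid = make_control_grid(lo, hi, config.n_control_points)
    return Template(surface, tet, grid, _template_frame())


# --- areal projection (aBMD analog) -------------------------------------

def projected_area(mesh: TetMesh, axis: int = 1,
                   length_scale: float = 1.0) -> float:
    """Area of the mesh's shadow on the plane normal to ``axis``
    (default y, i.e. the frontal/coronal plane), via polygon union of the
    projected boundary faces.  ``length_scale`` is cm per coordinate unit.
    """
    faces = mesh.boundary_faces()
    keep = [d for d in range(3) if d != axis]
    tri2d = mesh.points[faces][:, :, keep]
    polys = []
    for t in tri2d:
        poly = Polygon(t)
        if poly.area > 0:
            polys.append(poly)
    shadow = unary_union(polys)
    return float(shadow.area) * length_scale ** 2


def areal_projection(element_density: np.ndarray, tet_mesh: TetMesh,
                     axis: int = 1, length_scale: float = 1.0) -> float:
    """Areal bone-mineral-density analog (g/cm^2).

    ``sum_e rho_e V_e`` divided by the area of the mesh's shadow on the
    frontal plane, times 1e-3 (mg/cm^3 * cm^3 / cm^2 -> g/cm^2).
    ``length_scale`` converts mesh coordinates to cm (0.1 for mm meshes).
    """
    rho = np.asarray(element_density, dtype=float).ravel()
    if rho.size != tet_mesh.n_elements:
        raise ValueError(f"{rho.size} densities for {tet_mesh.n_elements} "
                         "elements")
    vol = float(np.sum(rho * tet_mesh.volumes())) * length_scale ** 3
    area = projected_area(tet_mesh, axis=axis, length_scale=length_scale)
    if area <= 0:
        raise ValueError("zero projected area; the mesh casts no shadow on "
                         "the frontal plane")
    return 1e-3 * vol / area


# --- cohort sampling ----------------------------------------------------

@dataclass
class SyntheticCohort(Cohort):
    """Cohort plus the generative record (``truth``): latent directions,
    scores and effect sizes actually used."""

    truth: Dict = field(default_factory=dict)
    template: Optional[Template] = None
    config: Optional[GeneratorConfig] = None


def template_density_baseline(template: Template) -> np.ndarray:
    """Mean density profile (mg/cm^3): high-density cortical boundary
    layer over a trabecular interior, assigned from each element
    centroid's depth below the template surface."""
    depth = -_implicit(template.tet_mesh.centroids())
    return np.where(depth < 2.5, 950.0, 280.0)


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


# Spatial-variation-to-mean ratio of the density effect direction: the
# class density effect is mostly a spatial redistribution riding on a
# global mass loss, so an areal average sees only part of the signal.
_UI_SPATIAL_SD = 6.0
_W_NUISANCE_RATIO = 1.0


def sample_cohort(config: GeneratorConfig) -> SyntheticCohort:
    """Draw one synthetic cohort.

    Draw order on the single seeded stream: template lattice jitter,
    status permutation, shape direction u_s, intensity direction u_i
    (positively biased), interaction direction u_x (orthogonalised to
    u_i), nuisance directions, latent scores, moment noise, density noise.

    Construction per subject i (c_i = status_i - 1/2, so fractured lie
    low on both latents):

        a_i = z_a,i - d_s * c_i                      (shape latent)
        b_i = z_b,i - d_i * c_i                      (intensity latent)
        moments_i  = a_i u_s + sum_l z_l,i v_l + eps
        density_i  = base + b_i u_i + d_si 1[a_i<0, b_i<0] u_x
                     + sum_l z_l,i w_l + eps
        abmd_i     = areal_projection(density_i, morphed tet mesh)

    The class-mean difference of the density projection onto u_i is d_i by
    construction; densities are clamped at 0 (the baseline keeps them
    positive in practice).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    template = make_template(config, rng=rng)
    N = config.n_subjects
    p = 3 * config.n_control_points
    n = template.tet_mesh.n_elements

    n1 = int(round(config.class_balance * N))
    status = np.zeros(N, dtype=int)
    status[:n1] = 1
    status = status[rng.permutation(N)]
    c = status - 0.5

    u_s = _unit(rng.standard_normal(p))
    # density effect: global mass loss plus spatial redistribution, so the
    # areal-average aBMD analog inherits part (not all) of the signal
    u_i = _unit(1.0 + _UI_SPATIAL_SD * rng.standard_normal(n))
    # interaction footprint: orthogonal to the main density direction and
    # to the element-volume vector, so it is invisible to the areal average
    vols_dir = _unit(template.tet_mesh.volumes())
    u_x = rng.standard_normal(n)
    u_x = u_x - (u_x @ u_i) * u_i
    u_x = _unit(u_x - (u_x @ vols_dir) * vols_dir)
    V = np.vstack([_unit(rng.standard_normal(p))
                   for _ in range(config.n_latents)]) \
        if config.n_latents else np.zeros((0, p))
    W = np.vstack([_unit(rng.standard_normal(n))
                   for _ in range(config.n_latents)]) \
        if config.n_latents else np.zeros((0, n))

    z_a = rng.standard_normal(N)
    z_b = rng.standard_normal(N)
    z_nuis = rng.standard_normal((N, config.n_latents))
    eps_shape = rng.standard_normal((N, p))
    eps_int = rng.standard_normal((N, n))

    a = z_a - config.shape_effect * c
    b = z_b - config.intensity_effect * c
    inter = ((a < 0) & (b < 0)).astype(float)

    amps = config.nuisance_amplitudes()
    moments = np.outer(a, u_s) + (z_nuis * amps) @ V \
        + config.noise_sd * eps_shape
    base = template_density_baseline(template)
    density = (base[None, :] + np.outer(b, u_i)
               + config.interaction_effect * np.outer(inter, u_x)
               + (z_nuis * (_W_NUISANCE_RATIO * amps)) @ W
               + config.noise_sd * eps_int)
    density = np.clip(density, 0.0, None)

    # aBMD analog: densitometric average through the template mesh
    # (mm -> cm scale).  Projection geometry is shared, so the analog
    # isolates the density content of the scan, as DXA's single areal
    # average does.
    vols = template.tet_mesh.volumes() * 0.1 ** 3
    area = projected_area(template.tet_mesh, length_scale=0.1)
    abmd = 1e-3 * (density @ vols) / area

    truth = {
        "u_shape": u_s,
        "u_intensity": u_i,
        "u_interaction": u_x,
        "nuisance_shape": V,
        "nuisance_intensity": W,
        "shape_scores": a,
        "intensity_scores": b,
        "interaction_indicator": inter,
        "effects": {
            "shape": config.shape_effect,
            "intensity": config.intensity_effect,
            "interaction": config.interaction_effect,
        },
    }
    return SyntheticCohort(moments=moments, element_density=density,
                           status=status, abmd_analog=abmd,
                           subject_ids=None, truth=truth,
                           template=template, config=config)
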