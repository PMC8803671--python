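"""Intensity pipeline: phantom calibration, element density mapping, G.

CT grey levels are converted to hydroxyapatite-equivalent bone mineral
density (mg/cm^3) through a linear calibration fitted on a multi-sample
phantom (standard range 0-200 mg/cm^3).  Densities are then sampled once
per tetrahedral element of the subject-morphed template mesh; because every
subject mesh is the same template morphed by that subject's moments, element
k corresponds across subjects and the per-subject vectors stack into a
consistent N x n intensity matrix G.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, List, Optional, Sequence, Union

import numpy as np

from .meshes import TetMesh

__all__ = [
    "CalibrationLine",
    "IntensityVector",
    "IntensityMatrix",
    "fit_calibration",
    "map_element_density",
    "build_intensity_matrix",
]

log = logging.getLogger(__name__)


@dataclass
class CalibrationLine:
    """density = slope * intensity + intercept (mg/cm^3)."""

    slope: float
    intercept: float
    r2: float = 1.0

    def __call__(self, intensity):
        return self.slope * np.asarray(intensity, dtype=float) + \
            self.intercept

    @classmethod
    def identity(cls) -> "CalibrationLine":
        return cls(1.0, 0.0, 1.0)


@dataclass
class IntensityVector:
    """One subject's element-wise densities (mg/cm^3), i.e. one row of G."""

    values: np.ndarray
    n_clamped: int = 0
    subject_id: Optional[str] = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float).ravel()


@dataclass
class IntensityMatrix:
    G: np.ndarray
    subject_ids: List[str]

    @property
    def n_elements(self) -> int:
        return self.G.shape[1]


def fit_calibration(phantom_intensities: Sequence[float],
                    phantom_densities: Sequence[float]) -> CalibrationLine:
    """Ordinary least-squares line through the phantom samples.

    Standard use has five samples spanning 0-200 mg/cm^3; any >= 2 samples
    with at least two distinct intensities are accepted.
    """
    x = np.asarray(phantom_intensities, dtype=float).ravel()
    y = np.asarray(phantom_densities, dtype=float).ravel()
    if x.size != y.size or x.size < 2:
        raise ValueError("need matching intensity/density arrays with >= 2 "
                         "samples")
    if np.ptp(x) == 0:
        raise ValueError("all phantom intensities identical; the "
                         "calibration line is undefined")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(resid ** 2)) / ss_tot
    return CalibrationLine(float(slope), float(intercept), r2)


FieldLike = Callable[[np.ndarray], np.ndarray]


def _sample_points(mesh: TetMesh, rule: str) -> np.ndarray:
    cent = mesh.centroids()
    if rule == "centroid":
        return cent[:, None, :]
    if rule == "mean5":
        nodes = mesh.points[mesh.cells]          # (e, 4, 3)
        return np.concatenate([nodes, cent[:, None, :]], axis=1)
    raise ValueError(f"unknown sampling rule {rule!r}; use 'centroid' or "
                     "'mean5'")


def map_element_density(subject_field: FieldLike, morphed_mesh: TetMesh,
                        calibration: Optional[CalibrationLine] = None,
                        rule: str = "centroid",
                        subject_id: Optional[str] = None) -> IntensityVector:
    """Sample the subject's intensity field per element and calibrate.

    ``subject_field`` is any callable mapping (k, 3) points to k scalars
    (e.g. a ``scipy.interpolate.RegularGridInterpolator``).  The field is
    aggregated per element by ``rule`` ('centroid' = one sample at the
    element centroid; 'mean5' = mean of the four nodes plus the centroid),
    then passed through the calibration line.  Calibrated values below zero
    are clamped to 0 and counted.

    Raises a hard error naming the offending element ids if any sample
    falls outside the field domain (NaN/inf or interpolator bounds error).
    """
    if calibration is None:
        calibration = CalibrationLine.identity()
    pts = _sample_points(morphed_mesh, rule)
    e, s, _ = pts.shape
    flat = pts.reshape(-1, 3)
    try:
        raw = np.asarray(subject_field(flat), dtype=float).reshape(e, s)
    except ValueError as exc:
        # bounds error from a grid interpolator: identify elements
        bad = []
        for i in range(e):
            try:
                subject_field(pts[i])
            except ValueError:
                bad.append(i)
        raise ValueError(f"elements outside field domain: {bad[:20]}"
                         f"{'...' if len(bad) > 20 else ''}") from exc
    agg = raw.mean(axis=1)
    if not np.all(np.isfinite(agg)):
        bad = np.nonzero(~np.isfinite(agg))[0].tolist()
        raise ValueError(f"elements outside field domain: {bad[:20]}"
                         f"{'...' if len(bad) > 20 else ''}")
    dens = np.asarray(calibration(agg), dtype=float)
    neg = dens < 0
    n_clamped = int(neg.sum())
    if n_clamped:
        log.info("clamped %d negative calibrated densities to 0", n_clamped)
        dens = np.where(neg, 0.0, dens)
    return IntensityVector(dens, n_clamped, subject_id)


def build_intensity_matrix(vectors: Sequence[IntensityVector],
                           subject_ids: Optional[Sequence[str]] = None
                           ) -> IntensityMatrix:
    """Stack per-subject density vectors into the N x n matrix G.

    Ragged lengths violate iso-topology and are a hard error naming the
    offending subject.
    """
    if not vectors:
        raise ValueError("no intensity vectors given")
    n = vectors[0].values.size
    for i, v in enumerate(vectors):
        if v.values.size != n:
            who = v.subject_id or f"index {i}"
            raise ValueError(f"intensity vector for subject {who} has "
                             f"{v.values.size} elements, expected {n} "
                             "(iso-topology violated)")
    if subject_ids is None:
        subject_ids = [v.subject_id or f"subject_{i:03d}"
                       for i, v in enumerate(vectors)]
    return IntensityMatrix(np.vstack([v.values for v in vectors]),
                           list(subject_ids))
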