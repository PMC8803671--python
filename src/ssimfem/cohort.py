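"""Cohort container shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np

__all__ = ["Cohort"]


@dataclass
class Cohort:
    """Subjects' shape and intensity data with fracture status.

    - ``moments``: N x 3q flattened moment vectors (shape matrix rows)
    - ``element_density``: N x n element densities (mg/cm^3, rows of G)
    - ``status``: N binary array, 0 = non-fracture, 1 = fracture
    - ``abmd_analog``: N areal-density scalars (g/cm^2 scale)
    """

    moments: np.ndarray
    element_density: np.ndarray
    status: np.ndarray
    abmd_analog: np.ndarray
    subject_ids: Optional[List[str]] = None

    def __post_init__(self):
        self.moments = np.atleast_2d(np.asarray(self.moments, dtype=float))
        self.element_density = np.atleast_2d(
            np.asarray(self.element_density, dtype=float))
        self.status = np.asarray(self.status).ravel().astype(int)
        self.abmd_analog = np.asarray(self.abmd_analog, dtype=float).ravel()
        n = len(self.status)
        if not set(np.unique(self.status)) <= {0, 1}:
            raise ValueError("status must be binary (0 = non-fracture, "
                             "1 = fracture)")
        for name in ("moments", "element_density"):
            if getattr(self, name).shape[0] != n:
                raise ValueError(f"{name} has {getattr(self, name).shape[0]} "
                                 f"rows for {n} subjects")
        if self.abmd_analog.size != n:
            raise ValueError("abmd_analog length mismatch")
        if self.subject_ids is None:
            self.subject_ids = [f"subject_{i:03d}" for i in range(n)]
        elif len(self.subject_ids) != n:
            raise ValueError("subject_ids length mismatch")

    @property
    def n_subjects(self) -> int:
        return len(self.status)

    def subset(self, indices) -> "Cohort":
        idx = np.asarray(indices, dtype=int)
        return Cohort(self.moments[idx], self.element_density[idx],
                      self.status[idx], self.abmd_analog[idx],
                      [self.subject_ids[i] for i in idx])
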