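"""Configuration, file I/O and the end-to-end pipeline runner.

File conventions
----------------
- Matrices: comma-delimited text with a one-line header
  ``# rows=N cols=p kind=shape|intensity|components``; status and aBMD as
  single-column delimited text (``kind=status`` / ``kind=abmd``).
- Surfaces: ASCII PLY/STL (trimesh); tet meshes + element fields: legacy
  ASCII VTK.
- Reports: JSON (AUC, CI, confusion, coefficients, variance explained) and
  CSV (ROC points, Cook's distances).
- Every run writes ``manifest.json`` with the fully-echoed configuration,
  package version and SHA-256 digests of all outputs, so identical
  config + seed reproduce identical digests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import yaml

from . import __version__
from . import classify, pls as plsmod, qc
from .cohort import Cohort
from .synthetic import GeneratorConfig, SyntheticCohort, sample_cohort

__all__ = [
    "write_matrix",
    "read_matrix",
    "write_cohort",
    "read_cohort",
    "RunConfig",
    "run_pipeline",
]

log = logging.getLogger(__name__)

_HEADER_RE = re.compile(r"#\s*rows=(\d+)\s+cols=(\d+)\s+kind=(\S+)")
_KINDS = {"shape", "intensity", "components", "status", "abmd"}


def write_matrix(path, X: np.ndarray, kind: str) -> None:
    if kind not in _KINDS:
        raise ValueError(f"unknown matrix kind {kind!r}")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    np.savetxt(path, X, delimiter=",",
               header=f"rows={X.shape[0]} cols={X.shape[1]} kind={kind}",
               comments="# ")


def read_matrix(path, expect_kind: Optional[str] = None):
    """Read a delimited matrix, validating the header against contents.

    Returns ``(array, kind)``.  Dimension mismatches, unknown headers and
    truncated rows are hard errors with file/line context.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    m = _HEADER_RE.match(first)
    if not m:
        raise ValueError(f"{path}:1: missing or malformed header "
                         "'# rows=N cols=p kind=...'")
    rows, cols, kind = int(m.group(1)), int(m.group(2)), m.group(3)
    if kind not in _KINDS:
        raise ValueError(f"{path}:1: unknown kind {kind!r}")
    if expect_kind is not None and kind != expect_kind:
        raise ValueError(f"{path}: expected kind={expect_kind}, found "
                         f"{kind}")
    try:
        X = np.loadtxt(path, delimiter=",", comments="#", ndmin=2)
    except ValueError as exc:
        raise ValueError(f"{path}: malformed row ({exc})") from exc
    if X.shape != (rows, cols):
        raise ValueError(f"{path}: header declares {rows}x{cols} but file "
                         f"contains {X.shape[0]}x{X.shape[1]}")
    return X, kind


def write_cohort(cohort: Cohort, out_dir) -> None:
    """Write a cohort as delimited text (+ JSON sidecar for synthetic
    cohorts, recording the generator config and latent truth)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_matrix(out / "moments.csv", cohort.moments, "shape")
    write_matrix(out / "element_density.csv", cohort.element_density,
                 "intensity")
    write_matrix(out / "status.csv",
                 cohort.status.reshape(-1, 1).astype(float), "status")
    write_matrix(out / "abmd.csv", cohort.abmd_analog.reshape(-1, 1),
                 "abmd")
    if isinstance(cohort, SyntheticCohort) and cohort.truth:
        sidecar = {
            "config": dataclasses.asdict(cohort.config),
            "truth": {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                      for k, v in cohort.truth.items()},
        }
        (out / "cohort.json").write_text(
            json.dumps(sidecar, indent=2, sort_keys=True))


def read_cohort(in_dir) -> Cohort:
    """Read a cohort directory; validates consistent N across all files
    and binary status."""
    d = Path(in_dir)
    moments, _ = read_matrix(d / "moments.csv", "shape")
    dens, _ = read_matrix(d / "element_density.csv", "intensity")
    status_raw, _ = read_matrix(d / "status.csv", "status")
    abmd, _ = read_matrix(d / "abmd.csv", "abmd")
    status_f = status_raw.ravel()
    if not np.all(np.isin(status_f, (0.0, 1.0))):
        bad = sorted(set(status_f) - {0.0, 1.0})
        raise ValueError(f"{d / 'status.csv'}: status must be 0/1, found "
                         f"{bad}")
    n = len(status_f)
    for name, arr in (("moments", moments), ("element_density", dens),
                      ("abmd", abmd)):
        if arr.shape[0] != n:
            raise ValueError(f"{d}: {name} has {arr.shape[0]} rows for "
                             f"{n} status entries")
    return Cohort(moments, dens, status_f.astype(int), abmd.ravel())


@dataclass
class RunConfig:
    """End-to-end run settings (mirrors the YAML config file)."""

    # input: either a cohort directory or a synthetic generator config
    cohort_dir: Optional[str] = None
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    # model settings
    n_components: int = 2
    varexp_cut: float = 0.9
    scale_columns: bool = False
    m_shape: Optional[int] = None     # SSIM block sizes; None = varexp cut
    m_int: Optional[int] = None
    # cross-validation
    k: int = 10
    seed: int = 0
    n_boot: int = 2000
    # QC
    qc_threshold: Optional[float] = None    # None = 4/N
    qc_components: int = 2
    # output
    out_dir: str = "ssimfem_run"
    export_modes: int = 2

    def validate(self) -> "RunConfig":
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        if not 0 < self.varexp_cut < 1:
            raise ValueError("varexp_cut must lie in (0, 1)")
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.n_boot < 100:
            raise ValueError("n_boot must be >= 100")
        if self.cohort_dir is None:
            self.generator.validate()
            n1 = int(round(self.generator.class_balance
                           * self.generator.n_subjects))
            if self.k > min(n1, self.generator.n_subjects - n1):
                raise ValueError(f"k={self.k} exceeds the smallest class "
                                 "count; folds would lose a class")
        elif not Path(self.cohort_dir).is_dir():
            raise ValueError(f"cohort_dir {self.cohort_dir!r} does not "
                             "exist")
        return self

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        gen = GeneratorConfig(**raw.pop("generator", {}))
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(generator=gen, **raw)

    def to_dict(self) -> Dict:
        d = dataclasses.asdict(self)
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _save_roc(path, roc_points):
    np.savetxt(path, np.asarray(roc_points, dtype=float), delimiter=",",
               header="fpr,tpr", comments="# ")


def run_pipeline(config: RunConfig) -> Dict:
    """Execute the full analysis and write the result bundle.

    Stages: generate-or-load cohort -> Cook's-distance LOO screen (shape
    and intensity regressions; flagged subjects excluded) -> full-cohort
    SSM / SIM / SSIM fits with variance-explained tables and +/-sigma mode
    exports -> balanced k-fold cross-validated classification for SSM,
    SIM, SSIM and the aBMD baseline -> JSON/CSV reports and a manifest of
    SHA-256 digests.  Any stage error aborts with the stage named.

    Returns the manifest dictionary.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        stage = "cohort"
        if config.cohort_dir is not None:
            cohort = read_cohort(config.cohort_dir)
            template = None
        else:
            gen = dataclasses.replace(config.generator)
            cohort = sample_cohort(gen)
            template = cohort.template
            write_cohort(cohort, out / "cohort")
            template.surface.export(str(out / "cohort" / "template.ply"),
                                    encoding="ascii")
            from .meshes import write_vtk
            write_vtk(out / "cohort" / "template_volume.vtk",
                      template.tet_mesh,
                      cell_data=None, title="template tet mesh")

        stage = "qc"
        y = cohort.status
        qc_rows = {}
        flagged = set()
        for name, X in (("shape", cohort.moments),
                        ("intensity", cohort.element_density)):
            rep = qc.cooks_distance_loo(X, y, m=config.qc_components,
                                        threshold=config.qc_threshold)
            qc_rows[name] = rep
            flagged.update(rep.flagged)
        np.savetxt(out / "cooks_distances.csv",
                   np.column_stack([qc_rows["shape"].cooks_d,
                                    qc_rows["intensity"].cooks_d]),
                   delimiter=",", header="shape,intensity", comments="# ")
        if flagged:
            log.warning("excluding %d flagged subjects: %s", len(flagged),
                        sorted(flagged))
            rep = qc.OutlierReport(
                cooks_d=np.zeros(cohort.n_subjects),
                threshold=0.0, flagged=sorted(flagged))
            cohort = qc.apply_exclusions(cohort, rep)
            y = cohort.status

        stage = "models"
        ssm = plsmod.fit_pls(cohort.moments, y,
                             varexp_target=config.varexp_cut,
                             scale=config.scale_columns)
        sim = plsmod.fit_pls(cohort.element_density, y,
                             varexp_target=config.varexp_cut,
                             scale=config.scale_columns)
        m_s = config.m_shape or \
            plsmod.modes_to_explain(ssm, config.varexp_cut).n_modes
        m_i = config.m_int or \
            plsmod.modes_to_explain(sim, config.varexp_cut).n_modes
        ssim = plsmod.fit_ssim(ssm, sim, y, m_shape=m_s, m_int=m_i)
        varexp = {}
        for name, model in (("ssm", ssm), ("sim", sim), ("ssim", ssim)):
            varexp[name] = {
                "varexp_x": model.varexp_x.tolist(),
                "varexp_y": model.varexp_y.tolist(),
                "mode_variance": model.mode_variance.tolist(),
                "n_modes": model.n_modes,
            }
            np.savetxt(out / f"varexp_{name}.csv",
                       np.column_stack([model.varexp_x, model.varexp_y]),
                       delimiter=",", header="varexp_x,varexp_y",
                       comments="# ")

        stage = "mode-export"
        if template is not None and config.export_modes > 0:
            modes_dir = out / "modes"
            modes_dir.mkdir(exist_ok=True)
            for j in range(min(config.export_modes, ssm.n_modes)):
                for s, tag in ((-1.0, "minus"), (1.0, "plus")):
                    plsmod.export_shape_mode(
                        ssm, template.surface, template.grid, j, s,
                        modes_dir / f"ssm_mode{j + 1}_{tag}_sigma.ply")
            for j in range(min(config.export_modes, sim.n_modes)):
                for s, tag in ((-1.0, "minus"), (1.0, "plus")):
                    plsmod.export_intensity_mode(
                        sim, template.tet_mesh, j, s,
                        modes_dir / f"sim_mode{j + 1}_{tag}_sigma.vtk")
            for j in range(min(config.export_modes, ssim.n_modes)):
                for s, tag in ((-1.0, "minus"), (1.0, "plus")):
                    plsmod.export_ssim_mode(
                        ssim, ssm, sim, template.surface, template.grid,
                        template.tet_mesh, j, s,
                        modes_dir / f"ssim_mode{j + 1}_{tag}_sigma.ply",
                        modes_dir / f"ssim_mode{j + 1}_{tag}_sigma.vtk")

        stage = "cross-validation"
        reports = {}
        for kind in classify.MODEL_KINDS:
            rep = classify.cross_validate(
                cohort, kind, k=config.k, seed=config.seed,
                n_components=config.n_components,
                varexp_cut=config.varexp_cut, n_boot=config.n_boot)
            reports[kind] = rep
            _save_roc(out / f"roc_{kind}.csv", rep.roc_points)

        stage = "reports"
        summary = {
            kind: {
                "auc": rep.auc,
                "auc_ci95": list(rep.auc_ci) if rep.auc_ci else None,
                "confusion": rep.confusion.tolist(),
                "fold_coefficients": [m.coefficients.tolist()
                                      for m in rep.per_fold_models],
            }
            for kind, rep in reports.items()
        }
        report = {
            "n_subjects": int(cohort.n_subjects),
            "n_fractured": int(cohort.status.sum()),
            "qc": {name: {"threshold": r.threshold,
                          "flagged": r.flagged}
                   for name, r in qc_rows.items()},
            "ssim_blocks": {"m_shape": m_s, "m_int": m_i},
            "varexp": varexp,
            "classification": summary,
        }
        (out / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True))

        stage = "manifest"
        outputs = {}
        for f in sorted(out.rglob("*")):
            if f.is_file() and f.name != "manifest.json":
                outputs[str(f.relative_to(out))] = _sha256(f)
        manifest = {
            "package_version": __version__,
            "config": config.to_dict(),
            "outputs": outputs,
        }
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True))
        return manifest
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") \
            from exc
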