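"""Two-stage non-negative least-squares beam-model commissioning.

The commissioning unknowns are multiplicative correction factors applied
to the sub-source intensities.  Because dose is linear in the sub-source
intensities, the calculated dose at the commissioning voxels is ``A x``
where ``A`` is the pre-computed sub-source dose matrix, and commissioning
reduces to two constrained least-squares problems solved in sequence:

stage 1 (photons)
    minimize ||A1p x_p - b1||^2 over x_p >= 0, where A1p keeps the photon
    columns and the rows beyond the contaminant-electron penetration depth
    (i.e. after the build-up region), with penumbra rows excluded.

stage 2 (electrons)
    minimize ||A2e x_e + A2p x_p_hat - b2||^2 over x_e >= 0 on the
    build-up rows, with the photon dose fixed from stage 1.  Electron
    sub-sources within one energy bin are grouped into an "effective" PSR
    sharing a single factor, which averages out the poor statistics of the
    sparse electron population.  Because stage-2 rows are disjoint from
    stage-1 rows, the electron stage does not change any stage-1 residual.

Both problems carry no regularization term; beam rotational symmetry is
already built into the ring-based model.  The solver is projected gradient
descent with Barzilai-Borwein steps and a halving line search.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field as dc_field
from enum import IntEnum
from pathlib import Path

import numpy as np

from .model import BeamModel, group_electron_effective_psrs
from .transport import RowMeta, SubsourceDoseMatrix
from .metrics import find_dmax

__all__ = [
    "RegionLabel",
    "MeasurementCurve",
    "MeasurementSet",
    "CommissioningConfig",
    "CorrectionFactors",
    "Submatrices",
    "ElectronStageError",
    "LabelingError",
    "label_regions",
    "extract_submatrices",
    "solve_nnls_pgd",
    "run_commissioning",
    "apply_correction_factors",
]


class RegionLabel(IntEnum):
    BUILD_UP = 0
    AFTER_BUILD_UP = 1
    PENUMBRA = 2
    INNER_BEAM = 3
    OUTER_BEAM = 4


class LabelingError(ValueError):
    pass


class ElectronStageError(ValueError):
    pass


@dataclass
class MeasurementCurve:
    """One measured-style scan: a depth-dose curve or a lateral profile."""

    field: str
    curve_type: str                # depth | inline | crossline
    depth: float                   # nan for the depth curve
    positions: np.ndarray
    doses: np.ndarray

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.doses = np.asarray(self.doses, dtype=float)
        if self.positions.shape != self.doses.shape:
            raise ValueError("positions/doses length mismatch")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if np.any(self.doses < 0):
            raise ValueError("doses must be >= 0")

    def value_at(self, position: float) -> float:
        return float(np.interp(position, self.positions, self.doses))


@dataclass
class MeasurementSet:
    """Measured-style water doses per field: depth curve + profiles."""

    curves: list[MeasurementCurve]
    normalization: str = "relative"
    detector: str = "synthetic"

    def fields(self) -> list[str]:
        seen: list[str] = []
        for c in self.curves:
            if c.field not in seen:
                seen.append(c.field)
        return seen

    def lookup(self, field: str, curve_type: str,
               depth: float | None = None) -> MeasurementCurve:
        for c in self.curves:
            if c.field != field or c.curve_type != curve_type:
                continue
            if curve_type == "depth" or depth is None:
                return c
            if abs(c.depth - depth) < 1e-6:
                return c
        raise KeyError(f"no curve {field}/{curve_type}/{depth}")

    # -- CSV I/O: one file per curve ---------------------------------------

    def to_csv_dir(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for i, c in enumerate(self.curves):
            dep = "na" if np.isnan(c.depth) else f"{c.depth:g}"
            name = f"{c.field}_{c.curve_type}_{dep}.csv"
            with open(directory / name, "w", newline="") as fh:
                w = csv.writer(fh)
                w.writerow(["# field_size_cm", c.field])
                w.writerow(["# curve_type", c.curve_type])
                w.writerow(["# depth_cm", dep])
                w.writerow(["# normalization", self.normalization])
                w.writerow(["position_cm", "dose_rel"])
                for p, v in zip(c.positions, c.doses):
                    w.writerow([repr(float(p)), repr(float(v))])

    @classmethod
    def from_csv_dir(cls, directory: str | Path) -> "MeasurementSet":
        curves = []
        norm = "relative"
        for path in sorted(Path(directory).glob("*.csv")):
            header = {}
            rows = []
            with open(path, newline="") as fh:
                for row in csv.reader(fh):
                    if row and row[0].startswith("#"):
                        header[row[0].lstrip("# ")] = row[1]
                    elif row and row[0] != "position_cm":
                        rows.append((float(row[0]), float(row[1])))
            dep = header.get("depth_cm", "na")
            curves.append(MeasurementCurve(
                header["field_size_cm"], header["curve_type"],
                float("nan") if dep == "na" else float(dep),
                np.array([r[0] for r in rows]),
                np.array([r[1] for r in rows])))
            norm = header.get("normalization", norm)
        return cls(curves, normalization=norm)


@dataclass
class CommissioningConfig:
    """Knobs of the two-stage fit.

    The electron/photon row split is the per-field dmax of the measured
    depth curve unless ``electron_depth_cm`` overrides it.  The penumbra is
    the 20-80% band of the same-depth central-axis dose, dilated by one
    measurement point on each side.
    """

    electron_depth_cm: float | None = None
    penumbra_low: float = 0.2
    penumbra_high: float = 0.8
    tol: float = 1e-10
    max_iter: int = 20000
    inverse_variance_weighting: bool = False

    def __post_init__(self):
        if self.tol <= 0:
            raise ValueError("tol must be > 0")


@dataclass
class CorrectionFactors:
    """Non-negative multiplicative reweights, the commissioning output."""

    x_photon: np.ndarray
    x_electron: np.ndarray | None
    diagnostics: dict = dc_field(default_factory=dict)

    def __post_init__(self):
        self.x_photon = np.asarray(self.x_photon, dtype=float)
        if np.any(self.x_photon < 0):
            raise ValueError("photon factors must be >= 0")
        if self.x_electron is not None:
            self.x_electron = np.asarray(self.x_electron, dtype=float)
            if np.any(self.x_electron < 0):
                raise ValueError("electron factors must be >= 0")

    def to_json(self, path: str | Path, model_hash: str = "") -> None:
        doc = {
            "model_hash": model_hash,
            "x_photon": self.x_photon.tolist(),
            "x_electron": (None if self.x_electron is None
                           else self.x_electron.tolist()),
            "diagnostics": self.diagnostics,
        }
        Path(path).write_text(json.dumps(doc, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "CorrectionFactors":
        doc = json.loads(Path(path).read_text())
        xe = doc["x_electron"]
        return cls(np.array(doc["x_photon"]),
                   None if xe is None else np.array(xe),
                   doc.get("diagnostics", {}))


# ---------------------------------------------------------------------------
# region labelling

def label_regions(measurements: MeasurementSet, row_meta: list[RowMeta],
                  config: CommissioningConfig | None = None) -> np.ndarray:
    """Assign one TG-53-style region label per commissioning row.

    Depth-curve rows split at the per-field dmax (build-up vs after);
    profile rows split into inner beam / penumbra / outer beam by the
    20%-80% rule against the same-depth central-axis dose, with the
    penumbra dilated by one measurement point on each side.
    """
    config = config or CommissioningConfig()
    labels = np.empty(len(row_meta), dtype=np.int8)
    split_depth: dict[str, float] = {}
    for f in {r.field for r in row_meta}:
        pdd = measurements.lookup(f, "depth")
        if config.electron_depth_cm is not None:
            split_depth[f] = config.electron_depth_cm
        else:
            imax = int(np.argmax(pdd.doses))
            if imax == 0 or imax == len(pdd.doses) - 1:
                raise LabelingError(
                    f"depth curve for field {f} has no interior dmax")
            split_depth[f], _ = find_dmax(pdd.positions, pdd.doses)

    # group profile rows per curve so the penumbra dilation sees the whole
    # profile in position order
    by_curve: dict[tuple, list[int]] = {}
    for i, r in enumerate(row_meta):
        if r.curve_type == "depth":
            labels[i] = (RegionLabel.BUILD_UP
                         if r.depth < split_depth[r.field]
                         else RegionLabel.AFTER_BUILD_UP)
        else:
            by_curve.setdefault((r.field, r.curve_type, r.depth),
                                []).append(i)

    for (f, ctype, depth), rows in by_curve.items():
        rows = sorted(rows, key=lambda i: row_meta[i].offset)
        pdd = measurements.lookup(f, "depth")
        cax = pdd.value_at(depth)
        if cax <= 0:
            raise LabelingError(f"non-positive central-axis dose at {depth}")
        curve = measurements.lookup(f, ctype, depth)
        doses = np.array([curve.value_at(row_meta[i].offset) for i in rows])
        lo, hi = config.penumbra_low * cax, config.penumbra_high * cax
        pen = (doses > lo) & (doses < hi)
        if np.any(pen):
            dil = pen.copy()
            dil[:-1] |= pen[1:]
            dil[1:] |= pen[:-1]
            pen = dil
        for j, i in enumerate(rows):
            if pen[j]:
                labels[i] = RegionLabel.PENUMBRA
            elif doses[j] >= hi:
                labels[i] = RegionLabel.INNER_BEAM
            else:
                labels[i] = RegionLabel.OUTER_BEAM
    return labels


# ---------------------------------------------------------------------------
# submatrix extraction

@dataclass
class Submatrices:
    A1p: np.ndarray            # photon cols x non-build-up, non-penumbra rows
    A2p: np.ndarray            # photon cols x build-up rows
    A2e: np.ndarray            # electron effective-PSR cols x build-up rows
    rows1: np.ndarray          # row indices into A for stage 1
    rows2: np.ndarray          # row indices into A for stage 2
    photon_cols: np.ndarray
    electron_groups: list[tuple[int, list[int]]]   # (energy bin, columns)


def extract_submatrices(A: SubsourceDoseMatrix, labels: np.ndarray,
                        model: BeamModel) -> Submatrices:
    """Slice A into the stage-1 and stage-2 systems.

    Penumbra rows are excluded everywhere; electron columns are summed
    within each energy bin to form the effective-PSR columns.
    """
    if len(labels) != A.n_rows:
        raise ValueError("labels not aligned with A rows")
    labels = np.asarray(labels)
    rows1 = np.flatnonzero(
        (labels == RegionLabel.AFTER_BUILD_UP)
        | (labels == RegionLabel.INNER_BEAM)
        | (labels == RegionLabel.OUTER_BEAM))
    rows2 = np.flatnonzero(labels == RegionLabel.BUILD_UP)
    pcols = model.photon_indices()
    groups = sorted(group_electron_effective_psrs(model).items())
    A1p = A.values[np.ix_(rows1, pcols)]
    A2p = A.values[np.ix_(rows2, pcols)]
    if rows2.size == 0:
        raise ElectronStageError("no build-up rows for the electron stage")
    A2e = np.column_stack([
        A.values[np.ix_(rows2, np.asarray(cols))].sum(axis=1)
        for _, cols in groups])
    return Submatrices(A1p, A2p, A2e, rows1, rows2, pcols, groups)


# ---------------------------------------------------------------------------
# projected-gradient NNLS

def solve_nnls_pgd(M: np.ndarray, target: np.ndarray,
                   x0: np.ndarray | None = None,
                   config: CommissioningConfig | None = None):
    """Minimize ||M x - target||^2 subject to x >= 0.

    Projected gradient descent with Barzilai-Borwein step lengths and a
    halving line search that keeps the objective non-increasing.  Returns
    (x, diagnostics); diagnostics carries iterations, the final objective,
    and a ``converged`` flag (False when the iteration cap was hit).
    """
    config = config or CommissioningConfig()
    M = np.asarray(M, dtype=float)
    target = np.asarray(target, dtype=float)
    if not (np.all(np.isfinite(M)) and np.all(np.isfinite(target))):
        raise ValueError("non-finite entries in the NNLS system")
    if M.shape[0] != target.shape[0]:
        raise ValueError("row count mismatch")
    x = (np.ones(M.shape[1]) if x0 is None
         else np.maximum(np.asarray(x0, dtype=float), 0.0))

    def objective(v):
        r = M @ v - target
        return float(r @ r)

    f = objective(x)
    g = 2.0 * M.T @ (M @ x - target)
    # initial step from a cheap Lipschitz bound
    col_norm = np.linalg.norm(M, ord="fro")
    alpha = 1.0 / max(2.0 * col_norm ** 2, 1e-300)
    x_prev, g_prev = None, None
    it = 0
    converged = False
    for it in range(1, config.max_iter + 1):
        if x_prev is not None:
            s = x - x_prev
            ydiff = g - g_prev
            sy = float(s @ ydiff)
            alpha = (float(s @ s) / sy if sy > 1e-300
                     else 1.0 / max(2.0 * col_norm ** 2, 1e-300))
        step = alpha
        for _ in range(60):
            x_new = np.maximum(x - step * g, 0.0)
            f_new = objective(x_new)
            if f_new <= f or np.array_equal(x_new, x):
                break
            step *= 0.5
        if np.array_equal(x_new, x):
            converged = True
            break
        x_prev, g_prev = x, g
        x, f_old, f = x_new, f, f_new
        g = 2.0 * M.T @ (M @ x - target)
        if abs(f_old - f) <= config.tol * max(f_old, 1e-300):
            converged = True
            break
    diagnostics = {"iterations": it, "objective": f, "converged": converged}
    return x, diagnostics


# ---------------------------------------------------------------------------
# end-to-end commissioning

class NormalizationError(ValueError):
    pass


def _measurement_vector(A: SubsourceDoseMatrix,
                        measurements: MeasurementSet) -> np.ndarray:
    """Measured dose aligned with the rows of A."""
    b = np.empty(A.n_rows)
    for i, r in enumerate(A.row_meta):
        if r.curve_type == "depth":
            curve = measurements.lookup(r.field, "depth")
            b[i] = curve.value_at(r.depth)
        else:
            curve = measurements.lookup(r.field, r.curve_type, r.depth)
            b[i] = curve.value_at(r.offset)
    return b


def run_commissioning(A: SubsourceDoseMatrix, measurements: MeasurementSet,
                      model: BeamModel,
                      config: CommissioningConfig | None = None):
    """Solve both commissioning stages and build the commissioned model.

    Returns ``(CorrectionFactors, commissioned BeamModel)``.  A single
    closed-form scalar rescales the measurement vector first so that
    factors near 1 mean "no change" (measurements are relative); the scale
    is folded back into the returned factors, so commissioned doses are in
    the measurement's units.  If no build-up rows exist the electron stage
    is skipped with a warning and the stage-1 factors are still returned.
    """
    config = config or CommissioningConfig()
    b = _measurement_vector(A, measurements)
    if not np.any(b > 0):
        raise NormalizationError("measurement vector is all zero")
    labels = label_regions(measurements, A.row_meta, config)

    diagnostics: dict = {}
    try:
        sub = extract_submatrices(A, labels, model)
        electron_ok = True
    except ElectronStageError as err:
        # photon stage proceeds on its own rows
        rows1 = np.flatnonzero(
            (labels == RegionLabel.AFTER_BUILD_UP)
            | (labels == RegionLabel.INNER_BEAM)
            | (labels == RegionLabel.OUTER_BEAM))
        sub = Submatrices(A.values[np.ix_(rows1, model.photon_indices())],
                          np.empty((0, model.n_photon_subsources)),
                          np.empty((0, 0)), rows1, np.array([], dtype=int),
                          model.photon_indices(),
                          sorted(group_electron_effective_psrs(model).items()))
        electron_ok = False
        diagnostics["electron_stage_warning"] = str(err)

    b1 = b[sub.rows1]
    c = sub.A1p.sum(axis=1)
    cc = float(c @ c)
    if cc <= 0:
        raise NormalizationError("reference photon dose is zero on stage-1 rows")
    scale = float(c @ b1) / cc
    if scale <= 0:
        raise NormalizationError("scale mismatch between A and measurements")

    xp, diag1 = solve_nnls_pgd(sub.A1p, b1 / scale, config=config)
    xp = xp * scale
    diagnostics["stage1"] = diag1

    xe = None
    if electron_ok:
        b2 = b[sub.rows2]
        residual2 = b2 - sub.A2p @ xp
        if sub.A2e.shape[1] > 0 and np.any(sub.A2e > 0):
            xe0 = np.full(sub.A2e.shape[1], scale)
            xe, diag2 = solve_nnls_pgd(sub.A2e, residual2, x0=xe0,
                                       config=config)
            diagnostics["stage2"] = diag2
        else:
            xe = np.zeros(sub.A2e.shape[1])
            diagnostics["stage2"] = {"note": "all-zero electron columns"}

    cf = CorrectionFactors(xp, xe, diagnostics)
    return cf, apply_correction_factors(model, cf)


def apply_correction_factors(model: BeamModel,
                             cf: CorrectionFactors) -> BeamModel:
    """Scale sub-source intensities by their commissioning factors.

    Photon sub-sources are scaled individually; every electron sub-source
    is scaled by its energy-bin group factor.  Dose linearity then makes
    the commissioned dose at the commissioning voxels equal ``A x``.
    """
    if cf.x_photon.shape != (model.n_photon_subsources,):
        raise ValueError("photon factor length mismatch")
    intensity = np.array([s.relative_intensity for s in model.subsources])
    intensity[model.photon_indices()] *= cf.x_photon
    if cf.x_electron is not None:
        groups = group_electron_effective_psrs(model)
        if len(cf.x_electron) != len(groups):
            raise ValueError("electron factor length mismatch")
        for (ebin, cols), xe in zip(sorted(groups.items()), cf.x_electron):
            intensity[np.asarray(cols)] *= xe
    return model.with_intensities(intensity)
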