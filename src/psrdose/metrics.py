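"""Dosimetric evaluation metrics.

Region-specific comparison of calculated against measured/reference dose:
RMS and maximum point differences (as % of the measured dmax dose) for
low-gradient regions, distance-to-agreement (DTA) for high-gradient
regions, output factors at dmax, and the 3D gamma index combining dose
difference and DTA.

Gamma here uses *global* normalization (the reference grid's maximum by
default) and is asymmetric: gamma(eval, ref) != gamma(ref, eval) in
general, since the search interpolates the evaluated dose around each
reference voxel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

from .transport import DoseGrid

__all__ = [
    "DoseComparisonSet",
    "GammaCriteria",
    "GammaResult",
    "DTAResult",
    "find_dmax",
    "rms_percent",
    "max_percent",
    "dta",
    "output_factor",
    "gamma_index_3d",
]


@dataclass
class DoseComparisonSet:
    """Paired calculated/measured dose points with a dmax normalizer."""

    d_calc: np.ndarray
    d_meas: np.ndarray
    d_max_meas: float
    positions: np.ndarray | None = None
    labels: np.ndarray | None = None

    def __post_init__(self):
        self.d_calc = np.asarray(self.d_calc, dtype=float)
        self.d_meas = np.asarray(self.d_meas, dtype=float)
        if self.d_calc.shape != self.d_meas.shape:
            raise ValueError("length mismatch")
        if self.d_calc.size < 1:
            raise ValueError("empty comparison set")
        if self.d_max_meas <= 0:
            raise ValueError("d_max_meas must be > 0")


def rms_percent(cmp: DoseComparisonSet) -> float:
    """Root-mean-square dose difference, % of the measured dmax dose."""
    diff = cmp.d_calc - cmp.d_meas
    return float(100.0 / cmp.d_max_meas * np.sqrt(np.mean(diff ** 2)))


def max_percent(cmp: DoseComparisonSet) -> float:
    """Maximum absolute dose difference, % of the measured dmax dose."""
    return float(100.0 / cmp.d_max_meas * np.max(np.abs(cmp.d_calc
                                                        - cmp.d_meas)))


def find_dmax(positions: np.ndarray, doses: np.ndarray):
    """Sub-sample dmax by a parabola through the three highest samples.

    Returns (position, value).  Falls back to the raw argmax when it sits
    on a curve end.
    """
    positions = np.asarray(positions, dtype=float)
    doses = np.asarray(doses, dtype=float)
    i = int(np.argmax(doses))
    if i == 0 or i == len(doses) - 1:
        return float(positions[i]), float(doses[i])
    x = positions[i - 1:i + 2]
    y = doses[i - 1:i + 2]
    a, b, c = np.polyfit(x, y, 2)
    if a >= 0:
        return float(positions[i]), float(doses[i])
    xs = -b / (2.0 * a)
    if not x[0] <= xs <= x[2]:
        return float(positions[i]), float(doses[i])
    return float(xs), float(np.polyval([a, b, c], xs))


@dataclass
class DTAResult:
    per_point: np.ndarray
    flagged: np.ndarray            # True where no crossing within the cap
    average: float
    maximum: float


def dta(curve_calc, curve_meas, mask=None, cap: float = 1.0) -> DTAResult:
    """Distance-to-agreement of a calculated curve against a measured one.

    For each masked measured point x the DTA is the smallest |x - y| such
    that the linearly interpolated calculated curve attains the measured
    value at y.  Points with no crossing get ``cap`` and are flagged.
    """
    pc, dc = (np.asarray(a, dtype=float) for a in curve_calc)
    pm, dm = (np.asarray(a, dtype=float) for a in curve_meas)
    if pc.size < 2:
        raise ValueError("calculated curve needs >= 2 points")
    mask = (np.ones(pm.size, dtype=bool) if mask is None
            else np.asarray(mask, dtype=bool))
    if not np.any(mask):
        raise ValueError("empty mask")

    per_point = np.full(pm.size, np.nan)
    flagged = np.zeros(pm.size, dtype=bool)
    seg_lo = dc[:-1]
    seg_hi = dc[1:]
    for i in np.flatnonzero(mask):
        v = dm[i]
        crossings = []
        hit = (seg_lo - v) * (seg_hi - v) <= 0.0
        for j in np.flatnonzero(hit):
            if seg_hi[j] == seg_lo[j]:
                y = pc[j] if abs(pc[j] - pm[i]) < abs(pc[j + 1] - pm[i]) \
                    else pc[j + 1]
            else:
                y = pc[j] + (v - seg_lo[j]) / (seg_hi[j] - seg_lo[j]) * (
                    pc[j + 1] - pc[j])
            crossings.append(abs(pm[i] - y))
        if crossings:
            per_point[i] = min(min(crossings), cap)
            flagged[i] = min(crossings) > cap
        else:
            per_point[i] = cap
            flagged[i] = True
    vals = per_point[mask]
    return DTAResult(per_point, flagged, float(vals.mean()),
                     float(vals.max()))


def _central_axis_curve(grid: DoseGrid):
    xc = grid.voxel_centers(0)
    yc = grid.voxel_centers(1)
    ix0 = int(np.argmin(np.abs(xc)))
    iy0 = int(np.argmin(np.abs(yc)))
    depths = grid.voxel_centers(2) - grid.origin[2]
    return depths, grid.values[ix0, iy0, :]


def output_factor(dose_field: DoseGrid, dose_ref: DoseGrid) -> float:
    """Central-axis dmax dose of a field relative to the reference field.

    Both grids must share the SSD set-up; each field is evaluated at its
    own dmax (parabolic sub-voxel refinement).
    """
    if (dose_field.ssd is not None and dose_ref.ssd is not None
            and dose_field.ssd != dose_ref.ssd):
        raise ValueError("grids have different SSD")
    _, vf = find_dmax(*_central_axis_curve(dose_field))
    _, vr = find_dmax(*_central_axis_curve(dose_ref))
    if vr <= 0:
        raise ValueError("zero reference dose")
    return float(vf / vr)


@dataclass(frozen=True)
class GammaCriteria:
    """Gamma-index acceptance criteria (global dose normalization)."""

    dose_percent: float = 2.0
    dist_mm: float = 2.0
    low_dose_threshold: float = 0.1
    normalizer: float | None = None     # defaults to the reference maximum
    search_radius_factor: float = 3.0
    refine: int = 10

    def __post_init__(self):
        if min(self.dose_percent, self.dist_mm,
               self.low_dose_threshold) <= 0:
            raise ValueError("criteria must be positive")


@dataclass
class GammaResult:
    gamma: DoseGrid
    passing_rate: float              # percent of evaluated voxels
    n_evaluated: int


def gamma_index_3d(d_eval: DoseGrid, d_ref: DoseGrid,
                   crit: GammaCriteria = GammaCriteria()) -> GammaResult:
    """3D gamma index of an evaluated dose against a reference dose.

    gamma(r) = min over the search neighborhood y of
    sqrt(|y - r|^2 / dist^2 + (D_eval(y) - D_ref(r))^2 / (dose crit)^2)
    with D_eval trilinearly interpolated on a sub-grid refined by
    ``crit.refine``.  Only reference voxels above the low-dose threshold
    are evaluated.  Offsets are visited in increasing spatial distance and
    the search stops once no voxel can improve, which keeps the exhaustive
    search tractable.
    """
    if d_eval.dims != d_ref.dims or not np.allclose(
            d_eval.voxel_size, d_ref.voxel_size) or not np.allclose(
            d_eval.origin, d_ref.origin):
        raise ValueError("grids are not co-registered")
    norm = crit.normalizer if crit.normalizer is not None \
        else float(d_ref.values.max())
    if norm <= 0:
        raise ValueError("non-positive normalizer")
    dd = crit.dose_percent / 100.0 * norm
    dist_cm = crit.dist_mm / 10.0
    radius = crit.search_radius_factor * dist_cm

    dv = np.asarray(d_ref.voxel_size)
    sub = dv / crit.refine
    noff = np.floor(radius / sub).astype(int)
    offs = [np.arange(-n, n + 1) * s for n, s in zip(noff, sub)]
    ox, oy, oz = np.meshgrid(*offs, indexing="ij")
    offsets = np.column_stack([ox.ravel(), oy.ravel(), oz.ravel()])
    r2 = (offsets ** 2).sum(axis=1)
    keep = r2 <= radius ** 2
    offsets, r2 = offsets[keep], r2[keep]
    order = np.argsort(r2, kind="stable")
    offsets, r2 = offsets[order], r2[order]

    mask = d_ref.values > crit.low_dose_threshold * norm
    n_eval = int(mask.sum())
    if n_eval == 0:
        raise ValueError("no reference voxel above the low-dose threshold")
    centers = np.stack(np.meshgrid(*(d_ref.voxel_centers(a)
                                     for a in range(3)),
                                   indexing="ij"), axis=-1)[mask]
    ref_vals = d_ref.values[mask]
    gamma2 = np.full(n_eval, np.inf)

    dims = np.asarray(d_eval.dims)
    for off, rr in zip(offsets, r2):
        dr2 = rr / dist_cm ** 2
        if np.all(gamma2 <= dr2):
            break
        pts = centers + off
        f = (pts - np.asarray(d_eval.origin)) / dv - 0.5
        inside = np.all((f >= 0) & (f <= dims - 1), axis=1)
        if not np.any(inside):
            continue
        vals = map_coordinates(d_eval.values, f[inside].T, order=1)
        cand = dr2 + (vals - ref_vals[inside]) ** 2 / dd ** 2
        g = gamma2[inside]
        gamma2[inside] = np.minimum(g, cand)

    gamma_map = np.full(d_ref.dims, np.nan)
    gamma_map[mask] = np.sqrt(gamma2)
    rate = float(100.0 * np.count_nonzero(gamma2 <= 1.0 + 1e-12) / n_eval)
    return GammaResult(d_ref.like(gamma_map), rate, n_eval)
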