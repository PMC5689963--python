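"""VMAT plan information in source sampling.

A treatment arc is a sequence of control points (gantry angle, MU fraction,
MLC aperture).  For each arc a fluence-map stack FM(x, y, k) is built on a
plane at the MLC upper surface: the FM value at a pixel and control point k
is the MU weight of k times 1 where the pixel is inside the aperture,
times the leaf transmission where it is under a closed leaf (within the
jaw), and 0 outside the jaw.  Pixel coordinates are stated at isocenter
scale (divergence-projected), so apertures defined at the isocenter apply
directly.

Two ways to attach plan information to source particles:

biased sampling (the efficient route)
    Per pixel, the control-point CPDF is the normalized cumulative sum of
    FM over k.  A pre-built numerical inverse look-up table maps a uniform
    deviate straight to a control-point index, so a particle is most
    likely assigned to a control point with both large MU and an open leaf
    at its position; it then carries weight sum_k FM(x, y, k).

FM weighting (the conventional baseline)
    The control point is drawn uniformly over k and the particle carries
    weight K * FM(x, y, k).  Both estimators have the same expectation
    E[w 1{k=m}] = FM(x, y, m); the biased one has per-pixel constant
    weights and hence no extra variance, and far fewer particles end up
    under closed leaves ("less useful" particles).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

from .model import BeamModel, Jaw, ParticleBatch, sample_source_particles
from .transport import (Collimator, DoseGrid, TransportResult, collimate,
                        estimate_average_uncertainty, transport_and_tally)

__all__ = [
    "PlanControlPoint",
    "FluenceMapStack",
    "CPDF",
    "InverseCPDFTable",
    "LessUsefulStats",
    "PlanDoseResult",
    "build_fluence_maps",
    "compute_cpdf",
    "build_inverse_lookup",
    "assign_control_points_biased",
    "assign_control_points_weighting",
    "rotate_to_beam",
    "count_less_useful",
    "calculate_plan_dose",
    "particle_reduction_factor",
    "load_plan",
    "save_plan",
]

DEFAULT_FM_PLANE_Z = 50.0       # cm from the focal spot (MLC upper surface)
DEFAULT_TRANSMISSION = 0.015
DEFAULT_PIXEL_CM = 0.25         # at isocenter scale


@dataclass(frozen=True)
class PlanControlPoint:
    """One discrete VMAT arc state.

    ``leaves`` holds per-leaf-pair (left, right) x-edges at the isocenter
    plane; a pair with left == right is closed.  Leaf pairs partition the
    jaw y-extent uniformly.
    """

    index: int
    gantry_angle_deg: float
    mu_weight: float
    jaw: Jaw
    leaves: np.ndarray            # (n_pairs, 2)

    def __post_init__(self):
        object.__setattr__(self, "leaves",
                           np.asarray(self.leaves, dtype=float))
        if self.leaves.ndim != 2 or self.leaves.shape[1] != 2:
            raise ValueError("leaves must be (n_pairs, 2)")
        if np.any(self.leaves[:, 0] > self.leaves[:, 1]):
            raise ValueError("left leaf edge beyond right edge")
        if self.mu_weight < 0:
            raise ValueError("mu_weight must be >= 0")


@dataclass
class FluenceMapStack:
    """FM(x, y, k) on a pixel grid at isocenter scale.

    ``values[iy, ix, k]``; ``open_mask`` marks in-aperture pixels and
    ``in_jaw`` marks pixels inside the jaw, both used for the less-useful
    particle accounting.
    """

    origin: tuple[float, float]       # low corner (x, y) cm
    pixel_size: float
    values: np.ndarray                # (ny, nx, K)
    open_mask: np.ndarray             # (ny, nx, K) bool
    in_jaw: np.ndarray                # (ny, nx) bool
    mu_weights: np.ndarray            # (K,)
    transmission: float
    arc_id: str = "arc0"
    fm_plane_z: float = DEFAULT_FM_PLANE_Z
    total: np.ndarray = field(init=False)

    def __post_init__(self):
        if np.any(self.values < 0):
            raise ValueError("FM values must be >= 0")
        self.total = self.values.sum(axis=2)
        if not np.any(self.total > 0):
            raise ValueError("fluence-map stack has no mass")

    @property
    def n_control_points(self) -> int:
        return self.values.shape[2]

    def pixel_of(self, x: np.ndarray, y: np.ndarray):
        """Pixel indices of isocenter-scale positions; raises off-grid."""
        ix = np.floor((x - self.origin[0]) / self.pixel_size).astype(int)
        iy = np.floor((y - self.origin[1]) / self.pixel_size).astype(int)
        ny, nx = self.values.shape[:2]
        if np.any((ix < 0) | (ix >= nx) | (iy < 0) | (iy >= ny)):
            raise ValueError("particle outside the FM grid")
        return iy, ix

    def to_hdf5(self, path: str | Path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("values", data=self.values)
            f.create_dataset("open_mask", data=self.open_mask)
            f.create_dataset("in_jaw", data=self.in_jaw)
            f.create_dataset("mu_weights", data=self.mu_weights)
            f.attrs["origin"] = self.origin
            f.attrs["pixel_size"] = self.pixel_size
            f.attrs["transmission"] = self.transmission
            f.attrs["arc_id"] = self.arc_id
            f.attrs["fm_plane_z"] = self.fm_plane_z

    @classmethod
    def from_hdf5(cls, path: str | Path) -> "FluenceMapStack":
        with h5py.File(path, "r") as f:
            return cls(tuple(f.attrs["origin"]), float(f.attrs["pixel_size"]),
                       f["values"][()], f["open_mask"][()].astype(bool),
                       f["in_jaw"][()].astype(bool), f["mu_weights"][()],
                       float(f.attrs["transmission"]),
                       arc_id=str(f.attrs["arc_id"]),
                       fm_plane_z=float(f.attrs["fm_plane_z"]))


def build_fluence_maps(arc: list[PlanControlPoint],
                       transmission: float = DEFAULT_TRANSMISSION,
                       pixel_size: float = DEFAULT_PIXEL_CM,
                       pad: float = 3.0,
                       arc_id: str = "arc0") -> FluenceMapStack:
    """Rasterize an arc's apertures into the fluence-map stack.

    FM(x, y, k) = mu_k inside the aperture, mu_k * transmission elsewhere
    inside the jaw, 0 outside the jaw.  The grid covers the jaw expanded
    by ``pad`` cm so particles sampled "nearby" the jaw still land on it.
    """
    if not arc:
        raise ValueError("empty arc")
    if not 0.0 < transmission < 1.0:
        raise ValueError("transmission must be in (0, 1)")
    jaw = arc[0].jaw
    hx, hy = jaw.half_x + pad, jaw.half_y + pad
    nx = int(np.ceil(2 * hx / pixel_size))
    ny = int(np.ceil(2 * hy / pixel_size))
    origin = (-hx, -hy)
    xc = origin[0] + (np.arange(nx) + 0.5) * pixel_size
    yc = origin[1] + (np.arange(ny) + 0.5) * pixel_size
    in_jaw = ((np.abs(yc)[:, None] <= jaw.half_y)
              & (np.abs(xc)[None, :] <= jaw.half_x))

    K = len(arc)
    values = np.zeros((ny, nx, K))
    open_mask = np.zeros((ny, nx, K), dtype=bool)
    for k, cp in enumerate(arc):
        n_pairs = cp.leaves.shape[0]
        lw = 2.0 * cp.jaw.half_y / n_pairs
        pair = np.clip(np.floor((yc + cp.jaw.half_y) / lw).astype(int),
                       0, n_pairs - 1)
        left = cp.leaves[pair, 0][:, None]
        right = cp.leaves[pair, 1][:, None]
        open_k = in_jaw & (xc[None, :] > left) & (xc[None, :] < right)
        open_mask[:, :, k] = open_k
        values[:, :, k] = cp.mu_weight * np.where(
            open_k, 1.0, np.where(in_jaw, transmission, 0.0))
    return FluenceMapStack(origin, pixel_size, values, open_mask, in_jaw,
                           np.array([cp.mu_weight for cp in arc]),
                           transmission, arc_id=arc_id)


@dataclass
class CPDF:
    """Per-pixel cumulative probability over control points."""

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if np.any(np.diff(self.values) < -1e-12):
            raise ValueError("CPDF must be non-decreasing")


def compute_cpdf(fm: FluenceMapStack, pixel: tuple[int, int]) -> CPDF:
    """CPDF_m = sum_{k<=m} FM / sum_k FM at one pixel (inclusive sum)."""
    iy, ix = pixel
    total = fm.total[iy, ix]
    if total <= 0:
        raise ValueError("all-zero FM pixel has no CPDF")
    c = np.cumsum(fm.values[iy, ix, :]) / total
    c[-1] = 1.0
    return CPDF(c)


@dataclass
class InverseCPDFTable:
    """Numerical inverse of the per-pixel CPDF.

    ``table[iy, ix, i]`` is the control-point index for the i-th
    probability bin (bin-center convention); zero-mass pixels are flagged
    in ``zero_mass``.  Nearest-bin lookups may differ from an exact CPDF
    search by one control point within half a bin of a CPDF jump.
    """

    table: np.ndarray                 # (ny, nx, n_prob_bins) int32
    zero_mass: np.ndarray             # (ny, nx) bool
    n_prob_bins: int


def build_inverse_lookup(fm: FluenceMapStack,
                         n_prob_bins: int | None = None) -> InverseCPDFTable:
    """Tabulate k(gamma) per pixel: k with CPDF_{k-1} <= gamma < CPDF_k."""
    if n_prob_bins is None:
        n_prob_bins = 16 * fm.n_control_points
    if n_prob_bins < 1:
        raise ValueError("n_prob_bins must be >= 1")
    ny, nx, K = fm.values.shape
    gam = (np.arange(n_prob_bins) + 0.5) / n_prob_bins
    table = np.zeros((ny, nx, n_prob_bins), dtype=np.int32)
    zero_mass = fm.total <= 0
    cum = np.cumsum(fm.values, axis=2)
    for iy in range(ny):
        for ix in range(nx):
            if zero_mass[iy, ix]:
                continue
            c = cum[iy, ix] / fm.total[iy, ix]
            c[-1] = 1.0
            table[iy, ix] = np.minimum(
                np.searchsorted(c, gam, side="right"), K - 1)
    return InverseCPDFTable(table, zero_mass, n_prob_bins)


@dataclass
class AssignmentStats:
    n_zero_mass: int = 0


def _inside_fm_grid(fm: FluenceMapStack, x: np.ndarray,
                    y: np.ndarray) -> np.ndarray:
    ny, nx = fm.values.shape[:2]
    ix = np.floor((x - fm.origin[0]) / fm.pixel_size)
    iy = np.floor((y - fm.origin[1]) / fm.pixel_size)
    return (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny)


def _fm_plane_positions(batch: ParticleBatch, fm: FluenceMapStack,
                        sad: float = 100.0, source_z: float = 0.0):
    """Isocenter-scale (x, y) where each particle crosses the FM plane."""
    t = (fm.fm_plane_z - batch.plane_z) / batch.direction[:, 2]
    x = batch.x + t * batch.direction[:, 0]
    y = batch.y + t * batch.direction[:, 1]
    scale = (sad - source_z) / (fm.fm_plane_z - source_z)
    return x * scale, y * scale


def assign_control_points_biased(batch: ParticleBatch, fm: FluenceMapStack,
                                 table: InverseCPDFTable, rng_seed=None,
                                 sad: float = 100.0):
    """Draw control points through the inverse look-up table.

    Each particle's weight is multiplied by sum_k FM at its pixel.
    Zero-mass pixels give weight 0 and index -1, counted separately.
    Returns (assigned batch, AssignmentStats).
    """
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    out = batch.copy()
    x, y = _fm_plane_positions(batch, fm, sad=sad)
    iy, ix = fm.pixel_of(x, y)
    gam = rng.random(len(batch))
    bins = np.minimum((gam * table.n_prob_bins).astype(int),
                      table.n_prob_bins - 1)
    k = table.table[iy, ix, bins]
    dead = table.zero_mass[iy, ix]
    out.cp_index = np.where(dead, -1, k).astype(np.int32)
    out.weight = np.where(dead, 0.0, out.weight * fm.total[iy, ix])
    return out, AssignmentStats(n_zero_mass=int(dead.sum()))


def assign_control_points_weighting(batch: ParticleBatch,
                                    fm: FluenceMapStack, rng_seed=None,
                                    sad: float = 100.0):
    """Conventional FM weighting: uniform k, weight *= K * FM(x, y, k).

    The uniform control-point draw with the K-fold weight makes this an
    unbiased estimator of the same quantity as the biased method.
    """
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    out = batch.copy()
    x, y = _fm_plane_positions(batch, fm, sad=sad)
    iy, ix = fm.pixel_of(x, y)
    K = fm.n_control_points
    k = rng.integers(0, K, size=len(batch))
    dead = fm.total[iy, ix] <= 0
    out.cp_index = np.where(dead, -1, k).astype(np.int32)
    out.weight = np.where(dead, 0.0,
                          out.weight * K * fm.values[iy, ix, k])
    return out, AssignmentStats(n_zero_mass=int(dead.sum()))


def rotate_to_beam(batch: ParticleBatch, arc: list[PlanControlPoint],
                   isocenter=(0.0, 0.0, 100.0)) -> ParticleBatch:
    """Rotate particles about the isocenter y-axis by their control point's
    gantry angle (IEC 61217 sense); positions become full 3-vectors in
    phantom coordinates."""
    angles = np.array([cp.gantry_angle_deg for cp in arc])
    if not np.all(np.isfinite(angles)):
        raise ValueError("non-finite gantry angle")
    k = batch.cp_index
    theta = np.deg2rad(np.where(k >= 0, angles[np.maximum(k, 0)], 0.0))
    c, s = np.cos(theta), np.sin(theta)
    iso = np.asarray(isocenter)
    pos = batch.positions3() - iso
    d = batch.direction
    out = batch.copy()
    px = c * pos[:, 0] + s * pos[:, 2]
    pz = -s * pos[:, 0] + c * pos[:, 2]
    dx = c * d[:, 0] + s * d[:, 2]
    dz = -s * d[:, 0] + c * d[:, 2]
    out.pos3 = np.column_stack([px, pos[:, 1], pz]) + iso
    out.direction = np.column_stack([dx, d[:, 1], dz])
    return out


@dataclass
class LessUsefulStats:
    """Particles that hit closed MLC leaves (inside the jaw)."""

    count: int
    total: int

    @property
    def fraction(self) -> float:
        return self.count / self.total if self.total else 0.0

    @property
    def percent(self) -> float:
        return 100.0 * self.fraction


def count_less_useful(batch: ParticleBatch, fm: FluenceMapStack,
                      sad: float = 100.0) -> LessUsefulStats:
    """Count assigned particles whose FM-plane position is inside the jaw
    but under a closed leaf at their assigned control point."""
    if np.all(batch.cp_index < 0):
        raise ValueError("control points not assigned")
    assigned = batch.cp_index >= 0
    x, y = _fm_plane_positions(batch, fm, sad=sad)
    iy, ix = fm.pixel_of(x[assigned], y[assigned])
    k = batch.cp_index[assigned]
    in_jaw = fm.in_jaw[iy, ix]
    open_leaf = fm.open_mask[iy, ix, k]
    return LessUsefulStats(int(np.count_nonzero(in_jaw & ~open_leaf)),
                           int(assigned.sum()))


def particle_reduction_factor(n_baseline: float, n_biased: float) -> float:
    """Particle-count reduction factor of biased sampling vs the baseline."""
    if n_biased <= 0:
        raise ValueError("n_biased must be > 0")
    return n_baseline / n_biased


@dataclass
class PlanDoseResult:
    dose: DoseGrid
    uncertainty_percent: float
    less_useful: LessUsefulStats
    n_particles: int
    n_zero_mass: int
    batch_doses: list[DoseGrid]


class BudgetError(RuntimeError):
    pass


def calculate_plan_dose(arc: list[PlanControlPoint], model: BeamModel,
                        phantom: DoseGrid, method: str = "biased",
                        n_particles: int | None = None,
                        target_uncertainty: float | None = None,
                        rng_seed: int = 0, batch_particles: int = 20000,
                        max_particles: int = 5_000_000,
                        isocenter=None, margin: float = 0.5,
                        fm: FluenceMapStack | None = None,
                        table: InverseCPDFTable | None = None,
                        transmission: float = DEFAULT_TRANSMISSION,
                        min_batches: int = 4) -> PlanDoseResult:
    """Monte Carlo dose of a single arc with either sampling method.

    Samples source particles near the jaw, assigns control points by the
    chosen method, collimates at the jaw planes, rotates to the gantry
    angle, and transports batches until ``target_uncertainty`` (percent,
    relative to the running maximum dose) is met or ``n_particles`` have
    been used.  Statistical uncertainty is estimated from batch spread.
    """
    if method not in ("biased", "weighting"):
        raise ValueError("method must be 'biased' or 'weighting'")
    if n_particles is None and target_uncertainty is None:
        raise ValueError("give n_particles or target_uncertainty")
    jaw = arc[0].jaw
    if fm is None:
        fm = build_fluence_maps(arc, transmission=transmission)
    if method == "biased" and table is None:
        table = build_inverse_lookup(fm)
    if isocenter is None:
        iso_z = model.sad
        isocenter = (0.0, 0.0, iso_z)
    collimator = Collimator(jaw, sad=model.sad, source_z=model.source_z)

    ss = np.random.SeedSequence(rng_seed)
    batch_grids: list[DoseGrid] = []
    batch_sizes: list[int] = []
    n_used = 0
    lu_count = 0
    lu_total = 0
    zero_mass = 0
    while True:
        n_this = (batch_particles if n_particles is None
                  else min(batch_particles, n_particles - n_used))
        if n_this <= 0:
            break
        child = np.random.default_rng(ss.spawn(1)[0])
        batch = sample_source_particles(model, n_this, jaw, margin=margin,
                                        rng_seed=child)
        # collimate in the beam frame first; jaw-blocked particles carry no
        # dose and never reach the MLC plane
        batch, _ = collimate(batch, collimator)
        # survivors that still drift off the padded FM grid are outside the
        # jaw shadow where FM = 0: drop them as zero-weight, not an error
        x, y = _fm_plane_positions(batch, fm, sad=model.sad,
                                   source_z=model.source_z)
        on_grid = _inside_fm_grid(fm, x, y)
        zero_mass += int(np.count_nonzero(~on_grid))
        batch = batch.select(on_grid)
        if method == "biased":
            batch, stats = assign_control_points_biased(
                batch, fm, table, rng_seed=child, sad=model.sad)
        else:
            batch, stats = assign_control_points_weighting(
                batch, fm, rng_seed=child, sad=model.sad)
        zero_mass += stats.n_zero_mass
        if len(batch):
            lu = count_less_useful(batch, fm, sad=model.sad)
            lu_count += lu.count
            lu_total += lu.total
        batch = rotate_to_beam(batch, arc, isocenter=isocenter)
        res = transport_and_tally(batch, phantom, n_batches=1,
                                  n_histories=n_this)
        batch_grids.append(res.batch_doses[0])
        batch_sizes.append(n_this)
        n_used += n_this

        if n_particles is not None and n_used >= n_particles:
            break
        if target_uncertainty is not None and len(batch_grids) >= min_batches:
            mean = np.mean([g.values for g in batch_grids], axis=0)
            ref = float(mean.max())
            if ref > 0:
                unc = estimate_average_uncertainty(batch_grids, ref)
                if unc <= target_uncertainty:
                    break
        if n_used >= max_particles:
            raise BudgetError(
                f"target uncertainty not reached within {max_particles} "
                "particles")

    if len(batch_grids) == 1:
        mean = batch_grids[0].values
    elif len(set(batch_sizes)) == 1:
        mean = np.mean([g.values for g in batch_grids], axis=0)
    else:
        # history-weighted combination when the last batch is short
        mean = sum(g.values * nb for g, nb in
                   zip(batch_grids, batch_sizes)) / n_used
    dose = phantom.like(mean)
    ref = float(mean.max())
    unc = (estimate_average_uncertainty(batch_grids, ref)
           if len(batch_grids) >= 2 and ref > 0 else float("nan"))
    return PlanDoseResult(dose, unc, LessUsefulStats(lu_count, lu_total),
                          n_used, zero_mass, batch_grids)


# ---------------------------------------------------------------------------
# plan JSON I/O

def save_plan(arcs: list[list[PlanControlPoint]], path: str | Path) -> None:
    doc = {"arcs": []}
    for arc in arcs:
        doc["arcs"].append({"control_points": [
            {
                "gantry_angle_deg": cp.gantry_angle_deg,
                "mu_weight": cp.mu_weight,
                "jaw": [cp.jaw.half_x, cp.jaw.half_y],
                "leaves": cp.leaves.tolist(),
            }
            for cp in arc
        ]})
    Path(path).write_text(json.dumps(doc, indent=1))


def load_plan(path: str | Path) -> list[list[PlanControlPoint]]:
    doc = json.loads(Path(path).read_text())
    arcs = []
    for arc_doc in doc["arcs"]:
        arc = [
            PlanControlPoint(i, cp["gantry_angle_deg"], cp["mu_weight"],
                             Jaw(*cp["jaw"]), np.asarray(cp["leaves"]))
            for i, cp in enumerate(arc_doc["control_points"])
        ]
        arcs.append(arc)
    return arcs
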