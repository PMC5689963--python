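"""Water-phantom transport stand-in and the concurrent sub-source tally.

Transport is *deterministic per particle*: each source particle is ray
traced through the phantom and deposits energy along its ray with a class-
and energy-dependent depth kernel (photons: exponential attenuation minus
a build-up term, giving a realistic dmax; electrons: finite range with a
linear ramp-down).  Each ray step is deposited with trilinear
(cloud-in-cell) weights into the eight surrounding voxels.  All statistical
noise therefore originates in source sampling, and a given particle list
always produces a bit-identical dose grid.

The commissioning sub-source dose matrix ``A`` is accumulated concurrently
in the same pass: a per-voxel row-index look-up table maps commissioning
voxels (central-axis depth dose plus inline/cross-line profile rows) to
rows of ``A``; negative entries mark voxels that are ignored.  The column
is the sub-source index carried by the particle.  ``A`` entries are
accumulated strictly in particle-stream order, so a concurrent pass over a
mixed stream reproduces, bit-exactly, the sum of per-sub-source passes fed
the identical stream partitioned by sub-source.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import SimpleITK as sitk
from scipy.ndimage import map_coordinates

from .model import ParticleBatch, ParticleClass, Jaw

__all__ = [
    "DoseGrid",
    "RowMeta",
    "SubsourceDoseMatrix",
    "CommissioningGeometry",
    "Collimator",
    "TransportResult",
    "select_commissioning_voxels",
    "transport_and_tally",
    "dose_at",
    "estimate_average_uncertainty",
    "collimate",
]


# ---------------------------------------------------------------------------
# dose grid

@dataclass
class DoseGrid:
    """3D voxelized dose, values indexed [ix, iy, iz] in Gy per history.

    ``origin`` is the low corner of the grid (cm); voxel values live at
    voxel centers; voxel extents are half-open.  ``ssd`` records the
    source-to-surface distance of the set-up when meaningful.
    """

    origin: tuple[float, float, float]
    voxel_size: tuple[float, float, float]
    values: np.ndarray
    ssd: float | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError("values must be 3D")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.values.shape

    @classmethod
    def empty(cls, origin, voxel_size, dims, ssd=None) -> "DoseGrid":
        return cls(tuple(origin), tuple(voxel_size),
                   np.zeros(dims, dtype=np.float64), ssd=ssd)

    def like(self, values: np.ndarray) -> "DoseGrid":
        return DoseGrid(self.origin, self.voxel_size, values, ssd=self.ssd)

    def voxel_centers(self, axis: int) -> np.ndarray:
        n = self.dims[axis]
        return (self.origin[axis]
                + (np.arange(n) + 0.5) * self.voxel_size[axis])

    # -- MetaImage I/O (.mhd + .raw, 32-bit float) -------------------------

    def write_mhd(self, path: str | Path) -> None:
        img = sitk.GetImageFromArray(
            np.ascontiguousarray(self.values.transpose(2, 1, 0),
                                 dtype=np.float32))
        img.SetSpacing(tuple(float(v) for v in self.voxel_size))
        # MetaImage origin is the center of the first voxel
        img.SetOrigin(tuple(o + 0.5 * v for o, v in
                            zip(self.origin, self.voxel_size)))
        sitk.WriteImage(img, str(path))

    @classmethod
    def read_mhd(cls, path: str | Path, ssd: float | None = None) -> "DoseGrid":
        img = sitk.ReadImage(str(path))
        values = sitk.GetArrayFromImage(img).transpose(2, 1, 0).astype(
            np.float64)
        spacing = img.GetSpacing()
        origin = tuple(o - 0.5 * v for o, v in zip(img.GetOrigin(), spacing))
        return cls(origin, tuple(spacing), values, ssd=ssd)


def dose_at(grid: DoseGrid, depth: float, lateral=(0.0, 0.0)) -> float:
    """Trilinear interpolation at lateral (x, y) and depth below the surface.

    The phantom surface is the low-z face of the grid (z = origin_z).
    """
    point = (lateral[0], lateral[1], grid.origin[2] + depth)
    return interpolate_points(grid, np.asarray(point)[None, :])[0]


def interpolate_points(grid: DoseGrid, points: np.ndarray) -> np.ndarray:
    """Trilinear interpolation at (n, 3) physical points; range-checked."""
    points = np.asarray(points, dtype=float)
    f = ((points - np.asarray(grid.origin))
         / np.asarray(grid.voxel_size)) - 0.5
    dims = np.asarray(grid.dims)
    if np.any(f < -1e-9) or np.any(f > dims - 1 + 1e-9):
        raise ValueError("query point outside the dose grid")
    return map_coordinates(grid.values, f.T, order=1, mode="nearest")


# ---------------------------------------------------------------------------
# commissioning voxel selection

@dataclass(frozen=True)
class RowMeta:
    """Descriptor of one commissioning row (one voxel on a scan curve)."""

    field: str
    curve_type: str          # depth | inline | crossline
    depth: float             # cm below the surface (voxel center)
    offset: float            # lateral offset cm (0 for the depth curve)


@dataclass(frozen=True)
class CommissioningGeometry:
    """Open-field measurement geometry: field size, SSD, profile depths."""

    field: str
    field_size: tuple[float, float]
    ssd: float
    profile_depths: tuple[float, ...]

    def jaw(self) -> Jaw:
        return Jaw(self.field_size[0] / 2.0, self.field_size[1] / 2.0)


class GeometryError(ValueError):
    pass


def select_commissioning_voxels(grid: DoseGrid,
                                geom: CommissioningGeometry):
    """Build the row-index LUT and ordered row metadata.

    Rows cover the central-axis depth-dose column first, then, per
    requested depth in the given order, the cross-line (along x) and
    inline (along y) voxel rows; voxels already on the central axis are
    not duplicated.  All other voxels are marked -1.
    """
    nx, ny, nz = grid.dims
    xc = grid.voxel_centers(0)
    yc = grid.voxel_centers(1)
    zc = grid.voxel_centers(2)
    ix0 = int(np.argmin(np.abs(xc)))
    iy0 = int(np.argmin(np.abs(yc)))

    lut = np.full(grid.dims, -1, dtype=np.int32)
    row_meta: list[RowMeta] = []
    row = 0
    for iz in range(nz):
        lut[ix0, iy0, iz] = row
        row_meta.append(RowMeta(geom.field, "depth",
                                float(zc[iz] - grid.origin[2]), 0.0))
        row += 1
    depth_span = zc[-1] - grid.origin[2] + 0.5 * grid.voxel_size[2]
    for d in geom.profile_depths:
        if d < 0 or d > depth_span:
            raise GeometryError(f"profile depth {d} cm outside the phantom")
        izd = int(np.argmin(np.abs(zc - (grid.origin[2] + d))))
        dz = float(zc[izd] - grid.origin[2])
        for ix in range(nx):
            if lut[ix, iy0, izd] >= 0:
                continue
            lut[ix, iy0, izd] = row
            row_meta.append(RowMeta(geom.field, "crossline", dz,
                                    float(xc[ix])))
            row += 1
        for iy in range(ny):
            if lut[ix0, iy, izd] >= 0:
                continue
            lut[ix0, iy, izd] = row
            row_meta.append(RowMeta(geom.field, "inline", dz, float(yc[iy])))
            row += 1
    return lut, row_meta


# ---------------------------------------------------------------------------
# sub-source dose matrix

@dataclass
class SubsourceDoseMatrix:
    """Commissioning-voxel x sub-source dose tally (matrix A).

    ``values[r, j]`` is the dose per history at commissioning voxel r from
    sub-source j; ``stderr`` is the per-entry standard error from batch
    statistics.  ``col_meta`` records (ring, energy bin, class) per column
    in the model's canonical order.
    """

    values: np.ndarray
    stderr: np.ndarray
    row_meta: list[RowMeta]
    col_meta: list[tuple[int, int, int]]

    def __post_init__(self):
        if self.values.shape != self.stderr.shape:
            raise ValueError("values/stderr shape mismatch")
        if self.values.shape[0] != len(self.row_meta):
            raise ValueError("row_meta length mismatch")
        if self.values.shape[1] != len(self.col_meta):
            raise ValueError("col_meta length mismatch")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @staticmethod
    def stack(matrices: list["SubsourceDoseMatrix"]) -> "SubsourceDoseMatrix":
        """Stack the rows of per-field matrices sharing a column layout."""
        cm = matrices[0].col_meta
        for m in matrices[1:]:
            if m.col_meta != cm:
                raise ValueError("column layouts differ")
        return SubsourceDoseMatrix(
            np.vstack([m.values for m in matrices]),
            np.vstack([m.stderr for m in matrices]),
            [r for m in matrices for r in m.row_meta], cm)

    def to_hdf5(self, path: str | Path) -> None:
        rm = np.array(
            [(r.field.encode(), r.curve_type.encode(), r.depth, r.offset)
             for r in self.row_meta],
            dtype=[("field", "S16"), ("curve_type", "S10"),
                   ("depth", "f8"), ("offset", "f8")])
        with h5py.File(path, "w") as f:
            f.create_dataset("values", data=self.values)
            f.create_dataset("stderr", data=self.stderr)
            f.create_dataset("row_meta", data=rm)
            f.create_dataset("col_meta", data=np.asarray(self.col_meta,
                                                         dtype=np.int32))

    @classmethod
    def from_hdf5(cls, path: str | Path) -> "SubsourceDoseMatrix":
        with h5py.File(path, "r") as f:
            values = f["values"][()]
            stderr = f["stderr"][()]
            rm = f["row_meta"][()]
            cm = [tuple(int(v) for v in row) for row in f["col_meta"][()]]
        row_meta = [RowMeta(r["field"].decode(), r["curve_type"].decode(),
                            float(r["depth"]), float(r["offset"]))
                    for r in rm]
        return cls(values, stderr, row_meta, cm)


# ---------------------------------------------------------------------------
# jaw collimation

@dataclass(frozen=True)
class Collimator:
    """Rectangular jaws at two planes below the source (zero transmission).

    X jaws shape the beam in x at ``z_x`` and Y jaws in y at ``z_y`` (cm
    from the focal spot); openings are given at the isocenter plane and
    scale with the focal divergence.  The different jaw elevations make
    rectangular fields non-interchangeable (6x15 vs 15x6).
    """

    jaw: Jaw
    z_x: float = 36.0
    z_y: float = 44.0
    sad: float = 100.0
    source_z: float = 0.0

    def passes(self, batch: ParticleBatch) -> np.ndarray:
        pos = batch.positions3()
        d = batch.direction
        ok = np.ones(len(batch), dtype=bool)
        for axis, z_plane, half in ((0, self.z_x, self.jaw.half_x),
                                    (1, self.z_y, self.jaw.half_y)):
            t = (z_plane - pos[:, 2]) / d[:, 2]
            coord = pos[:, axis] + t * d[:, axis]
            limit = half * (z_plane - self.source_z) / (self.sad - self.source_z)
            ok &= np.abs(coord) <= limit
        return ok


def collimate(batch: ParticleBatch, collimator: Collimator):
    """Remove particles blocked by the jaws; stream order is preserved.

    Returns (surviving batch, number blocked).  Blocked particles still
    count as histories for per-history normalization.
    """
    ok = collimator.passes(batch)
    return batch.select(ok), int(np.count_nonzero(~ok))


# ---------------------------------------------------------------------------
# depth kernels (toy, water)

def photon_mu(energy: np.ndarray) -> np.ndarray:
    """Effective attenuation coefficient (1/cm), softening with energy."""
    return 0.04 + 0.05 * np.exp(-energy / 3.0)


def photon_beta(energy: np.ndarray) -> np.ndarray:
    """Build-up rate (1/cm); larger energy -> deeper dmax."""
    return np.maximum(5.0 / (1.0 + energy / 2.0), 2.0 * photon_mu(energy))


def electron_range(energy: np.ndarray) -> np.ndarray:
    """Practical range (cm) of contaminant electrons, ~E/2 in water."""
    return np.maximum(0.5 * energy, 1e-3)


def _deposit_kernel(pclass: np.ndarray, energy: np.ndarray,
                    depth: np.ndarray) -> np.ndarray:
    """Energy deposited per unit path (MeV/cm) at water depth ``depth``.

    Photon: N (exp(-mu d) - exp(-beta d)) with N chosen so the infinite-
    depth integral equals the particle energy.  Electron: linear ramp to
    the practical range, same total energy.
    """
    out = np.empty_like(depth)
    ph = pclass != int(ParticleClass.ELECTRON)
    if np.any(ph):
        e = energy[ph]
        mu = photon_mu(e)
        beta = photon_beta(e)
        n0 = e / (1.0 / mu - 1.0 / beta)
        d = depth[ph]
        out[ph] = n0 * (np.exp(-mu * d) - np.exp(-beta * d))
    el = ~ph
    if np.any(el):
        r = electron_range(energy[el])
        d = depth[el]
        out[el] = np.where(d < r, 2.0 * energy[el] / r * (1.0 - d / r), 0.0)
    return np.maximum(out, 0.0)


# ---------------------------------------------------------------------------
# transport + concurrent tally

@dataclass
class TransportResult:
    dose: DoseGrid
    matrix: SubsourceDoseMatrix | None
    batch_doses: list[DoseGrid] = field(default_factory=list)
    n_histories: int = 0


class TallyError(ValueError):
    pass


def _ray_entry_exit(pos, d, origin, upper):
    """Slab intersection of rays with the grid's bounding box."""
    with np.errstate(divide="ignore", invalid="ignore"):
        t_lo = (origin - pos) / d
        t_hi = (upper - pos) / d
    t_near = np.minimum(t_lo, t_hi)
    t_far = np.maximum(t_lo, t_hi)
    # parallel rays: component outside slab -> miss
    par = d == 0.0
    inside = (pos >= origin) & (pos <= upper)
    t_near[par] = np.where(inside[par], -np.inf, np.inf)
    t_far[par] = np.where(inside[par], np.inf, -np.inf)
    t0 = np.maximum(t_near.max(axis=1), 0.0)
    t1 = t_far.min(axis=1)
    return t0, t1


def transport_and_tally(particles: ParticleBatch, grid: DoseGrid,
                        lut: np.ndarray | None = None, n_batches: int = 10,
                        *, n_subsources: int | None = None,
                        row_meta: list[RowMeta] | None = None,
                        col_meta: list | None = None,
                        n_histories: int | None = None,
                        step: float | None = None,
                        chunk: int = 40000) -> TransportResult:
    """Deposit dose and (optionally) accumulate the sub-source matrix A.

    ``n_histories`` defaults to the particle count; pass the pre-collimation
    count when blocked particles were removed upstream.  Batch statistics
    split the stream into ``n_batches`` contiguous groups.
    """
    if n_batches < 1:
        raise ValueError("n_batches must be >= 1")
    n = len(particles)
    n_hist = n if n_histories is None else int(n_histories)
    origin = np.asarray(grid.origin)
    dv = np.asarray(grid.voxel_size)
    dims = grid.dims
    upper = origin + dv * np.asarray(dims)
    nvox = int(np.prod(dims))
    voxel_volume = float(np.prod(dv))
    ds = float(step) if step is not None else float(min(dv))

    tally = lut is not None
    if tally:
        if np.any(particles.subsource < 0):
            raise TallyError("particle with unset subsource index")
        if n_subsources is None:
            raise TallyError("n_subsources required when a LUT is given")
        n_rows = int(lut.max()) + 1 if lut.size else 0
        a_flat = np.zeros(n_rows * n_subsources)
        a_batch = np.zeros((n_batches, n_rows * n_subsources))
        a_batch_flat = a_batch.reshape(-1)
        lut_flat = lut.ravel()

    dose_batches = np.zeros((n_batches, nvox))

    if n > 0:
        batch_of = (np.arange(n) * n_batches) // n
        pos_all = particles.positions3()
        for lo in range(0, n, chunk):
            hi = min(lo + chunk, n)
            pos = pos_all[lo:hi]
            d = particles.direction[lo:hi]
            w = particles.weight[lo:hi]
            energy = particles.energy[lo:hi]
            pclass = particles.pclass[lo:hi]
            bidx = batch_of[lo:hi]
            m = hi - lo

            t0, t1 = _ray_entry_exit(pos, d, origin, upper)
            path = np.maximum(t1 - t0, 0.0)
            n_steps = int(np.ceil(path.max() / ds)) if path.max() > 0 else 0
            if n_steps == 0:
                continue
            # (particle, step) arrays, particle-major ordering throughout
            s = t0[:, None] + (np.arange(n_steps)[None, :] + 0.5) * ds
            live = s < t1[:, None]
            depth = s - t0[:, None]
            dep = (w[:, None] * _deposit_kernel(
                np.broadcast_to(pclass[:, None], (m, n_steps)),
                np.broadcast_to(energy[:, None], (m, n_steps)),
                depth) * ds / voxel_volume)
            dep[~live] = 0.0

            p = pos[:, None, :] + s[:, :, None] * d[:, None, :]
            f = (p - origin) / dv - 0.5          # fractional voxel index
            i0 = np.floor(f).astype(np.int64)
            frac = f - i0

            # trilinear cloud-in-cell deposit into the 8 corners
            a_keys, a_idx, a_amt, a_bat = [], [], [], []
            for corner in range(8):
                off = np.array([(corner >> 2) & 1, (corner >> 1) & 1,
                                corner & 1])
                iv = i0 + off
                cw = np.ones_like(dep)
                for ax in range(3):
                    cw = cw * np.where(off[ax] == 1, frac[:, :, ax],
                                       1.0 - frac[:, :, ax])
                valid = live.copy()
                for ax in range(3):
                    valid &= (iv[:, :, ax] >= 0) & (iv[:, :, ax] < dims[ax])
                amount = dep * cw
                flat = ((iv[:, :, 0] * dims[1] + iv[:, :, 1]) * dims[2]
                        + iv[:, :, 2])
                flat = np.where(valid, flat, 0)
                amount = np.where(valid, amount, 0.0)
                bflat = (np.broadcast_to(bidx[:, None], flat.shape) * nvox
                         + flat)
                dose_batches += np.bincount(
                    bflat.ravel(), weights=amount.ravel(),
                    minlength=n_batches * nvox).reshape(n_batches, nvox)
                if tally:
                    rows = np.where(valid, lut_flat[flat], -1)
                    sel = rows >= 0
                    if np.any(sel):
                        psel, ssel = np.nonzero(sel)
                        cols = particles.subsource[lo:hi][psel]
                        a_idx.append(rows[sel] * n_subsources + cols)
                        a_amt.append(amount[sel])
                        a_bat.append(bidx[psel])
                        a_keys.append((psel * n_steps + ssel) * 8 + corner)
            if tally and a_keys:
                # accumulate A strictly in (particle, step, corner) order so
                # that a concurrent pass is bit-identical to the sum of
                # per-sub-source passes on the partitioned stream,
                # independent of chunk boundaries
                order = np.argsort(np.concatenate(a_keys), kind="stable")
                aidx = np.concatenate(a_idx)[order]
                amt = np.concatenate(a_amt)[order]
                abat = np.concatenate(a_bat)[order]
                np.add.at(a_flat, aidx, amt)
                np.add.at(a_batch_flat,
                          abat * (n_rows * n_subsources) + aidx, amt)

    hist_per_batch = n_hist / n_batches if n_hist > 0 else 1.0
    dose_values = dose_batches.sum(axis=0).reshape(dims) / max(n_hist, 1)
    dose = grid.like(dose_values)
    batch_doses = [grid.like(dose_batches[b].reshape(dims) / hist_per_batch)
                   for b in range(n_batches)]

    matrix = None
    if tally:
        values = a_flat.reshape(n_rows, n_subsources) / max(n_hist, 1)
        bm = a_batch.reshape(n_batches, n_rows, n_subsources) / hist_per_batch
        if n_batches > 1:
            stderr = bm.std(axis=0, ddof=1) / np.sqrt(n_batches)
        else:
            stderr = np.zeros_like(values)
        matrix = SubsourceDoseMatrix(
            values, stderr,
            row_meta if row_meta is not None else
            [RowMeta("", "unknown", np.nan, np.nan)] * n_rows,
            col_meta if col_meta is not None else
            [(-1, -1, -1)] * n_subsources)
    return TransportResult(dose, matrix, batch_doses, n_hist)


# ---------------------------------------------------------------------------
# batch statistics

def estimate_average_uncertainty(batch_doses: list[DoseGrid],
                                 reference_dose: float,
                                 threshold_fraction: float = 0.5) -> float:
    """Average relative statistical uncertainty, in percent.

    Per-voxel standard error of the batch mean divided by
    ``reference_dose`` (the prescription-dose stand-in), averaged over
    voxels whose mean dose exceeds ``threshold_fraction * reference_dose``.
    """
    if len(batch_doses) < 2:
        raise ValueError("need at least 2 batches")
    if reference_dose <= 0:
        raise ValueError("reference_dose must be > 0")
    stack = np.stack([b.values for b in batch_doses])
    mean = stack.mean(axis=0)
    sem = stack.std(axis=0, ddof=1) / np.sqrt(stack.shape[0])
    mask = mean > threshold_fraction * reference_dose
    if not np.any(mask):
        raise ValueError("no voxel above the averaging threshold")
    return float(100.0 * sem[mask].mean() / reference_dose)
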