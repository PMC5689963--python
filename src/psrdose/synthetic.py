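"""Synthetic study generation: every input the pipeline needs, in-repo.

Generators for toy beam models, measured-style water doses with *known*
ground-truth correction factors, toy VMAT arcs, and water phantoms, so
that commissioning and plan-dose calculation are testable end to end with
no external data.  Measurements are manufactured from the sub-source dose
matrix itself (b = A x_true + Gaussian noise), which makes parameter
recovery a well-posed check: the commissioned doses must reproduce
A x_true regardless of the Monte Carlo noise inside A.

The default study is a scaled-down version of the full setting: an
8-ring x 6-energy-bin model (432 sub-sources) commissioned on the
40x40 / 10x10 / 2x2 cm^2 field trio at 100 cm SSD with profile depths
dmax / 5 / 10 / 20 cm, and a K = 36 single-arc plan.  A "full-scale"
preset (40 x 20 rings/bins, K = 178) exists for slow runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .commission import MeasurementCurve, MeasurementSet
from .metrics import find_dmax
from .model import (BeamModel, Jaw, ParticleClass, ToySpectrum,
                    build_toy_beam_model, sample_source_particles)
from .plan import PlanControlPoint
from .transport import (Collimator, CommissioningGeometry, DoseGrid,
                        SubsourceDoseMatrix, TransportResult, collimate,
                        select_commissioning_voxels, transport_and_tally)

__all__ = [
    "SyntheticStudySpec",
    "StudyData",
    "make_synthetic_measurements",
    "make_toy_vmat_arc",
    "make_default_phantom",
    "make_study_phantom",
    "simulate_field",
    "build_study_matrix",
    "draw_ground_truth_factors",
    "run_study",
]

STUDY_FIELDS = ("40x40", "10x10", "2x2")
STUDY_PROFILE_DEPTHS = (1.5, 5.0, 10.0, 20.0)   # first entry ~ dmax
STUDY_SSD = 100.0


@dataclass
class SyntheticStudySpec:
    """Everything that defines one synthetic commissioning + plan study."""

    n_rings: int = 8
    n_energy_bins: int = 6
    spectrum: ToySpectrum = field(default_factory=ToySpectrum)
    noise_sigma: float = 0.0          # percent of the dmax dose
    x_true_mode: str = "random"       # random | ones
    fields: tuple[str, ...] = STUDY_FIELDS
    profile_depths: tuple[float, ...] = STUDY_PROFILE_DEPTHS
    n_particles_per_field: int = 150_000
    plan_control_points: int = 36
    aperture_schedule: str = "sweeping_slit"
    mu_schedule: str = "uniform"
    rng_seed: int = 0

    def __post_init__(self):
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")

    @classmethod
    def full_scale(cls, **kw) -> "SyntheticStudySpec":
        kw.setdefault("n_rings", 40)
        kw.setdefault("n_energy_bins", 20)
        kw.setdefault("plan_control_points", 178)
        return cls(**kw)


def parse_field(label: str) -> tuple[float, float]:
    wx, wy = label.split("x")
    return float(wx), float(wy)


def make_default_phantom(profile: str = "test") -> DoseGrid:
    """Water phantom at 100 cm SSD.

    ``test``: 30^3 voxels at 5 mm (15 cm cube).  ``full``: 200x200x160 at
    2.5 mm (50x50x40 cm^3), covering the 40x40 cm^2 field.
    """
    if profile == "test":
        dims, v = (30, 30, 30), 0.5
    elif profile == "full":
        dims, v = (200, 200, 160), 0.25
    else:
        raise ValueError(f"unknown profile {profile!r}")
    origin = (-dims[0] * v / 2.0, -dims[1] * v / 2.0, STUDY_SSD)
    return DoseGrid.empty(origin, (v, v, v), dims, ssd=STUDY_SSD)


def make_study_phantom() -> DoseGrid:
    """Commissioning phantom of the default study.

    41 x 41 lateral voxels at 1.25 cm (51.25 cm, holding the 40x40 cm^2
    field) and 100 depth voxels at 2.5 mm (25 cm, past the 20 cm profile
    depth, resolving the build-up region).
    """
    dims = (41, 41, 100)
    vx, vz = 1.25, 0.25
    origin = (-dims[0] * vx / 2.0, -dims[1] * vx / 2.0, STUDY_SSD)
    return DoseGrid.empty(origin, (vx, vx, vz), dims, ssd=STUDY_SSD)


def simulate_field(model: BeamModel, field_label: str, phantom: DoseGrid,
                   n_particles: int, rng_seed, *,
                   profile_depths=STUDY_PROFILE_DEPTHS, tally: bool = True,
                   n_batches: int = 10, chunk: int = 40000) -> TransportResult:
    """Open-field dose (and optionally matrix A) for one field size."""
    wx, wy = parse_field(field_label)
    jaw = Jaw(wx / 2.0, wy / 2.0)
    geom = CommissioningGeometry(field_label, (wx, wy), STUDY_SSD,
                                 tuple(profile_depths))
    batch = sample_source_particles(model, n_particles, jaw,
                                    rng_seed=rng_seed)
    batch, _ = collimate(batch, Collimator(jaw, sad=model.sad,
                                           source_z=model.source_z))
    lut = row_meta = None
    if tally:
        lut, row_meta = select_commissioning_voxels(phantom, geom)
    col_meta = [(s.ring_index, s.energy_bin_index, int(s.particle_class))
                for s in model.subsources]
    return transport_and_tally(
        batch, phantom, lut=lut, n_batches=n_batches,
        n_subsources=model.n_subsources, row_meta=row_meta,
        col_meta=col_meta, n_histories=n_particles, chunk=chunk)


def build_study_matrix(model: BeamModel, phantom: DoseGrid,
                       fields=STUDY_FIELDS, n_particles_per_field=150_000,
                       rng_seed: int = 0,
                       profile_depths=STUDY_PROFILE_DEPTHS,
                       chunk: int = 40000) -> SubsourceDoseMatrix:
    """Stacked sub-source dose matrix over the commissioning fields."""
    ss = np.random.SeedSequence(rng_seed)
    mats = []
    for f, child in zip(fields, ss.spawn(len(fields))):
        res = simulate_field(model, f, phantom, n_particles_per_field,
                             np.random.default_rng(child),
                             profile_depths=profile_depths, chunk=chunk)
        mats.append(res.matrix)
    return SubsourceDoseMatrix.stack(mats)


def draw_ground_truth_factors(model: BeamModel, mode: str = "random",
                              rng_seed: int = 0):
    """Ground-truth (x_photon, x_electron) commissioning factors.

    ``random``: log-normal around 1 (sigma 0.2, clipped to [0.5, 2]) per
    photon sub-source and per electron energy-bin group; ``ones``: the
    identity commissioning.
    """
    n_p = model.n_photon_subsources
    n_e = model.n_energy_bins
    if mode == "ones":
        return np.ones(n_p), np.ones(n_e)
    rng = np.random.default_rng(rng_seed)
    xp = np.clip(rng.lognormal(0.0, 0.2, n_p), 0.5, 2.0)
    xe = np.clip(rng.lognormal(0.0, 0.2, n_e), 0.5, 2.0)
    return xp, xe


def _x_full(model: BeamModel, x_photon, x_electron) -> np.ndarray:
    """Per-column factor vector in matrix-A column order."""
    x = np.empty(model.n_subsources)
    x[model.photon_indices()] = x_photon
    for e in range(model.n_energy_bins):
        for r in range(model.n_rings):
            x[model.subsource_index(r, e, ParticleClass.ELECTRON)] = \
                x_electron[e]
    return x


def make_synthetic_measurements(A: SubsourceDoseMatrix, x_true: np.ndarray,
                                noise_sigma: float = 0.0,
                                rng_seed: int = 0) -> MeasurementSet:
    """Measured-style curves b = A x_true + noise, reshaped per row_meta.

    ``noise_sigma`` is in percent of each field's dmax (depth-curve
    maximum) dose; noise is i.i.d. Gaussian, homoscedastic in absolute
    dose.  Profile curves include the central-axis point taken from the
    depth-curve row at the same depth, so every curve is complete.
    """
    x_true = np.asarray(x_true, dtype=float)
    if x_true.shape != (A.n_cols,):
        raise ValueError("x_true length does not match A columns")
    b = A.values @ x_true
    rng = np.random.default_rng(rng_seed)

    rows_by_field: dict[str, list[int]] = {}
    for i, r in enumerate(A.row_meta):
        rows_by_field.setdefault(r.field, []).append(i)

    if noise_sigma > 0:
        noisy = b.copy()
        for f, rows in rows_by_field.items():
            depth_rows = [i for i in rows
                          if A.row_meta[i].curve_type == "depth"]
            dmax_dose = max(b[i] for i in depth_rows)
            sigma = noise_sigma / 100.0 * dmax_dose
            idx = np.asarray(rows)
            noisy[idx] = np.maximum(
                b[idx] + rng.normal(0.0, sigma, idx.size), 0.0)
        b = noisy

    curves: list[MeasurementCurve] = []
    for f, rows in rows_by_field.items():
        depth_rows = sorted(
            (i for i in rows if A.row_meta[i].curve_type == "depth"),
            key=lambda i: A.row_meta[i].depth)
        dpos = np.array([A.row_meta[i].depth for i in depth_rows])
        dval = np.array([b[i] for i in depth_rows])
        curves.append(MeasurementCurve(f, "depth", float("nan"), dpos, dval))
        prof: dict[tuple, list[int]] = {}
        for i in rows:
            r = A.row_meta[i]
            if r.curve_type != "depth":
                prof.setdefault((r.curve_type, r.depth), []).append(i)
        for (ctype, depth), idxs in sorted(prof.items()):
            idxs = sorted(idxs, key=lambda i: A.row_meta[i].offset)
            pos = [A.row_meta[i].offset for i in idxs]
            val = [b[i] for i in idxs]
            # insert the central-axis point from the depth curve
            j = int(np.argmin(np.abs(dpos - depth)))
            k = int(np.searchsorted(pos, 0.0))
            pos.insert(k, 0.0)
            val.insert(k, dval[j])
            curves.append(MeasurementCurve(f, ctype, depth,
                                           np.array(pos), np.array(val)))
    return MeasurementSet(curves)


def make_toy_vmat_arc(K: int, aperture_schedule: str = "sweeping_slit",
                      mu_schedule: str = "uniform", rng_seed: int = 0,
                      jaw: Jaw = Jaw(5.0, 5.0),
                      n_pairs: int = 10) -> list[PlanControlPoint]:
    """Toy single-arc VMAT plan.

    Gantry angles are evenly spaced over 360 (K-1)/K degrees; MU weights
    are normalized to 1.  ``sweeping_slit`` moves a narrow slit across the
    field (sparse fluence maps, as in clinical VMAT); ``oscillating``
    wobbles a variable-width aperture; ``open`` keeps the field fully
    open.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    rng = np.random.default_rng(rng_seed)
    angles = 360.0 * np.arange(K) / K
    if mu_schedule == "uniform":
        mu = np.full(K, 1.0 / K)
    elif mu_schedule == "peaked":
        mu = np.exp(-0.5 * ((np.arange(K) - K / 2.0) / (K / 6.0)) ** 2)
        mu /= mu.sum()
    else:
        raise ValueError(f"unknown mu_schedule {mu_schedule!r}")

    hx = jaw.half_x
    arc = []
    for k in range(K):
        if aperture_schedule == "open":
            leaves = np.tile([-hx - 1.0, hx + 1.0], (n_pairs, 1))
        elif aperture_schedule == "sweeping_slit":
            w = 1.0
            frac = k / max(K - 1, 1)
            center = -hx + w / 2.0 + frac * (2 * hx - w)
            leaves = np.tile([center - w / 2.0, center + w / 2.0],
                             (n_pairs, 1))
        elif aperture_schedule == "oscillating":
            w = 1.0 + 0.5 * np.sin(2.0 * np.pi * k / K)
            center = (hx - 1.0) * np.sin(2.0 * np.pi * 3.0 * k / K)
            base = np.array([center - w, center + w])
            jitter = rng.normal(0.0, 0.2, (n_pairs, 2))
            leaves = np.sort(base[None, :] + jitter, axis=1)
            leaves = np.clip(leaves, -hx, hx)
        else:
            raise ValueError(
                f"unknown aperture_schedule {aperture_schedule!r}")
        arc.append(PlanControlPoint(k, float(angles[k]), float(mu[k]),
                                    jaw, leaves))
    return arc


@dataclass
class StudyData:
    """One fully generated synthetic study."""

    spec: SyntheticStudySpec
    model: BeamModel
    phantom: DoseGrid
    A: SubsourceDoseMatrix
    x_true: np.ndarray
    x_true_photon: np.ndarray
    x_true_electron: np.ndarray
    measurements: MeasurementSet
    arc: list[PlanControlPoint]


def run_study(spec: SyntheticStudySpec | None = None,
              chunk: int = 40000) -> StudyData:
    """Generate the whole study deterministically from its spec."""
    spec = spec or SyntheticStudySpec()
    root = np.random.SeedSequence(spec.rng_seed)
    s_matrix, s_truth, s_noise, s_arc = root.spawn(4)
    model = build_toy_beam_model(spec.n_rings, spec.n_energy_bins,
                                 spec.spectrum)
    phantom = make_study_phantom()
    A = build_study_matrix(model, phantom, fields=spec.fields,
                           n_particles_per_field=spec.n_particles_per_field,
                           rng_seed=int(s_matrix.generate_state(1)[0]) % (2 ** 31),
                           profile_depths=spec.profile_depths, chunk=chunk)
    xp, xe = draw_ground_truth_factors(model, spec.x_true_mode,
                                       int(s_truth.generate_state(1)[0]) % (2 ** 31))
    x_true = _x_full(model, xp, xe)
    meas = make_synthetic_measurements(A, x_true, spec.noise_sigma,
                                       int(s_noise.generate_state(1)[0]) % (2 ** 31))
    arc = make_toy_vmat_arc(spec.plan_control_points,
                            spec.aperture_schedule, spec.mu_schedule,
                            int(s_arc.generate_state(1)[0]) % (2 ** 31))
    return StudyData(spec, model, phantom, A, x_true, xp, xe, meas, arc)
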