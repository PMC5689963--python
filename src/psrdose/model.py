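"""Field-independent phase-space-ring (PSR) beam model.

The linac beam is described on a plane just above the secondary collimator.
That plane is partitioned into concentric rings; within each ring the
particle population is further split by energy bin and by particle class
(primary photon, scattered photon, contaminant electron).  Each (ring,
energy bin, class) cell is a *sub-source* holding a relative intensity
(particles per history) and an angular width (polar spread of directions
about the ray from the focal spot through the sampled position).

The analytical functional forms fitted from vendor phase-space files are
not reproduced here; a documented toy parameterization (:class:`ToySpectrum`)
stands in for them while preserving the model structure that the
commissioning and sampling algorithms rely on: one intensity and one
angular width per sub-source, with scattered photons wider than primaries
and a softer, broader contaminant-electron population.

Geometry: right-handed, z along the beam axis from the focal spot (z = 0)
toward the isocenter at z = ``sad`` (default 100 cm).  The phase-space
plane sits at z = ``plane_z`` (default 26 cm).  All lengths in cm, energies
in MeV, angles in radians.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from enum import IntEnum
from pathlib import Path

import numpy as np
from scipy import stats

__all__ = [
    "ParticleClass",
    "PSRSubSource",
    "BeamModel",
    "SourceParticle",
    "ParticleBatch",
    "ToySpectrum",
    "Jaw",
    "EmptyFieldError",
    "build_toy_beam_model",
    "sample_source_particles",
    "group_electron_effective_psrs",
]


class ParticleClass(IntEnum):
    """The three interaction-history / particle-type classes of the model."""

    PRIMARY_PHOTON = 0
    SCATTERED_PHOTON = 1
    ELECTRON = 2


N_CLASSES = 3
PHOTON_CLASSES = (ParticleClass.PRIMARY_PHOTON, ParticleClass.SCATTERED_PHOTON)


class EmptyFieldError(ValueError):
    """Raised when a jaw opening overlaps no ring of the beam model."""


@dataclass(frozen=True)
class PSRSubSource:
    """One phase-space-ring sub-source (ring x energy bin x class cell)."""

    ring_index: int
    energy_bin_index: int
    particle_class: ParticleClass
    r_inner: float
    r_outer: float
    e_low: float
    e_high: float
    relative_intensity: float
    angular_width: float

    def __post_init__(self):
        if not self.r_inner < self.r_outer:
            raise ValueError("r_inner must be < r_outer")
        if not self.e_low < self.e_high:
            raise ValueError("e_low must be < e_high")
        if self.relative_intensity < 0:
            raise ValueError("relative_intensity must be >= 0")
        if self.angular_width < 0:
            raise ValueError("angular_width must be >= 0")


@dataclass(frozen=True)
class ToySpectrum:
    """Parameters of the stand-in spectrum / fluence parameterization.

    r_max
        Outer radius of the outermost ring on the phase-space plane (cm).
    e_min, e_max
        Energy range spanned by the energy bins (MeV).
    electron_fraction
        Fraction of the total relative intensity carried by contaminant
        electrons (the beam is ~1% electrons).
    primary_fraction
        Fraction of the *photon* intensity in the primary class.
    radial_scale
        Exponential fall-off length (cm) of the radial fluence per class.
    mean_energy
        Mean energy (MeV) of the gamma-shaped spectrum per class, on axis.
    softening
        Fractional reduction of the mean energy from axis to r_max
        (off-axis softening).
    angular_width_0 / angular_width_slope
        Polar spread at r = 0 and its linear growth to r_max (radians);
        primaries are narrow and flat, scattered photons widen with radius.
    """

    r_max: float = 8.0
    e_min: float = 0.25
    e_max: float = 6.0
    electron_fraction: float = 0.01
    primary_fraction: float = 0.8
    radial_scale: tuple[float, float, float] = (6.0, 12.0, 9.0)
    mean_energy: tuple[float, float, float] = (2.0, 1.2, 1.0)
    spectrum_shape: float = 2.0
    softening: float = 0.3
    angular_width_0: tuple[float, float, float] = (0.010, 0.030, 0.120)
    angular_width_slope: tuple[float, float, float] = (0.0, 0.050, 0.050)

    def validate(self) -> None:
        if self.r_max <= 0 or self.e_min < 0 or self.e_max <= self.e_min:
            raise ValueError("invalid geometry/energy span")
        if not 0.0 <= self.electron_fraction < 1.0:
            raise ValueError("electron_fraction must be in [0, 1)")
        if not 0.0 < self.primary_fraction <= 1.0:
            raise ValueError("primary_fraction must be in (0, 1]")
        for name in ("radial_scale", "mean_energy", "angular_width_0",
                     "angular_width_slope"):
            if any(v < 0 for v in getattr(self, name)):
                raise ValueError(f"negative value in {name}")
        if self.spectrum_shape <= 0:
            raise ValueError("spectrum_shape must be > 0")


@dataclass
class BeamModel:
    """Ordered collection of PSR sub-sources plus the beam geometry.

    Sub-sources are stored in canonical order -- class-major, then energy
    bin, then ring -- which is also the column order of the sub-source
    dose matrix used in commissioning:
    ``index = class * (n_energy_bins * n_rings) + energy_bin * n_rings + ring``.
    """

    n_rings: int
    n_energy_bins: int
    plane_z: float
    source_z: float
    subsources: list[PSRSubSource]
    sad: float = 100.0
    spectrum: ToySpectrum | None = None
    _arrays: dict | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        expected = self.n_rings * self.n_energy_bins * N_CLASSES
        if len(self.subsources) != expected:
            raise ValueError(
                f"expected {expected} sub-sources, got {len(self.subsources)}")
        for i, s in enumerate(self.subsources):
            if i != self.subsource_index(s.ring_index, s.energy_bin_index,
                                         s.particle_class):
                raise ValueError("sub-sources not in canonical order")

    @property
    def n_subsources(self) -> int:
        return len(self.subsources)

    def subsource_index(self, ring: int, ebin: int,
                        pclass: ParticleClass) -> int:
        return (int(pclass) * self.n_energy_bins * self.n_rings
                + ebin * self.n_rings + ring)

    @property
    def n_photon_subsources(self) -> int:
        return 2 * self.n_energy_bins * self.n_rings

    def photon_indices(self) -> np.ndarray:
        return np.arange(self.n_photon_subsources)

    def electron_indices(self) -> np.ndarray:
        return np.arange(self.n_photon_subsources, self.n_subsources)

    def arrays(self) -> dict:
        """Vectorized view of the sub-source attributes (cached)."""
        if self._arrays is None:
            ss = self.subsources
            self._arrays = {
                "intensity": np.array([s.relative_intensity for s in ss]),
                "r_inner": np.array([s.r_inner for s in ss]),
                "r_outer": np.array([s.r_outer for s in ss]),
                "e_low": np.array([s.e_low for s in ss]),
                "e_high": np.array([s.e_high for s in ss]),
                "angular_width": np.array([s.angular_width for s in ss]),
                "pclass": np.array([int(s.particle_class) for s in ss],
                                   dtype=np.int8),
            }
        return self._arrays

    def with_intensities(self, intensity: np.ndarray) -> "BeamModel":
        """Copy of the model with per-sub-source intensities replaced."""
        intensity = np.asarray(intensity, dtype=float)
        if intensity.shape != (self.n_subsources,):
            raise ValueError("intensity length mismatch")
        if np.any(intensity < 0):
            raise ValueError("intensities must be >= 0")
        subs = [
            PSRSubSource(s.ring_index, s.energy_bin_index, s.particle_class,
                         s.r_inner, s.r_outer, s.e_low, s.e_high,
                         float(intensity[i]), s.angular_width)
            for i, s in enumerate(self.subsources)
        ]
        return BeamModel(self.n_rings, self.n_energy_bins, self.plane_z,
                         self.source_z, subs, sad=self.sad,
                         spectrum=self.spectrum)

    # -- JSON serialization (exact round-trip) -----------------------------

    def to_json(self, path: str | Path) -> None:
        header = {
            "n_rings": self.n_rings,
            "n_energy_bins": self.n_energy_bins,
            "plane_z": self.plane_z,
            "source_z": self.source_z,
            "sad": self.sad,
        }
        if self.spectrum is not None:
            header["spectrum"] = asdict(self.spectrum)
        records = [
            {
                "ring_index": s.ring_index,
                "energy_bin_index": s.energy_bin_index,
                "particle_class": int(s.particle_class),
                "r_inner": s.r_inner,
                "r_outer": s.r_outer,
                "e_low": s.e_low,
                "e_high": s.e_high,
                "relative_intensity": s.relative_intensity,
                "angular_width": s.angular_width,
            }
            for s in self.subsources
        ]
        Path(path).write_text(
            json.dumps({"header": header, "subsources": records}, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "BeamModel":
        doc = json.loads(Path(path).read_text())
        h = doc["header"]
        spec = h.get("spectrum")
        if spec is not None:
            for key in ("radial_scale", "mean_energy", "angular_width_0",
                        "angular_width_slope"):
                spec[key] = tuple(spec[key])
            spec = ToySpectrum(**spec)
        subs = [
            PSRSubSource(r["ring_index"], r["energy_bin_index"],
                         ParticleClass(r["particle_class"]), r["r_inner"],
                         r["r_outer"], r["e_low"], r["e_high"],
                         r["relative_intensity"], r["angular_width"])
            for r in doc["subsources"]
        ]
        return cls(h["n_rings"], h["n_energy_bins"], h["plane_z"],
                   h["source_z"], subs, sad=h["sad"], spectrum=spec)


@dataclass(frozen=True)
class SourceParticle:
    """Single source particle (scalar view; bulk work uses ParticleBatch)."""

    particle_class: ParticleClass
    energy: float
    position: tuple[float, float]
    direction: tuple[float, float, float]
    weight: float
    subsource_index: int
    control_point_index: int = -1


class ParticleBatch:
    """Struct-of-arrays container for source particles.

    Positions ``(x, y)`` are on the phase-space plane at ``plane_z`` unless
    the batch has been rotated to a beam geometry, in which case ``pos3``
    holds full 3-vectors in phantom (fixed) coordinates.
    """

    def __init__(self, pclass, energy, x, y, direction, weight, subsource,
                 plane_z, cp_index=None, pos3=None):
        n = len(energy)
        self.pclass = np.asarray(pclass, dtype=np.int8)
        self.energy = np.asarray(energy, dtype=float)
        self.x = np.asarray(x, dtype=float)
        self.y = np.asarray(y, dtype=float)
        self.direction = np.asarray(direction, dtype=float).reshape(n, 3)
        self.weight = np.asarray(weight, dtype=float)
        self.subsource = np.asarray(subsource, dtype=np.int32)
        self.plane_z = float(plane_z)
        self.cp_index = (np.full(n, -1, dtype=np.int32) if cp_index is None
                         else np.asarray(cp_index, dtype=np.int32))
        self.pos3 = None if pos3 is None else np.asarray(pos3, float).reshape(n, 3)

    def __len__(self) -> int:
        return len(self.energy)

    def positions3(self) -> np.ndarray:
        """Full 3-vector start positions in phantom coordinates."""
        if self.pos3 is not None:
            return self.pos3
        return np.column_stack(
            [self.x, self.y, np.full(len(self), self.plane_z)])

    def select(self, mask) -> "ParticleBatch":
        return ParticleBatch(
            self.pclass[mask], self.energy[mask], self.x[mask], self.y[mask],
            self.direction[mask], self.weight[mask], self.subsource[mask],
            self.plane_z, cp_index=self.cp_index[mask],
            pos3=None if self.pos3 is None else self.pos3[mask])

    def copy(self) -> "ParticleBatch":
        return self.select(slice(None))

    def __getitem__(self, i: int) -> SourceParticle:
        return SourceParticle(
            ParticleClass(int(self.pclass[i])), float(self.energy[i]),
            (float(self.x[i]), float(self.y[i])),
            tuple(float(v) for v in self.direction[i]),
            float(self.weight[i]), int(self.subsource[i]),
            int(self.cp_index[i]))

    @staticmethod
    def concatenate(batches: list["ParticleBatch"]) -> "ParticleBatch":
        if not batches:
            raise ValueError("no batches to concatenate")
        pz = batches[0].plane_z
        has3 = batches[0].pos3 is not None
        return ParticleBatch(
            np.concatenate([b.pclass for b in batches]),
            np.concatenate([b.energy for b in batches]),
            np.concatenate([b.x for b in batches]),
            np.concatenate([b.y for b in batches]),
            np.concatenate([b.direction for b in batches]),
            np.concatenate([b.weight for b in batches]),
            np.concatenate([b.subsource for b in batches]),
            pz,
            cp_index=np.concatenate([b.cp_index for b in batches]),
            pos3=(np.concatenate([b.pos3 for b in batches]) if has3 else None))


@dataclass(frozen=True)
class Jaw:
    """Rectangular jaw opening, half-widths in cm at the isocenter plane."""

    half_x: float
    half_y: float

    def __post_init__(self):
        if self.half_x <= 0 or self.half_y <= 0:
            raise ValueError("jaw half-widths must be > 0")

    @classmethod
    def square(cls, side_cm: float) -> "Jaw":
        return cls(side_cm / 2.0, side_cm / 2.0)


def build_toy_beam_model(n_rings: int, n_energy_bins: int,
                         spec: ToySpectrum | None = None,
                         plane_z: float = 26.0, source_z: float = 0.0,
                         sad: float = 100.0) -> BeamModel:
    """Build the stand-in PSR beam model.

    Rings are equal-width annuli spanning [0, spec.r_max]; energy bins are
    equal-width over [spec.e_min, spec.e_max].  Per class, intensity factors
    as (ring area x exponential radial fall-off) x (gamma-shaped spectrum
    whose mean softens off axis).  Total intensity is normalized to 1 and
    the electron class carries exactly ``spec.electron_fraction`` of it.
    """
    if n_rings < 1 or n_energy_bins < 1:
        raise ValueError("n_rings and n_energy_bins must be >= 1")
    spec = spec or ToySpectrum()
    spec.validate()

    r_edges = np.linspace(0.0, spec.r_max, n_rings + 1)
    e_edges = np.linspace(spec.e_min, spec.e_max, n_energy_bins + 1)
    r_mid = 0.5 * (r_edges[:-1] + r_edges[1:])
    e_mid = 0.5 * (e_edges[:-1] + e_edges[1:])
    ring_area = np.pi * (r_edges[1:] ** 2 - r_edges[:-1] ** 2)

    class_mass = np.array([
        (1.0 - spec.electron_fraction) * spec.primary_fraction,
        (1.0 - spec.electron_fraction) * (1.0 - spec.primary_fraction),
        spec.electron_fraction,
    ])

    subsources: list[PSRSubSource] = []
    intensities = np.empty(N_CLASSES * n_energy_bins * n_rings)
    for c in ParticleClass:
        radial = ring_area * np.exp(-r_mid / spec.radial_scale[c])
        radial /= radial.sum()
        k = spec.spectrum_shape
        # per-ring spectrum: gamma pdf sampled at bin centers, softening mean
        mean_e = spec.mean_energy[c] * (
            1.0 - spec.softening * r_mid / spec.r_max)
        spectral = stats.gamma.pdf(
            e_mid[None, :], a=k, scale=(mean_e / k)[:, None])  # (ring, ebin)
        norm = spectral.sum(axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        spectral = spectral / norm
        width = (spec.angular_width_0[c]
                 + spec.angular_width_slope[c] * r_mid / spec.r_max)
        for e in range(n_energy_bins):
            for r in range(n_rings):
                idx = (int(c) * n_energy_bins * n_rings + e * n_rings + r)
                intensities[idx] = class_mass[c] * radial[r] * spectral[r, e]
                subsources.append(PSRSubSource(
                    r, e, c, float(r_edges[r]), float(r_edges[r + 1]),
                    float(e_edges[e]), float(e_edges[e + 1]), 0.0,
                    float(width[r])))

    intensities /= intensities.sum()
    subsources = [
        PSRSubSource(s.ring_index, s.energy_bin_index, s.particle_class,
                     s.r_inner, s.r_outer, s.e_low, s.e_high,
                     float(intensities[i]), s.angular_width)
        for i, s in enumerate(subsources)
    ]
    return BeamModel(n_rings, n_energy_bins, plane_z, source_z, subsources,
                     sad=sad, spectrum=spec)


def _restricted_subsources(model: BeamModel, jaw: Jaw,
                           margin: float) -> np.ndarray:
    """Indices of sub-sources whose ring overlaps the expanded jaw shadow."""
    scale = (model.plane_z - model.source_z) / (model.sad - model.source_z)
    hx = jaw.half_x * scale + margin
    hy = jaw.half_y * scale + margin
    half_diag = np.hypot(hx, hy)
    arr = model.arrays()
    return np.flatnonzero(arr["r_inner"] <= half_diag)


def sample_source_particles(model: BeamModel, n: int, jaw: Jaw,
                            margin: float = 0.5,
                            rng_seed=None) -> ParticleBatch:
    """Sample ``n`` source particles restricted to the jaw neighbourhood.

    Sub-sources are drawn proportional to relative intensity among those
    whose ring overlaps the jaw projection on the phase-space plane
    expanded by ``margin`` (cm at the plane).  Each particle carries the
    acceptance weight q = restricted/total intensity mass so that
    (1/n) * sum(w * dose) is an unbiased per-full-history estimate.
    Positions are area-uniform within the ring annulus; directions are the
    focal ray perturbed transversally by a Gaussian of scale equal to the
    sub-source angular width; energies are uniform within the bin.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    arr = model.arrays()
    accepted = _restricted_subsources(model, jaw, margin)
    if accepted.size == 0:
        raise EmptyFieldError("jaw projection intersects no ring")
    p = arr["intensity"][accepted]
    mass = p.sum()
    total = arr["intensity"].sum()
    if mass <= 0:
        raise EmptyFieldError("restricted sub-sources carry zero intensity")
    q = mass / total

    draw = rng.choice(accepted.size, size=n, p=p / mass)
    idx = accepted[draw]

    ri = arr["r_inner"][idx]
    ro = arr["r_outer"][idx]
    u = rng.random(n)
    radius = np.sqrt(ri ** 2 + u * (ro ** 2 - ri ** 2))
    phi = rng.random(n) * 2.0 * np.pi
    x = radius * np.cos(phi)
    y = radius * np.sin(phi)

    energy = arr["e_low"][idx] + rng.random(n) * (
        arr["e_high"][idx] - arr["e_low"][idx])

    # focal ray through (x, y, plane_z), then transverse Gaussian kick
    dz = model.plane_z - model.source_z
    d0 = np.column_stack([x, y, np.full(n, dz)])
    d0 /= np.linalg.norm(d0, axis=1, keepdims=True)
    sigma = arr["angular_width"][idx]
    if np.any(sigma > 0):
        ref = np.zeros((n, 3))
        use_y = np.abs(d0[:, 0]) > 0.9
        ref[use_y, 1] = 1.0
        ref[~use_y, 0] = 1.0
        e1 = np.cross(d0, ref)
        e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
        e2 = np.cross(d0, e1)
        g1 = rng.standard_normal(n) * sigma
        g2 = rng.standard_normal(n) * sigma
        d = d0 + g1[:, None] * e1 + g2[:, None] * e2
        d /= np.linalg.norm(d, axis=1, keepdims=True)
    else:
        d = d0

    weight = np.full(n, q)
    return ParticleBatch(arr["pclass"][idx], energy, x, y, d, weight, idx,
                         model.plane_z)


def group_electron_effective_psrs(model: BeamModel) -> dict[int, list[int]]:
    """Group electron sub-sources by energy bin into "effective" PSRs.

    Electron sub-sources within the same energy bin share one commissioning
    correction factor; the grouping averages out the large statistical
    noise of the sparse contaminant-electron population.
    """
    groups: dict[int, list[int]] = {}
    for e in range(model.n_energy_bins):
        groups[e] = [
            model.subsource_index(r, e, ParticleClass.ELECTRON)
            for r in range(model.n_rings)
        ]
    return groups
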