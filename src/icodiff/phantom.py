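"""Synthetic icosahedral procapsid phantoms with known ground truth.

The generator emulates the architecture of a cystovirus procapsid map:

* a spherical shell with Gaussian radial cross-section (the 120-copy P1
  lattice), with recess dimples at the 12 five-fold vertices (the
  unexpanded, dodecahedral state);
* P4 blobs at the five-fold directions on the outer surface (the packaging
  NTPase);
* P2 blobs at the three-fold directions inside the shell (the
  polymerase), with three P7 blobs bracketing each P2 around its axis;
* an optional diffuse central Gaussian (disordered internal protein);
* additive white Gaussian noise.

Substoichiometric occupancy is rendered as amplitude scaling — exactly
what icosahedral averaging does to a partially occupied site — so every
blob's effective amplitude is ``amplitude * occupancy``.  All protein
positions are built as orbits of a single seed point under the 60
rotations, which makes the noiseless phantom exactly icosahedrally
symmetric by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .density_map import Map3D
from .symmetry import axis_directions, build_icosahedral_group

__all__ = [
    "BlobSpec",
    "PhantomSpec",
    "GroundTruth",
    "generate_procapsid",
    "generate_mutant_triple",
    "generate_half_maps",
    "add_gaussian_blobs",
    "shell_volume_fwhm",
]


@dataclass(frozen=True)
class BlobSpec:
    """One protein species rendered as Gaussian blobs.

    sigma and radius are in Å; amplitude is in the same arbitrary density
    units as the shell; occupancy in [0, 1] scales the amplitude.
    """

    sigma: float
    radius: float
    amplitude: float
    occupancy: float = 1.0

    def __post_init__(self):
        if self.sigma <= 0 or self.radius < 0:
            raise ValueError("blob sigma must be positive and radius non-negative")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError("occupancy must lie in [0, 1]")

    @property
    def effective_amplitude(self) -> float:
        return self.amplitude * self.occupancy


def _default_p2():
    # the polymerase is a compact globular blob; its full-occupancy peak
    # density is set to twice the shell crest (the shell spreads its mass
    # over a thin layer, a blob concentrates it), so the half-occupied
    # site still clears the 2-sigma difference contour
    return BlobSpec(sigma=8.0, radius=76.0, amplitude=2.0, occupancy=0.5)


def _default_p4():
    return BlobSpec(sigma=8.0, radius=112.0, amplitude=1.0, occupancy=1.0)


def _default_p7():
    # P7 brackets P2 close to its axis; amplitude chosen so the fully
    # occupied cofactor would match the shell crest (its monomer is
    # compact and shell-attached), making the substoichiometric site
    # visible at the standard 2-sigma difference contour.
    return BlobSpec(sigma=8.0, radius=80.0, amplitude=1.6, occupancy=0.57)


@dataclass(frozen=True)
class PhantomSpec:
    """Everything needed to generate one procapsid phantom, reproducibly.

    The defaults describe a 96^3 grid at 2.9 Å/voxel holding a shell of
    radius 100 Å — the real particle scaled down to a box that renders in
    seconds.  Default occupancies are the substoichiometric values typical
    of the complete particle (P2 ~0.5, P7 ~0.57, P4 full).
    """

    box_size: int = 96
    voxel_size: float = 2.9  # Å
    shell_radius: float = 100.0  # Å
    shell_thickness: float = 10.0  # Gaussian sigma of the radial cross-section, Å
    shell_amplitude: float = 1.0
    vertex_recess_depth: float = 0.5  # fraction of shell amplitude
    p2: BlobSpec = field(default_factory=_default_p2)
    p4: BlobSpec = field(default_factory=_default_p4)
    p7: BlobSpec = field(default_factory=_default_p7)
    p7_tilt_deg: float = 13.0  # angular offset of each P7 from its three-fold axis
    central_diffuse_amplitude: float = 0.3
    central_diffuse_sigma: float = 30.0  # Å
    noise_sigma: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.box_size < 8 or self.voxel_size <= 0:
            raise ValueError("box_size must be >= 8 and voxel_size positive")
        if self.shell_radius <= 0 or self.shell_thickness <= 0:
            raise ValueError("shell radius and thickness must be positive")
        if not 0.0 <= self.vertex_recess_depth <= 1.0:
            raise ValueError("vertex_recess_depth must lie in [0, 1]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        half = self.box_size * self.voxel_size / 2.0
        if self.shell_radius + 3 * self.shell_thickness >= half:
            raise ValueError("shell clips the box edge")
        for name, blob in (("p2", self.p2), ("p4", self.p4), ("p7", self.p7)):
            if blob.radius + 3 * blob.sigma >= half:
                raise ValueError(f"{name} blobs clip the box edge")

    @property
    def half_extent(self) -> float:
        return self.box_size * self.voxel_size / 2.0


@dataclass
class GroundTruth:
    """Per-protein site geometry and true signal levels of a phantom."""

    sites: dict[str, dict]  # protein -> {axis_order, directions, positions,
    #                                     occupancy, amplitude, sigma}

    def positions(self, protein: str) -> np.ndarray:
        return self.sites[protein]["positions"]

    def directions(self, protein: str) -> np.ndarray:
        return self.sites[protein]["directions"]

    def to_jsonable(self) -> dict:
        out = {}
        for name, s in self.sites.items():
            out[name] = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                         for k, v in s.items()}
        return out


def add_gaussian_blobs(data: np.ndarray, centers: np.ndarray, amplitude: float,
                       sigma: float, voxel_size: float) -> None:
    """Add isotropic Gaussian blobs in place.

    ``centers`` are Cartesian Å coordinates relative to the grid center;
    each blob is evaluated on a local +/-4 sigma patch for speed.
    """
    if amplitude == 0.0 or len(centers) == 0:
        return
    n = data.shape[0]
    c0 = n // 2
    reach = int(np.ceil(4.0 * sigma / voxel_size))
    ax = np.arange(n)
    for ctr in np.atleast_2d(centers):
        idx_c = ctr / voxel_size + c0
        lo = np.maximum(np.floor(idx_c).astype(int) - reach, 0)
        hi = np.minimum(np.floor(idx_c).astype(int) + reach + 2, n)
        if np.any(lo >= hi):
            continue
        xs = (ax[lo[0]:hi[0]] - c0) * voxel_size - ctr[0]
        ys = (ax[lo[1]:hi[1]] - c0) * voxel_size - ctr[1]
        zs = (ax[lo[2]:hi[2]] - c0) * voxel_size - ctr[2]
        d2 = (xs[:, None, None] ** 2 + ys[None, :, None] ** 2
              + zs[None, None, :] ** 2)
        data[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] += (
            amplitude * np.exp(-d2 / (2.0 * sigma ** 2)))


def _orbit(point: np.ndarray, group) -> np.ndarray:
    """Distinct images of a point under the rotation group (tolerance 1e-6 Å)."""
    pts: list[np.ndarray] = []
    for op in group:
        q = op.matrix @ point
        if not any(np.allclose(q, p, atol=1e-6) for p in pts):
            pts.append(q)
    return np.array(pts)


def _p7_positions(spec: PhantomSpec, three_fold_dirs: np.ndarray,
                  group) -> np.ndarray:
    """Orbit of one tilted seed point: three P7 per three-fold direction."""
    d0 = three_fold_dirs[0]
    # perpendicular reference for the tilt
    helper = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(helper, d0)) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(d0, helper)
    e1 /= np.linalg.norm(e1)
    alpha = np.radians(spec.p7_tilt_deg)
    seed_dir = np.cos(alpha) * d0 + np.sin(alpha) * e1
    return _orbit(spec.p7.radius * seed_dir, group)


def _build_components(spec: PhantomSpec, group=None):
    """Noiseless additive components of the phantom, as raw arrays."""
    if group is None:
        group = build_icosahedral_group()
    five = axis_directions(5, group).directions
    three = axis_directions(3, group).directions
    n = spec.box_size
    c0 = n // 2
    ax = (np.arange(n) - c0) * spec.voxel_size
    x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
    r = np.sqrt(x * x + y * y + z * z)

    shell = spec.shell_amplitude * np.exp(
        -((r - spec.shell_radius) ** 2) / (2.0 * spec.shell_thickness ** 2))
    if spec.vertex_recess_depth > 0:
        add_gaussian_blobs(shell, spec.shell_radius * five,
                           -spec.vertex_recess_depth * spec.shell_amplitude,
                           spec.shell_thickness, spec.voxel_size)

    def unit_blob_map(centers, sigma):
        m = np.zeros_like(shell)
        add_gaussian_blobs(m, centers, 1.0, sigma, spec.voxel_size)
        return m

    p4_pos = spec.p4.radius * five
    p2_pos = spec.p2.radius * three
    p7_pos = _p7_positions(spec, three, group)

    components = {
        "shell": shell,
        "p2": unit_blob_map(p2_pos, spec.p2.sigma),
        "p4": unit_blob_map(p4_pos, spec.p4.sigma),
        "p7": unit_blob_map(p7_pos, spec.p7.sigma),
        "central": np.exp(-(r ** 2) / (2.0 * spec.central_diffuse_sigma ** 2)),
    }
    def entry(blob: BlobSpec, order, dirs, pos):
        return {
            "axis_order": order, "directions": dirs, "positions": pos,
            "occupancy": blob.occupancy,
            "amplitude": blob.effective_amplitude, "sigma": blob.sigma,
            # what a density-anchored estimator should read back: the
            # site's effective amplitude relative to the shell crest
            "density_occupancy": (blob.effective_amplitude / spec.shell_amplitude
                                  if spec.shell_amplitude > 0 else float("nan")),
        }

    truth = GroundTruth(sites={
        "p2": entry(spec.p2, 3, three, p2_pos),
        "p4": entry(spec.p4, 5, five, p4_pos),
        "p7": entry(spec.p7, 3, three, p7_pos),
    })
    return components, truth


def _noise(shape, sigma: float, seed_seq: np.random.SeedSequence) -> np.ndarray:
    if sigma == 0:
        return np.zeros(shape)
    rng = np.random.default_rng(seed_seq)
    return rng.normal(0.0, sigma, size=shape)


def generate_procapsid(spec: PhantomSpec) -> tuple[Map3D, GroundTruth]:
    """One complete phantom: shell + all proteins + central density + noise.

    Deterministic for a fixed spec (same seed gives bit-identical maps);
    exactly icosahedrally symmetric before noise.
    """
    comp, truth = _build_components(spec)
    data = (comp["shell"]
            + spec.p2.effective_amplitude * comp["p2"]
            + spec.p4.effective_amplitude * comp["p4"]
            + spec.p7.effective_amplitude * comp["p7"]
            + spec.central_diffuse_amplitude * comp["central"])
    data += _noise(data.shape, spec.noise_sigma,
                   np.random.SeedSequence(spec.seed))
    return Map3D(data, spec.voxel_size), truth


def generate_mutant_triple(spec: PhantomSpec, *, central_boost: float = 1.5,
                           p4_reduction: float = 0.5,
                           p7_reduction: float = 0.33,
                           central_reduction: float = 0.3,
                           ) -> tuple[dict[str, Map3D], GroundTruth]:
    """The complete / P7-minus / P2-minus phantom triple.

    * ``P1247`` — the complete particle.
    * ``P124`` — P7 deleted; the diffuse central density is boosted by
      ``central_boost`` (the unbracketed polymerase delocalizes toward the
      center).
    * ``P147`` — P2 deleted; P4 and P7 amplitudes are reduced by the given
      factors and the central density by ``central_reduction`` (the
      polymerase-free particle is less stable, holds less motor and
      cofactor, and loses its central density).

    Each map carries an independent noise realization derived from
    ``spec.seed``.
    """
    comp, truth = _build_components(spec)
    base = comp["shell"]
    p2 = spec.p2.effective_amplitude * comp["p2"]
    p4 = spec.p4.effective_amplitude * comp["p4"]
    p7 = spec.p7.effective_amplitude * comp["p7"]
    central = spec.central_diffuse_amplitude * comp["central"]

    seeds = np.random.SeedSequence(spec.seed).spawn(3)
    vs = spec.voxel_size
    maps = {
        "P1247": Map3D(base + p2 + p4 + p7 + central
                       + _noise(base.shape, spec.noise_sigma, seeds[0]), vs),
        "P124": Map3D(base + p2 + p4 + central_boost * central
                      + _noise(base.shape, spec.noise_sigma, seeds[1]), vs),
        "P147": Map3D(base + p4_reduction * p4 + p7_reduction * p7
                      + central_reduction * central
                      + _noise(base.shape, spec.noise_sigma, seeds[2]), vs),
    }
    return maps, truth


def generate_half_maps(spec: PhantomSpec) -> tuple[Map3D, Map3D]:
    """The same noiseless phantom plus two independent noise realizations."""
    comp, _ = _build_components(spec)
    signal = (comp["shell"]
              + spec.p2.effective_amplitude * comp["p2"]
              + spec.p4.effective_amplitude * comp["p4"]
              + spec.p7.effective_amplitude * comp["p7"]
              + spec.central_diffuse_amplitude * comp["central"])
    seeds = np.random.SeedSequence(spec.seed).spawn(2)
    a = Map3D(signal + _noise(signal.shape, spec.noise_sigma, seeds[0]),
              spec.voxel_size)
    b = Map3D(signal + _noise(signal.shape, spec.noise_sigma, seeds[1]),
              spec.voxel_size)
    return a, b


def shell_volume_fwhm(spec: PhantomSpec) -> float:
    """Analytic volume (nm^3) of the shell at half-maximum thickness.

    4 pi r^2 times the FWHM of the Gaussian cross-section — the natural
    volume budget for thresholding a phantom's shell, standing in for the
    mass-derived budget used with real reconstructions.
    """
    fwhm = 2.0 * np.sqrt(2.0 * np.log(2.0)) * spec.shell_thickness
    vol_a3 = 4.0 * np.pi * spec.shell_radius ** 2 * fwhm
    return vol_a3 / 1.0e3


def spec_to_jsonable(spec: PhantomSpec) -> dict:
    return asdict(spec)
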