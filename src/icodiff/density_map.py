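"""Cubic density volumes: MRC I/O, low-pass filtering, radial statistics.

Conventions
-----------
* Grids are cubic, N voxels per edge, with a physical voxel size in
  Angstrom.  Density units are arbitrary and only relative; every
  downstream statistic is covariant under affine density transforms.
* The grid center is the voxel at index (N//2, N//2, N//2) on each axis
  (even N supported); all radii are measured from that voxel's center.
* Files are MRC2014 mode 2 (32-bit float); writing casts to float32, so
  a write-then-read round trip is bit-exact for float32 data.
"""

from __future__ import annotations

from dataclasses import dataclass

import gemmi
import numpy as np

__all__ = [
    "Map3D",
    "Mask",
    "RadialProfile",
    "read_map",
    "write_map",
    "pixel_size_from_scan",
    "low_pass_filter",
    "radial_average",
]


@dataclass
class Map3D:
    """A cubic voxel grid of densities with a physical voxel size (Å)."""

    data: np.ndarray
    voxel_size: float

    def __post_init__(self):
        d = np.asarray(self.data, dtype=np.float64)
        if d.ndim != 3 or len(set(d.shape)) != 1:
            raise ValueError(f"map grid must be cubic, got shape {d.shape}")
        if not np.isfinite(d).all():
            raise ValueError("map contains non-finite densities")
        if not self.voxel_size > 0:
            raise ValueError("voxel_size must be positive")
        self.data = d
        self.voxel_size = float(self.voxel_size)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n(self) -> int:
        return self.data.shape[0]

    @property
    def center_index(self) -> np.ndarray:
        """Grid-center voxel index (N//2 per axis)."""
        return np.array([s // 2 for s in self.data.shape])

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in Å^3."""
        return self.voxel_size ** 3

    def radius_grid(self) -> np.ndarray:
        """Distance of each voxel center from the grid center, in Å."""
        n = self.n
        c = n // 2
        ax = (np.arange(n) - c) * self.voxel_size
        x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
        return np.sqrt(x * x + y * y + z * z)

    def coordinate_grids(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Cartesian voxel-center coordinates (Å) relative to the grid center."""
        n = self.n
        c = n // 2
        ax = (np.arange(n) - c) * self.voxel_size
        return np.meshgrid(ax, ax, ax, indexing="ij")

    def same_grid(self, other: "Map3D | Mask") -> bool:
        return (self.data.shape == other.data.shape
                and np.isclose(self.voxel_size, other.voxel_size, rtol=1e-6))

    def copy(self) -> "Map3D":
        return Map3D(self.data.copy(), self.voxel_size)


@dataclass
class Mask:
    """Boolean voxel selection on the same grid as its parent map."""

    data: np.ndarray
    voxel_size: float

    def __post_init__(self):
        d = np.asarray(self.data)
        if d.dtype != bool:
            d = d.astype(bool)
        if d.ndim != 3 or len(set(d.shape)) != 1:
            raise ValueError(f"mask grid must be cubic, got shape {d.shape}")
        self.data = d
        self.voxel_size = float(self.voxel_size)

    def __and__(self, other: "Mask") -> "Mask":
        return Mask(self.data & other.data, self.voxel_size)

    def __or__(self, other: "Mask") -> "Mask":
        return Mask(self.data | other.data, self.voxel_size)

    def __invert__(self) -> "Mask":
        return Mask(~self.data, self.voxel_size)

    @property
    def count(self) -> int:
        return int(self.data.sum())

    @property
    def volume(self) -> float:
        """Enclosed volume in Å^3."""
        return self.count * self.voxel_size ** 3


@dataclass
class RadialProfile:
    """Per-shell mean density around the grid center.

    Shells are contiguous, non-overlapping spherical bins of equal width;
    ``means`` is NaN for empty shells (never silently 0).
    """

    shell_centers: np.ndarray  # Å
    means: np.ndarray
    counts: np.ndarray
    shell_width: float  # Å

    def same_shells(self, other: "RadialProfile") -> bool:
        return (len(self.shell_centers) == len(other.shell_centers)
                and np.allclose(self.shell_centers, other.shell_centers))


def pixel_size_from_scan(scan_pitch_um: float, magnification: float) -> float:
    """Pixel size at the specimen, in Å, from scanner pitch and magnification.

    A film scanned at ``scan_pitch_um`` micrometres per pixel and imaged at
    ``magnification`` represents ``scan_pitch_um * 1e4 / magnification``
    Angstrom per pixel — e.g. 14 µm at 48000x gives 2.9 Å.
    """
    if scan_pitch_um <= 0 or magnification <= 0:
        raise ValueError("scan pitch and magnification must be positive")
    return scan_pitch_um * 1.0e4 / magnification


def read_map(path) -> Map3D:
    """Read an MRC2014 volume (mode 2) into a :class:`Map3D`."""
    try:
        ccp4 = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, OSError, ValueError) as exc:
        raise ValueError(f"cannot read MRC map {path!r}: {exc}") from exc
    grid = ccp4.grid
    if not (grid.nu == grid.nv == grid.nw):
        raise ValueError(
            f"map {path!r} is not cubic: {grid.nu}x{grid.nv}x{grid.nw}")
    data = np.array(grid, copy=True)
    voxel = grid.unit_cell.a / grid.nu
    if voxel <= 0:
        raise ValueError(f"map {path!r} has a non-positive voxel size")
    return Map3D(data, voxel_size=voxel)


def write_map(map3d: Map3D, path) -> None:
    """Write a :class:`Map3D` as an MRC2014 mode-2 file."""
    n = map3d.n
    grid = gemmi.FloatGrid(np.ascontiguousarray(map3d.data, dtype=np.float32))
    edge = n * map3d.voxel_size
    grid.unit_cell = gemmi.UnitCell(edge, edge, edge, 90, 90, 90)
    grid.spacegroup = gemmi.find_spacegroup_by_name("P1")
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = grid
    ccp4.update_ccp4_header()
    ccp4.write_ccp4_map(str(path))


def _frequency_radius(n: int, voxel_size: float) -> np.ndarray:
    """Magnitude of spatial frequency (1/Å) for an n^3 FFT grid."""
    f = np.fft.fftfreq(n, d=voxel_size)
    fx, fy, fz = np.meshgrid(f, f, f, indexing="ij")
    return np.sqrt(fx * fx + fy * fy + fz * fz)


def low_pass_filter(map3d: Map3D, resolution: float, *, soft_edge: bool = True,
                    edge_fraction: float = 0.2) -> Map3D:
    """Suppress Fourier amplitudes beyond 1/``resolution``.

    Parameters
    ----------
    resolution
        Target resolution in Å; must be at least twice the voxel size
        (Nyquist).
    soft_edge
        If True (default) a raised-cosine roll-off of half-width
        ``edge_fraction`` times the cutoff frequency is centred on the
        cutoff, which avoids real-space ringing.  If False the cutoff is
        sharp.

    The DC term is untouched, so the map mean is preserved, and the filter
    is linear in the input densities.
    """
    if resolution < 2.0 * map3d.voxel_size:
        raise ValueError(
            f"resolution {resolution} Å is below the Nyquist limit "
            f"{2 * map3d.voxel_size} Å")
    fc = 1.0 / resolution
    fr = _frequency_radius(map3d.n, map3d.voxel_size)
    if soft_edge:
        half_width = edge_fraction * fc
        lo, hi = fc - half_width, fc + half_width
        transfer = np.ones_like(fr)
        ramp = (fr >= lo) & (fr <= hi)
        transfer[ramp] = 0.5 * (1.0 + np.cos(np.pi * (fr[ramp] - lo) / (hi - lo)))
        transfer[fr > hi] = 0.0
    else:
        transfer = (fr <= fc).astype(float)
    out = np.fft.ifftn(np.fft.fftn(map3d.data) * transfer).real
    return Map3D(out, voxel_size=map3d.voxel_size)


def radial_average(map3d: Map3D, mask: Mask | None = None,
                   shell_width: float = 1.0) -> RadialProfile:
    """Mean density in concentric spherical shells about the grid center.

    ``shell_width`` is in voxels.  If a mask is given, only masked voxels
    contribute; shells with no contributing voxels get mean NaN.
    """
    if mask is not None and mask.data.shape != map3d.data.shape:
        raise ValueError("mask grid does not match the map grid")
    if shell_width <= 0:
        raise ValueError("shell_width must be positive")
    r_vox = map3d.radius_grid() / map3d.voxel_size
    shell_idx = np.floor(r_vox / shell_width).astype(int)
    n_shells = shell_idx.max() + 1
    sel = mask.data if mask is not None else np.ones(map3d.shape, dtype=bool)
    counts = np.bincount(shell_idx[sel], minlength=n_shells)
    sums = np.bincount(shell_idx[sel], weights=map3d.data[sel], minlength=n_shells)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    centers = (np.arange(n_shells) + 0.5) * shell_width * map3d.voxel_size
    return RadialProfile(shell_centers=centers, means=means, counts=counts,
                         shell_width=shell_width * map3d.voxel_size)
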