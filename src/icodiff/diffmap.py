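"""Difference maps and detection of density sites at symmetry axes.

After normalization the maps are in background-sigma units, so difference
maps read directly in sigma.  Positive density marks mass present only in
the minuend; negative regions (mass stronger in the subtrahend) are kept
signed, never clipped — they are informative (e.g. density redistributed
toward the particle center in a deletion mutant).

Default contour conventions: 2 sigma for difference maps, 1 sigma for full
maps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .density_map import Map3D, Mask
from .symmetry import AxisSet

__all__ = [
    "DifferenceMap",
    "SiteDetection",
    "subtract",
    "composite_p14",
    "detect_axis_sites",
    "spherical_mask",
    "sites_to_frame",
    "DIFF_CONTOUR_SIGMA",
    "FULL_MAP_CONTOUR_SIGMA",
]

DIFF_CONTOUR_SIGMA = 2.0
FULL_MAP_CONTOUR_SIGMA = 1.0


@dataclass
class DifferenceMap:
    """Voxelwise difference of two normalized maps, in sigma units."""

    data: Map3D
    minuend_name: str
    subtrahend_name: str

    def signed_summary(self) -> dict:
        """Extrema and voxel counts above/below the +/-2 sigma contours."""
        d = self.data.data
        return {
            "min_sigma": float(d.min()),
            "max_sigma": float(d.max()),
            "voxels_above_2sigma": int((d > DIFF_CONTOUR_SIGMA).sum()),
            "voxels_below_minus_2sigma": int((d < -DIFF_CONTOUR_SIGMA).sum()),
        }


@dataclass
class SiteDetection:
    """A localized density peak near one symmetry-axis direction."""

    axis_direction: np.ndarray  # unit vector
    axis_order: int
    position: np.ndarray  # Å, Cartesian, relative to grid center
    peak_radius: float  # Å from center
    peak_value: float  # sigma units
    integrated_density: float  # sigma * nm^3 over the search region


def _require_same_grid(a: Map3D, b: Map3D) -> None:
    if a.data.shape != b.data.shape or not np.isclose(a.voxel_size, b.voxel_size):
        raise ValueError("maps are on different grids")


def subtract(a: Map3D, b: Map3D, minuend_name: str = "a",
             subtrahend_name: str = "b") -> DifferenceMap:
    """Voxelwise a - b; both maps must come from one normalized set."""
    _require_same_grid(a, b)
    return DifferenceMap(Map3D(a.data - b.data, a.voxel_size),
                         minuend_name, subtrahend_name)


def composite_p14(p124: Map3D, p147: Map3D, p1247: Map3D) -> Map3D:
    """The shell-plus-packaging-motor composite: p124 + p147 - p1247.

    Subtracting the complete map from the sum of the two deletion maps
    cancels the proteins unique to each mutant's complement, leaving the
    components common to all three (shell, and five-fold motor density).
    Together with the two difference maps this satisfies the exact
    decomposition (a - b) + (a - c) + (b + c - a) = a voxelwise.
    """
    _require_same_grid(p124, p147)
    _require_same_grid(p124, p1247)
    return Map3D(p124.data + p147.data - p1247.data, p124.voxel_size)


def detect_axis_sites(diff: DifferenceMap, axes: AxisSet,
                      radial_band: tuple[float, float],
                      threshold: float = DIFF_CONTOUR_SIGMA,
                      *, search_radius: float | None = None) -> list[SiteDetection]:
    """Find the density peak near each axis direction; keep those >= threshold.

    For every direction in ``axes`` the search region is a cylinder of
    radius ``search_radius`` (Å) about the half-line from the grid center
    along the direction, restricted to the radial band [r_min, r_max] (Å).
    The maximum voxel in the region is the candidate peak; it is reported
    as a site iff its value reaches ``threshold`` (sigma units).  The
    returned count is monotone non-increasing in the threshold.

    A peak nearly equidistant (< 1 degree) from two axis directions is
    assigned to the nearer one with a warning.
    """
    m = diff.data
    r_min, r_max = radial_band
    half_edge = m.n * m.voxel_size / 2.0
    if not (0 <= r_min < r_max):
        raise ValueError("radial band must satisfy 0 <= r_min < r_max")
    if r_min > m.radius_grid().max():
        raise ValueError("radial band lies outside the grid")
    if search_radius is None:
        # wide enough to catch a cofactor bracket tilted ~12 deg off-axis
        search_radius = 0.20 * min(r_max, half_edge)

    x, y, z = m.coordinate_grids()
    coords = np.stack([x, y, z])
    r = np.sqrt((coords ** 2).sum(axis=0))
    in_band = (r >= r_min) & (r <= r_max)

    dirs = axes.directions
    sites: list[SiteDetection] = []
    vox_nm3 = m.voxel_volume / 1.0e3
    for d in dirs:
        along = d[0] * x + d[1] * y + d[2] * z  # projection on the axis
        perp2 = r * r - along * along
        region = in_band & (along > 0) & (perp2 <= search_radius ** 2)
        if not region.any():
            continue
        vals = np.where(region, m.data, -np.inf)
        flat_idx = int(np.argmax(vals))
        peak = float(m.data.ravel()[flat_idx])
        if peak < threshold:
            continue
        ijk = np.unravel_index(flat_idx, m.shape)
        pos = (np.array(ijk) - m.center_index) * m.voxel_size

        # angular tie check against every other direction
        pr = np.linalg.norm(pos)
        if pr > 0:
            cosines = dirs @ (pos / pr)
            order = np.argsort(-cosines)
            if len(order) > 1:
                ang0 = np.degrees(np.arccos(np.clip(cosines[order[0]], -1, 1)))
                ang1 = np.degrees(np.arccos(np.clip(cosines[order[1]], -1, 1)))
                if abs(ang1 - ang0) < 1.0 and not np.allclose(dirs[order[0]], d):
                    warnings.warn(
                        f"peak at {pos} is nearly equidistant from two axes "
                        f"({ang0:.2f} vs {ang1:.2f} deg)", stacklevel=2)
        integrated = float(m.data[region].sum()) * vox_nm3
        sites.append(SiteDetection(axis_direction=d, axis_order=axes.order,
                                   position=pos, peak_radius=float(pr),
                                   peak_value=peak,
                                   integrated_density=integrated))
    return sites


def spherical_mask(center: np.ndarray, radius: float, grid_like: Map3D) -> Mask:
    """Boolean ball of ``radius`` Å about ``center`` (Å, relative to grid center).

    Used to cut individual protein densities out of a difference map.  An
    off-grid center simply yields an empty mask.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    x, y, z = grid_like.coordinate_grids()
    c = np.asarray(center, dtype=float)
    d2 = (x - c[0]) ** 2 + (y - c[1]) ** 2 + (z - c[2]) ** 2
    return Mask(d2 <= radius ** 2, grid_like.voxel_size)


def sites_to_frame(sites: list[SiteDetection]) -> pd.DataFrame:
    """Site table: axis order, direction, peak radius (Å), peak (sigma), integral."""
    rows = [{
        "axis_order": s.axis_order,
        "dir_x": s.axis_direction[0],
        "dir_y": s.axis_direction[1],
        "dir_z": s.axis_direction[2],
        "peak_radius_A": s.peak_radius,
        "peak_sigma": s.peak_value,
        "integrated_sigma_nm3": s.integrated_density,
    } for s in sites]
    return pd.DataFrame(rows, columns=["axis_order", "dir_x", "dir_y", "dir_z",
                                       "peak_radius_A", "peak_sigma",
                                       "integrated_sigma_nm3"])
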