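"""Fractional occupancy of a protein site in a symmetry-averaged map.

In an icosahedrally averaged reconstruction a protein present in only a
fraction of particles (or a fraction of symmetry-related sites) shows up
with proportionally reduced density.  Occupancy is therefore estimated on
a linear density scale anchored at two references: the densest region of
the shell protein is 100% and the background is 0%:

    occupancy = (site_mean - background_mean) / (p1_reference - background_mean)

The estimator is position-conditional: it measures occupancy at the
nominal site only and cannot see copies shifted away from it.  It is
invariant under any affine transform applied jointly to the map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .density_map import Map3D, Mask

__all__ = ["OccupancyEstimate", "estimate_occupancy", "max_occupancy",
           "occupancy_to_frame"]


@dataclass
class OccupancyEstimate:
    """One site's occupancy with its component statistics (sigma units)."""

    site_name: str
    occupancy: float
    site_mean: float
    p1_reference: float
    background_mean: float
    out_of_range: bool  # True if occupancy fell outside [0, 1] (noise/scaling flag)


def estimate_occupancy(map3d: Map3D, site_mask: Mask, p1_mask: Mask,
                       background_mask: Mask, reference_quantile: float = 0.01,
                       site_name: str = "site",
                       site_map: Map3D | None = None) -> OccupancyEstimate:
    """Estimate a site's fractional occupancy from a normalized map.

    ``site_mask`` selects the site density, ``p1_mask`` the shell protein
    and ``background_mask`` the solvent annulus.  The 100% reference is
    the mean of the top ``reference_quantile`` of shell-voxel densities
    (default top 1% — the "highest density region" of the shell, robust
    to single-voxel outliers).  Out-of-range estimates are reported, not
    clipped: they flag scaling or mask problems.

    If ``site_map`` is given (typically the difference map that isolates
    the protein), the site density is read from it instead of ``map3d``,
    as its background-corrected mean re-anchored to the background of
    ``map3d``; this removes shell and neighbouring-density contamination
    at the site while keeping the anchors of the occupancy scale on the
    full map.  Both maps must come from the same normalized set.
    """
    for name, mask in (("site", site_mask), ("p1", p1_mask),
                       ("background", background_mask)):
        if mask.data.shape != map3d.data.shape:
            raise ValueError(f"{name} mask grid does not match the map")
        if not mask.data.any():
            raise ValueError(f"{name} mask is empty")
    if not 0 < reference_quantile <= 1:
        raise ValueError("reference_quantile must be in (0, 1]")
    if (site_mask.data & background_mask.data).any():
        raise ValueError("site and background masks overlap")

    background_mean = float(map3d.data[background_mask.data].mean())
    if site_map is None:
        site_mean = float(map3d.data[site_mask.data].mean())
    else:
        if site_map.data.shape != map3d.data.shape:
            raise ValueError("site_map grid does not match the map")
        site_contrast = (float(site_map.data[site_mask.data].mean())
                         - float(site_map.data[background_mask.data].mean()))
        site_mean = site_contrast + background_mean
    p1_vals = np.sort(map3d.data[p1_mask.data])
    k = max(1, int(np.ceil(reference_quantile * p1_vals.size)))
    p1_reference = float(p1_vals[-k:].mean())
    if p1_reference <= background_mean:
        raise ValueError("shell reference density does not exceed background; "
                         "the map is not usable for occupancy")
    occ = (site_mean - background_mean) / (p1_reference - background_mean)
    return OccupancyEstimate(site_name=site_name, occupancy=occ,
                             site_mean=site_mean, p1_reference=p1_reference,
                             background_mean=background_mean,
                             out_of_range=not 0.0 <= occ <= 1.0)


def max_occupancy(available_sites: int, total_sites: int) -> float:
    """Upper bound on mean occupancy when only some sites can be occupied.

    E.g. if at most 12 of the 20 three-fold locations can hold a copy, the
    maximum occupancy over all nominal sites is 12/20 = 0.6.
    """
    if total_sites <= 0:
        raise ValueError("total_sites must be positive")
    if not 0 <= available_sites <= total_sites:
        raise ValueError("need 0 <= available_sites <= total_sites")
    return available_sites / total_sites


def occupancy_to_frame(estimates: list[OccupancyEstimate],
                       map_name: str = "") -> pd.DataFrame:
    rows = [{
        "map": map_name,
        "site": e.site_name,
        "occupancy": e.occupancy,
        "site_mean_sigma": e.site_mean,
        "p1_reference_sigma": e.p1_reference,
        "background_mean_sigma": e.background_mean,
        "out_of_range": e.out_of_range,
    } for e in estimates]
    return pd.DataFrame(rows, columns=["map", "site", "occupancy",
                                       "site_mean_sigma", "p1_reference_sigma",
                                       "background_mean_sigma", "out_of_range"])
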