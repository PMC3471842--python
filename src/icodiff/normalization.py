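"""Put reconstructions on a common intensity scale before subtraction.

The procedure mirrors standard difference-mapping practice for
single-particle reconstructions of the same particle family:

1. identify the protein shell in each map by the density threshold whose
   enclosed volume matches the expected protein volume (mass x copy number
   / protein density);
2. take the background from a spherical annulus that excludes both the
   particle and the apodized box boundary;
3. scale each map affinely to mean 0 and standard deviation 1 over the
   union of the background and its own shell region;
4. optionally flatten residual radial amplitude differences with
   per-shell factors from the masked radial averages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .density_map import Map3D, Mask, RadialProfile, radial_average

__all__ = [
    "AVOGADRO",
    "VolumeBudget",
    "NormalizedMapSet",
    "ThresholdResult",
    "expected_protein_volume",
    "threshold_for_volume",
    "p1_shell_mask",
    "background_annulus_mask",
    "normalize_set",
    "radial_scale",
]

AVOGADRO = 6.02214076e23  # 1/mol


def expected_protein_volume(mass_kda: float, copies: int, density: float) -> float:
    """Expected volume (nm^3) of ``copies`` protein monomers.

    ``mass_kda`` is the monomer mass in kDa and ``density`` the protein
    mass density in g/cm^3 (1.41 g/cm^3 is the standard globular-protein
    value).  84 kDa x 120 copies at 1.41 g/cm^3 gives ~1.187e4 nm^3.
    """
    if mass_kda <= 0 or copies <= 0 or density <= 0:
        raise ValueError("mass, copies and density must all be positive")
    grams_per_copy = mass_kda * 1.0e3 / AVOGADRO
    cm3 = copies * grams_per_copy / density
    return cm3 * 1.0e21  # cm^3 -> nm^3


@dataclass(frozen=True)
class VolumeBudget:
    """Volume target for the shell-protein threshold, from physical inputs."""

    mass_per_copy: float  # kDa
    copies: int
    density: float  # g/cm^3

    def __post_init__(self):
        if self.mass_per_copy <= 0 or self.copies <= 0 or self.density <= 0:
            raise ValueError("all volume-budget fields must be positive")

    @property
    def expected_volume(self) -> float:
        """nm^3"""
        return expected_protein_volume(self.mass_per_copy, self.copies,
                                       self.density)


@dataclass(frozen=True)
class ThresholdResult:
    threshold: float
    achieved_volume: float  # Å^3
    target_volume: float  # Å^3


def threshold_for_volume(map3d: Map3D, target_volume_nm3: float) -> ThresholdResult:
    """Density threshold whose enclosed volume best matches a target.

    Returns the value t such that ``count(density >= t) * voxel_volume`` is
    the closest achievable to ``target_volume_nm3`` (given in nm^3); the
    achieved volume is reported alongside.  The threshold is an observed
    voxel value, so ties can make the achieved volume overshoot slightly.
    """
    target_a3 = target_volume_nm3 * 1.0e3  # nm^3 -> Å^3
    total = map3d.data.size * map3d.voxel_volume
    if target_a3 > total:
        raise ValueError(
            f"target volume {target_volume_nm3} nm^3 exceeds the grid volume "
            f"{total / 1e3} nm^3")
    if target_a3 <= 0:
        raise ValueError("target volume must be positive")
    flat = np.sort(map3d.data.ravel())[::-1]
    k = int(np.clip(np.rint(target_a3 / map3d.voxel_volume), 1, flat.size))
    t = flat[k - 1]
    achieved = int(np.count_nonzero(map3d.data >= t)) * map3d.voxel_volume
    return ThresholdResult(threshold=float(t), achieved_volume=achieved,
                           target_volume=target_a3)


def p1_shell_mask(map3d: Map3D, threshold: float,
                  radial_band: tuple[float, float] | None = None) -> Mask:
    """Voxels at or above a density threshold, optionally radius-banded.

    The band is half-open, ``r_min <= r < r_max`` in Å, so a degenerate
    band selects nothing.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    sel = map3d.data >= threshold
    if radial_band is not None:
        r = map3d.radius_grid()
        sel &= (r >= radial_band[0]) & (r < radial_band[1])
    if not sel.any():
        import warnings
        warnings.warn("shell mask is empty", stacklevel=2)
    return Mask(sel, map3d.voxel_size)


def background_annulus_mask(map3d: Map3D, r_inner: float, r_outer: float) -> Mask:
    """Spherical annulus r_inner <= r < r_outer (Å) around the grid center.

    Chosen to exclude both the particle (inside) and the apodized box
    boundary (outside); a default of [0.40, 0.47] x box edge serves when
    nothing better is known.
    """
    half_edge = map3d.n * map3d.voxel_size / 2.0
    if not (0 < r_inner < r_outer <= half_edge + 1e-9):
        raise ValueError(
            f"need 0 < r_inner < r_outer <= half box edge ({half_edge} Å); "
            f"got [{r_inner}, {r_outer}]")
    r = map3d.radius_grid()
    return Mask((r >= r_inner) & (r < r_outer), map3d.voxel_size)


def default_annulus(map3d: Map3D) -> Mask:
    """Background annulus at [0.40, 0.47] x box edge."""
    edge = map3d.n * map3d.voxel_size
    return background_annulus_mask(map3d, 0.40 * edge, 0.47 * edge)


@dataclass
class NormalizedMapSet:
    """Maps brought to a common affine intensity scale.

    Each map has mean 0 and standard deviation 1 over the union of the
    shared background annulus and its own shell mask, so density values
    read directly in background-sigma units.  ``scale_report`` records the
    gain and offset applied per map (and radial factors if used).
    """

    maps: dict[str, Map3D]
    p1_masks: dict[str, Mask]
    background_mask: Mask
    scale_report: dict[str, dict] = field(default_factory=dict)

    def __getitem__(self, name: str) -> Map3D:
        return self.maps[name]

    def union_region(self, name: str) -> np.ndarray:
        return self.background_mask.data | self.p1_masks[name].data


def normalize_set(maps: dict[str, Map3D], p1_masks: dict[str, Mask],
                  background_mask: Mask, *,
                  union_mode: str = "own") -> NormalizedMapSet:
    """Affinely rescale each map to mean 0, std 1 over background ∪ shell.

    ``union_mode`` selects whether each map's own shell mask ("own",
    default — mutant shells may differ slightly) or the intersection of
    all shell masks ("intersection") is joined with the background.
    The applied gain and offset are recorded in the scale report, and the
    post-conditions (mean 0, std 1 over the region) are re-checked after
    scaling.
    """
    if union_mode not in ("own", "intersection"):
        raise ValueError("union_mode must be 'own' or 'intersection'")
    if set(maps) != set(p1_masks):
        raise ValueError("maps and p1_masks must have identical keys")
    shapes = {m.data.shape for m in maps.values()}
    if len(shapes) != 1 or background_mask.data.shape not in shapes:
        raise ValueError("all maps and masks must share one grid")

    if union_mode == "intersection":
        inter = np.logical_and.reduce([m.data for m in p1_masks.values()])
    out_maps: dict[str, Map3D] = {}
    report: dict[str, dict] = {}
    for name, m in maps.items():
        shell = inter if union_mode == "intersection" else p1_masks[name].data
        region = background_mask.data | shell
        vals = m.data[region]
        mu = float(vals.mean())
        sd = float(vals.std())
        if sd == 0:
            raise ValueError(f"zero variance over the scaling region of {name!r}")
        gain = 1.0 / sd
        offset = -mu / sd
        scaled = Map3D(m.data * gain + offset, m.voxel_size)
        post = scaled.data[region]
        assert abs(post.mean()) < 1e-6 and abs(post.std() - 1.0) < 1e-6
        out_maps[name] = scaled
        report[name] = {"gain": gain, "offset": offset,
                        "region_voxels": int(region.sum())}
    return NormalizedMapSet(maps=out_maps, p1_masks=dict(p1_masks),
                            background_mask=background_mask,
                            scale_report=report)


def radial_scale(target: Map3D, reference_profile: RadialProfile,
                 target_profile: RadialProfile, *,
                 epsilon: float | None = None) -> Map3D:
    """Multiply each voxel by reference/target per-shell mean ratio.

    Shells whose target mean is undefined (NaN) or smaller in magnitude
    than ``epsilon`` (default 1e-6 x the map's density standard deviation)
    get factor 1, as do voxels beyond the last shell.
    """
    if not reference_profile.same_shells(target_profile):
        raise ValueError("radial profiles are on different shell grids")
    if epsilon is None:
        epsilon = 1e-6 * float(target.data.std())
    ref = np.asarray(reference_profile.means, dtype=float)
    tgt = np.asarray(target_profile.means, dtype=float)
    factors = np.ones_like(ref)
    ok = ~np.isnan(ref) & ~np.isnan(tgt) & (np.abs(tgt) > epsilon)
    factors[ok] = ref[ok] / tgt[ok]

    shell_width_vox = target_profile.shell_width / target.voxel_size
    r_vox = target.radius_grid() / target.voxel_size
    idx = np.floor(r_vox / shell_width_vox).astype(int)
    voxel_factor = np.where(idx < len(factors), factors[np.minimum(idx, len(factors) - 1)], 1.0)
    return Map3D(target.data * voxel_factor, target.voxel_size)


def p1_radial_profiles(maps: dict[str, Map3D], p1_masks: dict[str, Mask],
                       shell_width: float = 1.0) -> dict[str, RadialProfile]:
    """Masked radial averages of each map over its own shell mask."""
    return {name: radial_average(m, p1_masks[name], shell_width)
            for name, m in maps.items()}
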