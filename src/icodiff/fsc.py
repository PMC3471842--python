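"""Fourier Shell Correlation between two maps and resolution at a cutoff.

FSC(s) = Re sum(F_a conj(F_b)) / sqrt(sum|F_a|^2 sum|F_b|^2) over the
Fourier voxels in spherical frequency shell s.  Resolution is read where
the curve first crosses below a cutoff (0.5 by convention here), with
linear interpolation between shells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .density_map import Map3D, _frequency_radius

__all__ = ["FSCCurve", "fsc_curve", "resolution_at_cutoff",
           "BETTER_THAN_NYQUIST"]

#: sentinel returned when the curve never drops below the cutoff
BETTER_THAN_NYQUIST = "better-than-Nyquist"


@dataclass
class FSCCurve:
    """Per-shell correlation of two maps' Fourier coefficients.

    ``correlations`` is NaN for shells where either map has zero power;
    elsewhere values lie in [-1, 1].  ``frequencies`` (1/Å) are strictly
    increasing, bounded by Nyquist.
    """

    frequencies: np.ndarray
    correlations: np.ndarray
    shell_voxel_counts: np.ndarray

    def to_table(self) -> str:
        """Two-column text export: frequency (1/Å) and FSC."""
        lines = [f"{f:.6e}\t{c:.6f}" for f, c in
                 zip(self.frequencies, self.correlations)]
        return "\n".join(lines) + "\n"


def fsc_curve(a: Map3D, b: Map3D, n_shells: int | None = None) -> FSCCurve:
    """Fourier Shell Correlation between two maps on identical grids.

    Shells are assigned by nearest-integer radius in frequency voxels
    (shell k covers |f| around k / (N * voxel)); by default every shell up
    to Nyquist (k = N//2) is returned.  The curve is exactly symmetric in
    its two arguments and invariant to positive rescaling of either map.
    """
    if a.data.shape != b.data.shape or not np.isclose(a.voxel_size, b.voxel_size):
        raise ValueError("FSC requires identical grids and voxel sizes")
    n = a.n
    max_shell = n // 2
    if n_shells is None:
        n_shells = max_shell + 1
    if not 1 <= n_shells <= max_shell + 1:
        raise ValueError(f"n_shells must be in [1, {max_shell + 1}]")

    fa = np.fft.fftn(a.data)
    fb = np.fft.fftn(b.data)
    # shell index = nearest integer radius in frequency-voxel units
    fr = _frequency_radius(n, a.voxel_size)
    shell = np.rint(fr * n * a.voxel_size).astype(int)
    keep = shell < n_shells

    idx = shell[keep]
    cross = np.bincount(idx, weights=(fa * np.conj(fb)).real[keep],
                        minlength=n_shells)
    pow_a = np.bincount(idx, weights=(np.abs(fa) ** 2)[keep], minlength=n_shells)
    pow_b = np.bincount(idx, weights=(np.abs(fb) ** 2)[keep], minlength=n_shells)
    counts = np.bincount(idx, minlength=n_shells)

    denom = np.sqrt(pow_a * pow_b)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(denom > 0, cross / np.where(denom > 0, denom, 1.0), np.nan)
    freqs = np.arange(n_shells) / (n * a.voxel_size)
    return FSCCurve(frequencies=freqs, correlations=corr,
                    shell_voxel_counts=counts)


def resolution_at_cutoff(curve: FSCCurve, cutoff: float = 0.5):
    """Resolution (Å) where the FSC first crosses below ``cutoff``.

    The crossing frequency is linearly interpolated between the two
    bracketing shells.  If the curve never drops below the cutoff the
    sentinel :data:`BETTER_THAN_NYQUIST` is returned (the map pair is
    consistent to the sampling limit).  A curve already below the cutoff
    at the first informative shell is an error: no resolution is defined.
    """
    if not -1.0 < cutoff < 1.0:
        raise ValueError("cutoff must lie in (-1, 1)")
    freqs = np.asarray(curve.frequencies, dtype=float)
    corr = np.asarray(curve.correlations, dtype=float)
    valid = ~np.isnan(corr)
    # skip the DC shell for crossing purposes but require the first
    # informative shell to be above the cutoff
    informative = np.nonzero(valid & (freqs > 0))[0]
    if len(informative) == 0:
        raise ValueError("FSC curve has no informative shells")
    if corr[informative[0]] < cutoff:
        raise ValueError("FSC is below the cutoff at the first shell; "
                         "no resolution can be assigned")
    prev = informative[0]
    for i in informative[1:]:
        if corr[i] < cutoff:
            # linear interpolation between shells prev and i
            f0, f1 = freqs[prev], freqs[i]
            c0, c1 = corr[prev], corr[i]
            f_star = f0 + (cutoff - c0) * (f1 - f0) / (c1 - c0)
            return 1.0 / f_star
        prev = i
    return BETTER_THAN_NYQUIST
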