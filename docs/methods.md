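# Methods

This note records the model behind each stage, the defaults and why, the
numerical choices, and what the synthetic phantoms do and do not show
about real data.

## Coordinate and symmetry conventions

Maps are cubic N³ grids with a physical voxel size in Å; densities are in
arbitrary units and every statistic downstream is covariant under affine
density transforms.  The grid center is the voxel at index (N//2, …) and
all radii are measured from its center; even N is supported.

The icosahedral rotation group *I* (60 proper rotations, no mirrors) is
built in the 222 setting: two-fold axes along the coordinate axes,
five-fold axes along directions like (0, 1, φ)/|·| with φ the golden
ratio.  The group is generated from the two-fold rotations about z and x
and the five-fold rotation about (0, 1, φ), closed under multiplication
with an SVD re-projection onto SO(3) after every product to stop numeric
drift; closure, identity and inverses are verified exhaustively in the
tests (all 3600 products, tolerance 1e-8).  Axis direction sets are the
rotation axes of the group elements with angle 2π/k (tolerance 1e-6 rad,
because arccos is ill-conditioned near π): 12 directions for k = 5, 20
for k = 3, 30 for k = 2, in antipodal pairs.  No published orientation
convention is attached to this analysis; all results are covariant with
the choice, which is fixed only for reproducibility.

`symmetrize` averages a map over the 60 rotations using trilinear
resampling with zero padding beyond the grid.  Trilinear interpolation was
chosen for speed and simplicity; its smoothing error on features of
Gaussian width σ sampled at spacing h is O((h/σ)²), i.e. a few percent for
the default phantoms (h = 2.9 Å, σ ≈ 8–10 Å).  Symmetry and idempotence
checks therefore use interpolation-scale tolerances (1–5 %), and mass
conservation holds to ~1e-3 for density kept away from the box edge, not
to machine precision.

## I/O and filtering

Maps are MRC2014 mode 2 (32-bit float), read and written through gemmi;
writing casts to float32, so write-then-read round trips are bit-exact for
float32 data.  Non-cubic volumes and malformed files are rejected.

Pixel size from film scanning is pitch × 10⁴ / magnification (µm to Å):
14 µm at 48000× gives 2.92 Å ≈ 2.9 Å.

The low-pass filter operates in Fourier space with a raised-cosine
roll-off of half-width 0.2 × the cutoff frequency centred on the cutoff
(sharp cutoff available as an option).  The soft edge suppresses the
real-space ringing that a hard edge would imprint on difference maps; the
exact kernel used by the original processing chain is not documented, so
both are exposed.  The DC term is untouched (mean preserved exactly) and
the filter is linear.  Resolutions below Nyquist (2 × voxel) are rejected.

## FSC

FSC per shell is Re Σ F_a·conj(F_b) / sqrt(Σ|F_a|² Σ|F_b|²), with shells
assigned by nearest-integer radius in frequency voxels; per-shell voxel
counts are recorded so degenerate shells are detectable, and zero-power
shells give NaN rather than a fabricated value.  Resolution at a cutoff
(0.5 by convention) is the reciprocal of the linearly interpolated
crossing frequency; a curve that never crosses yields an explicit
better-than-Nyquist outcome, and a curve already below the cutoff at the
first informative shell is an error.  The published per-dataset
resolutions cannot be recomputed without the raw micrographs; instead the
suite verifies the estimator on constructed half-maps whose signal is
sharply band-limited at a known resolution (recovered within ±15 % over
ten seeds).

## Normalization

The shell-volume budget converts protein mass to volume:
V = copies · (mass/N_A)/ρ, with defaults 84 kDa × 120 copies at
1.41 g/cm³ ≈ 1.187 × 10⁴ nm³.  The volume-matched threshold is found by
descending sort: the k-th largest voxel value with k = round(V / voxel
volume) — exact, and verified against a brute-force oracle.  Phantom-scale
runs use the analytic FWHM volume of the generated shell
(4π r² × 2.355 σ_shell) as the budget instead, because the grid-scaled
phantom is smaller than the real particle; on a Gaussian-cross-section
shell this lands the threshold at half the crest amplitude, which the
tests check.

The background annulus defaults to [0.40, 0.47] × box edge — outside any
default phantom particle, inside the apodization-prone boundary; the
radii are configuration because no measured values are documented.

Each map is scaled affinely to mean 0, std 1 over (background ∪ its own
P1 mask); the post-conditions are machine-checked after every call.
Standardizing to 1 makes the conventional 2 σ (difference map) and 1 σ
(full map) contours directly interpretable.  The union uses each map's
*own* shell mask by default since mutant shells may differ slightly; an
`intersection` mode restricts the statistics to voxels all maps agree on,
which is also the like-for-like region in which the scaled shell means of
a phantom triple agree to better than 2 %.

Radial scale factors are the per-shell ratios of masked radial averages
(reference/target); shells with undefined or near-zero target means
(|mean| < 1e-6 × the map std) and voxels beyond the last shell get factor
1.  Whether the original chain computed the factors this way is not
documented; the ratio-of-masked-averages reading is adopted.  On phantom
triples the difference maps change by well under one background σ at the
detected sites with or without radial scaling, consistent with the
reported insensitivity.

## Difference maps and site detection

Subtraction is voxelwise on normalized maps; negative regions are kept
signed and summarized (they are informative — e.g. density redistributed
to the particle center in the P7-minus mutant).  The decomposition
identity (a−b) + (a−c) + (b+c−a) = a is pure algebra and holds to 1e-9.

Site detection searches, for each axis direction, a cylinder about the
half-line from the center, restricted to a radial band (default
[0.5, 0.95] × the shell crest radius, estimated as the median radius of
the complete map's shell mask).  The cylinder radius defaults to 0.20 ×
the band's outer radius — wide enough to catch a cofactor bracket tilted
~13° off-axis, the default phantom geometry.  The maximum voxel in the
region is the candidate peak and is reported iff it reaches the threshold
(2 σ default), so the count is monotone non-increasing in the threshold.
Peaks nearly equidistant (< 1°) from two axes are assigned to the nearer
axis with a warning.  No peak-picking rule is documented for the original
count of 20; this axis-constrained search is the package's choice.

## Occupancy

occupancy = (site_mean − background_mean)/(p1_reference − background_mean),
with p1_reference the mean of the top 1 % of shell-mask voxel densities
("highest density region", robust to single-voxel outliers; quantile
configurable).  Estimates are never clipped; values outside [0, 1] are
flagged as scaling/mask problems.  The estimator is position-conditional:
it measures density at the nominal site only and cannot see copies
shifted elsewhere.

Site densities are read from the difference map that isolates the protein
(background-corrected and re-anchored to the full map's background), which
cancels the shell and neighbouring densities at the site.  The pipeline's
100 % reference additionally restricts the shell mask to a radial band
about the crest ([0.9, 1.1] × crest radius) and excludes 20° cones about
the five-fold axes, because the packaging motor rides directly on the
shell there and would otherwise inflate the reference.

Known bias: in the complete-particle P2 difference map the co-located
cofactor-reduction density (P7 is reduced in the P2-minus mutant) adds to
the polymerase site density, biasing that one estimate upward by roughly
+0.2 on the default phantom.  The cleanly measurable estimates (P7 in the
complete particle, P2 in the P7-minus mutant) recover the generated
density occupancy within ±0.10.  The published occupancy percentages are
data-bound and not recomputable; parameter recovery on phantoms at
occupancies 0.25/0.5/0.75 (±0.10, correct ordering across ten seeds)
substitutes.  The site-availability bound is available/total nominal
sites, e.g. 12/20 = 0.6.

## Phantoms

`PhantomSpec` defaults: 96³ voxels at 2.9 Å (the film-scan pixel size),
shell radius 100 Å with Gaussian cross-section σ = 10 Å and crest
amplitude 1 — the real ~250 Å particle scaled down so a triple renders in
seconds; recess dimples (depth 0.5 × crest) at the 12 five-fold vertices
model the unexpanded dodecahedral state.  P4: σ 8 Å at radius 112 Å,
amplitude 1, full occupancy.  P2: σ 8 Å at 76 Å on the three-fold axes,
amplitude 2 × crest (a compact globular blob concentrates its mass,
whereas the shell spreads it over a layer), occupancy 0.5.  P7: three σ
8 Å blobs per three-fold axis, tilted 13° off-axis at radius 80 Å
("bracket" geometry), amplitude 1.6 × crest, occupancy 0.57.  A diffuse
central Gaussian (σ 30 Å, amplitude 0.3) models disordered internal
protein, and white Gaussian noise defaults to σ = 0.1 × crest.  No
absolute protein radii are published for this system; these are free
parameters fixed once at plausible values.

Occupancy is rendered as amplitude scaling — exactly the effect of
icosahedral averaging over a partially occupied site — and the recorded
ground truth includes the density occupancy (effective amplitude / crest)
that a density-anchored estimator should read back.  All positions are
orbits of a single seed point under the 60 rotations, so noiseless
phantoms are exactly symmetric by construction.  The mutant triple applies
the qualitative mutant phenotypes: P124 deletes P7 and boosts the central
density ×1.5; P147 deletes P2, halves P4, reduces P7 to 0.33× and the
central density to 0.3×.  Noise is independent per map, with seeds spawned
deterministically from the spec seed (same spec ⇒ bit-identical maps).

What the phantoms do **not** emulate: CTF effects, resolution anisotropy,
reconstruction artifacts from orientation misassignment, solvent-density
structure, molecular shape beyond isotropic Gaussians, RNA, or the
expanded particle state.  Passing tests therefore demonstrate the
correctness of the map algebra, the detection geometry and the estimator
anchoring — not robustness to the full error budget of experimental
reconstructions.

## Problem sizes and determinism

Default grids are 96³ (phantom fidelity) and 32–64³ (unit tests); the
full suite runs in well under a minute and the acceptance script in a few
seconds on one CPU.  Every stochastic path takes an explicit integer seed
(numpy SeedSequence); pipelines re-run bit-identically for a fixed
configuration.
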