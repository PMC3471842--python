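# icodiff

Quantitative difference mapping for icosahedral cryo-EM reconstructions:
normalization of map triples onto a common intensity scale, voxelwise
difference maps, detection of density sites at icosahedral symmetry axes,
and density-anchored protein occupancy estimation — with a synthetic
procapsid phantom generator that provides ground truth for validation.

## The problem

Double-stranded RNA bacteriophages such as the cystovirus φ6 package their
genome into a preformed procapsid (PC) built from four proteins: the P1
shell (120 copies), the P2 RNA-dependent RNA polymerase, the P4 packaging
NTPase at the five-fold vertices, and the P7 packaging cofactor.  Locating
the minor proteins P2 and P7 inside the shell is done by comparing
icosahedrally averaged single-particle reconstructions of the complete
particle (P1247) with deletion mutants lacking one protein (P124 = P7-minus,
P147 = P2-minus).  Because the reconstructions come from different
micrograph sets, they must first be brought onto a common intensity scale
before subtraction means anything.

The normalization follows the standard recipe:

1. low-pass filter every map to the worst common resolution (default 16 Å);
2. find, per map, the density threshold *t* whose enclosed volume matches
   the expected P1 shell volume,
   V = copies · (m / N_A) / ρ with m = 84 kDa, ρ = 1.41 g/cm³,
   copies = 120 (≈ 1.19 × 10⁴ nm³);
3. take the background from a spherical annulus excluding both the particle
   and the apodized box boundary;
4. scale each map affinely to mean 0 and standard deviation 1 over
   (background ∪ its P1 region), so densities read in σ units;
5. optionally flatten residual radial differences with per-shell factors
   from the masked radial averages.

Difference maps D = P1247 − P124 (the P7 map) and D = P1247 − P147 (the P2
map) then isolate the deleted protein, and the composite
P124 + P147 − P1247 = P14 isolates the shell and motor.  The three pieces
satisfy the exact identity

    (P1247 − P124) + (P1247 − P147) + (P124 + P147 − P1247) = P1247.

Sites are counted by searching a cylinder about each symmetry-axis
direction (20 three-fold directions for P2/P7) within a radial band, and a
site's occupancy is read off a linear density scale anchored at the
background (0 %) and the highest-density region of the P1 shell (100 %):

    occupancy = (site_mean − background_mean) / (p1_reference − background_mean).

No public micrograph data exist for this system, so the package ships a
phantom generator (`PhantomSpec`, `generate_mutant_triple`) that renders
icosahedrally exact procapsid look-alikes — Gaussian-cross-section shell
with recessed five-fold vertices, P4/P2/P7 blobs at their axes,
substoichiometric occupancy as amplitude scaling, additive noise — with
full ground truth, so every stage can be validated end to end.

## Worked example

```python
import icodiff as ic

spec = ic.PhantomSpec(seed=42)                      # 96³ grid, 2.9 Å/voxel
maps, truth = ic.generate_mutant_triple(spec)       # P1247 / P124 / P147
cfg = ic.PipelineConfig(target_volume_nm3=ic.shell_volume_fwhm(spec), seed=42)
report = ic.run_pipeline(maps, cfg)
print(report.site_counts)
print(report.occupancy_table)
```

prints

```
site counts: {'P2': 20, 'P7': 20}
    site  occupancy  site_mean_sigma  p1_reference_sigma  background_mean_sigma
P2@P1247      1.180            1.906               1.487                 -0.838
 P2@P124      1.007            1.503               1.487                 -0.838
P7@P1247      0.928            1.319               1.487                 -0.838
 P7@P147      0.219           -0.328               1.487                 -0.838
```

Reading this: all 20 three-fold sites carry polymerase density above the
2 σ contour in the P2 difference map, and likewise for the cofactor.  The
phantom's P7 was generated at density occupancy 0.91 and is read back as
0.93 in the complete particle but only 0.22 in the P2-minus mutant (the
generator reduces the cofactor there, mimicking the destabilized mutant);
the P2 estimate in the complete particle (1.18 vs. true 1.0) is biased
upward by the co-located cofactor-reduction density in its difference map —
the estimator is position-conditional and shares the crudeness of its
experimental counterpart (see `docs/methods.md`).

A command-line interface mirrors the library:

```sh
icodiff simulate --mode triple --seed 42 --out-dir sim/
icodiff pipeline --p1247 sim/P1247.mrc --p124 sim/P124.mrc \
                 --p147 sim/P147.mrc --target-volume-nm3 3324 --out-dir out/
icodiff fsc out/P1247_normalized.mrc out/P124_normalized.mrc --cutoff 0.5
```

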