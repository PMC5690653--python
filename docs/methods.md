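# Methods

## Measurement model

The package treats a micro-CT tomogram of a medullo-papillary complex as a
3-D scalar grid with isotropic voxel spacing (default 5 μm, the resolution of
the scans this workflow targets) containing populations of near-straight,
roughly co-oriented tubules. Three tubule populations are of interest:
mineral-occluded tubules bright in the unstained channel, vasculature bright
in the iodine/contrast channel, and patent tubules visible only as dark
voids inside the tissue.

### Segmentation

Foreground is separated by intensity threshold — Otsu by default on
phantoms and whenever no calibrated density threshold is available; a fixed
threshold is exposed for calibrated scans. Patent tubules are obtained by
*void inversion*: `organ_mask AND NOT tissue_mask`. Each connected component
of the resulting mask is treated as one tubule instance. Defaults:

- connectivity **26** — the walls of a thin tilted tubule touch diagonally
  and fragment under 6-connectivity;
- `min_voxels` **27** (3³) — suppresses noise speckle at negligible risk of
  dropping a real tubule (a 2-voxel-wide tubule only 3 slices long);
- `max_voxels` unset by default, but essential in void channels, where the
  connected interstitial space forms one giant component that would
  otherwise be counted as a tubule.

Touching tubules are not split (no watershed); each component is one
instance. The phantom generator enforces a one-voxel clearance between
tubules so that this assumption is exact in validation data.

### Diameter estimation

For a label volume the pipeline:

1. computes each component's principal direction (dominant eigenvector of
   its voxel-coordinate covariance), sign-aligns them to one hemisphere and
   averages them into a **common axis**; components with low anisotropy
   (largest/middle eigenvalue < 4) have an ill-defined direction and are
   logged — they add noise, not bias, to the average;
2. **reslices** the label volume so slicing planes are perpendicular to that
   axis, using nearest-neighbor resampling (interpolation would invent label
   values) at the original in-plane pitch; when the axis coincides with a
   grid axis the reslice is an exact permutation;
3. on each cross-section of each label, fits the **minimum-area enclosing
   ellipse** to the pixel centers and takes its minor axis as the slice
   diameter. The minor axis is the tilt-invariant choice: a plane cutting a
   circular cylinder at angle θ produces an ellipse with axes d/cos θ × d,
   so the minor axis equals the diameter d for any θ < 90°;
4. summarizes each tubule by the **median** of its slice diameters. The
   median resists end-cap slices (where the section degenerates) and local
   wall defects; it is stable under randomly dropping 20% of slices.

Sections are discarded when they have fewer than `min_section_pixels`
(default 3) pixels or touch the slice border (their ellipse is truncated by
the field of view). Tubules are excluded — reported, not erroring — when
tilted more than `max_tilt_deg` (default 75°; beyond this the section
elongates without bound and pixelation dominates) or when fewer than
`min_slices` (default 3) sections survive.

The same minor-axis rule is applied to 2-D histology label images
(`measure_section_diameters`); ring-shaped vessel-wall profiles are measured
by their outer extent, which the enclosing ellipse sees.

**Boundary compensation.** The ellipse is fitted to pixel *centers*, which
sit inboard of the physical cross-section boundary: on each side the
outermost included center lies up to one pixel inside the true edge (half a
pixel in expectation over sub-voxel placements). Half a pixel is therefore
added to the minor axis before conversion to μm. Empirically this centers
the error distribution (signed errors −3.7 to +1.7 μm, mean −0.9 μm over a
20-case diameter × tilt sweep at 5 μm voxels) without risking systematic
overestimation; the full one-pixel correction would put on-grid-centered
cylinders at the +1-voxel error bound. One-pixel-thin sections are floored
at one pixel width rather than reporting zero.

### Minimum enclosing ellipse

"Smallest ellipse covering the section" is interpreted as the minimum-area
(Löwner–John) ellipse — the standard meaning, and the one that makes the
minor-axis rule geometrically exact. The solver lifts the points to
homogeneous coordinates and runs Khachiyan's barycentric ascent with
Wolfe–Atwood *away steps*, which converge linearly where the plain
Frank–Wolfe update stalls sublinearly; input is first reduced to its convex
hull vertices (only they can support the optimum). Defaults: tolerance 1e-4
on the optimality gap, 10,000 iteration cap (non-convergence raises).
After convergence the quadric is rescaled so the farthest point lies exactly
on the boundary — this guarantees containment to float round-off and can
only move the area toward the optimum. Collinear or single-point inputs are
handled as degenerate ellipses: the major axis spans √2 × the point extent
(the exact 1-D limit), the minor axis takes the caller's floor.

### Co-localization

Pre/post-stain channels of the same mounted specimen are assumed related by
a small rigid translation (rotation negligible); registration maximizes
zero-mean circular cross-correlation over integer shifts within ±10 voxels,
computed by FFT. A peak normalized correlation below 0.2 is flagged as
low-confidence. Overlap is reported as coverage of channel-A foreground
(|A∩B|/|A|), Dice, and per-A-tubule covered fractions; a tubule is called
co-localized at ≥ 0.5 covered (the threshold is a parameter — the underlying
fractions are always reported).

### Zones and histograms

The organ's axial extent is split into `n_zones` equal intervals (3 by
default — proximal I, mid II, papillary tip III; 5 supported for finer
axial profiles), and each tubule is assigned by the projection of its
centroid onto the organ axis; a centroid exactly on a boundary goes to the
more proximal zone. Histograms use left-closed right-open 10 μm bins over
[0, 100) μm by default — matching the ~10 μm granularity at which tubule
classes separate (vasa recta ~10–30 μm vs uriniferous ~30–60 μm); values at
or beyond the range are tallied as overflow, never silently binned. One
histogram entry per tubule (per-slice counting would weight tubules by
length); the per-slice diameters remain available on each measurement for
callers who want slice-weighted distributions. Modes are strict local
maxima of the count vector; plateaus resolve to their leftmost bin, mode
ranking is by count with ties to the smaller diameter, and a minimum mode
separation (default 1 bin) is enforced greedily.

## Synthetic phantoms

The generator emulates the validation-relevant features of the target
scans: a two-channel volume of straight cylinders with diameters drawn from
a Gaussian mixture (truncated at two voxel widths, the smallest grid-
representable diameter), axes perturbed from a common direction by up to a
configurable jitter (default within 20° in end-to-end runs), solid
("filled") or hollow capped ("shell") walls, foreground/background plateau
intensities with additive Gaussian noise, an optional paraboloid organ
envelope, and an exactly controlled fraction of channel-A tubules duplicated
into channel B at identical geometry. Placement is rejection-sampled with a
one-voxel clearance (at most 1000 attempts per tubule) so ground-truth
instance labels are unambiguous. Everything is deterministic given the seed.

Default study-scale conditions used in validation: 5 μm isotropic voxels;
the bimodal mixture 0.5·N(25 μm, 2²) + 0.5·N(45 μm, 4²) (the two tubule
populations the diameter analysis is meant to resolve); noise at 10% of the
600-unit foreground/background contrast; 150 tubules in a 256³ grid for the
end-to-end run. Tubule length defaults to 60% of the axial extent — long
enough for stable per-tubule medians, short enough to place without overlap.

What the phantoms do **not** emulate: tubule curvature and branching,
touching tubules, CT reconstruction artifacts (rings, beam hardening,
partial-volume blur), intensity inhomogeneity, and interstitial (non-
tubular) mineral morphologies. Passing phantom-based tests therefore
demonstrates the geometric correctness of the measurement chain at realistic
noise, not robustness to every real-scan artifact; on real data the fixed
threshold, size filters and tilt/slice gates are the knobs that absorb those
effects.

## Problem sizes and numerical choices

Validation runs use 256³ voxels / 150 tubules for the end-to-end bimodal
recovery, ten 128³ / 100-tubule phantom pairs for co-localization recovery,
and a 20-case diameter × tilt sweep for tilt invariance — sizes chosen to
exercise the full chain at study-like densities while keeping a complete
validation run in minutes on one CPU. Reslicing allocates the rotated
bounding grid (≤ √3× the input extent per axis). All randomness flows from
explicit seeds through `numpy.random.default_rng`; repeated runs are
byte-identical including CSV serialization (fixed column order, fixed float
format, `\n` line terminator).

## Known limitations

- One connected component = one tubule: touching or branching tubules merge.
- Diameters below ~2 voxels are unresolvable and the generator refuses to
  plant them; at 5 μm voxels the practical floor is ~10 μm, so the lower
  tail of the vasa recta range is censored at scan resolution.
- The common-axis model assumes one dominant tubule orientation; a field of
  strongly divergent orientations degrades per-slice sections (mitigated by
  the per-tubule tilt gate, at the cost of excluding those tubules).
- Registration is integer-translation only; rotational misalignment between
  channels is not corrected.
- The ellipse angle is reported but meaningless for near-circular sections
  (axis difference < 1e-9); consumers must not rely on it there.
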