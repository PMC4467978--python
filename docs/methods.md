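# Methods

This note documents the models and procedures behind `ctneoquant`, the
defaults that matter, the design choices made where the design was open,
and what the synthetic data does and does not establish about real scans.

## Synthetic constructs

Real CE-nanoCT scans of neo-tissue in metal or polymer scaffolds have three
greyscale phases — dark background (medium/air), intermediate stained
tissue, bright scaffold — degraded by partial-volume blur, detector noise
and metal artifacts. The phantom reproduces that statistical structure with
the simplest geometry that exhibits it:

- **Geometry.** A cylindrical construct envelope containing a rectilinear
  lattice of cylindrical struts along all three axes (pitch 24 voxels,
  strut radius 3 voxels by default). The in-plane strut layers sit half a
  pitch off the stack center so that the central and quartile slice heights
  are pore-level cross-sections. Each strut carries a neo-tissue shell of
  configurable thickness; `neo_shell_thickness_vox` is the "neo-tissue
  volume" dial. The default voxel size is 3.75 µm, the acquisition scale of
  the scans being emulated; shells of 2–3 voxels emulate tissue near the
  ~7.5–11.5 µm spatial resolution limit, where the partial-volume effect
  (PVE) suppresses tissue contrast.
- **Rendering.** With partial-volume blur enabled (`psf_sigma_vox > 0`),
  phase occupancy is rendered by 3× supersampling and box-averaging, so a
  sub-voxel shell produces the fractional greyscales that make thin tissue
  hard to segment; the volume is then Gaussian-blurred and Gaussian noise
  is added. With `psf_sigma_vox = 0`, voxels are sampled at centers and the
  volume takes exactly the three configured means — the degenerate case the
  exactness tests rely on. Ground-truth masks are thresholded (≥ 0.5)
  pre-blur occupancies and are always disjoint.
- **Artifacts.** Streaks are straight in-plane rays seeded at
  scaffold-lattice corners with alternating sign and linear radial decay,
  redrawn per slice so artifact load varies along the construct height;
  beam hardening is a radially increasing quadratic bias, identical per
  slice. These are the simplest fields that confound global thresholding
  the way metal artifacts do; they are not calibrated to any scanner, and
  amplitudes are free parameters.
- **Shrinkage transform.** `apply_shrinkage` removes voxels by iterative
  6-connected erosion, with a final trim that ranks boundary voxels by a
  smoothed (σ = 2 voxels) random field and removes the highest-ranked until
  the target count is met exactly. The smooth field matters: independent
  random pits one voxel wide would be undone by the 2-voxel closing later
  in the cleanup chain, whereas physical shrinkage — and this transform —
  removes spatially coherent patches.
- **Determinism.** All randomness (noise, streak directions, shrinkage
  trim) derives from the single `seed` field; equal specs give bit-identical
  outputs.

What the phantom does *not* model: polychromatic physics and real
reconstruction (the artifacts are additive stand-ins), tissue texture and
fibrous anisotropy, stain diffusion gradients, and scanner-specific noise.
Passing tests therefore demonstrate the correctness and calibration of the
*analysis*, not the biology of any particular construct.

## Normalized contrast

Profiles are sampled by bilinear interpolation at ≤ 1-voxel steps. Because
a manually drawn "arbitrary line" is not reproducible, default lines are
axis-aligned rays from the four slice borders toward the center, truncated
at the far edge of the scaffold strut nearest the center, with the start
point in the middle of the preceding background gap; the contrast slice is
the center of the longest run of minimal-scaffold-area slices in the middle
half of the stack (a pore-level cross-section). Manual lines override.

Phase boundaries: the profile is 3-sample median filtered (immune to
single-voxel spikes), candidate transitions are gradients ≥ 20% of the
maximum (10% fallback), and the candidate pair maximizing the
between-segment variance of the three resulting segments is chosen. A pure
top-two-gradients rule fails when a strong artifact edge inside a phase
outranks a weak background-to-tissue step; the variance criterion keeps the
boundaries at the phase transitions in that case. Phase means must be
monotone along the profile.

Plateau rule: within each segment, the plateau is the set of samples within
`tolerance_fraction` (default 0.10 — the deviation bound is not specified
by any source, so it is configurable) of the *phase-median span* (highest
minus lowest segment median) around the segment median. Using the median
span rather than the raw min–max range keeps a single outlier spike from
widening the tolerance band. Transition samples are thereby excluded from
the phase means, and `B/(A+B)` is evaluated on plateau means only. The
pipeline averages over up to 3 lines per volume and accepts 2-sample
plateaus (`min_phase_len=2`) so that tissue near the resolution limit still
yields a value; the library default remains 3.

## Segmentation

Multi-level Otsu on 256-bin per-slice histograms (deeper data is rebinned;
bin edges span the slice's own min–max, so labels are invariant under
increasing transforms that preserve bin order). Threshold semantics are
half-open, `t_{k-1} < g ≤ t_k`; ties break to the lexicographically
smallest tuple. k = 2, 3 use exhaustive vectorized search over all bin
boundaries; k = 4, 5 use a suffix dynamic programme over cumulative moments
with forward (lexicographic) reconstruction, cross-validated against brute
force at small bin counts in the tests. Constant or degenerate slices are
labeled all-background with a warning rather than raising — real stacks
have empty end slices.

Neo-tissue binarization: labels are greyscale-ordered, so the default rule
takes the classes strictly between the background class (0) and the
scaffold class (k−1); for k = 2 — used on scaffold-suppressed volumes,
where the bright phase must not claim a class — the upper class is the
tissue. Explicit class selectors override.

Level selection: candidate levels 2–5 are scored by the mismatched-slice
fraction against the reference masks, averaged over the provided volumes;
the chosen level is the smallest one within one standard error of the
minimum, since extra levels cost processing time and must buy a real
improvement. On the phantom families this returns 2 for the
scaffold-suppressed (equilibrium-agent) profile and 3 for the three-phase
thin-tissue (binding-agent) profile.

## Dataset quality

The differential overlay codes +1 (reference only), −1 (binarized only),
0 (agreement). Per-slice mismatch is the nonzero fraction of the *full*
slice surface (not the construct cross-section — the rule is defined on the
slide surface). The 1% exclusion threshold is inclusive: exactly 1%
mismatch flags the slice; only strictly smaller mismatches are attributed
to background noise. The quality statistic is flagged slices / total
slices. The reference mask is an explicit input — ground truth for
phantoms, a user-supplied stained-tissue mask for real data; the package
takes no position on how such a reference is produced for real scans.

## Morphometry

Structuring elements are Euclidean balls implemented exactly via distance
transforms (`EDT(~mask) ≤ r` for dilation; padding treats the volume border
as foreground for erosion, so closings do not erode at the stack faces).
The cleanup chain order is fixed: scaffold dilation (radius 2) and
subtraction, despeckle (white components < 200 voxels removed, then black
components < 200 voxels filled, 26-connected), closing (radius 2).

Local thickness follows the largest-inscribed-sphere definition:
`thickness(p)` is the diameter of the largest ball inside the mask
containing `p`, computed by painting EDT level sets from the largest radius
down. Distances are voxel-center metric, so a digitized disc of nominal
radius r can report up to ~1 voxel more than 2r; agreement with brute-force
inscribed-sphere search is within 1 voxel in the tests.

Registration is integer translation only (phantom pairs share a frame up to
translation; rotational alignment is out of scope): FFT cross-correlation
of mean-subtracted volumes ranks shifts inside the search window, and the
winner is scored by exact overlap NCC. Shrinkage (Eq. above) uses summed
cross-sectional areas over `n = 3` analysis slices at fractional heights
(i+1)/(n+1), snapped away from flagged slices when a mismatch report is
given; the synthetic pipeline also snaps them to pore-level cross-sections
(slices whose construct area is within 5% of the stack minimum), since
slices cutting in-plane struts mix strut-parallel tissue into the
transaxial area.

Known limitation, by construction: for tissue near the resolution limit
(thin shells), margin removal leaves a sub-voxel ring and the shrinkage
estimate becomes unreliable — recovery of programmed fractions within
±0.03 holds on medium/high-volume phantoms, not thin-tissue ones.

## Design of experiments

The 9-run design takes levels `(v, t)` over all pairs with concentration
level `c = 2(v + t) mod 3` — a Graeco-Latin square whose run set equals the
published condition table of the staining study for every seed; only the
run order is seed-shuffled. Main effects are OLS on coded −1/0/+1 levels
(equal spacing is the screening convention even though physical spacings
are unequal; physical values are carried alongside). With 9 runs × 3
replicates and 4 parameters, the residual has 23 degrees of freedom;
standardized effects are |t| statistics and the Pareto reference line is
the two-sided t critical value at α = 0.05 (2.07). Only linear main effects
are modeled — exactly three effects appear in the ranking. Constant
responses yield zero effects with p = 1 (coefficients at numerical zero are
not "infinitely significant").

Calibration is verified by simulation: with pure-noise responses each
factor is flagged at the nominal 5% (±3% over 200 simulations), and an
effect/σ ratio of 5 is detected with power ≥ 95%.

## The synthetic study's wiring

`run_staining_evaluation` encodes the factors as: concentration level →
tissue greyscale elevation multiplier (0.4/0.7/1.0) and, for the binding
stain, programmed shrinkage fraction `0.05 + 0.08·c + 0.04·v` (up to 0.29);
volume level → shell thickness (3.0/4.5/6.0 voxels); staining time → no
physical effect (the study finding being emulated: both agents fully
infiltrate within the shortest time). Default study phantoms are 64³ with
blur 0.5, noise 3, streak amplitude 45 and bias 10 — sizes chosen so the
full 27-condition study runs in well under a minute on one CPU while every
slice still contains several struts. Expected outcomes: concentration
dominates all three Pareto rankings; the mismatched-slice fraction
decreases monotonically with concentration; time is null.

## Numerical conventions

Axis order (z, y, x), z the construct height, 0-based; a transaxial slice
is one z-plane. Voxel sizes are isotropic and live in YAML sidecars next to
TIFF stacks (an explicit configuration value wins, with a logged warning).
16-bit output is clipped and rounded at write time. All seeds are explicit;
no global random state is used anywhere.
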