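# Methods

This document describes the algorithms and conventions implemented in
`emfit`. Everything here is recomputable from the code; numbers quoted in
the README come from the commands shown there.

## Maps and conventions

A `DensityMap` is a C-ordered `float64` array with a voxel size (Å per
axis) and an origin (Å position of voxel `[0,0,0]`). MRC files are read
and written through `gemmi`. Fractional positions are interpolated
trilinearly; `trilinear(dmap, positions)` also reports which points fall
inside the grid, and scoring functions treat outside points as
contributing zero.

### Robust statistics

`robust_map_stats` estimates a mean and standard deviation that are
insensitive to the large solvent/background peak typical of cryo-EM
boxes: the value histogram (256 bins) is built, the modal bin — which is
dominated by background — is discarded, and the mean/sd are computed from
the remaining voxels. A map whose voxels are all identical is degenerate
and raises an error rather than returning sd = 0.

### Z-weighted density score

Model-to-map agreement for fitting is scored as

    S(model) = Σ_atoms w_i · (ρ(x_i) − μ) / σ

where ρ is the trilinearly interpolated density, μ/σ the robust
statistics, and w_i the atomic number of atom i (`weight_mode =
"atomic_number"`; a uniform mode is also available). Heavier atoms thus
count more, and the background level of the map cancels. The score is
what Jiggle Fit, rigid-body refinement, helix orientation and fold
screening all optimize.

### Segmentation, sharpening, scaling

`segment_sphere` cuts a spherical region (default protein radius
34 Å) out of a map, zeroing everything outside the sphere.
`sharpen_map` applies `exp(−B s² / 4)` in reciprocal space (negative B
sharpens); `scale_amplitudes_to` matches the radial amplitude profile of
one map to a reference shell by shell. `average_maps` and composite
operations combine maps voxel-wise.

## Synthetic data

Structure factors are computed from five-Gaussian electron form factors
per element with per-atom B factors; `simulate_map` evaluates them on the
reciprocal grid of the requested box, applies a resolution cutoff, and
inverse-FFTs to real space. `simulate_half_maps` adds two independent
Gaussian noise realizations (controlled by `noise_sigma` and `seed`) to
produce a half-map pair with a shared signal. Ideal α-helices
(`build_ideal_helix`, backbone + Cβ), three-helix bundles
(`build_helix_bundle`), and A-form RNA/DNA duplexes
(`build_ideal_duplex`) provide ground-truth models; `shake_model`
(seeded Gaussian coordinate perturbation) and `bend_model` (rigid
rotation of residues past a hinge about an axis) perturb them.

## FSC metrics

The Fourier-shell correlation between two maps (or a model and a map,
via simulated structure factors on the same grid) is

    FSC(shell) = Re Σ F₁ F₂* / sqrt(Σ|F₁|² · Σ|F₂|²)

computed on a unique hemisphere of reciprocal space: a coefficient is
kept when its lexicographic frequency key is ≤ its Friedel mate's, and
F(000) is excluded. Shells are equal-width bins in s = 1/d between 0 and
the Nyquist s_max, with index `min(floor(s / s_max · n_shells), n−1)`;
empty shells are dropped with a warning.

Summary statistics:

- `fsc_average` — the shell-size-weighted mean of FSC over shells up to
  the resolution cutoff. It depends only on per-shell FSC values and
  shell sizes, so any per-shell-constant reweighting of the coefficients
  (for example `exp(−B s²/4)` evaluated at shell midpoints) leaves it
  exactly invariant, while amplitude-based statistics change.
- weighted R factor — `Σ w |A₁ − A₂| / Σ w A₁` over amplitudes, which is
  sensitive to exactly such scale/B-factor differences.
- `resolution_estimate` — the first crossing of a threshold (default
  0.143 for half maps) by linear interpolation between shell midpoints,
  with a `crossed` flag when the curve never drops below the threshold
  inside the measured range.

Curves serialize to JSON and a plain text table and round-trip exactly.

### Half-map cross-validation

`cross_validate` refines a (deliberately shaken) copy of the model
against half-map 1 only, then computes model-vs-map FSC against half-map
1 (`FSC_work`) and the held-out half-map 2 (`FSC_test`) on identical
shells. Overfitting shows up as `FSC_work` exceeding `FSC_test`; the
report carries the per-shell gap, its maximum and mean, and the
resolution cutoff used. A refinement protocol that follows the noise of
half-map 1 produces a large `max_gap` and a sharp drop in `FSC_work`
just past the refinement cutoff; a properly restrained protocol keeps
the gap small.

## Fitting

### Rigid-body refinement

`rigid_body_refine` maximizes the Z-weighted score over the 6
rigid-body parameters with a derivative-free coordinate search
(rotations about the model centroid), shrinking the step size over
rounds. It never returns a pose scoring below the input pose.

### Jiggle Fit

`jiggle_fit` performs a randomized rigid-body search:

1. Generate `n_trials` candidate poses: quasi-uniform orientations from
   the super-Fibonacci quaternion sequence (deterministic, no RNG)
   combined with seeded random translations up to `max_translation`,
   applied about the model centroid. The refined input pose is always a
   candidate, as is the principal-axis flip of the model (helices and
   other elongated domains score similarly under a 180° flip, so it is
   checked explicitly).
2. Score all candidates; locally refine the `n_top` best with
   `rigid_body_refine`.
3. Return the best refined pose. If nothing beats the refined input, the
   input pose is returned — the search never makes the model worse, and
   rerunning with the same seed is bit-reproducible.

`orient_helix` runs Jiggle Fit on a helix and on its end-to-end flip and
reports both scores plus which direction won; at ~4 Å the carbonyl
asymmetry of the helix makes the forward direction reliably
distinguishable, while near 7 Å the two scores converge.

### Morphing

`morph` fits a flexible model by sliding a window of
`fragment_length` residues along each chain, rigid-body refining each
fragment independently into its local density environment (a sphere of
`env_radius` around the fragment), and then moving every atom by the
average of the rigid transforms of all windows containing it. Averaging
overlapping windows keeps the chain connected (CA–CA steps change by
well under 1 Å per iteration) while letting the model bend; a few
iterations straighten a 15°-bent helix into its straight-truth map. On a
map that already matches the model, morphing is near a fixed point.

### Helix finding

`find_helices` scores an ideal polyalanine helix over map-derived seed
positions and the super-Fibonacci orientation set, locally refines the
best placements, and suppresses duplicates closer than a helix radius,
returning placements with their scores in decreasing order.

### Fold screening

`fold_screen` asks whether any domain in a library explains a map
segment. The segment is low-pass filtered to `d_limit` (default 5 Å),
then each domain is scored over ≥ 2 quasi-uniform orientations (200+
recommended) with translation-only local refinement per pose, giving a
score ensemble {S}. The reported statistic is the contrast

    contrast = (max S − mean S) / sd S

A correct domain produces one pose far above the ensemble bulk
(contrast ≥ 3 is the decision rule); wrong folds score flat ensembles.
Domains with degenerate ensembles (sd = 0, e.g. featureless maps or
point-symmetric domains) are flagged instead of ranked, and flagged
domains sort after ranked ones.

## Restraints

All distance restraints carry one or more `(target, sigma)` pairs and a
kind tag, serialize to JSON, and export to a REFMAC-style `exte dist`
text dialect (multi-target restraints carry `alt group` tags so mutually
exclusive alternatives stay grouped on re-import).

- **Reference restraints** (`generate_reference_restraints`): distances
  are measured in a reference model between atoms of the restrained
  subset (protein: N, CA, C, O, CB; nucleic: P, O5', C5', C4', C3',
  O3', O4', C1', N1/N9), same chain, sequence separation ≥ 2, distance
  < 4.2 Å, and imposed on the corresponding atoms of the target via an
  explicit or identity correspondence. Default sigma 0.1 Å.
- **Jelly-body restraints**: the same generator with the model as its
  own reference — current distances become targets, which resists
  overfitting by penalizing internal distortion while leaving rigid
  motion free.
- **Hydrogen-bond restraints**: α-helical O(i)–N(i+4) bonds at
  2.9 ± 0.2 Å for residues detected in helical conformation.
- **Helical fragment restraints**: ideal-helix internal distances
  imposed on detected helical stretches.
- **Base pairs**: `detect_base_pairs` matches nucleotides across chains
  by hydrogen-bond-atom geometry and classifies Watson–Crick G:C and
  A:U pairs and G:U wobble/reverse-wobble pairs, reporting pairs in
  order of increasing deviation from ideal. Canonical pairs generate
  single-target hydrogen-bond restraints (three for G:C, two for A:U).
  G:U pairs are ambiguous between the wobble and reverse-wobble
  geometries, so every G:U restraint carries **two** targets — one per
  configuration — and the refinement engine selects, per cycle and per
  restraint group, the target set currently in better agreement
  (`select_multi_targets`; index 0 = wobble, 1 = reverse wobble). The
  selection is stable once refinement converges.
- **Stacking restraints**: consecutive bases whose least-squares planes
  are parallel and ~3.4 Å apart with in-plane overlap get plane-distance
  restraints; widely separated or merely coplanar side-by-side bases are
  rejected.

### Robust weighting

Each distance deviation Δ = d − d_target enters the geometry energy
through the Geman–McClure ρ-function

    ρ(Δ) = Δ² / (1 + (Δ/c)²),    energy term = ρ(Δ) / σ²

which is quadratic near zero (ρ(Δ) ≈ Δ²) and saturates at c² for large
|Δ|, so a few badly violated restraints — wrong targets, register
errors — cannot dominate the gradient. The scale c (`gm_scale`, default
0.5 Å) sets where down-weighting begins. Analytic gradients match
central finite differences to 1e-4 relative accuracy.

## Refinement

`refine` minimizes

    E = w_data · E_data + E_geometry + E_nonbonded

by gradient descent with a trust-radius cap on the per-cycle atomic
shift (`max_shift`, default 0.5 Å) over `n_cycles` outer cycles of
`inner_steps` line-searched steps each. The trajectory of
(total, data, geometry, max shift) per cycle is recorded; accepted steps
never increase the total, so the trajectory is monotone non-increasing.

- **Data term**, two modes. `"reciprocal"` (default): squared residual
  between model structure factors and map coefficients up to `d_min` —
  exactly stationary when the model reproduces the map. `"real"`:
  negative interpolated density sum — cheaper, but the trilinear
  interpolant is only piecewise-linear, so its pointwise gradient does
  not vanish exactly at the optimum.
- **Geometry term**: the Geman–McClure-weighted restraint energy above.
  When no restraints are supplied, jelly-body plus hydrogen-bond
  restraints are generated from the input model.
- **Multi-target selection** happens at the start of each cycle
  (recorded per cycle in the trajectory).
- **Nonbonded term**: a repulsive penalty below `nb_dist` (default
  2.2 Å) between non-restrained atom pairs, extended across symmetry
  mates when a point-group symmetry (e.g. `"C2"`) is declared —
  refinement then maintains clearance to the symmetry copies without
  instantiating them in the model.
- **Masked refinement**: a center/radius mask restricts the data term to
  a region; atoms outside are held by geometry only, and density changes
  outside the mask do not affect the result.

With `data_weight = 0` the engine is a pure geometry regularizer and is
map-independent. The default protocol (jelly + hydrogen bonds,
reciprocal data term) recovers a 0.3 Å-shaken helix to well under half
its starting RMSD against a noiseless 3.5 Å map in 20 cycles.

## Command-line application

The `emfit` CLI (built on `click`) exposes the pipeline as subcommands
(see README). Conventions: every command accepts `--seed` (all
randomness flows through it; identical invocations give byte-identical
`--report` JSON), missing input files exit with status 1 naming the
path, and unknown options exit with status 2.

## Reproducibility

No global RNG state is used anywhere; every stochastic routine takes an
explicit seed with a documented default. The orientation sets are
deterministic by construction. `scripts/acceptance.py` recomputes the
packaged self-screen contrast statistic from scratch for any seed.
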