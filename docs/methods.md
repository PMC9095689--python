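# Methods

This note documents the models and numerical choices behind `myoshape`:
what is computed, under which assumptions, with which defaults, and what
the synthetic experiments do and do not demonstrate.

## Coordinate conventions

All geometry is in millimetres in a fixed anatomical frame: x =
medial–lateral, y = anterior–posterior, z = proximal–distal (+z proximal).
The canonical side is the right limb; left-limb meshes are mirrored across
the sagittal plane x = 0 (x negated, face winding reversed so outward
normals survive). In study manifests, rows with `side = L` are reflected
automatically. The axis labelling is a package convention — segmentation
pipelines differ, and inputs are expected in (or convertible to) this frame.

## Synthetic cohorts

The generator emulates cohorts of soleus-like muscles. The template is a
closed superellipsoid-like surface (exponent 2.5), 300 mm long, 80 mm wide
and 40 mm thick, with the width profile peaking 40% of the way from the
proximal end (a beta-shaped profile `t³(1−t)²`) and a medial bulge of the
cross-section centreline proportional to the same profile (so the overall
width stays 80 mm). These dimensions resemble an adolescent soleus envelope
and are design values, not measurements. Axial rings are warped toward the
distal end (`t^0.85`), which gives the vertex cloud a nonzero skewness along
z — the anchor for alignment sign disambiguation.

Five deformation modes are analytic displacement fields of the vertex
coordinates, *linear in their amplitude*:

| mode | field (unit amplitude) | emulates |
|---|---|---|
| `size` | `0.1·(v − c̄)` | overall size (isotropic 10% per SD) |
| `aspect` | `(−0.04x̃, −0.04ỹ, +0.08z̃)` | long-thin vs short-thick (volume-preserving to first order; 0.47% at amplitude 1) |
| `margin_side` | `(6·sin(πt), 0, 0)` | medial/lateral bowing of the curved margin |
| `proximal_width` | `0.25·(x̃, ỹ, 0)·smoothstep((t−0.7)/0.3)` | width of the proximal extremity |
| `broad_shift` | `(0, 0, 15·exp(−((t−0.6)/0.22)²))` | axial shift of the broad section |

(`t` is the relative axial position, `x̃` etc. centroid-centred
coordinates.) A specimen is the template plus the *sum* of fields scaled by
its true weights — drawn per mode from `N(group_offset, mode_sds²)` — plus
i.i.d. isotropic Gaussian vertex noise. Summing linear fields on template
coordinates (rather than composing deformations sequentially) makes the
population lie exactly in a 5-dimensional linear subspace plus noise, so
PCA recovery has an exact ground truth; sequential composition would leave
O(amplitude²) cross terms. Defaults: `mode_sds = (1.0, 0.8, 0.6, 0.5,
0.4)` (size-dominated, descending secondary modes, as real cohorts show),
`noise_sd = 0.5 mm` (sub-voxel for typical muscle MRI), resolution 20
(1562 vertices). `shuffle_topology` re-tessellates each specimen at a
random parametric seam: the surfaces are unchanged as point sets but vertex
indices no longer correspond, forcing the registration stage to do real
work.

What the generator does **not** emulate: segmentation artifacts
(staircasing, slice anisotropy), pose variation beyond what tests add
explicitly, non-linear or localized pathology effects, fibre architecture,
and tendon geometry. Passing tests therefore demonstrate correctness of the
machinery on populations with known linear structure, not performance on
clinical segmentations.

## Registration

Correspondence is one-to-all: a reference mesh is warped onto every
specimen. The warp is a scipy `RBFInterpolator` with a thin-plate-spline
kernel and a degree-1 polynomial (affine) term, fitted to displacements of
`n_control = 200` control vertices chosen by farthest-point sampling
(deterministic: seeded at the vertex farthest from the centroid, ties by
lowest index). The `regularization` parameter is the interpolator's
smoothing weight; at 0 the warp interpolates control displacements exactly.

Correspondence estimation runs in two stages:

1. **Symmetric affine ICP** (30 over-relaxed iterations, ω = 1.5).
   Closest-point correspondences slide tangentially on elongated shapes, so
   one-directional affine ICP under-recovers scale along the long axis. The
   solve therefore pairs reference control points with their closest points
   on the target *and* a farthest-point sample of target vertices with
   their barycentric preimages on the warped reference surface; the true
   affine map is then the only fixed point, and affine warps are recovered
   to numerical precision. The iteration is initialized from the two
   meshes' canonical inertial poses, so large rigid offsets never have to
   be discovered by closest points.
2. **Annealed RBF ICP** (default 10 iterations). With exact interpolation,
   closest-point correspondences are a fixed point after one pass; the
   early iterations therefore use a strong smoothing weight that decays by
   10× per iteration (coarse-to-fine), and the final solve uses the
   caller's regularization, preserving the exact-interpolation contract.

Point-to-surface distances use an own closest-point-on-triangle query
(k-d tree over triangle centroids prefilters 32 candidate triangles, exact
Ericson closest-point per candidate; exact for meshes with ≤ 32 triangles
and verified against brute force). The fitting RMS is the root mean square
of point-to-surface distances of all warped reference vertices.

Rigid alignment maps the centre of mass (uniform vertex weights) to the
origin and the principal axes of the vertex covariance to (z, x, y) in
descending-eigenvalue order. Signs of the first two axes are chosen so the
vertex-coordinate skewness along each is non-negative; the third axis is
their cross product (handedness). Meshes with (near-)degenerate inertia
(relative eigenvalue gap < 1e−9, e.g. spheres) are rejected rather than
silently tie-broken.

The cohort is refitted iteratively against its own mean (default
`max_iter = 5`, stopping when the mean RMS improves by less than
`tol_mm = 0.01`). At the method's noise floor the per-seed RMS history can
fluctuate by a few hundredths of a millimetre; averaged across seeds it is
non-increasing, which is what the tests assert.

## Shape models

PCA uses the sample covariance (divisor m − 1) of deviations from the mean,
eigen-decomposed through the m × m Gram matrix — exact and cheap since
3n ≫ m; equivalence with the direct 3n × 3n route is tested to 1e−8. Mode
signs follow a deterministic convention (largest-magnitude entry positive).
Near-zero-variance modes (below 1e−12 of total variance) are filled with
orthonormalized canonical vectors so the mode matrix stays orthonormal.
`cumulative_variance` divides by the *total* training variance (trace of
the covariance), not the retained-k sum, so truncated models report < 100%.
The default retained mode count is k = 9, capped at m − 1.

Size normalization is uniform scale only (no re-rotation), applied after
rigid alignment: the scalar minimizing `‖s·S − ref‖²` has the closed form
`s = ⟨S, ref⟩/⟨S, S⟩`; the cohort mean serves as the reference in the
pipeline. Models persist to HDF5 (mean, modes, variances, topology, flags,
provenance) with timestamps disabled so archives are byte-reproducible.

Variance-recovery checks compare fitted eigenvalues against the *expected
sample spectrum* under the generator, not the planted values directly:
sample PCA eigenvalues carry the standard spiked-covariance inflation
`ℓ → ℓ + c·σ²·ℓ/(ℓ − σ²)` with `c = 3n/m`. The package's size and aspect
fields are strongly collinear (their overlap is ~0.97), so the smallest
mixed eigenvalue is small enough (≈ 40 mm² at resolution 10) that this
finite-sample term is material; the check runs at m = 100, resolution 10
(`c ≈ 11`, where the first-order expression is solidly valid) averaged
over 8 seeds.

## Validation

Leave-one-out generality: for each fold a model is fitted on the remaining
m − 1 shapes and the left-out shape is reconstructed, by default by
orthogonal projection `S̄ + PPᵀ(S − S̄)` (the standard, monotone-in-k
metric). A PLS variant regresses fold deviations on fold scores
(scikit-learn `PLSRegression`, k components) and predicts the left-out
shape from its scores. The per-fold error is the RMS over vertices of the
Euclidean vertex distance (mm); folds are averaged arithmetically.

## Group comparison

Mean-shape difference maps report both notions conflated by "distance
between corresponding nodes": the per-corresponding-vertex Euclidean
distance (drives the colour map; exported as the PLY `quality` property)
and the true symmetric point-to-surface Hausdorff distance (one worst-case
summary). Per-vertex direction signs come from the first mesh's outward
vertex normals.

The per-PC battery on model weights gates a pooled-variance two-sample
t-test behind three criteria at 0.05: per-group Shapiro–Wilk normality,
Levene variance equality (mean-centred), and freedom from outliers beyond
1.5×IQR fences in either group. Any violation routes the PC to
Kruskal–Wallis on the full data. Outliers are *recorded, not deleted*:
trimming by the fences and then t-testing the trimmed samples inflates the
null family-wise error of the battery to ~0.13 in simulation, whereas
routing to the rank test keeps it at ~0.05–0.06. Raw p-values of all
tested PCs (both branches) form a single Holm–Bonferroni family per model
flavour; `significant` means the adjusted p ≤ α. PCs with zero weight
variance in both groups are reported with an error tag and excluded from
the family without affecting the rest.

Statistical power at the default study conditions is modest by
construction: a 0.8-SD group-mean offset at n = 19/17 gives a two-sample
t-test power of ~0.64 at α = 0.05 before multiplicity correction, and the
measured end-to-end detection rate of the planted size effect (after PCA
mixing with the collinear aspect mode and Holm correction over 5 PCs) is
~0.25–0.4. The acceptance suite states this honestly; detecting such an
effect reliably would need roughly double the separation or samples.

## Problem sizes

The default test and acceptance runs use: full study 19 + 17 specimens at
resolution 20 (1562 vertices, ~45 s for a double determinism run);
mode-recovery at m = 40, resolution 10; variance recovery at m = 100 × 8
seeds, resolution 10; statistical simulations at resolution 4 (58
vertices), 300–500 null and 200 power replicates. These sizes make the
whole suite run in a few minutes while keeping every Monte-Carlo margin
several standard errors wide.

## Known limitations

* Correspondence quality is only measured as point-to-surface RMS; low RMS
  does not guarantee anatomically meaningful landmark correspondence
  (a general limitation of closest-point-based fitting).
* The affine ICP assumes the target is a complete closed surface; partial
  or holed segmentations would bias the symmetric matching.
* Alignment relies on distinct inertia eigenvalues and nonzero coordinate
  skewness; shapes without these asymmetries need an external pose
  convention.
* The statistical battery treats PCs as the family; it does not model
  selection effects from choosing k, nor correct across the two model
  flavours jointly (configurable in principle, separate by default).
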