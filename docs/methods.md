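# Methods

## Diffusion map embedding

Connectivity rows are compared by cosine similarity, yielding an affinity
matrix `W` (symmetric, entries in [0, 1], self-similarity 1).  Negative
cosines are clipped to 0 by default — affinities must be nonnegative for the
Markov-chain interpretation — with `(1 + cos)/2` shifting offered as an
alternative (`negative_policy="shift"`).  Optional per-row sparsification
(keep the top fraction of each row's entries before the cosine step) is off
by default (`sparsify_keep_fraction=1`); related connectopic-mapping work
keeps the top 10%, so the option is exposed.

The embedding follows the standard anisotropic construction:

- `W' = D^-α W D^-α`, `D = diag(row sums of W)`, with α = 0.5 by default.
  α = 0.5 approximates Laplace–Beltrami geometry, making the recovered
  coordinates insensitive to sampling density; α is exposed because the
  literature also uses 0 (graph Laplacian) and 1.
- `P = D'^-1 W'` is the Markov matrix; its spectrum is computed through the
  symmetric conjugate `S = D'^1/2 P D'^-1/2` with a dense symmetric
  eigensolver, which is numerically safer than a nonsymmetric solve and
  exact for the matrix sizes involved (thousands of voxels).
- Right eigenvectors of `P` are recovered as `ψ = v / sqrt(d')`, normalized
  so the trivial eigenvalue-1 eigenvector is the all-ones vector, and the
  trivial component is dropped.
- Coordinates are scaled by `λ^t` for diffusion time `t > 0`, or by
  `λ/(1-λ)` at the default `t = 0`, which integrates the diffusion operator
  over all times.

Requirements and failure modes: the affinity graph must be a single
connected component (rejected otherwise, reporting the component count);
the input must be symmetric and nonnegative.  Eigenvector signs are whatever
the solver returns and are documented as arbitrary; `orient_gradients`
fixes the sign of a chosen component against a reference vector (e.g. a
motor-region indicator), negating it when the Pearson correlation is
negative.  Among numerically equal eigenvalues (|Δλ| < 1e-12) column order
follows solver output and is unstable; tests only touch degenerate spectra
where the degeneracy itself is the assertion (the ring's cos/sin pair).

`DiffusionMapEmbedding` wraps the same computation as a scikit-learn
estimator (`fit`, `fit_transform`, `get_params`/`set_params`,
trailing-underscore attributes).  Like `sklearn.manifold.SpectralEmbedding`
it has no out-of-sample `transform`: diffusion coordinates are defined only
for the fitted points.

## Volumetric preprocessing

Pipeline order: threshold/binarize → resample to the reference grid → slice
match → gray-matter mask.  Thresholding precedes downsampling deliberately
(it changes partial-volume behavior, and the order is part of the method's
contract).  Thresholding is strictly greater-than (`value > t`); `t = None`
keeps all nonzero voxels.

Resampling is affine-driven: world coordinates decide everything, voxel
indices nothing.  Continuous data are interpolated trilinearly
(`scipy.ndimage.map_coordinates`, order 1) at reference voxel centers.
Binary data instead use exact volume-fraction resampling: the fraction of
each reference voxel covered by nonzero source voxels is accumulated from
separable interval overlaps and re-binarized at ≥ 0.5.  Point interpolation
is the wrong tool for binary downsampling — a 1 mm voxel whose center
coincides with a 2 mm voxel center would survive at full weight despite
filling only 1/8 of it; volume-fraction resampling keeps a voxel exactly
when the majority of its volume is covered.  The box-overlap kernel is exact
for axis-aligned affines (which MNI-registered volumes have) and is the one
numeric primitive written in-house; obliquely oriented binary volumes are
rejected rather than silently approximated.

`match_grid` pads or crops whole slices, aligning grids by world coordinates
with an integer voxel offset, so no voxel's world position ever changes.
The reference grid defaults to the standard MNI152 2 mm geometry
(91×109×91, `mni152_reference_affine()`), and is fully configurable so the
miniature synthetic grids used in tests stand in without special-casing.
The slice-matching target grid is this standard geometry; a deployment
matching a different HCP file layout may differ by a fixed offset, which
`match_grid` absorbs by construction.

MNI registration is checked heuristically (axis-aligned affine; world
origin — the anterior commissure in MNI152 — within 20 mm of the volume's
bounding box) and produces a warning, never a rejection: user affines vary
in benign ways, and a hard failure would be wrong more often than the
warning is.

The QC report compares the in-mask nonzero voxel set of the thresholded,
reference-resampled input with the final output.  By construction of the
pipeline these sets are equal (masking only removes out-of-mask voxels, and
slice matching preserves world positions), so `moved_voxels` is empty on
every valid run; a nonempty list indicates a bug or a corrupted atlas, and
the glass-brain figure (three maximum-intensity projections, before and
after) gives the visual counterpart.  Re-running the pipeline on its own
output with `threshold=None` is a no-op (the output is already thresholded
and binarized; a second strict `> t` pass on a 0/1 volume would erase it,
so idempotence is defined with the threshold spent).

## Atlas and projection

Atlas voxel order is the row-major scan of the mask, fixed so CSV rows and
overplotting order are deterministic.  Gradient axes are 1-indexed in every
interface, matching the field's "gradient 1/2/3" naming.  `map_cluster`
emits one row per atlas voxel (value 0 outside the cluster); CSV export
writes only nonzero rows, full precision, columns
`voxel_i, voxel_j, voxel_k, g_x, g_y, value`.  The CSV layout is this
package's own contract.

## Statistics

Mann-Whitney U from rank sums with midrank ties.  Exact p by full
enumeration when both n ≤ 8 and the pooled sample is tie-free, otherwise
normal approximation with tie-corrected variance and continuity correction
(the scipy implementation; the exhaustive enumeration lives in the test
suite as an independent oracle).  Two-sided by default; one-sided
alternatives and a Bonferroni correction across axes are exposed but off by
default, matching per-axis reporting.  A pooled sample with zero variance
returns p = 1 with a warning rather than an error.

Known limitation: voxels are treated as independent observations.  Smooth
imaging data are spatially autocorrelated, so these p-values are
descriptive; an autocorrelation-aware null is out of scope.

## Synthetic data

The generator replaces three external data dependencies:

- **Connectivity** (stands in for HCP resting-state data): each of n points
  gets latent coordinates uniform on [0, 1]², and its row is Gaussian bump
  loadings over each latent axis (24 centers per axis, width 0.4), the
  axis-1 block weighted by `eigenvalue_gap_factor` (default 2, the minimum
  accepted) so the leading nontrivial eigenvalue pairs with axis 1 and
  recovery tests are free of rotation ambiguity.  The bump width matters:
  narrow bumps push harmonics of axis 1 above the axis-2 fundamental and
  the second component becomes a harmonic instead of the second axis; width
  0.4 keeps the spectrum ordered (fundamental 1, fundamental 2, harmonics)
  and recovery correlations ≥ 0.95 at noise_sd up to 0.1.  Additive
  Gaussian noise (default 0) models measurement noise.
- **Reference space**: a centered ellipsoidal mask on a miniature 2 mm grid
  (default 16–24 voxels per side, mask fraction 0.25–0.3, ~1000–2500
  voxels), mirror-symmetric along the first (left-right) axis.  Miniature
  grids keep the full suite in seconds; nothing in the pipeline depends on
  grid size.
- **Atlas**: gradients 1/2 are the planted latents, gradient 3 is built
  antisymmetric under the left-right mirror (echoing hemispheric
  asymmetry), and 7-network labels partition the gradient plane into
  angular sectors — mirroring the observation that networks occupy
  contiguous gradient-space territories, rather than modeling anatomy.
- **Clusters** are planted at reference-voxel granularity; finer-resolution
  outputs tile each chosen reference voxel completely with subvoxels, so
  the planted in-mask set survives volume-fraction resampling exactly and
  end-to-end tests can assert set equality, not approximate overlap.
  `spill_outside` adds adjacent out-of-mask voxels (boundary-straddling
  inputs); `values="graded"` writes per-voxel values in (0.5, 9.5) for
  threshold tests.  `make_shifted_cluster_pair` builds two clusters whose
  gradient-1 distributions are matched voxel-for-voxel while gradient 2 is
  shifted by a chosen number of pooled standard deviations (default 1) —
  the planted analogue of two task maps separated along one functional
  axis.

What the generator does **not** emulate: realistic fMRI time series or
hemodynamics, realistic cerebellar anatomy, spatial autocorrelation of
cluster values, or the actual HCP-derived gradient values.  Passing tests
therefore demonstrate correctness of the machinery (embedding, resampling
contracts, projection, test calibration) on data with known ground truth —
not that any particular real-data gradient map is reproduced.

All generation is seeded through `numpy.random.default_rng` with
integer-list seed derivation and integer-indexed constructions (no
order-dependent accumulation), so identical seeds give identical bytes
across platforms.

## Design notes

- The embedding is presented as a scikit-learn estimator because it is
  genuinely transform-shaped; the volumetric pipeline, projection, viz and
  stats operate on volumes and atlas objects and keep a plain functional
  surface.
- Reproducibility is delivered by the run manifest (inputs, parameters,
  package version, CSV SHA-256) plus seeded generation, not by
  containerization.
- Plot styling (neutral background color, point size, overlap color,
  outline-vs-fill for cluster membership in network mode) are package
  choices, configurable through `PlotSpec`; the 7-network color table is
  package data (`data/network_colors.json`), not code.  Tests assert the
  backing arrays (counts, classes, intensity ranks), never rendered pixels.
- Empty results (cluster entirely outside gray matter) warn and produce
  header-only CSVs with exit code 0; malformed inputs fail with the stage
  named and a nonzero exit code.
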