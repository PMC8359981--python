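# Methods

This note records the model implemented by trabkit, its parameter
conventions, the numerical choices that affect results, what the
validation phantoms do and do not emulate, and the known limitations.

## Conventions

* Voxel arrays are indexed `(x, y, z)` = (image width K, image height M,
  slice count N); `voxels[..., k]` is the k-th slice. Multi-page TIFF
  pages are reordered accordingly on read.
* Voxel indices are 0-based; crop boxes are half-open `[lo, hi)`.
* Physical coordinates are millimetres at voxel centers:
  `p = origin + index * spacing`. Anisotropic spacing is honored in all
  arc lengths, node positions and densities.
* TIFF stacks carry no reliable spacing, so reading one requires an
  explicit `spacing_override`; NIfTI spacing comes from the header.

## Compartment isolation

The five-step protocol separates the binarized bone `b` into cortical
shell, enclosed voids and cancellous lattice using only iterated binary
dilation and erosion with one shared structuring element:

1. mask `c = erodeⁿ(dilateⁿ(b))` (a closing),
2. voids `d = c AND NOT b`,
3. interior `e = close(d)`, clipped to `c`,
4. cortical `f = c AND NOT e`,
5. cancellous `g = c AND NOT d AND NOT f`.

The three output compartments tile the mask exactly by construction,
and `BoneCompartments` re-validates the partition on every construction.

Numerical choices:

* **Border padding.** Dilation pads the image border with background;
  erosion pads with foreground. For symmetric structuring elements this
  makes erosion the exact complement-dual of dilation
  (`erode(X) = NOT dilate(NOT X)`) and keeps bone that touches the crop
  boundary from being eaten. The dual consequence is that a dilation
  clipped by the array border is *not* undone by the erosion, so the
  closing inflates near the border: the structure of interest should
  keep a margin larger than the total dilation reach (n iterations of a
  disc-5 reach about 11–12 px; the default phantoms keep > 12 voxels).
* **Structuring element.** `disc` of size s contains the pixels within
  Euclidean radius s/2 (a 5×5 disc has 21 px); `box` is all ones.
  Elements must be odd-sized with the center set.
* **Iteration count vs structure scale.** A closing with reach r fills
  enclosed cavities of inradius up to about r and bridges gaps up to
  about 2r. For a square lattice of rods with spacing s and radius ρ the
  binding constraint is the diagonal interstice, inradius
  `√2/2·s − ρ`; the iteration count must be chosen so the reach exceeds
  it, which is why 4–6 iterations of the disc-5 element suit typical
  trabecular separations at ordinary μCT resolutions. Too many
  iterations waste the border margin; too few leave unfilled holes that
  the erosion re-expands, collapsing the mask.
* **2D vs 3D.** The default processes each Z slice independently (the
  protocol is slice-wise by design); `mode="3d"` substitutes a single
  volumetric closing with the spherical/cubic analogue of the element
  for shapes where slice-wise closing leaks through the cortex.
* **Binarization.** A single Otsu threshold over the pooled stack
  histogram (not per slice), so compartments stay consistent along Z.

## Skeletonization and graph extraction

The cancellous volume is thinned with topology-preserving 3D thinning
(Lee, Kashyap & Chu 1994, via scikit-image); components and tunnels of
the input survive, and the skeleton is a subset of the foreground.

Graph conversion classifies skeleton voxels by 26-neighbor count:
1 → terminal node, 2 → branch interior, ≥ 3 → junction. Maximal
26-connected junction clusters collapse to one node at their centroid.
Degree-2 chains are traced into branch polylines in physical mm. Pure
cycles that touch no node get one anchor voxel and a self-loop branch,
preserving the cycle count. Junction–junction branches with fewer than
`min_bridge_voxels` (default 2) interior voxels are treated as thinning
artifacts and contracted by merging their end nodes. Isolated single
voxels are dropped. Euler-characteristic identities
(cycles = E − V + components) hold on the output graph.

Externally produced skeletons can be imported from Amira/Avizo
SpatialGraph ASCII files; the writer produces files the reader
round-trips exactly. Landmark files (Amira LandmarkSet ASCII) provide
reference axes and homologous scaling lengths.

## Indices

* **Node density.** A Gaussian product kernel with per-axis Silverman
  normal-reference bandwidths (`h = σ (4/(5n))^{1/7}`, d = 3) is
  evaluated at the cell centers of a grid (default 100³) tiling the node
  bounding box, then renormalized so the discrete integral equals the
  node count. The renormalization is a boundary correction: the nodes
  live in a bounded region, and without it up to ~25% of the kernel mass
  leaks outside the box, biasing every density low. Units are nodes/cm³
  of the working frame (physical mm, or dimensionless after division by
  a homologous scale length). Summary statistics (mean/max/SD) are taken
  over support cells — density above 1% of the maximum — so empty
  corners of the bounding box do not dilute the mean.
* **Trabecular angle.** Branch directions (end node − start node,
  normalized) are axial: each is flipped into the hemisphere of the
  reference axis before the vector sum, making the result independent of
  traversal direction. The angle is `arccos(|r·â|/‖r‖)` ∈ [0°, 90°].
  The axis comes from landmarks or, with `axis="major"`, from the first
  right singular vector of the centered node cloud (numerical noise of
  that SVD is ~1e-6 degrees on degenerate clouds).
* **Connectivity.** Mean degree over non-terminal nodes (degree ≥ 2);
  terminals are excluded, self-loops contribute 2 to their node.
* **Tortuosity.** Per-branch polyline arc length over the end-to-end
  chord. Self-loops (chord 0) are excluded and counted.
* **Fractal dimension.** Box counting over cubic cells anchored at the
  bounding-box minimum corner, sides halving from the longest
  bounding-box side down to 4× the median nearest-neighbor spacing of
  the deduplicated polyline points (below that, counts saturate and
  flatten the fit). Cell indices are clipped so the final cell along
  each axis is closed — without the clip, points on the upper boundary
  faces spawn an extra layer of cells and bias the slope upward. The
  dimension is the OLS slope of log N(s) vs log(1/s); the per-scale
  table and R² are returned for diagnostics. Calibration: collinear
  points ≈ 1, planar grids ≈ 2, volume-filling grids ≈ 3. Note that for
  a curve network the measured slope legitimately depends on how densely
  the network fills space over the retained scales; it is a descriptive
  complexity index, not an estimate of a mathematical attractor
  dimension, and it shifts when the structure scale shifts.
* **Scale correction.** When a homologous scale length is given (e.g.,
  a landmark-to-landmark distance), node density and fractal dimension
  are computed on the rescaled skeleton; angle, connectivity and
  tortuosity are scale-invariant.

## Phantoms: what they emulate, and what they do not

`generate_phantom` builds a cortical-like shell (cylinder or ellipsoid)
enclosing a cubic lattice of rods (or random chords), rasterized by
distance to analytic centerlines. Because the centerlines are analytic,
the generator returns *exact* ground truth: the compartment masks, the
designed skeleton graph and blueprint statistics (junction count,
designed connectivity and tortuosity). Optional sinusoidal waviness
raises the designed tortuosity; `degrade` renders the binary phantom as
noisy grayscale (foreground 200 / background 10, salt-and-pepper noise,
then Gaussian blur standing in for the scanner PSF and reconstruction
smoothing — noise precedes blur because real reconstructions smooth
detector noise, and isolated full-contrast specks would otherwise defeat
any global threshold).

The phantoms emulate the *geometric and topological* challenges of the
pipeline: a closed shell with enclosed voids, thin connected struts,
junctions of known degree, wall insertions, tunable separation and
noise. They do **not** emulate μCT physics (beam hardening, ring
artifacts, partial-volume gray levels beyond a single blur), biological
variability (plate-like trabeculae, anisotropic thickening, marrow
inhomogeneity) or anatomical shape. Geometric constraints baked into
the generator, with reasons:

* semi-axes keep > 12 voxels of margin to the volume border so the
  iterated closing is never clipped;
* wall-parallel rods keep a clearance from the inner wall (trabeculae
  insert into the endosteal surface transversally; a rod running along
  the wall leaves one-sided voids the protocol cannot close);
* the lattice is anchored at an integer voxel coordinate so rods
  rasterize with odd width and the directional thinning sweep stays
  symmetric (an even-width rod loses entire stubs on one side).

## Determinism

All randomness is seeded (`PhantomSpec.seed`, `degrade(seed=...)`);
sidecar JSON files contain no timestamps; CSV output uses a fixed float
format. Running the full pipeline twice on the same input produces
byte-identical reports.

## Limitations

* The isolation protocol assumes an approximately closed cortical shell
  in each processed slice; open or fenestrated shells leak the closing
  and misclassify compartments (use `mode="3d"` or crop to a closed
  region).
* The closing reach couples resolution, trabecular separation and the
  border margin; defaults (disc-5, 5 iterations) target typical μCT
  voxel sizes and must be re-derived for other scales.
* Box-counting FD on skeleton graphs typically has few usable scales
  (3–8); the returned R² should be inspected before interpreting it.
* Node density depends on the Silverman bandwidth, which assumes a
  roughly unimodal cloud; strongly clustered nodes are over-smoothed.
* The thinning is voxel-based: sub-voxel trabecular thickness variation
  is not represented, and junction positions carry half-voxel centroid
  quantization.
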