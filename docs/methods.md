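# Methods

## Forward model

The 2D electrostatic EIT problem ∇·(σ∇u) = 0 is discretized with linear
(P1) triangular finite elements and piecewise-constant conductivity per
element. Electrodes are point electrodes: each electrode is a boundary
node group (size 1 by default) at which current is injected; contact
impedance is not modelled. Difference imaging is largely insensitive to
the electrode model, and all comparisons in this package are relative;
a complete-electrode model is a possible extension. The potential is
grounded at one node; all measurements are differences between electrode
potentials, so the grounding choice does not affect them (reciprocity of
the discrete system is verified to 1e-8 in the tests).

The adjacent protocol drives unit current between each neighbouring
electrode pair in turn and measures the voltage between every neighbouring
pair not touching a driven electrode: `n_meas = n_elec (n_elec − 3)`
measurements per frame (208 for the default 16 electrodes). The drive
amplitude is fixed at 1 (arbitrary units); voltage normalization makes all
downstream results amplitude-invariant, which a test asserts.

The Jacobian is computed with the adjoint formula
`J[i, j] = −∇u_d · ∇u_m · area_j` from the unit-current fields of the
drive and measurement pairs, and is verified column-by-column against
finite differences. For normalized difference imaging
(`y_i = (v_i − v⁰_i)/v⁰_i`) the rows of J are scaled by `1/v⁰_i`, with v⁰
computed on the reconstruction mesh.

## Meshes

Meshes are produced deterministically (no randomness): boundary nodes at
fixed arc-length positions with the `n_elec` electrode nodes placed
equidistantly counter-clockwise from the ventral midline, interior nodes
on a regular grid clipped away from the boundary, Delaunay triangulation
clipped to the polygon. A structured, exactly 16-fold rotationally
symmetric disk mesh is constructed directly (band-by-band) for the
symmetry tests, because Delaunay tie-breaking on cocircular polar grids is
not symmetric.

Simulation and reconstruction always use meshes with different target
element counts (defaults 2000 and 1000); the pipeline refuses to run
otherwise. These sizes keep the full study suite fast on a single CPU
while leaving ~330 lung elements on the reconstruction mesh, comfortably
above the 225 basis coefficients.

## Phantom and study conditions

The phantom is a parametric stand-in for a CT-derived thorax slice: an
elliptical thorax (semi-axes 1.0 × 0.75) with two elliptical lungs
(semi-axes 0.28 × 0.45, centers at x = ±0.45), rasterized to 64 × 64.
Row 0 is ventral; columns follow the radiological convention (viewer's
left = patient's right), both configurable. Baseline conductivity is 0.5
on lung elements and 1 elsewhere; ventilated tissue drops to 0.25.

Ventilation patterns: (a) whole lung, (b) dorsal half of the right lung
non-ventilated, (c) the most ventral and most dorsal bands of both lungs
non-ventilated (band height 25% of each lung's anterior–posterior extent
by default — the band height is a free parameter and configurable),
(d) ventral left + dorsal right halves non-ventilated. The atelectasis
series collapses a dorsal band of each lung growing linearly from 0% to
50% of its anterior–posterior extent over 25 evenly spaced levels.

What the phantom does not emulate: realistic thorax/lung contours,
out-of-plane (3D) current paths, contact impedances, cardiac-related
conductivity changes, and electrode placement errors. Passing tests
therefore demonstrate correctness of the algorithms under the stated 2D
conditions, not clinical performance; the pixel-classification fractions
in particular are geometry-dependent (on this phantom the
homogeneous-ventilation pattern scores g1+g4 ≈ 0.89 noise-free, and mesh
sizes in the 2000–4000 element range move it by a few points).

## Noise

"25% Gaussian noise" is implemented as zero-mean Gaussian noise with
standard deviation 0.25 × RMS(y) added to the normalized difference
signal y, seeded and reproducible. The convention is a documented choice
(the amplitude reference for EIT noise percentages varies across the
literature); adding the equivalent noise in raw voltage space before
normalization was evaluated and degrades the reconstructions more, because
normalization amplifies noise on low-baseline channels.

## Regularization and noise-figure calibration

The one-step solution `x̂ = (JᵀJ + λ²RᵀR)⁻¹ Jᵀ y` is computed by Cholesky
factorization of the normal matrix (no pseudo-inverse; problem sizes stay
in the low thousands). Priors: Tikhonov `R = I`; Laplace `R` = discrete
Laplacian over the element face-adjacency graph (diagonal = neighbour
count ≤ 3, −1 off-diagonals); the DCT solver uses the identity prior on
coefficients, with an optional expected-solution shift `‖R(g − h)‖²`.

The amplitude noise figure of a reconstruction matrix B is

    NF = (mean|y_ref| · mean_i ‖B_i‖) / mean|B y_ref|,

the closed form of (input SNR)/(output SNR) under unit-variance Gaussian
measurement noise (the Gaussian constant √(2/π) cancels); a Monte-Carlo
estimator cross-checks it to within 2%. For the DCT solver the output
amplitude is measured in image space (lung-pixel rows of the synthesis
operator applied to B), since the coefficients themselves are not
conductivities; the NF ratio is invariant to including the zero non-lung
rows. The reference signal y_ref is the noise-free homogeneous-ventilation
difference signal computed on the reconstruction mesh.

λ is found by bisection on log λ to NF = 0.5 ± 1e-3. NF(λ) decreases
monotonically over the operational range the bisection brackets
(roughly NF ∈ [5, 0.15] here); at the extremes it saturates — towards the
unregularized solution for λ → 0 and towards smoothed backprojection for
λ → ∞ — so targets below the saturation floor raise a calibration error
reporting the NF at both bracket ends.

## DCT basis construction

Orthonormal DCT-II weights throughout (`a_0 = √(1/M)`, `a_k = √(2/M)`),
so basis images have unit Frobenius norm and truncation/compression
statements are well-defined. Column ordering is `j = p·n_y + q` (0-based,
p = row frequency). Pixel-to-element aggregation uses the mean of a
column's masked-basis values over the lung pixels mapping to each element;
the mean keeps K's scale independent of raster resolution. Rank(K) is
asserted at build time and a rank error raised when the mask is too small
(fewer lung pixels than coefficients makes the columns dependent by
pigeonhole). Pixel centers are located in the mesh by a vectorized
barycentric test (lowest covering element index wins on shared edges,
tolerance 1e-12), verified against a brute-force all-triangles scan.

Note that with the default 16 electrodes, n_meas = 208 < n_DCT = 225: the
reduced problem is still (mildly) underdetermined and relies on the
regularization; the reduced-model recovery test therefore uses a smaller
grid for its well-posed check, as the reduced system's conditioning grows
steeply with frequency count (cond(JK) ≈ 5e3 at 5×5, ≈ 1e7 at 8×8 here).

## Evaluation

Pixels with `H < α · min(H)` (α = 0.65) are classified as conductivity
decrease and compared with the ventilated mask over the thorax-interior
region of interest (so solution mass blurred into non-lung tissue is
penalized); G1/G4 are correct decrease/no-change calls, G2/G3 the two
error types, always summing to 1. For l1 curves both the reconstruction
and the ground-truth change image are peak-normalized to amplitude 1
before summing absolute differences (difference EIT has arbitrary scale
under voltage normalization), and classical element-wise solutions are
rasterized through the same pixel-element map for a like-for-like
comparison.

## Problem sizes and determinism

Default study: 64 × 64 raster, 16 electrodes, 2000/1000-element
simulation/reconstruction meshes, 225 coefficients — a full suite build
(two meshes, Jacobian, basis, three calibrations) takes a few seconds on
one CPU, and the complete 25-level atelectasis sweep under a second more.
All randomness (measurement noise, test data) flows through seeded
generators; mesh and phantom generation are pure functions of their
configuration, so repeated runs are bit-identical. Study outputs embed a
hash of the configuration.

## Known limitations

- 2D only; no complete electrode model; absolute (non-difference) EIT out
  of scope.
- The linearized one-step solver is used as-is; the 0.5 → 0.25
  conductivity step is large enough that linearization error is visible,
  as in any one-step difference reconstruction.
- The number of retained frequencies (15 × 15) is a heuristic default;
  the optimal count relative to EIT's intrinsic resolution is an open
  question.
- A mismatched lung mask (anatomy changed between structural imaging and
  EIT measurement) acts as a wrong prior; sensitivity to mask errors is
  not studied here.
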