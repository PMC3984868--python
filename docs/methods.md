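# Methods

## Model and procedure

A 2D wrapped phase image ψ holds principal values in (−π, π]; the wrapping
operator ω maps any finite phase into that interval (boundary convention
ω(π) = π, ω(−π) = π, implemented deterministically). Wrapped gradients are
the wrapped forward differences Δψˣ (shape (M−1)×N, along rows) and Δψʸ
(M×(N−1), along columns). A *residue* is a 2×2 loop whose wrapped-gradient
circulation is ±2π; the loop sum is required to be within 1e−6 rad of a 2π
multiple (and the charge in {−1, 0, +1}), otherwise the field is flagged as
numerically inconsistent rather than silently accepted.

The estimator minimises the weighted Lᵖ misfit between the gradients of the
unwrapped estimate φ and the wrapped gradients. For p < 2 the objective is
nonconvex; it is attacked by iteratively reweighted least squares (IRLS):

1. **Bootstrap (k = 0).** Solve the weighted least-squares problem with the
   data-dependent factor set to 1 (edge weights = user weights). The IRLS
   weights need a current estimate, and weighted least squares is the
   natural starting member of the same family.
2. **Reweight.** R = wˣ·α/(|r|^{2−p} + α) per row edge (and C per column
   edge), where r is the current edge residual. The additive α (default
   0.01 rad) keeps weights finite and ≤ the user weight; for p < 2 the
   weight decreases monotonically in |r|, releasing discontinuity edges.
3. **Solve.** Assemble Q = AᵀWᵀWA (a weighted 5-point graph Laplacian over
   the column-major pixel vectorization) and s = AᵀWᵀWd directly in sparse
   form and solve Qφ = s with a direct factorization.
4. **Terminate on a residue-free distinction.** E = ω{ψ − φ} is tested for
   residues; if residue-free the loop ends, else it reweights, up to k_max
   (default 20) passes after the bootstrap.
5. **Congruence correction.** E is unwrapped by breadth-first flood fill
   from the centre pixel and added back: φ_final = φ + ω⁻¹{E}. By
   construction φ_final − ψ is an exact per-pixel integer multiple of 2π.

If k_max is exhausted the iterate with the fewest distinction residues
(earliest on ties) is still flood-filled and corrected, so congruence holds
on every run; the result is flagged `converged=False` and the flood fill is
then path dependent (the traversal is nevertheless fixed, so results are
reproducible).

## Weighting

The quality map z is the windowed variance of the wrapped gradients: for
each pixel, the squared deviations of the dx and dy samples inside an l×l
window (l = 3 by default, each block about its own window mean) are summed
and divided by l². Design choices the definition leaves open:

* windows are truncated at the image border (no padding);
* a gradient sample belongs to a window only when both endpoint pixels lie
  inside it;
* the division is by l² literally, although up to 2·l·(l−1) samples
  contribute.

User weights are the affine inversion w = (max z − z)/(max z − min z), so
w = 0 exactly at the worst pixel and w = 1 at the best; a constant quality
map (e.g. perfectly smooth data) degenerates to w ≡ 1. Edge weights take
the min of the two endpoint weights. Masked-out pixels get w = 0 before the
min rule. User weights are computed once from the wrapped input (the
quality map depends only on wrapped gradients); R and C are recomputed
every pass. An externally supplied weight image in [0, 1] may replace the
quality-map route.

## Linear algebra

Q is symmetric positive semidefinite with the constant vector as null
space; s is orthogonal to it by construction. The gauge is fixed by pinning
pixel (0, 0) to zero: the reduced (MN−1) system is strictly positive
definite and is factorized with SuperLU in symmetric mode with a symmetric
fill-reducing ordering (a Cholesky-type route), falling back to a plain LU
factorization if that reports failure. One step of iterative refinement is
applied; a second is attempted if the relative residual still exceeds 1e−8.
Before assembly all edge weights are clamped below at 1e−12 so the pixel
graph stays connected and the reduced matrix nonsingular even when IRLS
drives edges to numerical zero. Assembly never materialises A or WᵀW; the
dense-product construction exists only as a test oracle for grids up to
400 pixels. The sparse matrix's nonzeros are exchanged as (row, column,
value) triplets ordered by column then row (the natural CSC order), and can
be dumped in Matrix Market coordinate format.

## Flood fill

The flood fill starts at the centre pixel (row round(M/2), column
round(N/2), one-based; round-half-up) and visits 4-neighbours in the fixed
order up, down, left, right from a FIFO queue. Instead of accumulating
floating-point sums along the traversal, each pixel's integer 2π offset is
propagated; the output e + 2π·k is therefore bit-identical under any
traversal order on a residue-free field (verified against a LIFO
discipline) and exactly equals the input when no wrap events occur.

## Evaluation

The weighted L⁰ measure ρ divides the weighted count of mismatched edges by
MN (as defined — about 2MN edges are summed, so ρ ∈ [0, ~2]). "Mismatch" is
|residual| > 1e−6 rad: in floating point |x|⁰ is useless, and on congruent
solutions residuals are exact 2π multiples, so any threshold in (0, π)
counts the same edges; 1e−6 is a robustness margin against rounding. Note
the scale caveat: ρ of a raw least-squares iterate counts essentially every
edge (residuals are small but nonzero), whereas ρ of a congruent solution
counts only genuinely wrong or genuinely discontinuous edges — the two are
comparable only in the ≤ direction. Truth-based evaluation uses RMS error
after removing the mean offset, and discontinuity maps mark pixels whose
4-neighbour difference exceeds π.

## Synthetic phantoms

The shear phantom is a planar ramp (slopes 0.2 rad/pixel on both axes by
default) whose rows above the shear row (default 13) are raised by
jump + jump_tilt·j at column j, defaults jump = 3.5 rad, tilt = −0.03
rad/pixel, size 128×128. The tilt makes the phantom *identifiable*:

* the tear gradient slope_x − (jump + tilt·j) exceeds π in magnitude on a
  short leading segment — a genuine discontinuity whose band-edge crossing
  emits a residue;
* the long in-band remainder of the shear pins the true inter-plane 2π
  count, so the truth is the unique weighted-L⁰ optimum.

A constant full-width tear would instead cancel in every loop sum
(residue-free) and make any super-π offset invisible modulo 2π — no
unwrapper could recover it. The out-of-band segment must also stay shorter
than the upper plane is thick: otherwise a cut straight through the plane
is cheaper than the true tear and the optimum moves away from the truth.
With the defaults the out-of-band segment is 6 edges against a 13-row
plane, recovery is exact to machine precision and is robust to moderate
changes of jump, tilt, slopes, shear row and image size. Because the six
genuine tear edges carry positive weight under the global affine weight
normalization, the weighted L⁰ of the *truth itself* is positive
(1.85·10⁻⁴ on the defaults); an errorless reconstruction therefore scores
exactly that value, not zero — zero excess over the truth is the
"no unwrapping errors" statement.

Gaussian noise is added at a target SNR defined as
10·log₁₀(var(signal)/var(noise)) in dB, from a seeded generator; the
phantom is a pure function of its specification. This emulates additive
phase noise only — no complex-data noise model, coil maps, or magnitude
information — so noisy-phantom results say nothing about magnitude-guided
weighting on real acquisitions.

## Problem sizes and defaults

The packaged studies use the 128×128 noiseless phantom (converges in 8
passes, under 2 s) and 48–64 pixel noisy phantoms at 0.8–20 dB, where
low-SNR runs typically exhaust k_max without a residue-free distinction —
congruence still holds and the final ρ is roughly an order of magnitude
below the bootstrap's. Slices of multi-slice volumes are processed
independently; DICOM, 3D unwrapping and the comparison algorithms of the
wider literature (graph-cut, path-following) are out of scope.

## Known limitations

* The IRLS iteration is a local optimiser: on phantoms engineered so that
  the truth is only marginally optimal (e.g. long out-of-band tears behind
  thin planes) it may converge to a different congruent solution or stall
  with a persistent residue dipole when a tear gradient sits almost exactly
  on ±π.
* ρ depends on the user weights, so it is comparable only between solutions
  evaluated under the same weights.
* The weight floor bounds the matrix condition number at about 10¹²;
  extremely ill-conditioned reweighting patterns may degrade the achievable
  linear-system residual below the 1e−8 target, in which case the extra
  refinement pass is the only recourse.
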