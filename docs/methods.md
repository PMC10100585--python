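# Methods

This note describes what `solvmap` computes, the numerical choices behind it,
and the limits of what the simulation can say.

## 1. Problem

In parallel-beam CT the measured projection value for ray *j* is the line
integral of the attenuation image along that ray.  After pixel discretisation,

```
p = A x,        A_ji = length of the intersection of ray j with pixel i.
```

When the detector covers the whole object and the views span 180°, `A` has
full column rank (up to discretisation) and iterative solvers converge to a
faithful image.  When the detector is narrower than the object — the interior
or truncated-projection problem — some rays are never measured and the
restriction of `A` to measured rows is rank deficient: the data no longer
determine every pixel.  Which pixels survive depends jointly on the geometry
*and* on how the algorithm treats the missing bins.  The solvability map
quantifies this per pixel, empirically, for a concrete algorithm.

## 2. Geometry and system matrix

* **Image grid** — square pixels of width `px`; pixel `(r, c)` is centred at
  `((c − (nc−1)/2)·px, ((nr−1)/2 − r)·px)`, y increasing upward.
* **Extended detector** — every geometry is embedded in a virtual detector
  whose bins tile the full image diagonal, so the forward projection of any
  image is completely representable.  The physical detector occupies a
  contiguous run of extended bins (`measured_mask`).  The extension is chosen
  as the smallest bin count covering the diagonal whose lattice aligns with
  the physical bins (the physical `center_offset` must be an integer or
  half-integer multiple of the bin width), grown in steps of two until the
  physical bins fit inside.
* **Rays** — for view angle θ and detector coordinate *s*, the ray passes
  through `(s·cosθ, s·sinθ)` with direction `(−sinθ, cosθ)`.  Intersection
  lengths are computed exactly with an Amanatides–Woo / Siddon traversal
  (numba-compiled); rays exactly on pixel boundaries follow a floor
  convention, so shared boundaries are counted once.  The matrix is stored as
  scipy CSR; the backprojector is its literal transpose, so the pair is an
  exact adjoint (verified to ~1e−15 relative error in the tests).

## 3. Data simulation (inverse-crime avoidance)

Reconstructing data generated by the same discrete model that the solver
inverts is an inverse crime: it hides discretisation error and flatters every
algorithm.  `solvmap` therefore generates data on a refined model:

* phantom rasterised on a 3×-finer grid (pixel width /3);
* forward projected onto a detector with 3×-narrower bins (the fine extended
  detector is padded to exactly 3× the coarse extended bin count, so 3:1
  bin-averaging maps fine bins onto coarse bins exactly);
* **noise** — scaled Poisson: with `c` expected counts per unit line integral
  (default 500), each measured fine bin value `v` is replaced by
  `Poisson(c·v)/c`.  Unmeasured bins are left untouched and later discarded.
* **bin-down** — groups of 3 fine bins are averaged into each coarse bin; a
  coarse bin is *measured* only if all three fine bins are.

Phantoms are sums of 4 random ellipses (centres within 70 % of the half-side,
semi-axes between 15/384 and 90/384 of the image side, intensities 0.2–1.0),
smoothed with a σ=1 Gaussian and min–max normalised to [0, 1].  The ground
truth at reconstruction scale is the 3×3 block mean of the fine phantom.
Randomness is driven by `numpy.random.SeedSequence(entropy=seed, spawn_key=k)`
with `k = (0,)` for the phantom and `(1,)` for the noise, so phantom `m` of a
run uses seed `base_seed + m` and every stream is independent and
reproducible.

## 4. Reconstruction variants

Eight variants: {GD, ML-EM} × {with/without finite support} × {naive /
truncation-modified}.

* **GD** — `x ← x − α Aᵀ(Ax − p)` from the zero image.  Default step
  `α = 1.9 / λ_max(AᵀA)` with `λ_max` estimated by 50 power iterations; 1.9
  stays just inside the stability bound of 2 while damping the top modes
  fastest.  Divergence (non-finite iterate) raises an error naming `α`.
* **ML-EM** — the multiplicative Poisson-likelihood update from the all-ones
  image.  A guard `ε = 1e−12` in the ratio denominator prevents 0/0; pixels
  with zero sensitivity (`AᵀI = 0`) are held at zero.  The measured-bin
  log-likelihood is tracked and is non-decreasing.
* **Finite support** — GD zeroes pixels outside the support after every
  update; ML-EM only needs the support imposed on the initial image because a
  zero pixel stays zero under the multiplicative update.  In the Monte Carlo
  runs the support is the ground-truth object mask dilated by one pixel
  (dilation avoids fragile one-pixel boundaries).
* **Truncation handling** — *naive* mode leaves zeros in unmeasured extended
  bins, which the solver treats as real measurements of zero.  The
  *modification* overwrites each unmeasured bin with the current iterate's own
  forward projection before the update: for GD this zeroes the unmeasured
  residual; for ML-EM it forces the unmeasured data/model ratio to one.
  Either way missing bins exert no data-fit force.

Iteration counts default to 200 (GD) and 100 (ML-EM) in the full profile,
150/80 in the reduced profile — enough for the maps to stabilise, far short of
semi-convergence blow-up on noisy data.

## 5. Solvability map

For each phantom `m`, the per-pixel squared error
`e_i^(m) = (x̂_i^(m) − x_i^(m))²` is accumulated in a streaming running sum;
the map is the mean over phantoms.  For display the map can be compressed with
`v ↦ 1 − exp(−20 v)`, which maps 0 → 0 and saturates near 1 for `v ≳ 0.3`;
rate 20 puts the interesting error range [0, 0.1] on most of the grey scale.
The inverse transform is exact up to `v ≈ 0.5`, beyond which the forward map
saturates in double precision.

Two study profiles are built in: the full profile (128×128 reconstruction from
384×384 phantoms, 107-bin detector offset 39 bins or symmetric 185-bin
detector, 180 views, 1000 phantoms) and a reduced profile at exactly half the
linear scale (64×64 / 192×192, 53-bin detector offset 19 or 93-bin symmetric,
50 phantoms) that preserves the truncation fraction and asymmetry while
running in minutes; all package-level verification uses the reduced profile.

## 6. Fully measured region (ROI)

A pixel is *fully measured* when its projection line falls inside the measured
detector span at **every** view angle: with signed distance
`s(θ) = x·cosθ + y·sinθ`, the condition is `s(θ) ∈ [lo, hi]` for all θ over
180°.  For a symmetric detector of half-width `h` this is the central disk of
radius `h`; for an asymmetric detector (span `[lo, hi]` with `lo ≠ −hi`) it is
the intersection of the strips swept over all angles — a lens-shaped convex
region, **not** a disk of radius `min(|lo|, hi)`.  `roi_mask` implements the
definition directly by checking every view; `angular_coverage_map` returns the
fraction of views covering each pixel.  Interior-tomography theory predicts
pixels in this region are recoverable (given mild priors such as a known
support) while pixels outside are not; the maps reproduce this: ROI mean
errors sit roughly an order of magnitude below non-ROI object errors for the
support+modification variants.

## 7. Dense SVD oracle

For systems up to 64×64 pixels, the measured rows of `A` are assembled densely
and analysed by SVD:

* **condition number** — `σ_max / σ_min` over singular values above
  `1e−10 · σ_max`; if the numerical rank is below the number of pixels the
  system is flagged *effectively infinite* (AᵀA singular — exactly the
  under-determined truncated case).
* **`diag(A⁺A)`** — the diagonal of the projector onto the row space, equal to
  the squared row norms of `V_r`; each entry lies in [0, 1] and equals 1 for
  every pixel iff the system has full column rank.  The deficit
  `1 − diag(A⁺A)` is an algorithm-independent unsolvability score; on a 24×24
  truncated toy system it rank-correlates positively (Spearman ≈ 0.4) with the
  Monte Carlo map of the best variant.

The oracle is restricted to small grids (`MAX_DENSE_PIXELS = 4096`) because a
dense SVD of the full-profile matrix would need tens of gigabytes; the Monte
Carlo map is the scalable estimator, the oracle its ground-truth anchor.

## 8. Pipeline and reproducibility

`run_experiment` performs, per phantom: generate fine phantom → block-mean
truth → support mask → fine forward projection → Poisson noise → 3:1 bin-down
→ zero unmeasured bins → reconstruct with every requested variant → accumulate
squared errors.  The GD step size is estimated once per run.  State (running
sums, truth sum, last phantom index, config hash) is checkpointed to `.npz`
every 10 phantoms; `--resume` refuses to continue from a checkpoint whose
config hash does not match.  Outputs are HDF5 maps, display PNG images and a
JSON report with per-variant `{min, max, n}` summaries.

## 9. Assumptions and limitations

* 2-D parallel-beam only; no fan/cone beam, no detector blur or crosstalk, no
  scatter, beam hardening or electronic noise — the noise model is pure scaled
  Poisson on ideal line integrals.
* Phantoms are smooth ellipse composites; solvability maps are averages over
  *this* object class, and pathological objects can behave worse than the map
  suggests.
* The map measures the behaviour of a specific solver at a specific iteration
  count, not an information-theoretic limit; the SVD oracle provides the
  algorithm-independent counterpart on small systems only.
* The truncation modification stabilises reconstructions but does not restore
  missing information: outside the fully measured region the error remains
  object-dependent, merely bounded.
* Monte Carlo uncertainty of the map scales as `1/√M`; the default 1000
  phantoms resolve order-of-magnitude structure, not percent-level detail.
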