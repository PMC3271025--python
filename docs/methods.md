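# Methods

This note records the models, the synthetic world, and the numerical choices
behind `retinaquant`, in enough detail to judge what a green test does and
does not establish.

## Statistical models

**Constitutive expression.** When a promoter is uniformly active and protein
lifetimes far exceed mRNA lifetimes, the equilibrium protein level follows a
gamma distribution with shape `α = λ_m/γ_p` (mRNA production over protein
degradation) and scale `β = λ_p/γ_m` (protein production over mRNA
degradation). Measured levels carry a detection offset, so fits use a
*shifted* gamma `Δx + Gamma(α, β)`.

**Two-state mixture.** De-repressed Rhodopsin levels are modeled as a
mixture of cells producing at a basal (off) or high (on) rate, with
interconversion slow compared with expression equilibration (~1/γ_p, about a
day for Rhodopsin given measured half-lives; `half_life_to_rate` and
`switching_rate_upper_bound` encode the bound). Each state contributes a
shifted gamma: the off component is shifted by the detection floor Δx, the
on component by the **mode** of the off density, i.e.
`Δx + (α_off − 1)β_off` when `α_off > 1` and `Δx` otherwise (the boundary
case is a package decision; the mode of a gamma with shape ≤ 1 sits at its
support boundary). `p_on` is the fraction of cells in the on state.

**Shift estimation.** The detection floor of a real experiment is sharp, and
there the lowest observed level is a natural estimator of Δx. On data drawn
from a gamma with shape > 1, however, the sample minimum overestimates the
floor (the density vanishes at the boundary), and pinning the shift to the
minimum provably biases every other parameter: polishing from the generating
parameters yields log-likelihoods tens of nats above the pinned-minimum
optimum. Both fitters therefore *profile* the shift by default: a grid of
candidate shifts spanning the minimum down to 3 sample SDs below it, an
inner fixed-shift MLE at each candidate, and a bounded scalar refinement
around the best grid point (`shift_mode="mle"`). `shift_mode="min"` restores
the literal lowest-level rule; an explicit `shift=` overrides both.

**Optimization.** The inner two-state MLE runs bounded L-BFGS on
`(log α_off, log β_off, log α_on, log β_on, logit p_on)` from moment-based
starts split at data quantiles (plus log-normal jitter), tolerance 1e-9 on
the log-likelihood, four starts per candidate shift (≈50 starts overall).
Shapes and scales are bounded to `[0.05, 1000]`; the lower shape bound also
guards the classic unbounded-likelihood spike of location gammas with shape
< 1. With `fix_p_on=0` the model reduces exactly to the single shifted
gamma, which the tests verify (nesting).

At the published sample sizes (~1,000–4,500 cells) the recovered `p_on` of
overlapping mixtures (e.g. α_on < 1 with the on shift inside the off bulk)
has a sampling SD of ±0.02–0.03; single-seed recoveries within ±0.05 are the
realistic expectation and occasional 2σ excursions are sampling noise, not
optimizer failure.

**Nonparametrics.** The one-sided two-sample KS statistic is
`D+ = sup_x (ECDF_a − ECDF_b)`: a *stochastically smaller* first sample
gives a large D+ (the convention used for the per-cell repression
comparisons). KS and Spearman are thin wrappers over scipy, pinned by
brute-force oracles in the tests. Smoothed densities use the plain Gaussian
kernel sum with fixed bandwidth w (0.3 relative-intensity units for Rh3,
Rh6 and phalloidin; 0.5 for Rh5). Raw p-values are reported without
multiple-testing correction, matching how such comparison tables are
usually presented; a Bonferroni factor is a caller-side one-liner.

**Molecule conversion.** Anchoring the mean on-state level (11.0) to the
measured rhabdomeric Rhodopsin density (2.5×10⁵ molecules/µm³) gives
≈2.3×10⁴ molecules/µm³ per intensity unit.

## The synthetic retina

The generator renders what the pipeline assumes, not everything a retina is:

* **Geometry.** Hexagonal lattice (default spacing 13 µm, 37 ommatidia) on a
  spherical cap of radius 250 µm. The mounted tissue is modeled as a *bowl*:
  the surface is lowest over the retina's center, so central voxels lie
  under the least overlying tissue and image brightest, and central
  ommatidia — whose axes point at the center of curvature — are aligned with
  z and best resolved. Each ommatidium holds 7 cylindrical rhabdomeres
  (radius 0.5 µm): six outer cells on a circle (center spacing 2 µm)
  occupying slots of a 7-fold ring with one empty slot (the trapezoid's open
  side), plus the central R7/8 cell displaced off the mirror axis so that R3
  is strictly the farthest cell (≈5% margin over the runner-up — small, as
  in the real geometry, which is why labeling uses z-averaged centers). An
  optional helical twist (deg/µm) emulates the deep twisted region;
  chirality is configurable.
* **Optics.** Attenuation `exp(−c × overlying path)` with c = 0.02/µm by
  default; scattering as a fraction (0.05) of bright-cell intensity blurred
  with a 1.5 µm Gaussian — this produces exactly the low-level cross-cell
  contours the quantification must discard; additive Gaussian sensor noise
  (SD 2) and 8-bit clipping. Voxels 0.25 × 0.16 × 0.16 µm, 80 slices, z = 0
  deepest.
* **Expression calibration.** Ground-truth levels live on the I_l scale
  (the published parameter tables are in these units). A cell with level L
  is rendered as a rhabdomere plateau `P = b0 (L − 1)` against cytoplasm
  `b0 = 64`: the contour method's idealized response to a plateau is the
  midpoint `(b0 + P)/2 = b0 L/2` against a background reference `≈ b0/2`,
  so the measured I_l equals L. Consequences, deliberate and documented:
  the 8-bit range censors levels above `(255 + b0)/b0 ≈ 5` (as a real 8-bit
  acquisition would saturate), and cells at `L ≈ 2` render isointense with
  cytoplasm, produce no contour and are dropped by the empty-set rule —
  sensor noise fills this dead zone in realistic configurations, and the
  zero-noise recovery benchmark uses a level distribution (shifted gamma on
  ~[2.5, 4.5]) clear of both artifacts.
* **Not emulated.** Optical PSF beyond Gaussian scatter blur,
  photobleaching, chromatic effects, rhabdomere shrinkage with depth,
  biological structural variation between ommatidia. A green pipeline test
  therefore establishes algorithmic correctness on idealized geometry and
  optics, not robustness to all real-tissue pathology.

## Segmentation and tracing choices

* The max filter is **tiled** (non-overlapping 5×5 blocks each set to their
  maximum) per the literal description; the conventional sliding filter is
  a flag away. Detection thresholds are 20 equally spaced global levels over
  0–255, highest first; components are frozen on first entering the size
  range, and components touching a frozen region are treated as its
  continuation, which keeps per-slice regions disjoint.
* The acceptable region size defaults to 500–1000 px for unknown stacks;
  when a simulation config is at hand the pipeline derives the range from
  the rendered geometry (`π (r_px + 2)²` with ×[0.55, 1.35] slack), since
  region size is a geometry-dependent tuning input, not a universal
  constant.
* 3-D linking: overlap = ≥1 shared (y, x) pixel with a nascent ommatidium's
  footprint over the previous 4 slices; ties go to the largest overlap. The
  fused-region correction splits regions exceeding the running mean + 1 SD
  of the volume's recent sizes; the SD gets a 10% relative floor because on
  noiseless synthetic data the size SD collapses to ~0 and a literal 1-SD
  trigger would split every region that grows by a pixel. Split remainders
  seed new ommatidia only if they fall in the acceptable size range (the
  same gate new regions must pass). Volumes spanning fewer slices than the
  linking window are dropped; border-touching volumes are flagged, not
  removed.
* Tracing windows pool 5 slices; ties among equal-intensity pixels are
  broken by pixel index so runs are reproducible. The first window uses 10
  k-means restarts (best inertia kept) seeded from the config; subsequent
  windows are single runs seeded with the previous centers, which is what
  makes cluster indices follow cells. Empty per-slice member sets fall back
  to the window center.
* The z-range objective is the exhaustive product landscape
  `n_qualifying × interval_length` over all contiguous intervals with ≥2
  slices, ties toward longer then deeper intervals — a fully automatic
  version of an otherwise semi-automatic interval choice. The displacement
  cap defaults to 2 px (no printed value exists; exposed in config).
* Labeling decisions whose top two candidates differ by < 3% (relative) are
  refused (`undetermined`) and the ommatidium is excluded rather than
  guessed — including the unstated tie case of two equidistant-farthest
  cells. The distance chain is invariant under rotation, translation,
  uniform scaling and mirroring; chirality is reported separately from the
  orientation sign of (R3 − center) × (R2 − center).

## Quantification choices

* Contour levels are drawn from the **local** intensity range of each
  ommatidium crop (20…255-fixed grids are available as `level_mode=
  "global"`). Local levels are what make I_l invariant under per-slice
  intensity rescaling — the property the background normalization exists
  for — and what lets I_l exceed the ~20 ceiling a fixed 8-bit grid imposes.
* Quantification uses 128 levels (detection keeps 20). With 20 levels on
  8-bit data, the level spacing alone moves the background reference by
  ±10–15% per ommatidium depending on the crop maximum; at 128 levels
  quantization is subdominant (<2%).
* Overlap between a contour and a circular PR mask = any polyline vertex
  inside the disc, or the disc center enclosed by the contour; "encloses
  all 7" = all mask centers inside the polygon. Open contours clipped at
  the crop edge are closed along it and flagged. Bounding-box prefilters
  make the assignment O(contours) in practice.
* Masks are discs of radius 0.45 × (distance to the nearest other center),
  grown by at most 3 px only for cells left without contours, with one
  retry pass over previously unassigned contours. Slices with an empty
  background set are skipped (never imputed); cells with no usable slice
  are dropped and logged. Contours overlapping no mask and enclosing
  nothing are ignored (counts available in the assignment object).

## Toy network

`dP/dt = m (basal + v_max P^h / (P*^h + P^h)) − δ P` with defaults
`v_max = 1`, `basal = 0.05 v_max`, `P* = 1`, `h = 4`, `δ = 0.6`; `m` is the
dimensionless mRNA control parameter. Roots are bracketed on a 4000-point
grid over `[0, 1.5 m (basal + v_max)/δ + P*]` and refined by Brent's method;
stability is the sign of the net-rate slope. With these defaults the
bistable window is m ≈ 1.0–3.2, vanishing as h → 1. The rate balance is
written in the protein coordinate (the production machinery is not modeled
as a separate variable); that choice, the Hill form, and the defaults are
package decisions by analogy with classic bistable circuits.

## Known limitations

* The two-state MLE is a nonconvex optimization; pathological data can in
  principle defeat the restart strategy. Convergence failures raise rather
  than return garbage.
* Identity labeling relies on the trapezoid asymmetry; heavily distorted
  ommatidia are excluded (by design) rather than labeled, so yield trades
  against error rate via `tie_tol`.
* The generator's expression calibration inverts the analyzer's idealized
  plateau response; levels outside ~[1.2, 5] render censored or contourless
  (see above). Distribution fits to full-pipeline synthetic measurements are
  therefore truncated at the top end — the parameter-recovery benchmarks
  sample levels directly for exactly this reason.
* Runtime: ~15–20 s per default 37-ommatidium, 80-slice stack for
  segmentation + tracing + labeling on one CPU; contour quantification adds
  ~0.2 s per ommatidium-slice per channel.
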