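# retinaquant

Automated single-cell Rhodopsin quantification in 3-D confocal stacks of the
*Drosophila* compound eye, with a stochastic two-state model of gene
expression for the resulting level distributions.

## The problem

The fly retina is a lattice of ~800 ommatidia, each a stereotyped bundle of
eight photoreceptor neurons (PRs): six outer cells R1–R6 and the central
R7/R8 pair. Wild-type outer PRs express only Rhodopsin-1; loss of the
repressor Dve de-represses Rh3, Rh5 and Rh6 in outer PRs at levels that vary
widely from cell to cell. Quantifying that variability requires measuring
protein levels in thousands of single, *identified* cells inside a curved,
light-scattering 3-D tissue — by hand an impossible task. This package
implements an automated pipeline:

1. **Ommatidium segmentation** — each optical section of the phalloidin
   (actin) channel is max-filtered and thresholded at 20 contour levels from
   high to low; connected components are accepted once their size enters the
   expected ommatidial cross-section range, then linked through z with a
   sliding 5-slice window (deepest slice first) into 3-D ommatidium volumes,
   with fused-region splitting from running size statistics.
2. **Photoreceptor tracing** — within each ommatidium, k-means (k = 7) on the
   800 brightest structural-channel pixels of a 5-slice window; each window
   shifted by one slice is seeded with the previous centers, so cluster
   lineages follow cells. Cluster quality is the maximal center displacement
   between consecutive slices; the quantification z-range Z maximizes
   (number of well-resolved ommatidia) × (interval length).
3. **Geometric labeling** — R1–R6 identities follow from inter-center
   distances: the cell farthest from the central R7/8 cell is R3, its two
   nearest neighbors are R2/R4, their remaining neighbors R1/R5 (R1 has no
   further neighbor), R5's neighbor closest to R3 is R4, the other is R6.
4. **Local relative intensity** — per cell and slice, iso-intensity contours
   of the reporter channel are partitioned into sets exclusive to one PR
   mask (A_x), background contours enclosing all seven masks (B), and
   discarded multi-cell contours (scattering bleed). With length-weighted
   level averages I_pr (over A_x) and I_omma (over B),

   I_l = ⟨ I_pr / I_omma ⟩_Z

   is the cell's local relative intensity; normalizing by the local
   ommatidium background cancels the depth- and curvature-dependent
   attenuation of the tissue.
5. **Expression models** — distributions of I_l are fit by maximum
   likelihood to a shifted gamma (shape α = λ_m/γ_p, scale β = λ_p/γ_m;
   constitutive expression) and to a **two-state mixture**
   p(x) = (1 − p_on)·f_off(x) + p_on·f_on(x) of two shifted gammas, where
   the off component is shifted by the lowest detected level Δx, the on
   component by the mode of the off density, and p_on is the fraction of
   cells in the high-production state. Two-normal mixtures (for the bimodal
   Rh6 pattern in R8), one-sided two-sample Kolmogorov–Smirnov tests,
   Spearman correlations, Gaussian-kernel smoothed densities, the
   intensity→molecule-density conversion and half-life→rate relations
   complete the statistical layer.
6. **Toy bistable network** — a Hill-type positive-feedback model of
   Rhodopsin production, classified as monostable-low / bistable /
   monostable-high as a function of mRNA level; lowering mRNA (the modeled
   repressor action) restores monostability.

Because no raw retina stacks are publicly deposited, the package ships a
seeded **synthetic retina generator** (`retinaquant.simulate`): a hexagonal
ommatidial lattice on a spherical cap with tilted peripheral bundles, seven
cylindrical rhabdomeres per ommatidium in the stereotyped trapezoid,
depth-dependent attenuation, scattering halos, two-state per-cell expression
and 8-bit sensor noise — with complete ground truth for every stage.

## Worked example

```python
from retinaquant import (
    RetinaSimConfig, generate_retina_stack, PipelineConfig, run_pipeline,
    TwoStateGammaMixture, sample_two_state_levels,
)
from retinaquant.reference import TWO_STATE_FITS

cfg = RetinaSimConfig(n_ommatidia=7, n_slices=20, seed=2)
stack, truth = generate_retina_stack(cfg, {"Rh6": TWO_STATE_FITS["Rh6@2wk"]})
result = run_pipeline(stack, PipelineConfig(seed=0), sim_cfg=cfg)
print(len(result.volumes), "ommatidia,", len(result.resolved_ids), "resolved")
print(result.measurements.head(3))

levels, states = sample_two_state_levels(TWO_STATE_FITS["Rh5@2wk"], 2616, seed=3)
fit = TwoStateGammaMixture(random_state=0).fit(levels)
print(f"p_on = {fit.p_on_:.3f}  (simulated truth 0.68)")
```

prints

```
7 ommatidia, 7 resolved
   ommatidium pr_label channel       i_l  n_slices_used
0           0       R1     Rh6  1.997907             20
1           0       R5     Rh6  2.166707             20
2           0       R3     Rh6  5.003691             20
p_on = 0.663  (simulated truth 0.68)
```

Each `i_l` row is one photoreceptor's relative Rhodopsin level (1 ≈ the
ommatidium background; the basal Rh6 state sits near 2, the high state near
11); the mixture fit recovers the programmed on-state fraction.

## Acceptance script

`scripts/acceptance.py` re-runs the package's benchmark computations from
scratch: it simulates cell populations from the published bimodal and
two-state parameter sets and refits them by maximum likelihood, and runs the
full detection → tracing → labeling chain on 20 freshly generated synthetic
retinae to measure the photoreceptor-identity error rate:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

All randomness derives from `--seed`; the JSON maps each benchmark id to the
recomputed value and the problem size used.
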