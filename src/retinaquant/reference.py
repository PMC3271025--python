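"""Reference parameter sets for Rhodopsin expression in dve-mutant fly retinae.

These are published maximum-likelihood fits of the two-state expression model
(per Rhodopsin x developmental time point, dve-null retinae), the single-gamma
fits for wild-type outer photoreceptors, and the bimodal Rh6-in-R8 normal
mixture. They parameterize the synthetic retina generator and the
parameter-recovery benchmarks; `n` records the published sample size (number of
photoreceptor cells measured).
"""

from __future__ import annotations

from .params import GammaParams, NormalMixtureParams, TwoStateParams

#: Two-state shifted-gamma mixture fits, dve-null retinae.
#: Keyed "<rhodopsin>@<weeks>wk".
TWO_STATE_FITS: dict[str, TwoStateParams] = {
    "Rh3@0wk": TwoStateParams(5.6, 0.17, 2.0, 2.1, 0.34, shift=1.09, n=2737),
    "Rh3@1wk": TwoStateParams(5.6, 0.17, 1.9, 1.8, 0.35, shift=1.05, n=1169),
    "Rh3@2wk": TwoStateParams(5.6, 0.17, 1.0, 5.8, 0.32, shift=1.24, n=1736),
    "Rh3@4wk": TwoStateParams(9.0, 0.10, 0.59, 5.3, 0.20, shift=1.20, n=2163),
    "Rh5@0wk": TwoStateParams(2.0, 0.17, 0.32, 41.0, 0.02, shift=1.62, n=1687),
    "Rh5@1wk": TwoStateParams(1.8, 0.60, 0.63, 10.0, 0.31, shift=1.20, n=950),
    "Rh5@2wk": TwoStateParams(1.7, 0.58, 1.1, 3.3, 0.68, shift=1.20, n=2616),
    "Rh5@4wk": TwoStateParams(1.7, 0.59, 1.1, 4.8, 0.65, shift=1.20, n=1673),
    "Rh6@0wk": TwoStateParams(1.2, 0.40, 0.53, 11.0, 0.25, shift=1.65, n=4422),
    "Rh6@1wk": TwoStateParams(1.4, 0.41, 0.77, 4.3, 0.30, shift=1.65, n=2121),
    "Rh6@2wk": TwoStateParams(1.3, 0.44, 0.68, 5.9, 0.19, shift=1.65, n=4353),
    "Rh6@4wk": TwoStateParams(1.9, 0.55, 1.1, 5.0, 0.32, shift=1.40, n=3836),
}

#: Single shifted-gamma fits for wild-type outer photoreceptors (0 weeks).
WILDTYPE_GAMMA_FITS: dict[str, GammaParams] = {
    "Rh3": GammaParams(5.6, 0.17, shift=1.57, n=672),
    "Rh5": GammaParams(2.2, 0.17, shift=1.62, n=609),
    "Rh6": GammaParams(3.9, 0.12, shift=1.72, n=672),
}

#: Bimodal Rh6 distribution in R8 cells (dve-null, pooled over time points):
#: basal (off) and high (on) expression states, 80% of cells on.
RH6_R8_MIXTURE = NormalMixtureParams(
    mu_off=1.9, sigma_off=0.3, mu_on=11.0, sigma_on=5.1, weight_on=0.80
)

#: Rhodopsin density measured in the rhabdomere, molecules per cubic micron.
RHABDOMERE_RHODOPSIN_DENSITY = 2.5e5
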