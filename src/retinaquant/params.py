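"""Parameter containers for the expression models.

All levels are on the local relative intensity scale (I_l): a photoreceptor's
length-weighted contour intensity divided by its ommatidium's background
reference, averaged over the usable z-range. The gamma parameters follow the
standard burst interpretation: shape alpha = mRNA production rate over protein
degradation rate, scale beta = protein production rate over mRNA degradation
rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field


class ParameterError(ValueError):
    """Raised when a model parameter set violates its invariants."""


@dataclass(frozen=True)
class GammaParams:
    """Shifted gamma distribution: x ~ shift + Gamma(alpha, scale=beta)."""

    alpha: float
    beta: float
    shift: float = 0.0
    n: int | None = None

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and self.beta > 0):
            raise ParameterError(
                f"gamma shape/scale must be positive, got alpha={self.alpha}, beta={self.beta}"
            )
        if self.shift < 0:
            raise ParameterError(f"shift must be >= 0, got {self.shift}")

    @property
    def mode(self) -> float:
        """Location of the density maximum (at the boundary when alpha <= 1)."""
        if self.alpha > 1:
            return self.shift + (self.alpha - 1.0) * self.beta
        return self.shift

    @property
    def mean(self) -> float:
        return self.shift + self.alpha * self.beta

    @property
    def var(self) -> float:
        return self.alpha * self.beta**2


@dataclass(frozen=True)
class TwoStateParams:
    """Two-state expression mixture: off and on cells each follow a shifted gamma.

    The off component is shifted by ``shift`` (the lowest level detected in an
    experiment); the on component is shifted to the mode of the off density,
    i.e. shift + (alpha_off - 1) * beta_off when alpha_off > 1, else shift.
    ``p_on`` is the fraction of cells in the high-production state.
    """

    alpha_off: float
    beta_off: float
    alpha_on: float
    beta_on: float
    p_on: float
    shift: float = 0.0
    n: int | None = None

    def __post_init__(self) -> None:
        for name in ("alpha_off", "beta_off", "alpha_on", "beta_on"):
            v = getattr(self, name)
            if not v > 0:
                raise ParameterError(f"{name} must be positive, got {v}")
        if not 0.0 <= self.p_on <= 1.0:
            raise ParameterError(f"p_on must lie in [0, 1], got {self.p_on}")
        if self.shift < 0:
            raise ParameterError(f"shift must be >= 0, got {self.shift}")

    @property
    def off(self) -> GammaParams:
        return GammaParams(self.alpha_off, self.beta_off, self.shift)

    @property
    def shift_on(self) -> float:
        """On-component shift: the mode of the off density."""
        return self.off.mode

    @property
    def on(self) -> GammaParams:
        return GammaParams(self.alpha_on, self.beta_on, self.shift_on)

    @property
    def mean(self) -> float:
        return (1.0 - self.p_on) * self.off.mean + self.p_on * self.on.mean

    @property
    def var(self) -> float:
        m = self.mean
        second = (1.0 - self.p_on) * (self.off.var + self.off.mean**2) + self.p_on * (
            self.on.var + self.on.mean**2
        )
        return second - m * m


@dataclass(frozen=True)
class NormalMixtureParams:
    """Two-component normal mixture, components ordered by mean (off < on)."""

    mu_off: float
    sigma_off: float
    mu_on: float
    sigma_on: float
    weight_on: float

    def __post_init__(self) -> None:
        if not (self.sigma_off > 0 and self.sigma_on > 0):
            raise ParameterError("mixture component sigmas must be positive")
        if not 0.0 <= self.weight_on <= 1.0:
            raise ParameterError(f"weight_on must lie in [0, 1], got {self.weight_on}")
        if self.mu_off > self.mu_on:
            raise ParameterError("components must be ordered: mu_off <= mu_on")


@dataclass(frozen=True)
class KineticRates:
    """First-order rates of the constitutive expression model (per unit time)."""

    lambda_m: float  # mRNA production
    gamma_m: float  # mRNA degradation
    lambda_p: float  # protein production
    gamma_p: float  # protein degradation

    def __post_init__(self) -> None:
        for name in ("lambda_m", "gamma_m", "lambda_p", "gamma_p"):
            if not getattr(self, name) > 0:
                raise ParameterError(f"{name} must be positive")

    @property
    def alpha(self) -> float:
        return self.lambda_m / self.gamma_p

    @property
    def beta(self) -> float:
        return self.lambda_p / self.gamma_m

    @property
    def equilibration_time(self) -> float:
        """Relaxation timescale of protein levels, 1/gamma_p."""
        return 1.0 / self.gamma_p
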