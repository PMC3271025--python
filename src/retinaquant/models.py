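"""Stochastic models of single-cell Rhodopsin expression.

The protein-level distribution of a constitutively expressed gene (protein
lifetime >> mRNA lifetime) is a gamma distribution with shape alpha =
lambda_m/gamma_p and scale beta = lambda_p/gamma_m.  De-repressed Rhodopsins
in outer photoreceptors are modeled as a *two-state* mixture: cells produce
protein at either a basal (off) or a high (on) rate, interconverting slowly
compared to expression equilibration, so each state contributes a shifted
gamma component; ``p_on`` is the fraction of cells in the on state.  The off
component is shifted by the lowest level detected in an experiment and the on
component is shifted to the mode of the off density.

Estimators follow the scikit-learn protocol (``fit``, fitted attributes with a
trailing underscore, ``get_params``/``set_params``) and accept 1-D arrays or
single-column matrices of levels.  Thin module-level functions wrap them for
script use.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator, DensityMixin
from sklearn.mixture import GaussianMixture
from sklearn.utils.validation import check_is_fitted

from .params import (
    GammaParams,
    KineticRates,
    NormalMixtureParams,
    ParameterError,
    TwoStateParams,
)

__all__ = [
    "shifted_gamma_pdf",
    "shifted_gamma_cdf",
    "two_state_pdf",
    "two_state_cdf",
    "sample_shifted_gamma",
    "sample_two_state",
    "sample_normal_mixture",
    "ShiftedGamma",
    "TwoStateGammaMixture",
    "TwoNormalMixture",
    "fit_shifted_gamma",
    "fit_two_state",
    "fit_normal_mixture",
    "refit_mixture_weight",
    "ks_one_sample",
    "ks_two_sample_one_sided",
    "spearman_correlation",
    "repression_comparisons",
    "CO_RECRUITED_PAIRS",
    "SmoothedDensity",
    "smoothed_density",
    "kinetic_rates_from_gamma",
    "intensity_to_molecules",
    "half_life_to_rate",
    "switching_rate_upper_bound",
]


# --------------------------------------------------------------------------
# densities and samplers
# --------------------------------------------------------------------------

def shifted_gamma_pdf(x, params: GammaParams) -> np.ndarray:
    """Density of shift + Gamma(alpha, scale=beta); zero below the shift."""
    x = np.asarray(x, dtype=float)
    return stats.gamma.pdf(x, params.alpha, loc=params.shift, scale=params.beta)


def shifted_gamma_cdf(x, params: GammaParams) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return stats.gamma.cdf(x, params.alpha, loc=params.shift, scale=params.beta)


def two_state_pdf(x, params: TwoStateParams) -> np.ndarray:
    """Mixture density (1 - p_on) f_off(x) + p_on f_on(x) with the shift rules."""
    return (1.0 - params.p_on) * shifted_gamma_pdf(x, params.off) + (
        params.p_on
    ) * shifted_gamma_pdf(x, params.on)


def two_state_cdf(x, params: TwoStateParams) -> np.ndarray:
    return (1.0 - params.p_on) * shifted_gamma_cdf(x, params.off) + (
        params.p_on
    ) * shifted_gamma_cdf(x, params.on)


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def sample_shifted_gamma(params: GammaParams, n: int, seed=None) -> np.ndarray:
    rng = _as_rng(seed)
    return params.shift + rng.gamma(params.alpha, params.beta, size=n)


def sample_two_state(
    params: TwoStateParams, n: int, seed=None
) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``n`` levels from the two-state mixture.

    Returns ``(levels, states)`` where ``states`` is a boolean array, True for
    cells drawn from the on component.
    """
    if n < 1:
        raise ParameterError(f"n must be >= 1, got {n}")
    rng = _as_rng(seed)
    on = rng.random(n) < params.p_on
    levels = np.where(
        on,
        params.shift_on + rng.gamma(params.alpha_on, params.beta_on, size=n),
        params.shift + rng.gamma(params.alpha_off, params.beta_off, size=n),
    )
    return levels, on


def sample_normal_mixture(params: NormalMixtureParams, n: int, seed=None) -> np.ndarray:
    rng = _as_rng(seed)
    on = rng.random(n) < params.weight_on
    return np.where(
        on,
        rng.normal(params.mu_on, params.sigma_on, size=n),
        rng.normal(params.mu_off, params.sigma_off, size=n),
    )


def _column(X) -> np.ndarray:
    x = np.asarray(X, dtype=float)
    if x.ndim == 2 and x.shape[1] == 1:
        x = x[:, 0]
    if x.ndim != 1:
        raise ValueError(f"expected a 1-D sample of levels, got shape {x.shape}")
    if not np.all(np.isfinite(x)):
        raise ValueError("levels must be finite")
    return x


# --------------------------------------------------------------------------
# single shifted-gamma MLE
# --------------------------------------------------------------------------

def _shift_candidates(x: np.ndarray) -> np.ndarray:
    """Candidate off-component shifts at and below the smallest observation.

    The detection floor of an experiment lies at or below the smallest level
    measured; for gamma shapes > 1 the sample minimum overestimates the floor
    (the density vanishes at the boundary), so the likelihood is profiled over
    a grid reaching a few sample SDs below the minimum.
    """
    minx = float(np.min(x))
    sd = max(float(np.std(x)), 1e-12)
    cs = np.array([1e-4, 0.02, 0.05, 0.1, 0.2, 0.35, 0.5, 0.75, 1.0, 1.5, 2.2, 3.0])
    shifts = minx - cs * sd
    return np.unique(np.clip(shifts, 0.0, None))[::-1]


class ShiftedGamma(DensityMixin, BaseEstimator):
    """Maximum-likelihood shifted (three-parameter) gamma fit.

    With ``shift_mode="mle"`` (default) the shift is profiled: for each
    candidate shift the conditional gamma MLE is computed and the shift with
    the best profile likelihood is refined by bounded scalar search.  With
    ``shift_mode="min"`` the shift is pinned just below the minimum observed
    level (the literal lowest-level-detected rule, appropriate when the data
    have a hard detection floor).  An explicit ``shift`` overrides both.

    Parameters
    ----------
    shift : float or None
        Fixed shift; if None, estimated per ``shift_mode``.
    shift_mode : {"mle", "min"}
        Shift estimation rule.
    """

    def __init__(self, shift: float | None = None, shift_mode: str = "mle"):
        self.shift = shift
        self.shift_mode = shift_mode

    @staticmethod
    def _conditional_fit(x: np.ndarray, shift: float) -> tuple[float, float, float]:
        """Gamma MLE with the support boundary fixed at ``shift``; returns (a, b, ll)."""
        y = x - shift
        if np.any(y <= 0):
            return np.nan, np.nan, -np.inf
        alpha, _, beta = stats.gamma.fit(y, floc=0.0)
        ll = float(np.sum(stats.gamma.logpdf(y, alpha, scale=beta)))
        return float(alpha), float(beta), ll

    def fit(self, X, y=None):
        x = _column(X)
        if x.size < 2:
            raise ValueError("need at least 2 observations")
        if np.std(x) == 0:
            raise ValueError("degenerate sample: all observations identical")
        sd = float(np.std(x))
        minx = float(np.min(x))
        if self.shift is not None:
            shift = float(self.shift)
            alpha, beta, ll = self._conditional_fit(x, shift)
        elif self.shift_mode == "min":
            shift = minx - 1e-4 * sd
            alpha, beta, ll = self._conditional_fit(x, shift)
        elif self.shift_mode == "mle":
            cands = _shift_candidates(x)
            fits = [self._conditional_fit(x, s) for s in cands]
            lls = np.array([f[2] for f in fits])
            k = int(np.argmax(lls))
            lo = cands[min(k + 1, len(cands) - 1)]
            hi = min(cands[max(k - 1, 0)], minx - 1e-9 * sd)
            if hi > lo:
                res = optimize.minimize_scalar(
                    lambda s: -self._conditional_fit(x, s)[2],
                    bounds=(lo, hi),
                    method="bounded",
                    options={"xatol": 1e-4 * sd},
                )
                shift = float(res.x) if -res.fun >= lls[k] else float(cands[k])
            else:
                shift = float(cands[k])
            alpha, beta, ll = self._conditional_fit(x, shift)
        else:
            raise ValueError(f"unknown shift_mode {self.shift_mode!r}")
        if not np.isfinite(ll):
            raise RuntimeError("shifted-gamma fit did not converge to a finite likelihood")
        self.alpha_ = float(alpha)
        self.beta_ = float(beta)
        self.shift_ = float(shift)
        self.n_ = int(x.size)
        self.loglik_ = float(ll)
        return self

    @property
    def params_(self) -> GammaParams:
        check_is_fitted(self, "alpha_")
        return GammaParams(self.alpha_, self.beta_, max(self.shift_, 0.0), self.n_)

    def pdf(self, x) -> np.ndarray:
        return shifted_gamma_pdf(x, self.params_)

    def cdf(self, x) -> np.ndarray:
        return shifted_gamma_cdf(x, self.params_)

    def score(self, X, y=None) -> float:
        x = _column(X)
        return float(np.mean(np.log(np.maximum(self.pdf(x), 1e-300))))

    def sample(self, n_samples: int = 1, random_state=None) -> np.ndarray:
        return sample_shifted_gamma(self.params_, n_samples, random_state)


# --------------------------------------------------------------------------
# two-state gamma-mixture MLE
# --------------------------------------------------------------------------

def _two_state_nll(theta, y, son_from_off: bool, p_fixed: float | None) -> float:
    """Negative log-likelihood in shifted coordinates y = x - shift."""
    la_off, lb_off, la_on, lb_on = theta[:4]
    a_off, b_off = np.exp(la_off), np.exp(lb_off)
    a_on, b_on = np.exp(la_on), np.exp(lb_on)
    if p_fixed is None:
        p = 1.0 / (1.0 + np.exp(-theta[4]))
    else:
        p = p_fixed
    son = (a_off - 1.0) * b_off if (son_from_off and a_off > 1.0) else 0.0
    with np.errstate(over="ignore", under="ignore"):
        f_off = stats.gamma.pdf(y, a_off, scale=b_off)
        f_on = stats.gamma.pdf(y - son, a_on, scale=b_on)
    dens = (1.0 - p) * f_off + p * f_on
    if not np.all(np.isfinite(dens)):
        return 1e12
    ll = np.sum(np.log(np.maximum(dens, 1e-300)))
    return -ll if np.isfinite(ll) else 1e12


class TwoStateGammaMixture(DensityMixin, BaseEstimator):
    """Joint MLE of the two-state shifted-gamma expression mixture.

    Free parameters are (alpha_off, beta_off, alpha_on, beta_on, p_on); the
    on-component shift is tied to the mode of the off component.  Shape and
    scale parameters are optimized on the log scale and p_on on the logit
    scale by bounded quasi-Newton iterations from several moment-based starts
    per candidate shift; the off-component shift is profiled over a grid at
    and below the smallest observation (see ``_shift_candidates``) and the
    best profile point is refined by bounded scalar search.  The best
    log-likelihood overall is kept.

    ``shift_mode="min"`` instead pins the shift just below the minimum
    observed level (the lowest-level-detected rule for data with a hard
    detection floor).

    Parameters
    ----------
    n_restarts : int
        Optimizer starts per candidate shift.
    shift : float or None
        Fixed off-component shift; if None, estimated per ``shift_mode``.
    shift_mode : {"mle", "min"}
        Shift estimation rule.
    fix_p_on : float or None
        If set, the mixture fraction is held at this value (e.g. 0 reduces
        the model to a single shifted gamma).
    tol : float
        Convergence tolerance on the log-likelihood.
    random_state : int or None
        Seed for the restart jitter.
    """

    #: lower bound on shapes/scales; guards the alpha_on < 1 boundary spike
    _LOG_BOUNDS = (np.log(5e-2), np.log(1e3))

    def __init__(
        self,
        n_restarts: int = 6,
        shift: float | None = None,
        shift_mode: str = "mle",
        fix_p_on: float | None = None,
        tol: float = 1e-9,
        random_state: int | None = 0,
    ):
        self.n_restarts = n_restarts
        self.shift = shift
        self.shift_mode = shift_mode
        self.fix_p_on = fix_p_on
        self.tol = tol
        self.random_state = random_state

    def _starts(self, y: np.ndarray, rng: np.random.Generator):
        """Moment-based starting points split at data quantiles, plus jitter."""
        starts = []
        for q in (0.5, 0.65, 0.8):
            thr = np.quantile(y, q)
            lo = y[y <= thr]
            hi = y[y > thr]
            if hi.size < 5:
                hi = y[y > np.median(y)]
            m_lo, v_lo = np.mean(lo), max(np.var(lo), 1e-6)
            hi0 = np.maximum(hi - np.median(lo), 1e-3)
            m_hi, v_hi = np.mean(hi0), max(np.var(hi0), 1e-6)
            a_off = np.clip(m_lo**2 / v_lo, 0.1, 100.0)
            b_off = np.clip(v_lo / max(m_lo, 1e-9), 1e-3, 1e2)
            a_on = np.clip(m_hi**2 / v_hi, 0.1, 100.0)
            b_on = np.clip(v_hi / max(m_hi, 1e-9), 1e-3, 1e2)
            starts.append((a_off, b_off, a_on, b_on, 1.0 - q))
        base = list(starts)
        while len(starts) < max(self.n_restarts, 1):
            a_off, b_off, a_on, b_on, p = base[len(starts) % len(base)]
            jit = rng.lognormal(0.0, 0.5, size=4)
            starts.append(
                (
                    a_off * jit[0],
                    b_off * jit[1],
                    a_on * jit[2],
                    b_on * jit[3],
                    float(np.clip(p * rng.lognormal(0, 0.4), 0.02, 0.95)),
                )
            )
        return starts[: max(self.n_restarts, 1)]

    def _fit_at_shift(self, x: np.ndarray, shift: float, rng, theta_warm=None):
        """Best fixed-shift optimum over restarts; returns (nll, theta)."""
        yy = x - shift
        if np.any(yy <= 0):
            return np.inf, None
        bounds = [self._LOG_BOUNDS] * 4
        theta_list = []
        for a_off, b_off, a_on, b_on, p0 in self._starts(yy, rng):
            theta0 = np.log([a_off, b_off, a_on, b_on])
            if self.fix_p_on is None:
                p0 = np.clip(p0, 1e-4, 1 - 1e-4)
                theta0 = np.append(theta0, np.log(p0 / (1 - p0)))
            theta_list.append(theta0)
        if theta_warm is not None:
            theta_list.insert(0, theta_warm)
        full_bounds = bounds + ([(-12.0, 12.0)] if self.fix_p_on is None else [])
        best = (np.inf, None)
        for theta0 in theta_list:
            res = optimize.minimize(
                _two_state_nll,
                theta0,
                args=(yy, True, self.fix_p_on),
                method="L-BFGS-B",
                bounds=full_bounds,
                options={"ftol": self.tol, "maxiter": 800},
            )
            if res.fun < best[0]:
                best = (float(res.fun), res.x)
        return best

    def fit(self, X, y=None):
        x = _column(X)
        if x.size < 10:
            raise ValueError("need at least 10 observations for a mixture fit")
        rng = np.random.default_rng(self.random_state)
        sd = max(float(np.std(x)), 1e-12)
        minx = float(np.min(x))

        if self.shift is not None:
            shift = float(self.shift)
            best_nll, best_theta = self._fit_at_shift(x, shift, rng)
        elif self.shift_mode == "min":
            shift = minx - 1e-4 * sd
            best_nll, best_theta = self._fit_at_shift(x, shift, rng)
        elif self.shift_mode == "mle":
            cands = _shift_candidates(x)
            # profile the shift, chaining the incumbent optimum as a warm
            # start so the optimizer tracks the likelihood ridge across shifts
            results = []
            warm = None
            for s in cands:
                nll_s, th_s = self._fit_at_shift(x, s, rng, theta_warm=warm)
                results.append((nll_s, th_s))
                if th_s is not None and (warm is None or nll_s <= min(r[0] for r in results)):
                    warm = th_s
            nlls = np.array([r[0] for r in results])
            k = int(np.argmin(nlls))
            shift, (best_nll, best_theta) = float(cands[k]), results[k]
            # refine the shift around the best grid point, warm-started
            lo = cands[min(k + 1, len(cands) - 1)]
            hi = min(cands[max(k - 1, 0)], minx - 1e-9 * sd)
            if hi > lo and best_theta is not None:
                warm = best_theta

                def prof(s):
                    nll, th = self._fit_at_shift(x, s, rng, theta_warm=warm)
                    return nll

                res = optimize.minimize_scalar(
                    prof, bounds=(lo, hi), method="bounded", options={"xatol": 1e-3 * sd}
                )
                if res.fun < best_nll:
                    shift = float(res.x)
                    best_nll, best_theta = self._fit_at_shift(
                        x, shift, rng, theta_warm=warm
                    )
        else:
            raise ValueError(f"unknown shift_mode {self.shift_mode!r}")

        if best_theta is None or not np.isfinite(best_nll) or best_nll >= 1e12:
            raise RuntimeError(
                "two-state fit failed to converge from all starts "
                f"(n={x.size}, best objective={best_nll})"
            )
        a_off, b_off, a_on, b_on = np.exp(best_theta[:4])
        if self.fix_p_on is None:
            p = float(1.0 / (1.0 + np.exp(-best_theta[4])))
        else:
            p = float(self.fix_p_on)
        self.alpha_off_ = float(a_off)
        self.beta_off_ = float(b_off)
        self.alpha_on_ = float(a_on)
        self.beta_on_ = float(b_on)
        self.p_on_ = p
        self.shift_ = float(shift)
        self.loglik_ = float(-best_nll)
        self.n_ = int(x.size)
        return self

    @property
    def params_(self) -> TwoStateParams:
        check_is_fitted(self, "p_on_")
        return TwoStateParams(
            self.alpha_off_,
            self.beta_off_,
            self.alpha_on_,
            self.beta_on_,
            self.p_on_,
            max(self.shift_, 0.0),
            self.n_,
        )

    @property
    def shift_on_(self) -> float:
        return self.params_.shift_on

    def pdf(self, x) -> np.ndarray:
        return two_state_pdf(x, self.params_)

    def cdf(self, x) -> np.ndarray:
        return two_state_cdf(x, self.params_)

    def predict_proba(self, X) -> np.ndarray:
        """Posterior probability of the on state for each cell."""
        x = _column(X)
        p = self.params_
        f_on = p.p_on * shifted_gamma_pdf(x, p.on)
        tot = two_state_pdf(x, p)
        return np.where(tot > 0, f_on / np.maximum(tot, 1e-300), 0.0)

    def predict(self, X) -> np.ndarray:
        """Classify each cell as on (True) or off (False)."""
        return self.predict_proba(X) > 0.5

    def score(self, X, y=None) -> float:
        x = _column(X)
        return float(np.mean(np.log(np.maximum(self.pdf(x), 1e-300))))

    def sample(self, n_samples: int = 1, random_state=None):
        return sample_two_state(self.params_, n_samples, random_state)


# --------------------------------------------------------------------------
# two-normal mixture
# --------------------------------------------------------------------------

class TwoNormalMixture(DensityMixin, BaseEstimator):
    """MLE two-component normal mixture; components ordered by mean."""

    def __init__(self, n_restarts: int = 10, tol: float = 1e-6, random_state: int | None = 0):
        self.n_restarts = n_restarts
        self.tol = tol
        self.random_state = random_state

    def fit(self, X, y=None):
        x = _column(X)
        if x.size < 4:
            raise ValueError("need at least 4 observations")
        gm = GaussianMixture(
            n_components=2,
            covariance_type="spherical",
            n_init=self.n_restarts,
            tol=self.tol,
            reg_covar=1e-10,
            random_state=self.random_state,
        ).fit(x[:, None])
        means = gm.means_[:, 0]
        sds = np.sqrt(gm.covariances_)
        order = np.argsort(means)
        lo, hi = order[0], order[1]
        self.mu_off_ = float(means[lo])
        self.sigma_off_ = float(sds[lo])
        self.mu_on_ = float(means[hi])
        self.sigma_on_ = float(sds[hi])
        self.weight_on_ = float(gm.weights_[hi])
        self.loglik_ = float(gm.score(x[:, None]) * x.size)
        self.n_ = int(x.size)
        return self

    @property
    def params_(self) -> NormalMixtureParams:
        check_is_fitted(self, "weight_on_")
        return NormalMixtureParams(
            self.mu_off_, self.sigma_off_, self.mu_on_, self.sigma_on_, self.weight_on_
        )

    def pdf(self, x) -> np.ndarray:
        p = self.params_
        x = np.asarray(x, dtype=float)
        return (1 - p.weight_on) * stats.norm.pdf(x, p.mu_off, p.sigma_off) + (
            p.weight_on
        ) * stats.norm.pdf(x, p.mu_on, p.sigma_on)

    def cdf(self, x) -> np.ndarray:
        p = self.params_
        x = np.asarray(x, dtype=float)
        return (1 - p.weight_on) * stats.norm.cdf(x, p.mu_off, p.sigma_off) + (
            p.weight_on
        ) * stats.norm.cdf(x, p.mu_on, p.sigma_on)


def refit_mixture_weight(samples, fixed: NormalMixtureParams, tol: float = 1e-10) -> float:
    """One-parameter MLE of the on-state weight with component shapes held fixed.

    Used to re-estimate the on fraction per retina against pooled component
    fits. The likelihood is concave in the weight, so EM iterations on the
    single free parameter converge to the unique optimum.
    """
    x = _column(samples)
    f_off = stats.norm.pdf(x, fixed.mu_off, fixed.sigma_off)
    f_on = stats.norm.pdf(x, fixed.mu_on, fixed.sigma_on)
    w = float(np.clip(fixed.weight_on, 1e-6, 1 - 1e-6))
    for _ in range(10_000):
        denom = (1 - w) * f_off + w * f_on
        resp = np.where(denom > 0, w * f_on / np.maximum(denom, 1e-300), 0.5)
        w_new = float(np.mean(resp))
        if abs(w_new - w) < tol:
            return w_new
        w = w_new
    return w


# --------------------------------------------------------------------------
# nonparametric comparisons
# --------------------------------------------------------------------------

def ks_one_sample(samples, cdf) -> tuple[float, float]:
    """Two-sided one-sample Kolmogorov-Smirnov test against a model cdf."""
    x = _column(samples)
    if x.size < 5:
        import warnings

        warnings.warn("KS test on fewer than 5 samples is unreliable", stacklevel=2)
    res = stats.kstest(x, cdf)
    return float(res.statistic), float(res.pvalue)


def ks_two_sample_one_sided(a, b) -> tuple[float, float]:
    """One-sided two-sample KS test.

    Returns ``(D_plus, p)`` with D+ = sup_x (ECDF_a(x) - ECDF_b(x)): when the
    first sample is stochastically *smaller* than the second, its ECDF sits
    above and D+ is large. Used for the cell-specific repression comparisons
    (one photoreceptor versus the pooled others, co-recruited pairs, ...).
    """
    a = _column(a)
    b = _column(b)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    res = stats.ks_2samp(a, b, alternative="greater")
    return float(res.statistic), float(res.pvalue)


def spearman_correlation(x, y) -> tuple[float, float]:
    """Spearman rank correlation with tie handling; two-sided p-value."""
    x = _column(x)
    y = _column(y)
    if x.size != y.size:
        raise ValueError("paired samples must have equal length")
    if x.size < 5:
        raise ValueError("need at least 5 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman correlation undefined for constant input")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


#: outer-photoreceptor groupings compared for shared repression tendencies
CO_RECRUITED_PAIRS = (("R2", "R5"), ("R3", "R4"), ("R1", "R6"))


def repression_comparisons(
    measurements,
    value: str = "i_l",
    label: str = "pr_label",
    channel_col: str = "channel",
) -> "pd.DataFrame":
    """Cell-specific repression tests on a measurement table.

    For each reporter channel, runs one-sided two-sample KS tests (first
    sample stochastically smaller => large D+, i.e. *more repressed*) for
    three comparison families: each outer photoreceptor against the pooled
    other outer cells; the pooled {R2, R4, R5} group against {R1, R3, R6};
    and the co-recruited pairs (R2/R5, R3/R4, R1/R6) against each other.
    Raw p-values are reported with their -log10 transform; no multiple-
    testing correction is applied.
    """
    import pandas as pd

    df = pd.DataFrame(measurements)
    outer = [f"R{i}" for i in range(1, 7)]
    rows = []

    def add(channel, name, a_labels, b_labels, sub):
        a = sub.loc[sub[label].isin(a_labels), value].to_numpy(dtype=float)
        b = sub.loc[sub[label].isin(b_labels), value].to_numpy(dtype=float)
        if a.size == 0 or b.size == 0:
            return
        d, p = ks_two_sample_one_sided(a, b)
        rows.append(
            {
                "channel": channel,
                "comparison": name,
                "group_a": "+".join(a_labels),
                "group_b": "+".join(b_labels),
                "n_a": int(a.size),
                "n_b": int(b.size),
                "D_plus": d,
                "p": p,
                "neg_log10_p": float(-np.log10(max(p, 1e-300))),
            }
        )

    for channel, sub in df.groupby(channel_col):
        for pr in outer:
            rest = [x for x in outer if x != pr]
            add(channel, f"{pr}_vs_rest", [pr], rest, sub)
            add(channel, f"rest_vs_{pr}", rest, [pr], sub)
        add(channel, "R2R4R5_vs_R1R3R6", ["R2", "R4", "R5"], ["R1", "R3", "R6"], sub)
        add(channel, "R1R3R6_vs_R2R4R5", ["R1", "R3", "R6"], ["R2", "R4", "R5"], sub)
        for (a1, a2), (b1, b2) in (
            (CO_RECRUITED_PAIRS[1], CO_RECRUITED_PAIRS[0]),
            (CO_RECRUITED_PAIRS[0], CO_RECRUITED_PAIRS[2]),
            (CO_RECRUITED_PAIRS[1], CO_RECRUITED_PAIRS[2]),
        ):
            add(channel, f"{a1}{a2}_vs_{b1}{b2}", [a1, a2], [b1, b2], sub)
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# smoothed densities
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SmoothedDensity:
    """Gaussian-kernel smoothed density P(x) = (1/n) sum_i K_w(x - x_i)."""

    grid: np.ndarray
    density: np.ndarray
    bandwidth: float

    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.grid))


def smoothed_density(samples, w: float, grid=None, n_grid: int = 512) -> SmoothedDensity:
    """Kernel-smoothed histogram with a Gaussian kernel of SD ``w``.

    The published bandwidths are 0.3 relative-intensity units for Rh3, Rh6 and
    the structural (phalloidin) channel, and 0.5 for Rh5.
    """
    if not w > 0:
        raise ParameterError(f"bandwidth must be positive, got {w}")
    x = _column(samples)
    if grid is None:
        lo = x.min() - 4 * w
        hi = x.max() + 4 * w
        grid = np.linspace(lo, hi, n_grid)
    grid = np.asarray(grid, dtype=float)
    dens = stats.norm.pdf(grid[:, None], loc=x[None, :], scale=w).mean(axis=1)
    return SmoothedDensity(grid=grid, density=dens, bandwidth=float(w))


# --------------------------------------------------------------------------
# rates, molecule conversion, timescales
# --------------------------------------------------------------------------

def kinetic_rates_from_gamma(
    alpha: float, beta: float, gamma_p: float, gamma_m: float
) -> KineticRates:
    """Invert the burst relations alpha = lambda_m/gamma_p, beta = lambda_p/gamma_m.

    Degradation rates are not identifiable from protein-level distributions
    alone and must be supplied from independent turnover measurements.
    """
    if not (alpha > 0 and beta > 0 and gamma_p > 0 and gamma_m > 0):
        raise ParameterError("all rates and gamma parameters must be positive")
    return KineticRates(
        lambda_m=alpha * gamma_p, gamma_m=gamma_m, lambda_p=beta * gamma_m, gamma_p=gamma_p
    )


def intensity_to_molecules(
    i_l, mean_on: float, rhabdomere_density: float = 2.5e5
) -> np.ndarray:
    """Convert relative intensity to Rhodopsin molecules per cubic micron.

    Anchors the mean on-state level to the measured rhabdomere Rhodopsin
    density (2.5e5 molecules/um^3), so one intensity unit corresponds to
    density/mean_on molecules/um^3.
    """
    if not mean_on > 0:
        raise ParameterError("mean_on must be positive")
    return np.asarray(i_l, dtype=float) * (rhabdomere_density / mean_on)


def half_life_to_rate(t_half: float) -> float:
    """First-order rate constant ln(2)/t_half."""
    if not t_half > 0:
        raise ParameterError("half-life must be positive")
    return float(np.log(2.0) / t_half)


def switching_rate_upper_bound(equilibration_time: float) -> float:
    """Upper bound on the on<->off switching rate: 1 / equilibration time.

    State switching must be slow compared to expression equilibration (itself
    of order the protein lifetime) for the two-state mixture to hold.
    """
    if not equilibration_time > 0:
        raise ParameterError("equilibration time must be positive")
    return 1.0 / equilibration_time


# --------------------------------------------------------------------------
# thin functional wrappers
# --------------------------------------------------------------------------

def fit_shifted_gamma(samples, shift: float | None = None) -> GammaParams:
    return ShiftedGamma(shift=shift).fit(samples).params_


def fit_two_state(samples, n_restarts: int = 10, random_state: int | None = 0) -> TwoStateParams:
    return (
        TwoStateGammaMixture(n_restarts=n_restarts, random_state=random_state)
        .fit(samples)
        .params_
    )


def fit_normal_mixture(samples, random_state: int | None = 0) -> NormalMixtureParams:
    return TwoNormalMixture(random_state=random_state).fit(samples).params_
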