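"""Generative observer model: decision, memory, estimation, and the
post-feedback model variants.

The observer sees a noisy measurement m ~ N(theta, sigma_s), decides the
stimulus category by comparing the posterior p(C|m) computed under
one-sided conditioned priors p(theta|C), then later estimates theta from a
memory sample m_m of the measurement.  The estimate is the posterior mean
under the prior conditioned on the observer's own categorical judgment
("self-consistent" inference).  After invalid-judgment feedback, five model
variants describe the estimate on incorrect trials:

* ``1a`` (prior only): the judgment overwrote memory; the estimate is the
  mean of the feedback-corrected prior.  Independent of sensory noise.
* ``1b`` (uncertainty only): heuristic; the estimate is sigma_s away from
  the reference on the feedback-corrected side.
* ``2a`` (flip decision): memory intact; self-consistent inference with the
  feedback-corrected category.
* ``2b`` (flip decision, resampled): memory recall resamples until the
  sample lies on the feedback-corrected side of the reference; the proposal
  is N(m, sqrt(sigma_s^2 + sigma_m^2)).
* ``2c`` (flip decision, reweighted): like 2a but the likelihood width is
  inflated to (1 + KL) * sigma_s, where KL is the Bayesian surprise of the
  negative feedback given the decision posterior at m.

Predictive estimate distributions are computed on the quadrature grid,
convolved with motor noise N(0, sigma_0) and integrated over 0.5-deg bins;
they are checked elsewhere against forward Monte-Carlo simulation of the
same generative rules.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import logsumexp, ndtr

from .grid import DEFAULT_GRID, OrientationGrid
from .params import ObserverParams
from .priors import CategoryLabel, ConditionedPrior, make_conditioned_prior

__all__ = [
    "MODEL_IDS",
    "PredictiveDistribution",
    "ObserverEngine",
    "DegenerateMeasurementError",
    "CriterionNotFoundError",
    "EmptyConditionError",
    "category_likelihood",
    "decision_posterior",
    "decide",
    "psychometric",
    "memory_sample_density",
    "estimate_posterior_mean",
    "model1a_estimate",
    "model1b_estimate",
    "kl_surprise",
    "reweighted_sigma",
    "resample_memory",
    "predictive_distribution",
    "estimate_bin_edges",
]

MODEL_IDS = ("1a", "1b", "2a", "2b", "2c", "selfconsistent")
BIN_WIDTH = 0.5
_SQRT2PI = float(np.sqrt(2.0 * np.pi))
_PROB_EPS = 1e-12


class DegenerateMeasurementError(ValueError):
    """Measurement lies outside the support of every category likelihood."""


class CriterionNotFoundError(RuntimeError):
    """The decision log-posterior-ratio has no sign change on the grid."""


class EmptyConditionError(RuntimeError):
    """The conditioned-on event (e.g. an incorrect choice) has ~zero probability."""


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def _norm_pdf(x: np.ndarray, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * (x / sigma) ** 2) / (sigma * _SQRT2PI)


def category_likelihood(
    m,
    sigma_s: float,
    prior_cw: ConditionedPrior,
    prior_ccw: ConditionedPrior,
    grid: OrientationGrid,
):
    """Likelihood of the measurement under each category.

    p(m|C) = integral N(m; theta, sigma_s) p(theta|C) dtheta, by grid
    quadrature.  Returns ``(p_m_cw, p_m_ccw)`` with the shape of ``m``.
    """
    if sigma_s <= 0:
        raise ValueError("sigma_s must be > 0")
    m_arr = np.atleast_1d(np.asarray(m, dtype=float))
    out = []
    for prior in (prior_cw, prior_ccw):
        s = prior.support
        th = grid.theta[s]
        pw = (prior.density * grid.weights)[s]
        dens = _norm_pdf(m_arr[:, None] - th[None, :], sigma_s)
        out.append(dens @ pw)
    if np.isscalar(m) or np.ndim(m) == 0:
        return float(out[0][0]), float(out[1][0])
    return out[0], out[1]


def _log_category_likelihood(
    m_arr: np.ndarray,
    sigma_s: float,
    prior: ConditionedPrior,
    grid: OrientationGrid,
) -> np.ndarray:
    """log p(m|C) computed stably in the log domain (far tails included)."""
    s = prior.support
    th = grid.theta[s]
    logpw = np.log((prior.density * grid.weights)[s])
    logk = -0.5 * ((m_arr[:, None] - th[None, :]) / sigma_s) ** 2 - np.log(sigma_s * _SQRT2PI)
    return logsumexp(logk + logpw[None, :], axis=1)


def decision_posterior(
    m,
    params: ObserverParams,
    grid: OrientationGrid = DEFAULT_GRID,
    sigma_s: float | None = None,
    priors: tuple[ConditionedPrior, ConditionedPrior] | None = None,
):
    """Posterior probability of the clockwise category given the measurement.

    p(cw|m) = p(m|cw) p_cw / (p(m|cw) p_cw + p(m|ccw) (1 - p_cw)).
    ``sigma_s`` defaults to the low-noise width.
    """
    if sigma_s is None:
        sigma_s = params.sigma_s_low
    if priors is None:
        priors = (
            make_conditioned_prior(CategoryLabel.CW, params.alpha_cw, params.beta, grid),
            make_conditioned_prior(CategoryLabel.CCW, params.alpha_ccw, params.beta, grid),
        )
    if params.p_cw == 1.0:
        return 1.0 if np.ndim(m) == 0 else np.ones(np.shape(m))
    if params.p_cw == 0.0:
        return 0.0 if np.ndim(m) == 0 else np.zeros(np.shape(m))
    m_arr = np.atleast_1d(np.asarray(m, dtype=float))
    log_cw = _log_category_likelihood(m_arr, sigma_s, priors[0], grid) + np.log(params.p_cw)
    log_ccw = _log_category_likelihood(m_arr, sigma_s, priors[1], grid) + np.log(1.0 - params.p_cw)
    if np.any(np.isneginf(log_cw) & np.isneginf(log_ccw)):
        raise DegenerateMeasurementError("measurement outside the support of both categories")
    p = 1.0 / (1.0 + np.exp(log_ccw - log_cw))
    return float(p[0]) if np.ndim(m) == 0 else p


def decide(
    m: float,
    params: ObserverParams,
    rng: np.random.Generator,
    grid: OrientationGrid = DEFAULT_GRID,
    sigma_s: float | None = None,
) -> CategoryLabel:
    """MAP category choice; an exact posterior tie is broken by a fair coin."""
    p = decision_posterior(m, params, grid, sigma_s=sigma_s)
    if abs(p - 0.5) < 1e-12:  # exact tie up to quadrature round-off
        return CategoryLabel.CW if rng.random() < 0.5 else CategoryLabel.CCW
    return CategoryLabel.CW if p > 0.5 else CategoryLabel.CCW


def psychometric(
    theta,
    noise_level: str,
    params: ObserverParams,
    grid: OrientationGrid = DEFAULT_GRID,
):
    """Probability of choosing 'cw' as a function of the true orientation.

    The MAP decision is a threshold rule in m, so the psychometric function
    is 1 - Phi((m* - theta) / sigma_s) with m* the criterion where the
    posterior odds cross 1.
    """
    engine = ObserverEngine(params, grid)
    return engine.psychometric(theta, noise_level)


def memory_sample_density(
    theta: float,
    sigma_s: float,
    sigma_m: float,
    grid: OrientationGrid = DEFAULT_GRID,
) -> np.ndarray:
    """Density of the memory sample m_m given theta: N(theta, sqrt(sigma_s^2+sigma_m^2))."""
    if sigma_s <= 0:
        raise ValueError("sigma_s must be > 0")
    sd = float(np.hypot(sigma_s, sigma_m))
    return _norm_pdf(grid.theta - theta, sd)


def _posterior_mean_given_mm(
    mm: np.ndarray,
    prior: ConditionedPrior,
    sigma_like,
    grid: OrientationGrid,
) -> np.ndarray:
    """Posterior-mean estimates for memory samples ``mm`` (log-domain stable).

    ``sigma_like`` may be scalar or per-row (Model 2c reweighting).
    """
    s = prior.support
    th = grid.theta[s]
    logpw = np.log((prior.density * grid.weights)[s])
    sig = np.asarray(sigma_like, dtype=float)
    inv2 = 0.5 / sig**2
    if inv2.ndim == 1:
        inv2 = inv2[:, None]
    logw = -inv2 * (mm[:, None] - th[None, :]) ** 2 + logpw[None, :]
    mx = logw.max(axis=1, keepdims=True)
    w = np.exp(logw - mx)
    return (w @ th) / w.sum(axis=1)


def estimate_posterior_mean(
    m_m,
    category: CategoryLabel,
    sigma_like: float,
    prior: ConditionedPrior,
    grid: OrientationGrid = DEFAULT_GRID,
):
    """Posterior-mean orientation estimate given a memory sample.

    posterior(theta) ~ N(m_m; theta, sigma_like) * p(theta | category);
    the estimate is its mean (L2 loss).  Always finite, with the sign of
    the conditioning category.
    """
    if sigma_like <= 0:
        raise ValueError("sigma_like must be > 0")
    if prior.category is not category:
        raise ValueError("prior does not match the conditioning category")
    mm_arr = np.atleast_1d(np.asarray(m_m, dtype=float))
    est = _posterior_mean_given_mm(mm_arr, prior, sigma_like, grid)
    return float(est[0]) if np.ndim(m_m) == 0 else est


def model1a_estimate(category_f: CategoryLabel, prior: ConditionedPrior) -> float:
    """Prior-only estimate after negative feedback: the conditioned-prior mean."""
    if prior.category is not category_f:
        raise ValueError("prior does not match the feedback-corrected category")
    return prior.mean


def model1b_estimate(category_f: CategoryLabel, sigma_s: float) -> float:
    """Uncertainty-only heuristic: sigma_s away from the reference on the correct side."""
    if sigma_s <= 0:
        raise ValueError("sigma_s must be > 0")
    return category_f.sign * sigma_s


def kl_surprise(p_choice):
    """Bayesian surprise of negative feedback.

    KL between the decision posterior (q, 1-q) and its flipped counterpart:
    (2q - 1) * ln(q / (1 - q)).  Symmetric about q = 0.5 where it is zero.
    """
    q = np.asarray(p_choice, dtype=float)
    eps = 1e-12
    if np.any(q <= 0.0) or np.any(q >= 1.0):
        warnings.warn("p_choice at {0,1} clamped to [1e-12, 1-1e-12] in kl_surprise")
        q = np.clip(q, eps, 1.0 - eps)
    kl = (2.0 * q - 1.0) * np.log(q / (1.0 - q))
    return float(kl) if np.ndim(p_choice) == 0 else kl


def reweighted_sigma(sigma_s: float, kl) -> float:
    """Surprise-inflated sensory width for Model 2c: (1 + KL) * sigma_s."""
    if np.any(np.asarray(kl) < 0):
        raise ValueError("kl must be >= 0")
    return (1.0 + kl) * sigma_s


def resample_memory(
    m: float,
    sigma_s: float,
    sigma_m: float,
    category_f: CategoryLabel,
    rng: np.random.Generator,
    max_draws: int = 10_000,
) -> tuple[float, int]:
    """Conditioned memory recall (Model 2b).

    Draws proposals N(m, sqrt(sigma_s^2 + sigma_m^2)) until one lies on the
    feedback-corrected side of the reference; returns the accepted sample and
    the number of proposals used (a response-time proxy).  If ``max_draws``
    is exhausted, falls back to an exact truncated-Gaussian draw and returns
    ``n_draws = max_draws`` (with a warning).
    """
    sigma_c = float(np.hypot(sigma_s, sigma_m))
    sgn = category_f.sign
    for n in range(1, max_draws + 1):
        x = rng.normal(m, sigma_c)
        if x * sgn > 0:
            return float(x), n
    warnings.warn("resample_memory hit the draw cap; using analytic truncated sampling")
    # inverse-CDF draw from the one-sided truncation
    u = rng.random()
    if sgn > 0:
        lo_cdf = ndtr((0.0 - m) / sigma_c)
        z = lo_cdf + u * (1.0 - lo_cdf)
    else:
        hi_cdf = ndtr((0.0 - m) / sigma_c)
        z = u * hi_cdf
    from scipy.special import ndtri

    return float(m + sigma_c * ndtri(z)), max_draws


def estimate_bin_edges(grid: OrientationGrid = DEFAULT_GRID) -> np.ndarray:
    """Estimate-histogram bin edges: width 0.5 deg, aligned to multiples of 0.5."""
    lo = np.ceil(grid.lo / BIN_WIDTH) * BIN_WIDTH
    hi = np.floor(grid.hi / BIN_WIDTH) * BIN_WIDTH
    n = int(round((hi - lo) / BIN_WIDTH))
    return lo + BIN_WIDTH * np.arange(n + 1)


@dataclass(frozen=True)
class PredictiveDistribution:
    """Binned predictive distribution p(theta_hat | theta, noise, correctness)."""

    model_id: str
    theta: float
    noise_level: str
    correctness: str
    bin_edges: np.ndarray = field(repr=False, compare=False)
    bin_probs: np.ndarray = field(repr=False, compare=False)

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def mean(self) -> float:
        """Mean estimate under the binned distribution."""
        return float(np.dot(self.bin_centers, self.bin_probs))

    @property
    def sd(self) -> float:
        mu = self.mean
        return float(np.sqrt(np.dot((self.bin_centers - mu) ** 2, self.bin_probs)))

    def prob_of(self, estimate) -> np.ndarray:
        """Probability of the bin containing each estimate (0 outside range)."""
        est = np.atleast_1d(np.asarray(estimate, dtype=float))
        idx = np.searchsorted(self.bin_edges, est, side="right") - 1
        ok = (idx >= 0) & (idx < self.bin_probs.size)
        out = np.zeros(est.size)
        out[ok] = self.bin_probs[idx[ok]]
        return out if np.ndim(estimate) else float(out[0])


# ---------------------------------------------------------------------------
# engine: cached grid computations for one parameter set
# ---------------------------------------------------------------------------

class ObserverEngine:
    """Caches priors, decision criteria, estimation curves and memory kernels
    for one parameter set, and assembles predictive distributions.

    Building an engine is cheap; heavy pieces are computed lazily and reused
    across stimulus conditions (the optimiser builds one engine per candidate
    parameter vector).
    """

    def __init__(self, params: ObserverParams, grid: OrientationGrid = DEFAULT_GRID):
        self.params = params
        self.grid = grid
        self.prior_cw = make_conditioned_prior(CategoryLabel.CW, params.alpha_cw, params.beta, grid)
        self.prior_ccw = make_conditioned_prior(
            CategoryLabel.CCW, params.alpha_ccw, params.beta, grid
        )
        self._criterion: dict[str, float] = {}
        self._curves: dict[tuple, np.ndarray] = {}
        self._memk: dict[tuple, np.ndarray] = {}

    def prior(self, category: CategoryLabel) -> ConditionedPrior:
        return self.prior_cw if category is CategoryLabel.CW else self.prior_ccw

    # -- decision stage ----------------------------------------------------

    def _log_odds(self, m_arr: np.ndarray, sigma_s: float) -> np.ndarray:
        p = self.params
        return (
            _log_category_likelihood(m_arr, sigma_s, self.prior_cw, self.grid)
            - _log_category_likelihood(m_arr, sigma_s, self.prior_ccw, self.grid)
            + np.log(p.p_cw)
            - np.log(1.0 - p.p_cw)
        )

    def criterion(self, noise_level: str) -> float:
        """Measurement criterion m*: the root of the posterior log-odds."""
        if noise_level not in self._criterion:
            p = self.params
            if p.p_cw in (0.0, 1.0):
                self._criterion[noise_level] = -np.inf if p.p_cw == 1.0 else np.inf
                return self._criterion[noise_level]
            sigma_s = p.sigma_s(noise_level)
            f = self._log_odds(self.grid.theta, sigma_s)
            sign_change = np.nonzero(np.diff(np.sign(f)) != 0)[0]
            if sign_change.size == 0:
                raise CriterionNotFoundError(
                    "posterior log-odds has no sign change on the grid"
                )
            i = sign_change[0]
            a, b = self.grid.theta[i], self.grid.theta[i + 1]
            root = brentq(
                lambda m: float(self._log_odds(np.array([m]), sigma_s)[0]), a, b, xtol=1e-10
            )
            self._criterion[noise_level] = float(root)
        return self._criterion[noise_level]

    def psychometric(self, theta, noise_level: str):
        """p(choose cw | theta) = 1 - Phi((m* - theta) / sigma_s)."""
        mstar = self.criterion(noise_level)
        if not np.isfinite(mstar):
            val = 1.0 if mstar == -np.inf else 0.0
            return val if np.ndim(theta) == 0 else np.full(np.shape(theta), val)
        sigma_s = self.params.sigma_s(noise_level)
        out = 1.0 - ndtr((mstar - np.asarray(theta, dtype=float)) / sigma_s)
        return float(out) if np.ndim(theta) == 0 else out

    def p_choice(self, theta: float, noise_level: str, chosen: CategoryLabel) -> float:
        pc = self.psychometric(theta, noise_level)
        return pc if chosen is CategoryLabel.CW else 1.0 - pc

    # -- estimation stage --------------------------------------------------

    def estimate_curve(self, category: CategoryLabel, sigma_like: float) -> np.ndarray:
        """Posterior-mean estimate for every grid value of the memory sample."""
        key = (category, round(float(sigma_like), 10))
        if key not in self._curves:
            self._curves[key] = _posterior_mean_given_mm(
                self.grid.theta, self.prior(category), sigma_like, self.grid
            )
        return self._curves[key]

    def _memory_kernel(self, sigma: float, trunc_sign: int | None) -> np.ndarray:
        """Column-stochastic kernel K[j, i] mapping m masses to m_m masses."""
        key = (round(float(sigma), 10), trunc_sign)
        if key not in self._memk:
            g = self.grid.theta
            dens = _norm_pdf(g[:, None] - g[None, :], sigma)
            if trunc_sign is not None:
                dens = dens * ((g[:, None] * trunc_sign) > 0)
            masses = dens * self.grid.weights[:, None]
            col = masses.sum(axis=0)
            col[col == 0.0] = np.inf  # columns with no admissible sample get zero mass
            self._memk[key] = masses / col[None, :]
        return self._memk[key]

    def _memory_marginal(
        self, p_m: np.ndarray, sigma: float, trunc_sign: int | None = None
    ) -> np.ndarray:
        if sigma == 0.0 and trunc_sign is None:
            return p_m
        q = self._memory_kernel(sigma, trunc_sign) @ p_m
        total = q.sum()
        if total <= 0:
            raise EmptyConditionError("memory marginal has no mass")
        return q / total

    # -- predictive assembly -----------------------------------------------

    def _measurement_masses(self, theta: float, noise_level: str, chosen: CategoryLabel):
        """Masses of m on the grid restricted to the decision region of ``chosen``."""
        sigma_s = self.params.sigma_s(noise_level)
        mstar = self.criterion(noise_level)
        z = (mstar - theta) / sigma_s
        p_region = 1.0 - ndtr(z) if chosen is CategoryLabel.CW else ndtr(z)
        if p_region < _PROB_EPS:
            raise EmptyConditionError(
                f"choice {chosen.value} at theta={theta}, {noise_level} noise has "
                f"probability {p_region:.3g}"
            )
        g = self.grid.theta
        mask = g >= mstar if chosen is CategoryLabel.CW else g <= mstar
        p_m = _norm_pdf(g - theta, sigma_s) * self.grid.weights * mask
        total = p_m.sum()
        if total <= 0:
            raise EmptyConditionError("decision region carries no grid mass")
        return p_m / total, float(p_region)

    def branch_atoms(
        self,
        theta: float,
        noise_level: str,
        chosen: CategoryLabel,
        est_category: CategoryLabel,
        rule: str,
    ) -> tuple[np.ndarray, np.ndarray]:
        """Pre-motor estimate atoms (values, masses) for one decision branch.

        ``rule`` is one of 'bayes' (self-consistent / Model 2a), '1a', '1b',
        '2b', '2c'.  The measurement is conditioned on the decision region of
        ``chosen``; estimation uses the prior of ``est_category``.
        """
        p = self.params
        sigma_s = p.sigma_s(noise_level)
        if rule == "1a":
            return np.array([self.prior(est_category).mean]), np.array([1.0])
        if rule == "1b":
            return np.array([model1b_estimate(est_category, sigma_s)]), np.array([1.0])
        p_m, _ = self._measurement_masses(theta, noise_level, chosen)
        sigma_c = p.sigma_like_for(noise_level)
        if rule == "bayes":
            q = self._memory_marginal(p_m, p.sigma_m)
            return self.estimate_curve(est_category, sigma_c), q
        if rule == "2b":
            q = self._memory_marginal(p_m, sigma_c, trunc_sign=est_category.sign)
            return self.estimate_curve(est_category, sigma_c), q
        if rule == "2c":
            return self._atoms_2c(p_m, sigma_s, est_category)
        raise ValueError(f"unknown estimation rule {rule!r}")

    def _atoms_2c(
        self, p_m: np.ndarray, sigma_s: float, est_category: CategoryLabel
    ) -> tuple[np.ndarray, np.ndarray]:
        """Model 2c atoms: the likelihood width varies with m through the surprise."""
        p = self.params
        # drop measurement nodes carrying < 1e-9 of the total mass
        order = np.argsort(p_m)[::-1]
        keep_n = int(np.searchsorted(np.cumsum(p_m[order]), 1.0 - 1e-9)) + 1
        nodes = np.zeros(p_m.size, dtype=bool)
        nodes[order[:keep_n]] = True
        m_nodes = self.grid.theta[nodes]
        pm = p_m[nodes]
        pm = pm / pm.sum()
        p_cw = decision_posterior(
            m_nodes, p, self.grid, sigma_s=sigma_s, priors=(self.prior_cw, self.prior_ccw)
        )
        # surprise is symmetric in the posterior, so the chosen side is immaterial
        kl = kl_surprise(np.clip(p_cw, 1e-12, 1.0 - 1e-12))
        sig_like = np.hypot(reweighted_sigma(sigma_s, kl), p.sigma_m)
        prior = self.prior(est_category)
        if p.sigma_m == 0.0:
            e = _posterior_mean_given_mm(m_nodes, prior, sig_like, self.grid)
            return e, pm
        # memory blur: identical node offsets around every m, weights shared;
        # the blur is smooth, so the offset step may be coarser than the grid
        step = max(self.grid.step, p.sigma_m / 6.0)
        half = int(np.ceil(5.0 * p.sigma_m / step))
        offs = step * np.arange(-half, half + 1)
        nu = _norm_pdf(offs, p.sigma_m)
        nu = nu / nu.sum()
        e_list, w_list = [], []
        chunk = 128
        for i0 in range(0, m_nodes.size, chunk):
            sl = slice(i0, i0 + chunk)
            mm = (m_nodes[sl, None] + offs[None, :]).ravel()
            sig_rows = np.repeat(sig_like[sl], offs.size)
            e_list.append(_posterior_mean_given_mm(mm, prior, sig_rows, self.grid))
            w_list.append((pm[sl, None] * nu[None, :]).ravel())
        return np.concatenate(e_list), np.concatenate(w_list)

    # -- motor convolution / binning -----------------------------------------

    def bin_atoms(
        self, e: np.ndarray, w: np.ndarray, bin_edges: np.ndarray
    ) -> np.ndarray:
        """Motor-noise convolution of point atoms, integrated over bins."""
        sigma_0 = self.params.sigma_0
        keep = w > w.max() * 1e-9
        e, w = e[keep], w[keep]
        w = w / w.sum()
        if sigma_0 == 0.0:
            probs = np.zeros(bin_edges.size - 1)
            idx = np.clip(
                np.searchsorted(bin_edges, e, side="right") - 1, 0, probs.size - 1
            )
            np.add.at(probs, idx, w)
        else:
            cdf = ndtr((bin_edges[None, :] - e[:, None]) / sigma_0)
            probs = w @ np.diff(cdf, axis=1)
        total = probs.sum()
        return probs / total if total > 0 else probs

    def atom_bin_prob(
        self, e: np.ndarray, w: np.ndarray, lo: np.ndarray, hi: np.ndarray
    ) -> np.ndarray:
        """Probability mass of atoms + motor noise inside each [lo, hi) bin."""
        sigma_0 = self.params.sigma_0
        keep = w > w.max() * 1e-10
        if not keep.all():
            e, w = e[keep], w[keep] / w[keep].sum()
        if sigma_0 == 0.0:
            ind = (e[:, None] >= lo[None, :]) & (e[:, None] < hi[None, :])
            return w @ ind
        return w @ (
            ndtr((hi[None, :] - e[:, None]) / sigma_0)
            - ndtr((lo[None, :] - e[:, None]) / sigma_0)
        )

    # -- full predictive distributions ---------------------------------------

    def _branch_rule(
        self, model_id: str, correctness: str, chosen: CategoryLabel
    ) -> tuple[CategoryLabel, str]:
        """(estimation category, rule) for a decision branch of a model."""
        if correctness == "correct":
            return chosen, "bayes"
        # incorrect branch: feedback-corrected category is the flip of the choice
        c_f = chosen.flip()
        if model_id == "selfconsistent":
            # the pure self-consistent observer ignores feedback
            return chosen, "bayes"
        rule = {"1a": "1a", "1b": "1b", "2a": "bayes", "2b": "2b", "2c": "2c"}[model_id]
        return c_f, rule

    def _conditional_atoms(
        self, theta: float, noise_level: str, model_id: str, correctness: str
    ) -> tuple[np.ndarray, np.ndarray]:
        """Atoms of the estimate conditioned on correctness (or the full marginal)."""
        if correctness == "marginal":
            ec, wc = self._conditional_atoms(theta, noise_level, model_id, "correct")
            try:
                ei, wi = self._conditional_atoms(theta, noise_level, model_id, "incorrect")
            except EmptyConditionError:
                return ec, wc
            p_corr = self._p_correct(theta, noise_level)
            return np.concatenate([ec, ei]), np.concatenate([wc * p_corr, wi * (1 - p_corr)])
        if theta == 0.0:
            # the true category is a fair coin independent of the measurement,
            # so conditioning on correctness leaves the choice distribution intact
            pcw = self.psychometric(0.0, noise_level)
            es, ws = [], []
            for chosen, wgt in ((CategoryLabel.CW, pcw), (CategoryLabel.CCW, 1.0 - pcw)):
                if wgt < _PROB_EPS:
                    continue
                est_cat, rule = self._branch_rule(model_id, correctness, chosen)
                e, w = self.branch_atoms(0.0, noise_level, chosen, est_cat, rule)
                es.append(e)
                ws.append(w * wgt)
            return np.concatenate(es), np.concatenate(ws)
        c_true = CategoryLabel.of_orientation(theta)
        chosen = c_true if correctness == "correct" else c_true.flip()
        est_cat, rule = self._branch_rule(model_id, correctness, chosen)
        e, w = self.branch_atoms(theta, noise_level, chosen, est_cat, rule)
        if rule in ("1a", "1b"):
            # constant-estimate rules still require the conditioned event to occur
            self._measurement_masses(theta, noise_level, chosen)
        return e, w

    def _p_correct(self, theta: float, noise_level: str) -> float:
        if theta == 0.0:
            return 0.5
        c_true = CategoryLabel.of_orientation(theta)
        return self.p_choice(theta, noise_level, c_true)

    def predictive(
        self,
        theta: float,
        noise_level: str,
        model_id: str = "selfconsistent",
        correctness: str = "correct",
        bin_edges: np.ndarray | None = None,
    ) -> PredictiveDistribution:
        """Binned predictive estimate distribution for one condition."""
        if model_id not in MODEL_IDS:
            raise ValueError(f"unknown model_id {model_id!r}")
        if correctness not in ("correct", "incorrect", "marginal"):
            raise ValueError(f"unknown correctness {correctness!r}")
        if bin_edges is None:
            bin_edges = estimate_bin_edges(self.grid)
        e, w = self._conditional_atoms(theta, noise_level, model_id, correctness)
        probs = self.bin_atoms(e, w, bin_edges)
        return PredictiveDistribution(
            model_id=model_id,
            theta=float(theta),
            noise_level=noise_level,
            correctness=correctness,
            bin_edges=bin_edges,
            bin_probs=probs,
        )


def predictive_distribution(
    theta: float,
    noise_level: str,
    model_id: str,
    correctness: str,
    params: ObserverParams,
    grid: OrientationGrid = DEFAULT_GRID,
) -> PredictiveDistribution:
    """Functional wrapper around :meth:`ObserverEngine.predictive`."""
    return ObserverEngine(params, grid).predictive(theta, noise_level, model_id, correctness)
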