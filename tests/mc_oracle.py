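"""Forward Monte-Carlo oracle for predictive estimate distributions.

Simulates the generative rules directly — conditional measurement draws,
memory recall (plain, conditioned-resampled, or surprise-reweighted),
posterior-mean estimation, motor noise — and histograms the estimates at
0.5 deg.  Used to cross-check the grid-based marginalisation.
"""

import numpy as np
from scipy.stats import truncnorm

from scobs import CategoryLabel, decision_posterior, kl_surprise, reweighted_sigma
from scobs.observer import ObserverEngine, _posterior_mean_given_mm, estimate_bin_edges


def _conditional_measurements(rng, n, theta, sigma_s, mstar, chosen):
    """Draw m ~ N(theta, sigma_s) conditioned on the decision region of ``chosen``."""
    if chosen is CategoryLabel.CW:
        a, b = (mstar - theta) / sigma_s, np.inf
    else:
        a, b = -np.inf, (mstar - theta) / sigma_s
    return truncnorm.rvs(a, b, loc=theta, scale=sigma_s, size=n, random_state=rng)


def mc_predictive(
    params,
    grid,
    theta,
    noise_level,
    model_id,
    correctness,
    n=100_000,
    seed=0,
):
    """Monte-Carlo estimate-histogram for one condition (bin probs at 0.5 deg)."""
    rng = np.random.default_rng(seed)
    engine = ObserverEngine(params, grid)
    sigma_s = params.sigma_s(noise_level)
    mstar = engine.criterion(noise_level)
    sigma_c = params.sigma_like_for(noise_level)

    if theta == 0.0:
        pcw = engine.psychometric(0.0, noise_level)
        chosen_cw = rng.random(n) < pcw
    else:
        c_true = CategoryLabel.of_orientation(theta)
        want = c_true if correctness == "correct" else c_true.flip()
        chosen_cw = np.full(n, want is CategoryLabel.CW)

    est = np.empty(n)
    for is_cw in (True, False):
        sel = chosen_cw == is_cw
        if not sel.any():
            continue
        chosen = CategoryLabel.CW if is_cw else CategoryLabel.CCW
        k = int(sel.sum())
        m = _conditional_measurements(rng, k, theta, sigma_s, mstar, chosen)
        if correctness == "correct":
            est_cat = chosen
        else:
            est_cat = chosen if model_id == "selfconsistent" else chosen.flip()
        prior = engine.prior(est_cat)

        if correctness == "incorrect" and model_id == "1a":
            est[sel] = prior.mean
            continue
        if correctness == "incorrect" and model_id == "1b":
            est[sel] = est_cat.sign * sigma_s
            continue
        if correctness == "incorrect" and model_id == "2b":
            sgn = est_cat.sign
            a = np.where(sgn > 0, (0.0 - m) / sigma_c, -np.inf)
            b = np.where(sgn > 0, np.inf, (0.0 - m) / sigma_c)
            mm = truncnorm.rvs(a, b, loc=m, scale=sigma_c, random_state=rng)
            sig_like = np.full(k, sigma_c)
        elif correctness == "incorrect" and model_id == "2c":
            mm = m + params.sigma_m * rng.standard_normal(k)
            pcw_m = decision_posterior(
                m, params, grid, sigma_s=sigma_s,
                priors=(engine.prior_cw, engine.prior_ccw),
            )
            kl = kl_surprise(np.clip(pcw_m, 1e-12, 1 - 1e-12))
            sig_like = np.hypot(reweighted_sigma(sigma_s, kl), params.sigma_m)
        else:  # self-consistent / Model 2a: plain memory recall
            mm = m + params.sigma_m * rng.standard_normal(k)
            sig_like = np.full(k, sigma_c)

        out = np.empty(k)
        for i0 in range(0, k, 4096):
            sl = slice(i0, min(i0 + 4096, k))
            out[sl] = _posterior_mean_given_mm(mm[sl], prior, sig_like[sl], grid)
        est[sel] = out

    est = est + params.sigma_0 * rng.standard_normal(n)
    edges = estimate_bin_edges(grid)
    counts, _ = np.histogram(est, bins=edges)
    return counts / n, edges


def total_variation(p, q):
    return 0.5 * float(np.abs(np.asarray(p) - np.asarray(q)).sum())
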