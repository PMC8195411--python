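"""Joint maximum-likelihood fit of the self-consistent observer.

The likelihood has two factors: the probability of every categorical choice
(all trials, via the psychometric function) and the probability of the
0.5-deg estimate bin on correct trials (via the grid-based predictive
distribution conditioned on the choice).  The negative log-likelihood is
minimised with Nelder-Mead in transformed coordinates (log for widths,
logit for the category prior) from multiple random starts; the category
prior is fixed at 0.5 in symmetric (Experiment-1) mode and free in
asymmetric (Experiment-2) mode.  Motor noise sigma_0 is measured
independently and is supplied, never fitted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import minimize

from .data import TrialTable
from .grid import OrientationGrid
from .observer import ObserverEngine, BIN_WIDTH
from .params import ObserverParams
from .priors import CategoryLabel

__all__ = ["FitConfig", "FitResult", "FitFailureError", "joint_nll", "fit_correct_trials"]

PROB_FLOOR = 1e-6  # floor on model bin probabilities before taking logs

DEFAULT_BOUNDS = {
    "sigma_s_low": (0.5, 40.0),
    "sigma_s_high": (0.5, 40.0),
    "sigma_m": (0.01, 20.0),
    "alpha": (5.0, 60.0),
    "alpha_cw": (5.0, 60.0),
    "alpha_ccw": (5.0, 60.0),
    "beta": (0.5, 40.0),
    "p_cw": (0.05, 0.95),
}


class FitFailureError(RuntimeError):
    """No optimizer restart converged."""


@dataclass
class FitConfig:
    """Optimisation settings for the joint fit."""

    experiment: str = "exp1"  # 'exp1' fixes p_cw = 0.5 and shares alpha
    sigma_0: float = 1.5
    n_restarts: int = 30
    seed: int = 0
    bounds: dict = field(default_factory=lambda: dict(DEFAULT_BOUNDS))
    xatol: float = 2e-3
    fatol: float = 2e-2
    maxiter: int = 2000
    grid_step: float = 0.4
    grid_halfwidth: float = 90.0

    def make_grid(self) -> OrientationGrid:
        return OrientationGrid(-self.grid_halfwidth, self.grid_halfwidth, self.grid_step)

    @property
    def param_names(self) -> list[str]:
        if self.experiment == "exp1":
            return ["sigma_s_low", "sigma_s_high", "sigma_m", "alpha", "beta"]
        if self.experiment == "exp2":
            return [
                "sigma_s_low",
                "sigma_s_high",
                "sigma_m",
                "alpha_cw",
                "alpha_ccw",
                "beta",
                "p_cw",
            ]
        raise ValueError(f"unknown experiment mode {self.experiment!r}")


@dataclass
class FitResult:
    """Best-fit parameters plus the per-restart optimisation record."""

    best_params: ObserverParams
    nll: float
    restarts: list
    config: FitConfig

    def to_json(self, path=None) -> str:
        payload = {
            "best_params": self.best_params.to_dict(),
            "nll": self.nll,
            "restarts": self.restarts,
            "config": {
                k: v
                for k, v in self.config.__dict__.items()
                if not isinstance(v, dict) or k == "bounds"
            },
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, path) -> "FitResult":
        payload = json.loads(Path(path).read_text())
        cfg = FitConfig(**{k: v for k, v in payload["config"].items() if k != "bounds"})
        cfg.bounds = payload["config"].get("bounds", dict(DEFAULT_BOUNDS))
        return cls(
            best_params=ObserverParams.from_dict(payload["best_params"]),
            nll=payload["nll"],
            restarts=payload["restarts"],
            config=cfg,
        )


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

def _estimate_bin_bounds(estimates: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    lo = np.floor(estimates / BIN_WIDTH) * BIN_WIDTH
    return lo, lo + BIN_WIDTH


def _prepare_tables(correct_table: TrialTable, all_trials_table: TrialTable):
    """Condition summaries so the objective never touches pandas."""
    decision = []
    adf = all_trials_table.df
    for (theta, level), g in adf.groupby(["theta_deg", "noise_level"], sort=False):
        if level not in ("low", "high"):
            raise ValueError(f"noise level {level!r} has no parameter in the model")
        n_cw = int((g["choice"].astype(str).str.lower() == "cw").sum())
        decision.append((float(theta), level, n_cw, len(g)))

    estimation = []
    cdf = correct_table.df
    for (theta, level, choice), g in cdf.groupby(
        ["theta_deg", "noise_level", "choice"], sort=False
    ):
        est = g["estimate_deg"].to_numpy(dtype=float)
        lo, hi = _estimate_bin_bounds(est)
        pairs, counts = np.unique(np.stack([lo, hi], axis=1), axis=0, return_counts=True)
        estimation.append(
            (float(theta), level, CategoryLabel.parse(choice), pairs[:, 0], pairs[:, 1], counts)
        )
    return decision, estimation


def _nll_prepared(params: ObserverParams, prepared, grid: OrientationGrid) -> float:
    decision, estimation = prepared
    engine = ObserverEngine(params, grid)
    ll = 0.0
    for theta, level, n_cw, n in decision:
        p = float(np.clip(engine.psychometric(theta, level), 1e-12, 1 - 1e-12))
        ll += n_cw * np.log(p) + (n - n_cw) * np.log(1.0 - p)
    for theta, level, chosen, lo, hi, counts in estimation:
        e, w = engine.branch_atoms(theta, level, chosen, chosen, "bayes")
        probs = engine.atom_bin_prob(e, w, lo, hi)
        ll += float(np.dot(counts, np.log(np.maximum(probs, PROB_FLOOR))))
    return -ll


def joint_nll(
    params: ObserverParams,
    correct_table: TrialTable,
    all_trials_table: TrialTable,
    grid: OrientationGrid,
) -> float:
    """Negative log-likelihood of the self-consistent observer.

    Decision term over all trials (psychometric choice probabilities),
    estimation term over correct trials only (0.5-deg estimate bins under
    the choice-conditioned predictive distribution, floored at 1e-6).
    """
    return _nll_prepared(params, _prepare_tables(correct_table, all_trials_table), grid)


# ---------------------------------------------------------------------------
# optimisation
# ---------------------------------------------------------------------------

def _vec_to_params(x: np.ndarray, config: FitConfig) -> tuple[ObserverParams, float]:
    """Map the transformed vector to parameters, returning a bound penalty."""
    names = config.param_names
    natural = {}
    for name, xi in zip(names, x):
        natural[name] = 1.0 / (1.0 + np.exp(-xi)) if name == "p_cw" else np.exp(xi)
    penalty = 0.0
    for name, v in natural.items():
        lo, hi = config.bounds[name]
        if v < lo:
            penalty += ((lo - v) / lo) ** 2
            natural[name] = lo
        elif v > hi:
            penalty += ((v - hi) / hi) ** 2
            natural[name] = hi
    # the prior support must stay inside the quadrature grid
    support_cap = config.grid_halfwidth - 4.0 * config.grid_step
    alpha_max = max(natural.get("alpha", 0.0), natural.get("alpha_cw", 0.0),
                    natural.get("alpha_ccw", 0.0))
    if alpha_max + natural["beta"] > support_cap:
        excess = alpha_max + natural["beta"] - support_cap
        penalty += (excess / support_cap) ** 2
        natural["beta"] = max(config.bounds["beta"][0], support_cap - alpha_max)
    if config.experiment == "exp1":
        params = ObserverParams.symmetric(
            natural["sigma_s_low"],
            natural["sigma_s_high"],
            natural["sigma_m"],
            natural["alpha"],
            natural["beta"],
            sigma_0=config.sigma_0,
        )
    else:
        params = ObserverParams(
            sigma_s_low=natural["sigma_s_low"],
            sigma_s_high=natural["sigma_s_high"],
            sigma_m=natural["sigma_m"],
            alpha_cw=natural["alpha_cw"],
            alpha_ccw=natural["alpha_ccw"],
            beta=natural["beta"],
            p_cw=natural["p_cw"],
            sigma_0=config.sigma_0,
        )
    return params, 1e4 * penalty


def _random_init(rng: np.random.Generator, config: FitConfig) -> np.ndarray:
    x = []
    for name in config.param_names:
        lo, hi = config.bounds[name]
        if name == "p_cw":
            p = rng.uniform(0.3, 0.7)
            x.append(np.log(p / (1 - p)))
        else:
            x.append(rng.uniform(np.log(lo * 1.5), np.log(hi / 1.5)))
    return np.array(x)


def fit_correct_trials(
    correct_table: TrialTable,
    all_trials_table: TrialTable,
    config: FitConfig,
) -> FitResult:
    """Nelder-Mead joint fit with random restarts; deterministic given the seed."""
    if len(correct_table) == 0 or len(all_trials_table) == 0:
        raise ValueError("fit requires non-empty correct and all-trials tables")
    grid = config.make_grid()
    rng = np.random.default_rng(config.seed)
    prepared = _prepare_tables(correct_table, all_trials_table)
    cache: dict[tuple, float] = {}

    def objective(x: np.ndarray) -> float:
        key = tuple(np.round(x, 10))
        if key in cache:
            return cache[key]
        params, penalty = _vec_to_params(x, config)
        val = _nll_prepared(params, prepared, grid) + penalty
        cache[key] = val
        return val

    restarts = []
    best = None
    for r in range(config.n_restarts):
        x0 = _random_init(rng, config)
        res = minimize(
            objective,
            x0,
            method="Nelder-Mead",
            options={
                "xatol": config.xatol,
                "fatol": config.fatol,
                "maxiter": config.maxiter,
                "maxfev": 4 * config.maxiter,
            },
        )
        params, _ = _vec_to_params(res.x, config)
        init_params, _ = _vec_to_params(x0, config)
        record = {
            "restart": r,
            "init": init_params.to_dict(),
            "final": params.to_dict(),
            "nll": float(res.fun),
            "converged": bool(res.success),
            "n_evals": int(res.nfev),
        }
        restarts.append(record)
        if res.success and (best is None or res.fun < best[0]):
            best = (float(res.fun), params)
    if best is None:
        raise FitFailureError(
            f"none of {config.n_restarts} restarts converged; "
            f"best nll values: {sorted(r['nll'] for r in restarts)[:3]}"
        )
    return FitResult(best_params=best[1], nll=best[0], restarts=restarts, config=config)
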