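"""Parameter-free prediction of incorrect trials and model comparison.

All five post-feedback variants are evaluated on incorrect trials using
parameters fitted to correct trials only — no free parameters remain.  Model
log-likelihoods are normalised between the prior-only model (1a, score 0)
and an "omniscient" empirical bound (score 1) built from the data's own
0.5-deg bin frequencies per condition.  Uncertainty comes from a stratified
bootstrap (resampling trials with replacement within each orientation x
noise condition).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data import TrialTable
from .grid import DEFAULT_GRID, OrientationGrid
from .observer import BIN_WIDTH, EmptyConditionError, ObserverEngine, PredictiveDistribution
from .params import ObserverParams

__all__ = [
    "ComparisonReport",
    "predict_incorrect",
    "table_loglik",
    "omniscient_loglik",
    "normalized_loglik",
    "bootstrap_ci",
    "mean_estimate_summary",
    "asymmetry_statistic",
    "compare_models",
    "CoverageError",
]

PROB_FLOOR = 1e-6  # shared with fitting for comparability


class CoverageError(ValueError):
    """An estimate falls outside the predictive bin range."""


def _conditions(df: pd.DataFrame):
    return df.groupby(["theta_deg", "noise_level"], sort=True)


def predict_incorrect(
    params: ObserverParams,
    incorrect_table: TrialTable,
    model_id: str,
    grid: OrientationGrid = DEFAULT_GRID,
) -> dict[tuple[float, str], PredictiveDistribution]:
    """One binned predictive distribution per condition present in the table.

    ``params`` come from the correct-trial fit; the predictions are
    parameter-free.  Conditions whose incorrect-choice probability is
    essentially zero raise :class:`EmptyConditionError`.
    """
    engine = ObserverEngine(params, grid)
    out = {}
    for (theta, level), _ in _conditions(incorrect_table.df):
        out[(float(theta), level)] = engine.predictive(
            float(theta), level, model_id=model_id, correctness="incorrect"
        )
    return out


def table_loglik(
    distribution_set: dict[tuple[float, str], PredictiveDistribution],
    incorrect_table: TrialTable,
) -> float:
    """Sum of log model probabilities of each estimate's 0.5-deg bin."""
    ll = 0.0
    for (theta, level), g in _conditions(incorrect_table.df):
        dist = distribution_set[(float(theta), level)]
        est = g["estimate_deg"].to_numpy(dtype=float)
        if est.size and (est.min() < dist.bin_edges[0] or est.max() >= dist.bin_edges[-1]):
            raise CoverageError(
                f"estimate outside the predictive bin range at theta={theta}, {level}"
            )
        probs = dist.prob_of(est)
        ll += float(np.log(np.maximum(probs, PROB_FLOOR)).sum())
    return ll


def omniscient_loglik(incorrect_table: TrialTable) -> float:
    """In-sample log-likelihood of the empirical bin frequencies.

    Per condition, estimates are binned at 0.5 deg and each trial contributes
    the log frequency of its own bin — the "data explaining themselves"
    upper bound (a trial's own bin frequency is always positive).
    """
    ll = 0.0
    for _, g in _conditions(incorrect_table.df):
        est = g["estimate_deg"].to_numpy(dtype=float)
        bins = np.floor(est / BIN_WIDTH).astype(int)
        _, inverse, counts = np.unique(bins, return_inverse=True, return_counts=True)
        freq = counts[inverse] / est.size
        ll += float(np.log(freq).sum())
    return ll


def normalized_loglik(ll_model: float, ll_1a: float, ll_omni: float) -> float:
    """(LL_model - LL_1a) / (LL_omni - LL_1a): Model 1a at 0, the bound at 1."""
    denom = ll_omni - ll_1a
    if denom <= 0:
        raise ValueError("degenerate normalisation: omniscient LL must exceed Model 1a's")
    return (ll_model - ll_1a) / denom


def bootstrap_ci(
    statistic,
    table: TrialTable,
    n_boot: int = 200,
    seed: int = 0,
    ci: float = 0.95,
) -> tuple[float, float, float]:
    """Stratified bootstrap percentile interval of ``statistic(table)``.

    Trials are resampled with replacement within each (orientation, noise)
    condition so sparse conditions are never lost.  The percentile interval
    is widened, if necessary, to cover the point estimate (percentile
    intervals of nonlinear statistics — e.g. scores normalised by the
    in-sample omniscient bound — can otherwise exclude it).
    """
    point = float(statistic(table))
    rng = np.random.default_rng(seed)
    df = table.df
    groups = [g.index.to_numpy() for _, g in _conditions(df)]
    vals = np.empty(n_boot)
    for b in range(n_boot):
        idx = np.concatenate([rng.choice(g, size=g.size, replace=True) for g in groups])
        vals[b] = statistic(TrialTable(df.loc[idx].reset_index(drop=True), table.metadata))
    alpha = (1.0 - ci) / 2.0
    lo, hi = np.quantile(vals, [alpha, 1.0 - alpha])
    return point, min(float(lo), point), max(float(hi), point)


def mean_estimate_summary(
    incorrect_table: TrialTable,
    distribution_sets: dict[str, dict[tuple[float, str], PredictiveDistribution]],
) -> pd.DataFrame:
    """Per-condition data means vs model means, with global MSE and Pearson R.

    Returns a tidy DataFrame with one row per (condition, model); the
    ``mse``/``pearson_r`` columns repeat the pooled statistics per model
    (``pearson_r`` is null with fewer than 3 conditions).
    """
    rows = []
    cond_means = {
        (float(theta), level): float(g["estimate_deg"].mean())
        for (theta, level), g in _conditions(incorrect_table.df)
    }
    for model_id, dists in distribution_sets.items():
        data_m = np.array([cond_means[k] for k in sorted(cond_means)])
        model_m = np.array([dists[k].mean for k in sorted(cond_means)])
        mse = float(np.mean((data_m - model_m) ** 2))
        if data_m.size >= 3 and np.std(model_m) > 0 and np.std(data_m) > 0:
            r = float(np.corrcoef(data_m, model_m)[0, 1])
        else:
            r = None
        for k, dm, mm in zip(sorted(cond_means), data_m, model_m):
            rows.append(
                {
                    "model_id": model_id,
                    "theta_deg": k[0],
                    "noise_level": k[1],
                    "data_mean": dm,
                    "model_mean": mm,
                    "mse": mse,
                    "pearson_r": r,
                }
            )
    return pd.DataFrame(rows)


def asymmetry_statistic(incorrect_table: TrialTable) -> tuple[float, float, float]:
    """Mean |estimate| on the cw vs ccw side and their difference (deg).

    Sides are defined by the feedback-corrected category (the flip of the
    choice on incorrect trials).  Captures the asymmetric-prior signature:
    estimates repulsed further on the wide-prior (cw) side.
    """
    df = incorrect_table.df
    choice_cw = df["choice"].astype(str).str.lower() == "cw"
    correct = df["choice_correct"].to_numpy(dtype=bool)
    cat_f_cw = np.where(correct, choice_cw, ~choice_cw)
    est = np.abs(df["estimate_deg"].to_numpy(dtype=float))
    if not cat_f_cw.any() or cat_f_cw.all():
        raise ValueError("asymmetry statistic needs incorrect trials on both sides")
    cw_mean = float(est[cat_f_cw].mean())
    ccw_mean = float(est[~cat_f_cw].mean())
    return cw_mean, ccw_mean, cw_mean - ccw_mean


@dataclass
class ComparisonReport:
    """Per-model log-likelihoods, normalised scores and summary statistics."""

    models: list
    loglik: dict
    loglik_1a: float
    loglik_omniscient: float
    normalized: dict
    normalized_ci: dict = field(default_factory=dict)
    mean_summary: pd.DataFrame | None = None
    asymmetry: tuple | None = None
    asymmetry_ci: tuple | None = None
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {
            "models": self.models,
            "loglik": self.loglik,
            "loglik_1a": self.loglik_1a,
            "loglik_omniscient": self.loglik_omniscient,
            "normalized": self.normalized,
            "normalized_ci": self.normalized_ci,
            "asymmetry": self.asymmetry,
            "asymmetry_ci": self.asymmetry_ci,
            "metadata": self.metadata,
        }
        if self.mean_summary is not None:
            out["mean_summary"] = self.mean_summary.to_dict(orient="records")
        return out

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


def compare_models(
    params: ObserverParams,
    incorrect_table: TrialTable,
    models: tuple[str, ...] = ("1a", "1b", "2a", "2b", "2c"),
    grid: OrientationGrid = DEFAULT_GRID,
    n_boot: int = 200,
    seed: int = 0,
    with_asymmetry: bool = False,
) -> ComparisonReport:
    """Full comparison pipeline on one subject's incorrect trials."""
    models = list(dict.fromkeys(["1a", *models]))  # 1a always needed as anchor
    dist_sets: dict[str, dict] = {}
    for mid in models:
        try:
            dist_sets[mid] = predict_incorrect(params, incorrect_table, mid, grid)
        except EmptyConditionError:
            # drop conditions that the model deems impossible for every model alike
            raise
    ll = {mid: table_loglik(dist_sets[mid], incorrect_table) for mid in models}
    ll_omni = omniscient_loglik(incorrect_table)
    norm = {mid: normalized_loglik(ll[mid], ll["1a"], ll_omni) for mid in models}
    norm["omniscient"] = 1.0

    norm_ci = {}
    for mid in models:

        def stat(tbl, _mid=mid):
            return normalized_loglik(
                table_loglik(dist_sets[_mid], tbl),
                table_loglik(dist_sets["1a"], tbl),
                omniscient_loglik(tbl),
            )

        norm_ci[mid] = bootstrap_ci(stat, incorrect_table, n_boot=n_boot, seed=seed)

    summary = mean_estimate_summary(incorrect_table, dist_sets)
    asym = asym_ci = None
    if with_asymmetry:
        asym = asymmetry_statistic(incorrect_table)
        asym_ci = bootstrap_ci(
            lambda t: asymmetry_statistic(t)[2], incorrect_table, n_boot=n_boot, seed=seed
        )
    return ComparisonReport(
        models=models,
        loglik=ll,
        loglik_1a=ll["1a"],
        loglik_omniscient=ll_omni,
        normalized=norm,
        normalized_ci=norm_ci,
        mean_summary=summary,
        asymmetry=asym,
        asymmetry_ci=asym_ci,
        metadata={"n_boot": n_boot, "seed": seed, "params": params.to_dict()},
    )
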