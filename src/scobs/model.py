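"""Model / Results interface over the fitting and comparison machinery.

`SelfConsistentObserver` is constructed from a trial table (DataFrame or
CSV); `fit()` runs the joint maximum-likelihood estimation and returns an
`ObserverResults` carrying the estimates, the per-restart record, a text
`summary()`, parameter-free predictions for incorrect trials, and the model
comparison against the omniscient bound.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .compare import ComparisonReport, compare_models
from .data import TrialTable, split_and_filter
from .fitting import FitConfig, FitResult, fit_correct_trials, joint_nll
from .grid import DEFAULT_GRID, OrientationGrid
from .observer import ObserverEngine, PredictiveDistribution
from .params import ObserverParams

__all__ = ["SelfConsistentObserver", "ObserverResults"]


class SelfConsistentObserver:
    """Self-consistent Bayesian observer fitted to one subject's trials.

    Parameters
    ----------
    trials : TrialTable or pandas.DataFrame
        All trials of one subject (the split into correct / incorrect and
        the consistency filter are applied internally).
    experiment : {'exp1', 'exp2'}
        Symmetric mode shares the prior width across sides and fixes the
        category prior at 0.5; asymmetric mode frees both.
    sigma_0 : float
        Motor noise (deg), measured independently; never fitted.
    """

    def __init__(
        self,
        trials,
        experiment: str | None = None,
        sigma_0: float = 1.5,
        grid: OrientationGrid = DEFAULT_GRID,
    ):
        if isinstance(trials, pd.DataFrame):
            trials = TrialTable(trials, {})
        self.trials = trials
        if experiment is None:
            experiment = trials.metadata.get("experiment_id") or str(
                trials.df["experiment_id"].iloc[0]
            )
        self.experiment = experiment
        self.sigma_0 = float(sigma_0)
        self.grid = grid
        self.correct, self.incorrect, self.excluded, self.filter_report = split_and_filter(
            trials
        )

    @classmethod
    def from_csv(cls, path, **kwargs) -> "SelfConsistentObserver":
        from .data import read_trials

        return cls(read_trials(path), **kwargs)

    def loglike(self, params: ObserverParams) -> float:
        """Joint log-likelihood at ``params`` (decision + correct-trial estimates)."""
        return -joint_nll(params, self.correct, self.trials, self.grid)

    def fit(self, config: FitConfig | None = None, **overrides) -> "ObserverResults":
        if config is None:
            config = FitConfig(experiment=self.experiment, sigma_0=self.sigma_0)
        for k, v in overrides.items():
            setattr(config, k, v)
        config.experiment = self.experiment
        config.sigma_0 = self.sigma_0
        fit = fit_correct_trials(self.correct, self.trials, config)
        return ObserverResults(self, fit)


class ObserverResults:
    """Results of the joint fit; predictions and comparisons hang off it."""

    def __init__(self, model: SelfConsistentObserver, fit: FitResult):
        self.model = model
        self.fit_result = fit
        self.params: ObserverParams = fit.best_params
        self.nll: float = fit.nll
        self._engine = ObserverEngine(self.params, model.grid)

    @property
    def loglike(self) -> float:
        return -self.nll

    def predict(
        self,
        theta: float,
        noise_level: str,
        model_id: str = "selfconsistent",
        correctness: str = "correct",
    ) -> PredictiveDistribution:
        """Binned predictive estimate distribution for one condition."""
        return self._engine.predictive(theta, noise_level, model_id, correctness)

    def psychometric(self, theta, noise_level: str):
        return self._engine.psychometric(theta, noise_level)

    def compare(
        self,
        models: tuple[str, ...] = ("1a", "1b", "2a", "2b", "2c"),
        n_boot: int = 200,
        seed: int = 0,
    ) -> ComparisonReport:
        """Parameter-free model comparison on this subject's incorrect trials."""
        return compare_models(
            self.params,
            self.model.incorrect,
            models=models,
            grid=self.model.grid,
            n_boot=n_boot,
            seed=seed,
            with_asymmetry=self.model.experiment == "exp2",
        )

    def summary(self) -> str:
        """Plain-text summary of the fit."""
        p = self.params
        cfg = self.fit_result.config
        n_conv = sum(1 for r in self.fit_result.restarts if r["converged"])
        rows = [
            ("sigma_s (low noise)", p.sigma_s_low, "deg"),
            ("sigma_s (high noise)", p.sigma_s_high, "deg"),
            ("sigma_m (memory)", p.sigma_m, "deg"),
            ("alpha_cw (prior width)", p.alpha_cw, "deg"),
            ("alpha_ccw (prior width)", p.alpha_ccw, "deg"),
            ("beta (roll-off)", p.beta, "deg"),
            ("p(C = cw)", p.p_cw, "fixed" if cfg.experiment == "exp1" else ""),
            ("sigma_0 (motor, fixed)", p.sigma_0, "deg"),
        ]
        lines = [
            "Self-consistent Bayesian observer — joint ML fit",
            "=" * 52,
            f"experiment mode:    {cfg.experiment}",
            f"trials (all/correct/incorrect/excluded): "
            f"{self.model.filter_report['n_trials']}/"
            f"{self.model.filter_report['n_correct']}/"
            f"{self.model.filter_report['n_incorrect']}/"
            f"{self.model.filter_report['n_excluded']}",
            f"negative log-likelihood: {self.nll:.3f}",
            f"restarts converged: {n_conv}/{len(self.fit_result.restarts)}",
            "-" * 52,
            f"{'parameter':<26}{'estimate':>12}  unit",
        ]
        for name, val, unit in rows:
            lines.append(f"{name:<26}{val:>12.4f}  {unit}")
        lines.append("=" * 52)
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        return f"<ObserverResults nll={self.nll:.2f} params={self.params}>"
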