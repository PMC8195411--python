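"""Experimental designs, synthetic subjects, and trial-table I/O.

Two orientation-judgment designs are modelled.  Experiment 1 is symmetric:
orientations -21..21 deg in steps of 3 (15 values), stimulus-noise widths
(3, 18) deg.  Experiment 2 is asymmetric: [-12, 0] in steps of 2 on the ccw
side and [0, 30] in steps of 5 on the cw side (13 distinct values, 0 counted
once), noise widths (6, 18) deg.  Each (orientation x noise) condition is
repeated 70 times by default, giving 2100 / 1820 trials.

A synthetic subject runs the generative observer forward on every trial:
measurement -> categorical choice -> (valid) feedback -> memory recall ->
conditioned posterior-mean estimate -> motor noise.  On incorrect trials the
estimate is conditioned on the feedback-corrected category; under the
``2b-resampled`` generative variant, memory recall additionally resamples
until the sample lies on the feedback-corrected side (the number of draws is
kept as a response-time proxy).  An optional lapse probability replaces the
estimate with a uniform draw over the design range, injecting the
inconsistent trials that the exclusion filter is meant to catch.

Trial tables round-trip through plain CSV with a JSON metadata comment line.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .grid import DEFAULT_GRID, OrientationGrid
from .observer import ObserverEngine, resample_memory
from .params import ObserverParams
from .priors import CategoryLabel

__all__ = [
    "ExperimentDesign",
    "TrialTable",
    "SchemaError",
    "build_design",
    "simulate_subject",
    "write_trials",
    "read_trials",
    "split_and_filter",
    "default_params",
    "REQUIRED_COLUMNS",
]

GENERATING_MODELS = ("selfconsistent", "2b-resampled")

REQUIRED_COLUMNS = [
    "subject_id",
    "experiment_id",
    "trial_index",
    "theta_deg",
    "noise_level",
    "sigma_s_deg",
    "true_category",
    "choice",
    "choice_correct",
    "estimate_deg",
]
OPTIONAL_COLUMNS = ["consistent", "m", "m_m", "n_draws"]


class SchemaError(ValueError):
    """A trial CSV is missing a mandatory column or holds unparseable values."""


@dataclass(frozen=True)
class ExperimentDesign:
    """Factorial design of one experiment."""

    experiment_id: str
    orientations: tuple[float, ...]
    noise_sigmas: tuple[float, float]  # (low, high) stimulus-noise widths, deg
    repetitions: int = 70
    randomized_order: bool = True

    @property
    def n_trials(self) -> int:
        return len(self.orientations) * 2 * self.repetitions

    @property
    def noise_levels(self) -> tuple[str, str]:
        return ("low", "high")


def _design_orientations(experiment_id: str) -> tuple[float, ...]:
    if experiment_id == "exp1":
        return tuple(float(x) for x in range(-21, 22, 3))
    if experiment_id == "exp2":
        ccw = [float(x) for x in range(-12, 1, 2)]
        cw = [float(x) for x in range(5, 31, 5)]
        return tuple(ccw + cw)
    raise ValueError(f"unknown experiment_id {experiment_id!r} (expected 'exp1'/'exp2')")


def build_design(
    experiment_id: str, repetitions: int = 70, seed: int | None = None
) -> tuple[ExperimentDesign, pd.DataFrame]:
    """Build the full-factorial trial list, shuffled by ``seed``.

    Returns the design and a DataFrame with one row per trial
    (columns ``theta_deg``, ``noise_level``, ``sigma_s_deg``).
    """
    if repetitions < 1:
        raise ValueError("repetitions must be >= 1")
    orientations = _design_orientations(experiment_id)
    sigmas = (3.0, 18.0) if experiment_id == "exp1" else (6.0, 18.0)
    design = ExperimentDesign(experiment_id, orientations, sigmas, repetitions)
    rows = [
        (theta, level, sigma)
        for theta in orientations
        for level, sigma in zip(("low", "high"), sigmas)
        for _ in range(repetitions)
    ]
    df = pd.DataFrame(rows, columns=["theta_deg", "noise_level", "sigma_s_deg"])
    if seed is not None:
        rng = np.random.default_rng(seed)
        df = df.iloc[rng.permutation(len(df))].reset_index(drop=True)
    return design, df


@dataclass
class TrialTable:
    """One subject's trials plus generation metadata."""

    df: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.df)

    def copy(self) -> "TrialTable":
        return TrialTable(self.df.copy(), dict(self.metadata))


def default_params(experiment_id: str, sigma_0: float = 1.5, lapse: float = 0.0) -> ObserverParams:
    """Reference generative parameters for each design.

    Sensory noise matches the stimulus-noise widths; memory noise 4 deg and
    motor noise 1.5 deg are typical of trained observers in this task; the
    prior plateau matches the true orientation range (24 deg, slightly wider
    than the symmetric range; 30 cw / 12 ccw for the asymmetric design) with
    an 8-deg roll-off.
    """
    if experiment_id == "exp1":
        return ObserverParams.symmetric(3.0, 18.0, 4.0, 24.0, 8.0, sigma_0=sigma_0, lapse=lapse)
    if experiment_id == "exp2":
        return ObserverParams(
            sigma_s_low=6.0,
            sigma_s_high=18.0,
            sigma_m=4.0,
            alpha_cw=30.0,
            alpha_ccw=12.0,
            beta=8.0,
            p_cw=0.5,
            sigma_0=sigma_0,
            lapse=lapse,
        )
    raise ValueError(f"unknown experiment_id {experiment_id!r}")


def simulate_subject(
    params: ObserverParams,
    design: ExperimentDesign,
    generating_model: str = "selfconsistent",
    seed: int = 0,
    subject_id: str = "S1",
    grid: OrientationGrid = DEFAULT_GRID,
) -> TrialTable:
    """Simulate one synthetic subject through the full design.

    Per trial: m ~ N(theta, sigma_s); the choice is the MAP category
    (threshold m* in m); feedback is always valid; memory recall is
    m_m ~ N(m, sigma_m), or a conditioned resample after negative feedback
    when ``generating_model='2b-resampled'``; the estimate is the posterior
    mean under the feedback-corrected conditioned prior plus motor noise.
    """
    if generating_model not in GENERATING_MODELS:
        raise ValueError(f"unknown generating_model {generating_model!r}")
    rng = np.random.default_rng(seed)
    _, trials = build_design(design.experiment_id, design.repetitions, seed=seed)

    engine = ObserverEngine(params, grid)
    theta = trials["theta_deg"].to_numpy(dtype=float)
    level = trials["noise_level"].to_numpy()
    n = len(trials)
    sigma_s = np.where(level == "low", params.sigma_s_low, params.sigma_s_high)

    m = theta + sigma_s * rng.standard_normal(n)
    mstar = {lv: engine.criterion(lv) for lv in ("low", "high")}
    crit = np.array([mstar[lv] for lv in level])
    choice_cw = m > crit
    ties = m == crit
    if ties.any():
        choice_cw[ties] = rng.random(ties.sum()) < 0.5

    # true category: sign of theta; a fair coin at the reference
    true_cw = theta > 0
    at_ref = theta == 0
    if at_ref.any():
        true_cw[at_ref] = rng.random(at_ref.sum()) < 0.5
    correct = choice_cw == true_cw

    # estimation category: the observer's choice on correct trials, the
    # feedback-corrected category (= true category) otherwise
    est_cw = np.where(correct, choice_cw, true_cw)

    m_m = m + params.sigma_m * rng.standard_normal(n)
    n_draws = np.ones(n, dtype=int)
    if generating_model == "2b-resampled":
        for i in np.nonzero(~correct)[0]:
            cat_f = CategoryLabel.CW if true_cw[i] else CategoryLabel.CCW
            m_m[i], n_draws[i] = resample_memory(
                m[i], sigma_s[i], params.sigma_m, cat_f, rng
            )

    estimate = np.empty(n)
    for lv in ("low", "high"):
        sig_like = params.sigma_like_for(lv)
        for cat, is_cw in ((CategoryLabel.CW, True), (CategoryLabel.CCW, False)):
            sel = (level == lv) & (est_cw == is_cw)
            if sel.any():
                from .observer import _posterior_mean_given_mm

                estimate[sel] = _posterior_mean_given_mm(
                    m_m[sel], engine.prior(cat), sig_like, grid
                )
    estimate = estimate + params.sigma_0 * rng.standard_normal(n)

    if params.lapse > 0:
        lapses = rng.random(n) < params.lapse
        lo, hi = min(design.orientations), max(design.orientations)
        estimate[lapses] = rng.uniform(lo, hi, lapses.sum())

    cat_f_cw = est_cw  # feedback-corrected category coincides with the estimation category
    consistent = (estimate == 0.0) | (np.sign(estimate) == np.where(cat_f_cw, 1.0, -1.0))

    df = pd.DataFrame(
        {
            "subject_id": subject_id,
            "experiment_id": design.experiment_id,
            "trial_index": np.arange(n),
            "theta_deg": theta,
            "noise_level": level,
            "sigma_s_deg": sigma_s,
            "true_category": np.where(true_cw, "cw", "ccw"),
            "choice": np.where(choice_cw, "cw", "ccw"),
            "choice_correct": correct,
            "estimate_deg": estimate,
            "consistent": consistent,
            "m": m,
            "m_m": m_m,
            "n_draws": n_draws,
        }
    )
    metadata = {
        "subject_id": subject_id,
        "experiment_id": design.experiment_id,
        "repetitions": design.repetitions,
        "generating_model": generating_model,
        "seed": int(seed),
        "params": params.to_dict(),
    }
    return TrialTable(df, metadata)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_trials(table: TrialTable, path) -> None:
    """Write a trial table as CSV with a ``#``-prefixed JSON metadata line."""
    path = Path(path)
    buf = io.StringIO()
    buf.write("# " + json.dumps(table.metadata, sort_keys=True) + "\n")
    table.df.to_csv(buf, index=False, float_format="%.9g")
    path.write_text(buf.getvalue())


def read_trials(path) -> TrialTable:
    """Read a trial CSV; missing generator fields load as nulls."""
    path = Path(path)
    metadata: dict = {}
    with path.open() as fh:
        first = fh.readline()
    if first.startswith("#"):
        try:
            metadata = json.loads(first.lstrip("# ").strip() or "{}")
        except json.JSONDecodeError:
            metadata = {}
    df = pd.read_csv(path, comment="#")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"trial table missing mandatory column(s): {', '.join(missing)}")
    for col in ("theta_deg", "estimate_deg", "sigma_s_deg"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any():
            raise SchemaError(
                f"non-numeric value in column {col!r} at row(s) {list(df.index[bad][:5])}"
            )
        df[col] = vals.astype(float)
    for col in OPTIONAL_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    for col in ("m", "m_m"):
        df[col] = pd.to_numeric(df[col], errors="coerce").astype(float)
    if df["choice_correct"].dtype == object:
        df["choice_correct"] = df["choice_correct"].astype(str).str.lower().map(
            {"true": True, "false": False}
        )
    df["choice_correct"] = df["choice_correct"].astype(bool)
    return TrialTable(df, metadata)


# ---------------------------------------------------------------------------
# correct / incorrect split with the consistency filter
# ---------------------------------------------------------------------------

def split_and_filter(table: TrialTable):
    """Split trials into correct / incorrect and drop inconsistent estimates.

    A trial is inconsistent when the sign of the estimate conflicts with the
    feedback-corrected category (the choice on correct trials, its flip on
    incorrect trials); an estimate of exactly 0 is never flagged.  Returns
    ``(correct_table, incorrect_table, excluded_table, report)``.
    """
    df = table.df
    choice_cw = df["choice"].astype(str).str.lower() == "cw"
    correct = df["choice_correct"].to_numpy(dtype=bool)
    cat_f_cw = np.where(correct, choice_cw, ~choice_cw)
    est = df["estimate_deg"].to_numpy(dtype=float)
    consistent = (est == 0.0) | (np.sign(est) == np.where(cat_f_cw, 1.0, -1.0))

    meta = dict(table.metadata)
    correct_t = TrialTable(df[correct & consistent].reset_index(drop=True), meta)
    incorrect_t = TrialTable(df[~correct & consistent].reset_index(drop=True), meta)
    excluded_t = TrialTable(df[~consistent].reset_index(drop=True), meta)
    report = {
        "n_trials": int(len(df)),
        "n_correct": int(len(correct_t)),
        "n_incorrect": int(len(incorrect_t)),
        "n_excluded": int(len(excluded_t)),
        "excluded_fraction": float((~consistent).mean()) if len(df) else 0.0,
    }
    return correct_t, incorrect_t, excluded_t, report
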