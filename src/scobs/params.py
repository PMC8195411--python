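"""Observer parameter container.

The observer is parameterised by sensory noise per stimulus-noise level
(sigma_s), working-memory noise (sigma_m), the conditioned-prior shape
(alpha plateau half-widths per category, shared roll-off beta), the category
prior p(C=cw), and motor noise sigma_0.  sigma_0 is measured independently
(motor-training data) and is never fitted.  A lapse probability is carried
for the simulator only (it injects inconsistent trials); the fitted model
has no lapse parameter — inconsistent trials are excluded instead.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace

import numpy as np

__all__ = ["ObserverParams"]

_NOISE_LEVELS = ("low", "high")


@dataclass(frozen=True)
class ObserverParams:
    """All generative / fitted parameters of the observer (degrees).

    ``alpha_cw`` / ``alpha_ccw`` are the plateau widths of the conditioned
    prior on each side of the reference; in Experiment-1 (symmetric) mode
    they are equal and ``p_cw`` is 0.5.
    """

    sigma_s_low: float
    sigma_s_high: float
    sigma_m: float
    alpha_cw: float
    alpha_ccw: float
    beta: float
    p_cw: float = 0.5
    sigma_0: float = 0.0
    lapse: float = 0.0

    def __post_init__(self) -> None:
        for name in ("sigma_s_low", "sigma_s_high", "alpha_cw", "alpha_ccw"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and > 0, got {v}")
        for name in ("sigma_m", "beta", "sigma_0"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")
        for name in ("p_cw", "lapse"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")

    @classmethod
    def symmetric(
        cls,
        sigma_s_low: float,
        sigma_s_high: float,
        sigma_m: float,
        alpha: float,
        beta: float,
        sigma_0: float = 0.0,
        lapse: float = 0.0,
    ) -> "ObserverParams":
        """Experiment-1 style parameters: shared alpha, p_cw fixed at 0.5."""
        return cls(
            sigma_s_low=sigma_s_low,
            sigma_s_high=sigma_s_high,
            sigma_m=sigma_m,
            alpha_cw=alpha,
            alpha_ccw=alpha,
            beta=beta,
            p_cw=0.5,
            sigma_0=sigma_0,
            lapse=lapse,
        )

    def sigma_s(self, noise_level: str) -> float:
        if noise_level == "low":
            return self.sigma_s_low
        if noise_level == "high":
            return self.sigma_s_high
        raise KeyError(f"unknown noise level {noise_level!r} (expected 'low'/'high')")

    @property
    def sigma_like(self) -> float:
        """Width of the memory-sample likelihood, sqrt(sigma_s^2 + sigma_m^2) per level."""
        raise AttributeError("use sigma_like_for(noise_level)")

    def sigma_like_for(self, noise_level: str) -> float:
        s = self.sigma_s(noise_level)
        return float(np.hypot(s, self.sigma_m))

    def alpha(self, category) -> float:
        from .priors import CategoryLabel

        return self.alpha_cw if category == CategoryLabel.CW else self.alpha_ccw

    @property
    def is_symmetric(self) -> bool:
        return self.alpha_cw == self.alpha_ccw and self.p_cw == 0.5

    def replace(self, **kwargs) -> "ObserverParams":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ObserverParams":
        return cls(**d)
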