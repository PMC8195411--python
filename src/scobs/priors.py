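"""Category labels and the conditioned stimulus prior p(theta | C).

The conditioned prior is one-sided: flat at height 1/(alpha + beta/2) on the
plateau [0, alpha] away from the reference (in category-signed coordinates),
then falls to zero over (alpha, alpha + beta] with a raised-cosine roll-off

    p(theta) ~ 0.5 * (1 + cos(pi * (|theta| - alpha) / beta)),

and is exactly zero on the opposite side of the reference and beyond
alpha + beta.  The raised cosine halves the roll-off area, hence the plateau
height.  After discretisation onto the grid the density is renormalised so
the trapezoidal integral is exactly 1.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from .grid import OrientationGrid

__all__ = ["CategoryLabel", "ConditionedPrior", "make_conditioned_prior", "SupportTruncationError"]


class CategoryLabel(enum.Enum):
    """Stimulus category relative to the reference: clockwise is positive."""

    CW = "cw"
    CCW = "ccw"

    def flip(self) -> "CategoryLabel":
        return CategoryLabel.CCW if self is CategoryLabel.CW else CategoryLabel.CW

    @property
    def sign(self) -> int:
        return +1 if self is CategoryLabel.CW else -1

    @classmethod
    def of_orientation(cls, theta: float) -> "CategoryLabel":
        """Category of a nonzero orientation (theta = 0 has no category)."""
        if theta == 0:
            raise ValueError("theta = 0 lies on the reference; category is assigned at random")
        return cls.CW if theta > 0 else cls.CCW

    @classmethod
    def parse(cls, text: str) -> "CategoryLabel":
        return cls(str(text).lower())


class SupportTruncationError(ValueError):
    """The quadrature grid does not cover the prior's support."""


def _raised_cosine_profile(
    signed: np.ndarray, alpha: float, beta: float, halve_jumps: bool = False
) -> np.ndarray:
    """Unnormalised prior profile in category-signed coordinates (>=0 side).

    With ``halve_jumps`` the density discontinuities (the reference at 0 and,
    for beta = 0, the outer box edge) take their midpoint value, which makes
    trapezoidal quadrature of the discretised prior second-order accurate.
    """
    out = np.zeros_like(signed)
    plateau = (signed >= 0.0) & (signed <= alpha)
    out[plateau] = 1.0
    if beta > 0:
        roll = (signed > alpha) & (signed <= alpha + beta)
        out[roll] = 0.5 * (1.0 + np.cos(np.pi * (signed[roll] - alpha) / beta))
    if halve_jumps:
        out[signed == 0.0] = 0.5
        if beta == 0:
            out[signed == alpha] = 0.5
    return out


@dataclass(frozen=True)
class ConditionedPrior:
    """Discretised conditioned prior p(theta | C) on an orientation grid."""

    category: CategoryLabel
    alpha: float
    beta: float
    grid: OrientationGrid
    density: np.ndarray = field(repr=False, compare=False)

    @property
    def support(self) -> np.ndarray:
        """Boolean mask of grid nodes with nonzero density."""
        return self.density > 0.0

    @property
    def mean(self) -> float:
        """Prior mean — the Model 1a (prior only) estimate."""
        return self.grid.integrate(self.grid.theta * self.density)

    def pdf(self, theta) -> np.ndarray:
        """Continuous (pre-renormalisation scale matched) density at ``theta``."""
        signed = self.category.sign * np.asarray(theta, dtype=float)
        prof = _raised_cosine_profile(signed, self.alpha, self.beta)
        # match the discrete renormalisation so grid and off-grid values agree
        scale = self.density.max() if self.density.size else 1.0
        return prof * scale


def make_conditioned_prior(
    category: CategoryLabel,
    alpha: float,
    beta: float,
    grid: OrientationGrid,
) -> ConditionedPrior:
    """Build the discretised conditioned prior for one category.

    Raises
    ------
    SupportTruncationError
        If the grid does not cover [-(alpha+beta), alpha+beta].
    """
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    if beta < 0:
        raise ValueError("beta must be >= 0")
    if not grid.covers(-(alpha + beta), alpha + beta):
        raise SupportTruncationError(
            f"grid [{grid.lo}, {grid.hi}] does not cover the prior support "
            f"+/-{alpha + beta:g} deg"
        )
    signed = category.sign * grid.theta
    density = _raised_cosine_profile(signed, alpha, beta, halve_jumps=True) / (
        alpha + beta / 2.0
    )
    total = grid.integrate(density)
    density = density / total
    return ConditionedPrior(category=category, alpha=alpha, beta=beta, grid=grid, density=density)
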